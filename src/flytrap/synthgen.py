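"""Synthetic sticky-trap scene generator with exact ground truth.

Real e-trap imagery of *Bactrocera oleae* on yellow adhesive panels is
scarce, so every downstream stage (segmentation, localization,
classification, evaluation) is exercised on synthetic scenes that emulate
the statistical structure of trap photographs: a yellow panel under a
variable illumination gradient, dark elliptical insects of two classes,
and non-insect distractors (attractant bag, panel holes, shadows, printed
glyph strokes).  Every planted element is reported in the ground truth
with a pixel bounding box, a three-way label and a stable element id, so
detector recall and classifier accuracy can be scored exactly.

Morphology proxy
----------------
The two fly classes are separated by tunable morphometry rather than any
claim about real *B. oleae* appearance: olive flies are rendered as dark
ellipses with full major axis 14-20 px (at the nominal 1600x1200 frame),
aspect ratio 2.2-3.0 and a light wing-spot mark; other flies span a wider
size range (8-30 px), are rounder (aspect 1.2-2.0) and carry no mark.

Determinism: a fixed seed yields bit-identical images and annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
from skimage import draw as skdraw

from .core import (
    LABELS3,
    AnnotationError,
    BoundingBox,
    PlacementError,
    TrapImage,
)

#: Base trap-panel colour (RGB, unit scale): yellow, red and green well above blue.
PANEL_RGB = (0.85, 0.78, 0.22)
#: Background outside the panel when the trap does not fill the frame.
SURROUND_RGB = (0.45, 0.44, 0.42)

#: All distractor shapes the generator knows how to draw.
DISTRACTOR_KINDS = ("bag", "hole", "shadow", "glyph")

_MAX_PLACEMENT_ATTEMPTS = 200


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic trap scene.

    Defaults mirror a deployed e-trap frame: 1600x1200 RGB at 24-bit
    depth, a handful of trapped flies, and the distractor inventory seen
    on real panels.  ``illumination_gradient`` is the peak-to-peak
    relative intensity range of a multiplicative linear ramp across the
    frame; ``noise_sd`` is the additive Gaussian pixel noise in 8-bit
    intensity units.
    """

    width: int = 1600
    height: int = 1200
    n_olive_flies: int = 6
    n_other_flies: int = 4
    n_distractors: int = 6
    illumination_gradient: float = 0.2
    noise_sd: float = 2.0
    seed: int = 0
    #: Fraction of each frame dimension occupied by non-trap surround on
    #: every side; 0.0 means the panel fills the frame.
    trap_inset: float = 0.0
    #: Maximum allowed box-overlap fraction (intersection over smaller
    #: box) between planted elements.
    max_overlap: float = 0.0
    #: Which distractor shapes may be planted.
    distractor_kinds: tuple[str, ...] = DISTRACTOR_KINDS
    trap_id: str = "SYN"
    start_date: str = "2023-10-08"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if min(self.n_olive_flies, self.n_other_flies, self.n_distractors) < 0:
            raise ValueError("element counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.trap_inset < 0.5:
            raise ValueError("trap_inset must lie in [0, 0.5)")
        bad = [k for k in self.distractor_kinds if k not in DISTRACTOR_KINDS]
        if bad:
            raise ValueError(f"unknown distractor kinds {bad}")


@dataclass(frozen=True)
class GroundTruthElement:
    """One planted element: box, three-way label, stable id, pixel area."""

    box: BoundingBox
    label: str
    element_id: str
    area: int = 0

    def to_dict(self) -> dict:
        return {
            "element_id": self.element_id,
            "label": self.label,
            "box": self.box.to_dict(),
            "area": self.area,
        }


@dataclass
class TrapSequence:
    """A multi-day series of trap images with persistent ground truth.

    ``days`` holds ``(TrapImage, [GroundTruthElement, ...])`` pairs in
    chronological order.  With ``persistence = 1.0`` every trapped element
    stays put for the whole series, so the true per-day olive-fly count is
    non-decreasing; lighting jitter between days changes appearance only.
    """

    days: list[tuple[TrapImage, list[GroundTruthElement]]]
    arrival_rate: float = 0.0
    persistence: float = 1.0

    def __len__(self) -> int:
        return len(self.days)


# ---------------------------------------------------------------------------
# element geometry


@dataclass
class _Element:
    """Internal render parameters for one planted shape."""

    element_id: str
    label: str
    kind: str
    params: dict
    box: BoundingBox
    area: int


def trap_region(spec: SceneSpec) -> BoundingBox:
    """The rectangle occupied by the yellow panel within the frame."""
    x0 = int(round(spec.width * spec.trap_inset))
    y0 = int(round(spec.height * spec.trap_inset))
    return BoundingBox(x0, y0, spec.width - 2 * x0, spec.height - 2 * y0)


def _footprint(kind: str, params: dict, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/col pixel coordinates covered by a shape (clipped to the frame)."""
    if kind in ("olive_fly", "other_fly", "shadow"):
        return skdraw.ellipse(
            params["r"], params["c"], params["a"], params["b"],
            rotation=params["rot"], shape=shape,
        )
    if kind == "bag":
        rr, cc = skdraw.rectangle(
            (int(params["r0"]), int(params["c0"])),
            extent=(int(params["h"]), int(params["w"])), shape=shape)
        return rr.astype(np.intp).ravel(), cc.astype(np.intp).ravel()
    if kind == "hole":
        return skdraw.disk((params["r"], params["c"]), params["radius"], shape=shape)
    if kind == "glyph":
        rows, cols = [], []
        for (r0, c0, h, w) in params["strokes"]:
            rr, cc = skdraw.rectangle((int(r0), int(c0)), extent=(int(h), int(w)),
                                      shape=shape)
            rows.append(rr.astype(np.intp).ravel())
            cols.append(cc.astype(np.intp).ravel())
        return np.concatenate(rows), np.concatenate(cols)
    raise ValueError(f"unknown element kind {kind!r}")


def _sample_shape(kind: str, r: float, c: float, rng: np.random.Generator) -> dict:
    """Draw the geometric parameters of one element centred near (r, c)."""
    if kind == "olive_fly":
        a = rng.uniform(7.0, 10.0)  # semi-major axis; full axis 14-20 px
        aspect = rng.uniform(2.2, 3.0)
        shade = rng.uniform(0.04, 0.10)  # near-black body
        return {
            "r": r, "c": c, "a": a, "b": a / aspect,
            "rot": rng.uniform(0.0, np.pi),
            "rgb": (shade, shade * 0.9, shade * 0.8),
            "spot": {
                "offset": rng.uniform(0.35, 0.5),   # along major axis, relative
                "scale": rng.uniform(0.30, 0.42),   # spot size relative to body
                "shade": rng.uniform(0.72, 0.88),
            },
        }
    if kind == "other_fly":
        half_axis = rng.uniform(4.0, 15.0)  # full axis 8-30 px
        aspect = rng.uniform(1.2, 2.0)
        shade = rng.uniform(0.14, 0.24)  # paler than the olive fly
        return {
            "r": r, "c": c, "a": half_axis, "b": half_axis / aspect,
            "rot": rng.uniform(0.0, np.pi),
            "rgb": (shade, shade * 0.95, shade * 0.85),
        }
    if kind == "bag":
        w = rng.uniform(60, 120)
        h = rng.uniform(80, 160)
        return {
            "r0": r - h / 2, "c0": c - w / 2, "h": h, "w": w,
            "rgb": (0.32, 0.30, 0.28),
        }
    if kind == "hole":
        return {"r": r, "c": c, "radius": rng.uniform(4.0, 10.0),
                "rgb": (0.05, 0.05, 0.05)}
    if kind == "shadow":
        a = rng.uniform(20.0, 50.0)
        return {"r": r, "c": c, "a": a, "b": a * rng.uniform(0.5, 1.0),
                "rot": rng.uniform(0.0, np.pi),
                "factor": rng.uniform(0.78, 0.88)}
    if kind == "glyph":
        strokes = []
        for _ in range(int(rng.integers(2, 5))):
            length = rng.uniform(10, 25)
            dr = rng.uniform(-12, 12)
            dc = rng.uniform(-12, 12)
            if rng.random() < 0.5:  # horizontal stroke
                strokes.append((r + dr, c + dc - length / 2, 3.0, length))
            else:
                strokes.append((r + dr - length / 2, c + dc, length, 3.0))
        return {"strokes": strokes, "rgb": (0.15, 0.14, 0.13)}
    raise ValueError(f"unknown element kind {kind!r}")


def _half_extent(kind: str, params: dict) -> float:
    """Conservative half-size used to keep sampled centres inside the panel."""
    if kind in ("olive_fly", "other_fly", "shadow"):
        return params["a"] + 2
    if kind == "bag":
        return max(params["h"], params["w"]) / 2 + 2
    if kind == "hole":
        return params["radius"] + 2
    if kind == "glyph":
        return 26.0
    raise ValueError(kind)


def _overlap_fraction(a: BoundingBox, b: BoundingBox) -> float:
    inter = a.intersection_area(b)
    if inter == 0:
        return 0.0
    return inter / min(a.area, b.area)


def _sample_elements(spec: SceneSpec, rng: np.random.Generator,
                     start_index: int = 0,
                     existing: list[_Element] | None = None,
                     counts: tuple[int, int, int] | None = None) -> list[_Element]:
    """Rejection-sample non-overlapping elements inside the panel region.

    Raises :class:`PlacementError` naming the failing count when an
    element cannot be placed within the overlap constraint.
    """
    region = trap_region(spec)
    shape = (spec.height, spec.width)
    placed: list[_Element] = list(existing) if existing else []
    out: list[_Element] = []
    n_olive, n_other, n_distr = counts if counts is not None else (
        spec.n_olive_flies, spec.n_other_flies, spec.n_distractors)

    plan: list[tuple[str, str]] = (
        [("olive_fly", "olive_fly")] * n_olive
        + [("other_fly", "other_fly")] * n_other
    )
    for _ in range(n_distr):
        kind = str(rng.choice(spec.distractor_kinds)) if spec.distractor_kinds else "hole"
        plan.append((kind, "other_element"))

    idx = start_index
    for kind, label in plan:
        element = None
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            # sample a centre that keeps the whole shape inside the panel
            probe = _sample_shape(kind, 0.0, 0.0, rng)
            margin = _half_extent(kind, probe)
            lo_r = region.y + margin
            hi_r = region.y2 - margin
            lo_c = region.x + margin
            hi_c = region.x2 - margin
            if lo_r >= hi_r or lo_c >= hi_c:
                continue
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            params = _shift_params(kind, probe, r, c)
            rr, cc = _footprint(kind, params, shape)
            if rr.size == 0:
                continue
            box = BoundingBox(
                x=int(cc.min()), y=int(rr.min()),
                w=int(cc.max() - cc.min() + 1), h=int(rr.max() - rr.min() + 1),
            )
            if not box.within(spec.width, spec.height):
                continue
            if any(_overlap_fraction(box, p.box) > spec.max_overlap for p in placed):
                continue
            element = _Element(
                element_id=f"e{idx:04d}", label=label, kind=kind,
                params=params, box=box, area=int(np.unique(rr * spec.width + cc).size),
            )
            break
        if element is None:
            raise PlacementError(
                f"could not place element {idx - start_index + 1} of {len(plan)} "
                f"(kind={kind}) within overlap <= {spec.max_overlap}"
            )
        placed.append(element)
        out.append(element)
        idx += 1
    return out


def _shift_params(kind: str, probe: dict, r: float, c: float) -> dict:
    """Re-centre shape parameters sampled at the origin onto (r, c)."""
    params = dict(probe)
    if kind in ("olive_fly", "other_fly", "shadow", "hole"):
        params["r"] = r
        params["c"] = c
    elif kind == "bag":
        params["r0"] = r - probe["h"] / 2
        params["c0"] = c - probe["w"] / 2
    elif kind == "glyph":
        params["strokes"] = [(r0 + r, c0 + c, h, w) for (r0, c0, h, w) in probe["strokes"]]
    return params


# ---------------------------------------------------------------------------
# rendering


def _render(spec: SceneSpec, elements: list[_Element], rng: np.random.Generator,
            gradient_angle: float, brightness: float = 0.0,
            contrast: float = 1.0) -> np.ndarray:
    """Compose the scene in unit-scale floats and quantize to 8-bit."""
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = SURROUND_RGB
    region = trap_region(spec)
    img[region.y:region.y2, region.x:region.x2] = PANEL_RGB

    shape = (h, w)
    # shadows first: multiplicative darkening of whatever lies beneath
    for el in elements:
        if el.kind == "shadow":
            rr, cc = _footprint(el.kind, el.params, shape)
            img[rr, cc] *= el.params["factor"]
    # solid shapes next
    for el in elements:
        if el.kind == "shadow":
            continue
        rr, cc = _footprint(el.kind, el.params, shape)
        img[rr, cc] = el.params["rgb"]
        if el.kind == "olive_fly":
            spot = el.params["spot"]
            body_a, body_b, rot = el.params["a"], el.params["b"], el.params["rot"]
            # skimage rotates ellipses by -rot around the row axis; the major
            # axis therefore runs along (sin rot, cos rot) in (row, col)
            dr = spot["offset"] * body_a * np.sin(rot)
            dc = spot["offset"] * body_a * np.cos(rot)
            sr, sc = skdraw.ellipse(
                el.params["r"] + dr, el.params["c"] + dc,
                max(spot["scale"] * body_a, 1.0), max(0.75 * body_b, 1.0),
                rotation=rot, shape=shape,
            )
            # keep the mark inside the body so the box stays the body box
            body = np.zeros(shape, dtype=bool)
            body[rr, cc] = True
            keep = body[sr, sc]
            img[sr[keep], sc[keep]] = spot["shade"]

    # multiplicative linear illumination ramp across the whole scene
    if spec.illumination_gradient > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        proj = xx * np.cos(gradient_angle) + yy * np.sin(gradient_angle)
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1.0)
        ramp = 1.0 + spec.illumination_gradient * (proj - 0.5)
        img *= ramp[:, :, None]

    img = contrast * (img - 0.5) + 0.5 + brightness
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd / 255.0, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def _ground_truth(elements: list[_Element]) -> list[GroundTruthElement]:
    return [
        GroundTruthElement(box=el.box, label=el.label,
                           element_id=el.element_id, area=el.area)
        for el in elements
    ]


def _day_timestamp(spec: SceneSpec, day: int) -> datetime:
    base = datetime.fromisoformat(spec.start_date).replace(
        hour=12, minute=0, tzinfo=timezone.utc)
    return base + timedelta(days=day - 1)


def generate_trap_image(spec: SceneSpec) -> tuple[TrapImage, list[GroundTruthElement]]:
    """Render one synthetic trap photograph with its exact ground truth.

    The same seed always produces a bit-identical image and identical
    annotations.  Raises :class:`PlacementError` if the requested element
    counts cannot be placed under the overlap constraint.
    """
    rng = np.random.default_rng(spec.seed)
    elements = _sample_elements(spec, rng)
    gradient_angle = rng.uniform(0.0, 2 * np.pi)
    pixels = _render(spec, elements, rng, gradient_angle)
    image = TrapImage(pixels=pixels, trap_id=spec.trap_id,
                      timestamp=_day_timestamp(spec, 1))
    return image, _ground_truth(elements)


def generate_sequence(base_spec: SceneSpec, days: int, arrival_rate: float = 0.0,
                      persistence: float = 1.0) -> TrapSequence:
    """Simulate a multi-day trap series with persistent elements.

    Day 1 reproduces ``generate_trap_image(base_spec)`` exactly (for
    ``arrival_rate = 0``).  On every day, new olive flies arrive with a
    seeded Poisson count at the given rate; existing elements persist with
    probability ``persistence`` per day (removal is permanent, emulating
    a fly washing off the adhesive).  Day-to-day appearance varies through
    brightness/contrast jitter and fresh pixel noise at fixed element
    positions, the organic augmentation a real trap provides.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    if arrival_rate < 0:
        raise ValueError("arrival_rate must be non-negative")
    if not 0.0 <= persistence <= 1.0:
        raise ValueError("persistence must lie in [0, 1]")

    base_rng = np.random.default_rng(base_spec.seed)
    elements = _sample_elements(base_spec, base_rng)
    gradient_angle = base_rng.uniform(0.0, 2 * np.pi)
    next_id = len(elements)

    out_days: list[tuple[TrapImage, list[GroundTruthElement]]] = []
    alive = list(elements)
    for day in range(1, days + 1):
        day_rng = np.random.default_rng([base_spec.seed & 0x7FFFFFFF, 7919, day])
        if day > 1 and persistence < 1.0:
            alive = [el for el in alive if day_rng.random() < persistence]
        n_new = int(day_rng.poisson(arrival_rate)) if arrival_rate > 0 else 0
        if n_new:
            arrivals = _sample_elements(
                base_spec, day_rng, start_index=next_id,
                existing=alive, counts=(n_new, 0, 0))
            alive = alive + arrivals
            next_id += n_new

        if day == 1:
            pixels = _render(base_spec, alive, base_rng, gradient_angle)
        else:
            pixels = _render(
                base_spec, alive, day_rng, gradient_angle,
                brightness=day_rng.uniform(-0.06, 0.06),
                contrast=day_rng.uniform(0.9, 1.1),
            )
        image = TrapImage(pixels=pixels, trap_id=base_spec.trap_id,
                          timestamp=_day_timestamp(base_spec, day))
        out_days.append((image, _ground_truth(alive)))
    return TrapSequence(days=out_days, arrival_rate=arrival_rate,
                        persistence=persistence)


# ---------------------------------------------------------------------------
# crop-level generation (training data without full-scene detection)


def generate_crop_dataset(n_olive: int, n_other_fly: int, n_other_element: int,
                          seed: int = 0, noise_sd: float = 2.0
                          ) -> tuple[list[np.ndarray], list[str]]:
    """Render labelled 32x32x3 crops directly, one element per crop.

    Each crop shows a single element on yellow panel background with
    per-crop brightness jitter and pixel noise — the appearance a crop cut
    from a full scene would have, produced without running the detector.
    Returns parallel lists of patches and three-way labels.
    """
    rng = np.random.default_rng(seed)
    crops: list[np.ndarray] = []
    labels: list[str] = []
    plan = (["olive_fly"] * n_olive + ["other_fly"] * n_other_fly
            + ["other_element"] * n_other_element)
    canvas = 64
    for label in plan:
        if label == "other_element":
            kind = str(rng.choice(("hole", "glyph", "bag", "shadow")))
        else:
            kind = label
        r = canvas / 2 + rng.uniform(-3, 3)
        c = canvas / 2 + rng.uniform(-3, 3)
        probe = _sample_shape(kind, 0.0, 0.0, rng)
        params = _shift_params(kind, probe, r, c)

        img = np.empty((canvas, canvas, 3), dtype=np.float64)
        img[:] = PANEL_RGB
        rr, cc = _footprint(kind, params, (canvas, canvas))
        if kind == "shadow":
            img[rr, cc] *= params["factor"]
        else:
            img[rr, cc] = params["rgb"]
            if kind == "olive_fly":
                spot = params["spot"]
                dr = spot["offset"] * params["a"] * np.sin(params["rot"])
                dc = spot["offset"] * params["a"] * np.cos(params["rot"])
                sr, sc = skdraw.ellipse(
                    r + dr, c + dc,
                    max(spot["scale"] * params["a"], 1.0),
                    max(0.75 * params["b"], 1.0),
                    rotation=params["rot"], shape=(canvas, canvas),
                )
                body = np.zeros((canvas, canvas), dtype=bool)
                body[rr, cc] = True
                keep = body[sr, sc]
                img[sr[keep], sc[keep]] = spot["shade"]

        img *= rng.uniform(0.9, 1.1)
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd / 255.0, size=img.shape)
        img = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
        lo = (canvas - 32) // 2
        crops.append(img[lo:lo + 32, lo:lo + 32].copy())
        labels.append(label)
    return crops, labels


# ---------------------------------------------------------------------------
# annotation round-trip

_SCHEMA = "flytrap-annotations-1"


def write_annotations(elements: list[GroundTruthElement], path: str | Path) -> None:
    """Write ground-truth elements to a JSON file (documented schema v1)."""
    payload = {
        "schema": _SCHEMA,
        "elements": [el.to_dict() for el in elements],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_annotations(path: str | Path) -> list[GroundTruthElement]:
    """Read annotations back; lossless inverse of :func:`write_annotations`.

    Raises :class:`AnnotationError` with element context on malformed
    files or unknown label strings.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "elements" not in payload:
        raise AnnotationError(f"{path}: missing top-level 'elements' list")
    out: list[GroundTruthElement] = []
    for i, entry in enumerate(payload["elements"]):
        try:
            label = entry["label"]
            if label not in LABELS3:
                raise AnnotationError(
                    f"{path}: element {i}: unknown label {label!r}; "
                    f"expected one of {LABELS3}"
                )
            out.append(GroundTruthElement(
                box=BoundingBox.from_dict(entry["box"]),
                label=label,
                element_id=str(entry["element_id"]),
                area=int(entry.get("area", 0)),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"{path}: element {i}: {exc}") from exc
    return out
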