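"""Generate a synthetic sticky-trap photograph with exact ground truth.

Builds one 1600x1200 scene with six olive flies, four other flies and
six distractors, writes the image and its JSON annotations, and prints
the planted inventory.
"""

from pathlib import Path

import imageio.v3 as iio

from flytrap import SceneSpec, generate_trap_image, write_annotations

out = Path("example_output")
out.mkdir(exist_ok=True)

spec = SceneSpec(seed=7)  # defaults: 1600x1200, 6 olive flies, 4 other, 6 distractors
image, elements = generate_trap_image(spec)

iio.imwrite(out / "trap.png", image.pixels)
write_annotations(elements, out / "trap.json")

print(f"scene {image.width}x{image.height}, {len(elements)} planted elements:")
for el in elements:
    print(f"  {el.element_id}  {el.label:14s} box=({el.box.x},{el.box.y},"
          f"{el.box.w},{el.box.h})  area={el.area}px")
# Every element above is also in trap.json; a detector scoring against it
# can be evaluated with exact recall, because the ground truth is complete.
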