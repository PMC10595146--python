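"""E-trap sensor telemetry: per-minute readings to hourly summaries.

The trap's temperature/relative-humidity sensor is read once a minute
and logged locally as CSV; only the hourly maximum, minimum and mean are
transmitted upstream, which both shrinks the payload and filters
aberrant values.  "Aberrant" means outside the sensor's physical range
(-40..80 degC, 0..100 %RH) or non-finite; such readings never enter the
summaries but are counted, so per-hour bookkeeping is conserved:
n_valid + n_aberrant equals the number of parsed rows in that hour.

Hours are half-open wall-clock buckets [h:00, h+1:00); timestamps are
ISO-8601.  Summaries are order-invariant in the input.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

logger = logging.getLogger(__name__)

#: Physical sensor ranges; values outside are aberrant.
TEMP_RANGE_C = (-40.0, 80.0)
HUMIDITY_RANGE_RH = (0.0, 100.0)

_HEADER = ("timestamp", "temperature_c", "humidity_rh")


@dataclass(frozen=True)
class SensorReading:
    """One timestamped temperature (degC) / relative humidity (%RH) pair."""

    timestamp: datetime
    temperature_c: float
    humidity_rh: float

    @property
    def is_aberrant(self) -> bool:
        t, h = self.temperature_c, self.humidity_rh
        if not (math.isfinite(t) and math.isfinite(h)):
            return True
        return not (TEMP_RANGE_C[0] <= t <= TEMP_RANGE_C[1]
                    and HUMIDITY_RANGE_RH[0] <= h <= HUMIDITY_RANGE_RH[1])


@dataclass(frozen=True)
class HourlySummary:
    """Max/min/mean of the valid readings within one wall-clock hour.

    Statistics are ``None`` when the hour had no valid readings
    (``n_valid = 0``).
    """

    hour: datetime
    t_max: float | None
    t_min: float | None
    t_mean: float | None
    h_max: float | None
    h_min: float | None
    h_mean: float | None
    n_valid: int
    n_aberrant: int = 0


def summarize_hourly(readings: list[SensorReading]) -> list[HourlySummary]:
    """Group readings by hour, drop aberrant values, emit max/min/mean.

    Input order is irrelevant; output is sorted by hour.
    """
    buckets: dict[datetime, list[SensorReading]] = {}
    for reading in readings:
        hour = reading.timestamp.replace(minute=0, second=0, microsecond=0)
        buckets.setdefault(hour, []).append(reading)

    out: list[HourlySummary] = []
    for hour in sorted(buckets):
        valid = [r for r in buckets[hour] if not r.is_aberrant]
        n_aberrant = len(buckets[hour]) - len(valid)
        if n_aberrant:
            logger.warning("%s: discarded %d aberrant reading(s)",
                           hour.isoformat(), n_aberrant)
        if not valid:
            out.append(HourlySummary(hour, None, None, None, None, None, None,
                                     n_valid=0, n_aberrant=n_aberrant))
            continue
        temps = [r.temperature_c for r in valid]
        hums = [r.humidity_rh for r in valid]
        out.append(HourlySummary(
            hour=hour,
            t_max=max(temps), t_min=min(temps), t_mean=sum(temps) / len(temps),
            h_max=max(hums), h_min=min(hums), h_mean=sum(hums) / len(hums),
            n_valid=len(valid), n_aberrant=n_aberrant,
        ))
    return out


def write_sensor_log(readings: list[SensorReading], path: str | Path) -> None:
    """Write readings as CSV with the documented header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for r in readings:
            writer.writerow([r.timestamp.isoformat(),
                             repr(r.temperature_c), repr(r.humidity_rh)])


def read_sensor_log(path: str | Path) -> tuple[list[SensorReading], int]:
    """Read a sensor CSV; returns (readings, number of skipped rows).

    Malformed rows (wrong field count, unparsable timestamp or number)
    are skipped with a logged warning and counted, not fatal.
    """
    readings: list[SensorReading] = []
    skipped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for line_no, row in enumerate(reader, start=1):
            if not row or (line_no == 1 and row[0] == _HEADER[0]):
                continue
            try:
                if len(row) != 3:
                    raise ValueError(f"expected 3 fields, got {len(row)}")
                readings.append(SensorReading(
                    timestamp=datetime.fromisoformat(row[0]),
                    temperature_c=float(row[1]),
                    humidity_rh=float(row[2]),
                ))
            except (ValueError, TypeError) as exc:
                skipped += 1
                logger.warning("%s:%d: skipping malformed row: %s",
                               path, line_no, exc)
    return readings, skipped


def write_summaries(summaries: list[HourlySummary], path: str | Path) -> None:
    """Write hourly summaries as CSV (empty statistics for empty hours)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["hour", "t_max", "t_min", "t_mean",
                         "h_max", "h_min", "h_mean", "n_valid", "n_aberrant"])
        for s in summaries:
            stats = [s.t_max, s.t_min, s.t_mean, s.h_max, s.h_min, s.h_mean]
            writer.writerow([s.hour.isoformat()]
                            + ["" if v is None else repr(v) for v in stats]
                            + [s.n_valid, s.n_aberrant])
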