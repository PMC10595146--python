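"""Reduce per-minute sensor readings to hourly max/min/mean summaries.

Simulates two hours of per-minute temperature/humidity readings with a
couple of aberrant values (sensor glitches), then prints the hourly
records a trap would transmit.
"""

import math
from datetime import datetime, timedelta

from flytrap import SensorReading, summarize_hourly

t0 = datetime(2023, 10, 8, 11, 0)
readings = []
for i in range(120):
    temp = 21.0 + 4.0 * math.sin(i / 40.0)
    readings.append(SensorReading(t0 + timedelta(minutes=i),
                                  round(temp, 1), 55.0 - i * 0.05))
readings.append(SensorReading(t0 + timedelta(minutes=14), 998.0, 55.0))
readings.append(SensorReading(t0 + timedelta(minutes=75), 22.0, -5.0))

for s in summarize_hourly(readings):
    print(f"{s.hour.isoformat()}  T[{s.t_min:.1f}..{s.t_max:.1f}] "
          f"mean {s.t_mean:.2f} degC   RH[{s.h_min:.1f}..{s.h_max:.1f}] "
          f"mean {s.h_mean:.2f} %   valid={s.n_valid} aberrant={s.n_aberrant}")
# The two out-of-range readings are filtered before the statistics, so
# each hour reports 60 valid minutes and 1 aberrant one.
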