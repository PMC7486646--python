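"""Generate a synthetic daily blood-collection series and summarise it.

The generator emulates the structure of real outpatient sampling-room
demand: a Monday-peaked weekday profile with a deep Sunday trough, an
annual sinusoidal swing, a gentle trend, Gaussian noise, and occasional
holiday days with depressed volume.
"""

import numpy as np

from bloodcast import GeneratorConfig, generate_series, to_panel

series = generate_series(GeneratorConfig(n_weeks=61, seed=1))
panel = to_panel(series)

print(f"{len(series)} days from {series.dates[0].date()} "
      f"to {series.dates[-1].date()}")
print(f"mean {series.counts.mean():.1f}  SD {series.counts.std(ddof=1):.1f}")
for name, col in zip(("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"),
                     panel.values.T):
    print(f"  {name}: mean {col.mean():7.1f}")
print("Weekday means show the day-of-week effect the pipeline exploits: "
      "Monday highest, Sunday far lowest.")
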