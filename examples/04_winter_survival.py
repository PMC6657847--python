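"""Winter dormancy duration and overwinter survival per winter.

Counts days below the 9 degC critical temperature for growth per
July-June winter, computes winter severity, and evaluates the
Weibull accelerated-failure-time overwinter-survival model.  The
Weibull shape (lam) and salinity are study inputs with no universal
default; the values below are illustrative placeholders.
"""

import overwinter as ow

cfg = ow.ClimateSimConfig(seed=1)
_, water_raw, _ = ow.generate_pair(cfg)
water = ow.interpolate_gaps(water_raw)

records = ow.winter_metrics(water, threshold=9.0)
lengths = [r.length_days for r in records]
print(f"{len(records)} complete winters; dormancy "
      f"{min(lengths)}-{max(lengths)} days, mean {sum(lengths)/len(lengths):.0f}")

params = ow.SurvivalParams(lam=1.0, sal=12.0, size=40.0)  # placeholder lam/sal
surv = ow.winter_survival_series(records, params)
print(surv.tail(5).to_string(index=False,
                             float_format=lambda x: f"{x:.3f}"))
first = surv.head(10).survival.mean()
last = surv.tail(10).survival.mean()
print(f"mean survival, first decade {first:.2f} -> last decade {last:.2f}")
# Shorter, milder winters push survival up: each row shows a winter's
# days below 9 degC, the mean temperature of those days, and the
# modelled probability a 40 mm juvenile crab survives that winter.
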