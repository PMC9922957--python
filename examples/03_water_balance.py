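"""The daily deficit bucket, step by step, with an observation reset.

Ten hand-built days: steady drying under full canopy, a rain day, and a
neutron-probe observation that corrects the model mid-run.
"""

import pandas as pd

from fieldwater import DailyForcing, FieldCapacity, TrialConfig, run_balance

config = TrialConfig()
fc = FieldCapacity(plot_id="P01", fc_mm=180.0, n_obs=3)

dates = pd.date_range("2022-01-10", periods=10, freq="D")
rain = [0, 0, 0, 0, 18, 0, 0, 0, 0, 0]
observed = {dates[7]: 160.0}  # probe says the profile holds 160 mm on day 8

forcings = [
    DailyForcing(date=d, rain_mm=r, pet_mm=5.0, irrigation_mm=0.0, cover=1.0,
                 observed_storage_mm=observed.get(d))
    for d, r in zip(dates, rain)
]
traj = run_balance(forcings, fc, config, smd_init=0.0)

print("date        SMD    AET  drain  reset")
for row in traj.itertuples(index=False):
    flag = "  <- reset to obs (residual "
    note = f"{flag}{row.reset_residual_mm:+.1f} mm)" if row.reset else ""
    print(f"{row.date.date()}  {row.smd_mm:5.1f}  {row.aet_mm:5.1f}  "
          f"{row.drainage_mm:5.1f}  {str(bool(row.reset)):5s}{note}")

print("\nSMD grows by AET each dry day, rain pays the deficit down, and the "
      "day-8 observation (180-160 = 20 mm deficit) overrides the model; the "
      "residual measures model drift since the last correction.")
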