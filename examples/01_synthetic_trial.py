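"""Generate a synthetic two-plot trial and run the full pipeline.

Prints the recovered field capacity against the generator's truth and a
summary of the deficit/drainage trajectories.  With nonzero observation
noise the FC estimates land within a few mm of truth; re-run with
ndvi_sd=0, theta_sd=0 to see the exact closure.
"""

from fieldwater import TrialConfig, generate_trial, run_pipeline

config = TrialConfig()
bundle, truth = generate_trial(n_plots=2, seed=42, config=config)
result = run_pipeline(bundle, config)

print("plot  FC est (mm)  FC true (mm)  winter obs")
for plot, fc in result.field_capacity.items():
    print(f"{plot}   {fc.fc_mm:10.1f}  {truth.fc_mm[plot]:11.1f}  {fc.n_obs:9d}")

traj = result.trajectories
print(f"\n{len(traj)} plot-days simulated "
      f"({traj['date'].min().date()} .. {traj['date'].max().date()})")
print(f"max SMD          {traj['smd_mm'].max():6.1f} mm   "
      "(deficit below field capacity; 0 = profile full)")
print(f"total drainage   {traj.groupby('plot_id')['drainage_mm'].sum().mean():6.1f} mm/plot")
print(f"reset days       {int(traj['reset'].sum())} "
      "(model corrected to a probe observation)")
print(f"drainage events  {len(result.events)}")
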