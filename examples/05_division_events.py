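"""Local dynamics around division events versus random controls.

Injects division boosts (20 μm spatial, 30 min temporal scale) into a
Brownian background, then measures the event-centred mean displacement
against random control regions, the displacement-step series, and
recovers the injected scales from the data.
"""

import numpy as np

from epidyn import SyntheticParams, gen_trajectories, inject_events
from epidyn import events as ev

params = SyntheticParams(n_cells=2000, field_width=500.0, field_height=500.0,
                         n_frames=130, model="brownian", D=0.005,
                         boost_amplitude=0.4, division_rate=0.1,
                         extrusion_rate=0.0, boost_axis_bias=0.0, rng_seed=5)
tracks = gen_trajectories(params)
tracks, events = inject_events(tracks, params)
print(f"{len(events)} division events injected")

grid = np.arange(-40, 45, 10.0)
d_div = ev.event_mean_displacement(tracks, events, dt_grid=grid)
controls = ev.random_controls(tracks, 5 * len(events), rng_seed=6,
                              true_events=events, exclusion_radius=60.0)
d_ran = ev.event_mean_displacement(tracks, controls, dt_grid=grid)
m = d_div.merge(d_ran, on="dt_min", suffixes=("_div", "_ran"))
for _, row in m[m.dt_min.isin([-30.0, 30.0])].iterrows():
    print(f"  dt = {row.dt_min:+.0f} min: <d_div> = {row.d_mean_div:.2f} um, "
          f"<d_ran> = {row.d_mean_ran:.2f} um")
print("  (the event curve exceeds the control only after the division)")

steps = ev.displacement_step_series(tracks, events, dt_step=10.0)
peak = steps.loc[steps.step_um.idxmax()]
print(f"step series peaks at t = {peak.offset_min:+.0f} min "
      f"({peak.step_um:.2f} um per 10 min)")

lam, tau = ev.recover_boost_scales(tracks, events)
print(f"recovered boost scales: spatial {lam:.1f} um (injected 20), "
      f"temporal {tau:.1f} min (injected 30)")
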