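"""Simulate one motion-affected VMAT arc and quantify the interplay effect.

Builds the synthetic lung phantom, computes the 30-segment stand-in dose for
the default 150-degree arc, accumulates it over the 4.5 s sinusoidal
breathing scenario (case 1b: 20 mm SI / 10 mm AP peak-to-peak), and compares
the motion-affected coronal plane to the static plan with a local 3%/3 mm
gamma criterion.
"""

import vmat4d as v

cfg = v.ExperimentConfig(grid_spacing=2.5, roi_size=100.0, seed=1)
spec = cfg.scenario_spec("1b")

stats = v.AccumulationStats()
p_static, p_dyn, _ = v.simulate_arc(cfg, spec, delta_alpha=5.0, stats=stats)

rois = v.experiments.scenario_rois(cfg, spec, p_static)
res = v.gamma_index(p_static, p_dyn, cfg.gamma)

print(f"accumulated {stats.n_substeps} sub-steps, "
      f"off-grid leakage {100 * stats.leakage_fraction:.2f}%")
print(f"plane maximum dose: static {p_static.values.max():.2f} Gy, "
      f"dynamic {p_dyn.values.max():.2f} Gy")
for name in ("total", "ITV", "CTV"):
    roi = None if name == "total" else rois[name]
    rate_int, rate = v.passing_rate(res, roi)
    print(f"gamma passing rate ({name:5s}): {rate_int:3d}%  ({rate:.1f}%)")
print("Sub-100% rates quantify the simulated motion effect: dose blurring "
      "and interplay move the delivered dose away from the static plan.")
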