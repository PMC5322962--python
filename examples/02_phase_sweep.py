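"""Sweep the breathing starting phase and watch the SDD synchronization dip.

The simulated delivery is repeated with the breathing curve shifted by
delta-t in [0, 10] s.  The squared-dose-difference (SDD) to the reference
run at delta-t = 0 measures how sensitive the simulation is to the assumed
starting phase; for a sinusoid the curve repeats with the breathing period.
"""

import numpy as np

import vmat4d as v

cfg = v.ExperimentConfig(grid_spacing=4.0, roi_size=100.0, seed=1)
df = v.run_phase_sweep(cfg, "1b", delta_alpha=5.0)

sdd = df["sdd"].to_numpy()
off = df["delta_t"].to_numpy()
print(df.head(6).to_string(index=False))
print(f"...\nSDD minimum at delta-t = {off[np.argmin(sdd)]:.2f} s "
      f"(max/min contrast {sdd.max() / max(sdd[1], 1e-30):.0f}x)")
lag = np.argmin([np.mean(np.abs(sdd[:-k] - sdd[k:])) for k in range(8, 32)]) + 8
print(f"SDD curve repeats every {lag * cfg.phase_step:.2f} s "
      f"(breathing period of case 1b: 4.5 s)")
print("A synchronization error of even a fraction of a breathing cycle "
      "changes the simulated dose pattern substantially.")
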