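"""Simulate a misaligned dataset and stack a small candidate grid.

Generates monthly site-level exposure data from a daily separable GP (a
scaled-down version of the reference design), fits the conjugate model under
a 2 x 2 x 1 x 2 grid of kernel candidates, computes PSIS leave-one-out
densities and prints the stacking weights.  The weights say how much each
fixed-kernel posterior contributes to the combined predictive distribution;
candidates whose ranges fit the data poorly receive weight near zero.
"""

import warnings

import numpy as np

from cosstack import (
    ExposureData,
    GeometryCache,
    PriorConfig,
    SimConfig,
    make_candidate_grid,
    simulate_exposure,
)
from cosstack.basis import build_basis, monthly_indicator_spec
from cosstack.pipeline import stack_exposure

warnings.filterwarnings("ignore")

cfg = SimConfig(ns=30, nt=180, t_max=6.0, seed=42)
ds = simulate_exposure(cfg)
print(f"simulated {len(ds.x)} monthly records at {cfg.ns} sites "
      f"({cfg.missing_frac:.0%} removed)")

spec = monthly_indicator_spec(6)
data = ExposureData(supports=ds.supports, x=ds.x, basis=build_basis(spec, ds.supports))
priors = PriorConfig.default(r=spec.r)
cache = GeometryCache(supports=ds.supports)

kps = make_candidate_grid([2.0, 4.0], [0.3, 0.6], [0.5], [0.03, 0.5])
sp, loo = stack_exposure(data, kps, priors, cache, n_draws=300, seed=7)

print(f"\nstacked {len(kps)} candidates; mean LOO objective "
      f"{sp.weights.objective:.3f}")
for kp, a in zip(kps, sp.weights.alpha):
    marker = " <-- " if a > 0.05 else ""
    print(f"  alpha={a:5.3f}  ({kp.label()}){marker}")
print("\nweights concentrate on candidates whose decay and noise ratio are "
      "closest to the generating kernel (phi1=4, phi2=0.6, delta2~0.033).")
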