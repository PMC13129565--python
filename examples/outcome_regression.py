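"""Modular outcome regression with confounding adjustment.

Block-level outcomes are regressed on confounders and the block-averaged
latent exposure, refitting the conjugate regression for every posterior draw
of the latent process (modular, cut-model uncertainty propagation).  The
run compares the unadjusted regression with one augmented by a space-time
RBF basis, and prints posterior summaries plus exponentiated effect sizes.
"""

import warnings

import numpy as np

from cosstack import (
    ExposureData,
    GeometryCache,
    OutcomeData,
    PriorConfig,
    SimConfig,
    make_blocks,
    relative_effects,
    simulate_exposure,
    simulate_outcome,
)
from cosstack.basis import build_basis, fit_rbf_tensor, monthly_indicator_spec
from cosstack.model import fit_module1, fit_module2, predict_blocks, sample_module2

warnings.filterwarnings("ignore")

cfg = SimConfig(ns=30, nt=180, t_max=6.0, blocks_per_quarter=(10, 10), rho=0.9,
                seed=21, n_mc=150)
ds = simulate_exposure(cfg)
blocks = make_blocks(cfg)
ds = simulate_outcome(cfg, ds, blocks)

spec = monthly_indicator_spec(6)
data = ExposureData(supports=ds.supports, x=ds.x, basis=build_basis(spec, ds.supports))
priors = PriorConfig.default(r=spec.r, p=2)
cache = GeometryCache(supports=ds.supports, blocks=blocks, n_mc=cfg.n_mc, seed=1)

post = fit_module2(data, cfg.true_kernel, priors, cache=cache)
draws = sample_module2(post, data, 400, seed=3)
zl = predict_blocks(draws, post, data, blocks, build_basis(spec, blocks), cache, seed=5)

outcome = OutcomeData(blocks=blocks, y=ds.y, W=ds.W)
rbf = fit_rbf_tensor(blocks, Ks=4, Kt=1, seed=0)
base = fit_module1(outcome, zl, priors, seed=7)
adj = fit_module1(outcome, zl, priors, extra_basis=build_basis(rbf, blocks), seed=7)

names = ["intercept", "w2", "z_block"]
print("posterior medians (true values: 1, 1, 1):")
for i, nm in enumerate(names):
    print(f"  {nm:9s}  baseline {np.median(base.beta[:, i]):7.3f}   "
          f"+basis {np.median(adj.beta[:, i]):7.3f}")
print(f"residual variance tau2: baseline {np.median(base.tau2):.3f}, "
      f"+basis {np.median(adj.tau2):.3f}")
print("the basis absorbs part of the unmeasured confounder, which shows up "
      "as the large drop in the residual variance.")

eff = relative_effects(adj.beta, 1)
print(f"\nexponentiated w2 effect: median {eff['median']:.2f}, "
      f"95% CI ({eff['ci95'][0]:.2f}, {eff['ci95'][1]:.2f})")
print("on a log-scale outcome this is the multiplicative rate ratio per "
      "unit of the confounder.")
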