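"""Interspike-interval statistics: full model vs embedded LIF.

Calibrates the hazard at sigma0 = 0.01, draws first-firing times from
the full model (reset at the rest point) and from the reduced model by
hazard thinning along radial paths, and compares the two distributions.
(Reduced sample sizes; the reference comparison uses 1000 per side.)
"""

import numpy as np

import fhnlif as F

params = F.REFERENCE_PARAMS
sigma0 = 0.01
eq = F.analyze_equilibrium(params)
nf = F.build_normal_form(eq.M, eq.mu, eq.nu, sigma0)

fit = F.calibrate_firing(params, F.NoiseSpec("additive", sigma0),
                         n_trials=300, seed=9)
spec = F.HazardSpec(a_star=fit.a_star, b_star=fit.b_star, nu=eq.nu)
print(f"calibrated hazard: a* = {fit.a_star:.4f}, b* = {fit.b_star:.4f}, "
      f"ceiling nu/2pi = {spec.rate_scale:.5f}")

fhn = F.sample_isi_fhn(params, F.NoiseSpec("additive", sigma0),
                       F.SimConfig(dt=0.01, T=1000.0, seed=10), 400)
lif, _ = F.sample_isi_lif(F.RadialOUSampler(nf, R0=0.0), spec, 400, seed=11)
comp = F.compare_isi(fhn.times, lif)

print(f"\nfull-model first-firing times: mean {fhn.times.mean():.1f}, "
      f"median {np.median(fhn.times):.1f}  ({fhn.n_censored} censored)")
print(f"reduced-model (thinning):      mean {lif.mean():.1f}, "
      f"median {np.median(lif):.1f}")
print(f"two-sample KS distance {comp.ks_statistic:.3f} "
      f"(p = {comp.p_value:.2g})")
print()
print("Both distributions are unimodal and right-skewed on the same time")
print("scale; the reduced model fires somewhat faster because the radial")
print("hazard treats all directions alike while the nonlinear flow does")
print("not -- see docs/methods.md for the quantitative discussion.")
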