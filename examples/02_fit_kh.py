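"""Generate a healthy-brain TAC and estimate K_H by mono-exponential fit.

The generator returns ground truth alongside each regional TAC, so the
estimator can be checked directly: fitted K_H should sit within a few
percent of truth noise-free, and scatter like real inter-animal spread
(~0.05-0.08 1/h) at 5 % frame noise.
"""

from maglpet import fit_monoexp, generate_regional_tacs, make_scenario

tacs, truth = generate_regional_tacs(make_scenario("healthy"))
print(f"{'region':18s} {'true K_H':>9s} {'fitted':>8s}  (1/h, noise-free)")
for region, tac in tacs.items():
    fit = fit_monoexp(tac)  # default 15-90 min window
    print(f"{region:18s} {truth[region]['kh_per_h']:9.2f} {fit.kh:8.3f}")

noisy, _ = generate_regional_tacs(make_scenario("healthy", noise=0.05, seed=7))
fit = fit_monoexp(noisy["cerebral_cortex"])
print(f"\ncortex with 5 % frame noise (seed 7): K_H = {fit.kh:.3f} 1/h, "
      f"A = {fit.amplitude:.2f} SUV, converged = {fit.converged}")
print("-> the clearance rate is region-invariant even though delivery differs,")
print("   so K_H is a property of hydrolysis, not of blood flow.")
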