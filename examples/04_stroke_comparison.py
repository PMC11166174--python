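"""Stroke-model (MCAO) scenario: ipsilateral vs contralateral K_H.

The occluded hemisphere acidifies, slowing hydrolysis; its delivery also
drops to ~30 % of the contralateral side.  Fitting both TACs and forming
the ipsi/contra ratio separates the pH effect (rate) from the flow effect
(amplitude).
"""

from maglpet import (
    fit_monoexp,
    generate_regional_tacs,
    ips_cont_ratio,
    make_scenario,
    percent_reduction,
)

for scenario in ("mcao_1h", "mcao_3_4h", "mcao_6h"):
    tacs, truth = generate_regional_tacs(make_scenario(scenario))
    ips = fit_monoexp(tacs["ipsilateral"]).kh
    cont = fit_monoexp(tacs["contralateral"]).kh
    print(f"{scenario:10s}  K_H ips = {ips:.2f}, cont = {cont:.2f} 1/h   "
          f"ratio = {ips_cont_ratio(ips, cont):.2f}   "
          f"reduction = {percent_reduction(ips, cont):.0f} %")

print("\n-> at 3-4 h occlusion K_H is ~34 % lower ipsilaterally (ratio 0.66);")
print("   the deficit is smaller at 1 h and partially recovers by 6 h,")
print("   tracking the time course of intracellular acidification.")
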