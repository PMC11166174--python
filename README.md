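# maglpet

Kinetic analysis for **hydrolyzable covalent MAGL PET probes** — tracers
that bind monoacylglycerol lipase (MAGL) irreversibly and are then
hydrolyzed by the enzyme to [¹¹C]CO₂ at a pH-sensitive rate. Because the
hydrolysis rate **K_H** falls as intracellular pH falls, the late washout
of the tracer is an in-vivo proxy for tissue acidification (e.g. in
ischaemic stroke). The package is for PET modellers and preclinical
imaging groups who want to simulate, fit and map this class of probe
without scanner data: every input the pipeline needs can be generated
synthetically with known ground truth.

## The model

Tissue kinetics follow a linear compartment chain driven by a plasma
input C_P(t):

```
dC1/dt = K1·Cp − (k2 + k3)·C1        free probe
dC2/dt = k3·C1 − K_H·C2              covalent probe–enzyme complex
dC3/dt = K_H·C2 − k5·C3 (+ k4·Cp_CO2)  tissue CO2
```

with K1 (delivery), k2 (free-probe efflux), k3 (covalent association),
K_H (hydrolysis, reported in h⁻¹), k5 (CO₂ efflux, default 1.74 min⁻¹)
and optional k4 (CO₂ reuptake). Because k5 ≫ K_H and the input is
negligible ~15 min after a bolus, total activity C1+C2+C3 decays late in
the scan as

```
A(t) = A·e^(−a·t),   a = K_H
```

so K_H is estimated by mono-exponential non-linear least squares on the
15–90 min window of a time–activity curve (TAC). A voxel-wise **relative
K_H map** needs no fitting at all: average frames 3–10 (early uptake)
and 11–26 (late washout) of the 26-frame/90-min acquisition and form
(early − late)/early. The pH dependence of hydrolysis is a logistic
dose–response with half-maximal CO₂ production at pH 5.3, and a closed
in-vitro CO₂-collection assay (homogenate + bubbling trap) is simulated
for the bench-side counterpart.

## Worked example

```python
from maglpet import (make_scenario, generate_regional_tacs, fit_monoexp,
                     ips_cont_ratio, percent_reduction)

tacs, truth = generate_regional_tacs(make_scenario("mcao_3_4h"))
ips  = fit_monoexp(tacs["ipsilateral"]).kh     # 0.409 1/h  (truth 0.41)
cont = fit_monoexp(tacs["contralateral"]).kh   # 0.619 1/h  (truth 0.62)
print(round(ips_cont_ratio(ips, cont), 2))     # 0.66
print(round(percent_reduction(ips, cont)))     # 34
```

The `mcao_3_4h` scenario is a middle-cerebral-artery-occlusion stroke
model 3–4 h after occlusion: lesion delivery is cut to 30 % of the
contralateral side and lesion K_H to 0.41 vs 0.62 h⁻¹. The fits recover
both rates from the frame-binned TACs, giving an ipsi/contra ratio of
0.66 — a 34 % hydrolysis slowdown attributable to intracellular
acidification, separated cleanly from the delivery deficit.

The `examples/` directory holds one short script per capability
(compartment simulation, K_H fitting, in-vitro pH sweep, stroke
comparison, parametric mapping, file formats/CLI); each prints the
numbers it computes and what they mean. A thin CLI mirrors the
file-based steps: `maglpet simulate-tac | simulate-phantom | invitro-sim
| fit-kh | map-kh | report`.

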