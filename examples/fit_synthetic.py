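"""Fit the exposure model to a small synthetic rat population.

Generates two virtual obese rats on the 1 h i.v. protocol (seed-pinned
fixture), perturbs the generating elimination capacity, and re-estimates
it by maximizing the FOCE likelihood of the exposure stage.  (Absorption
plays no role under i.v. dosing, so the identifiable exposure parameter
here is the Michaelis-Menten capacity Vmax1.)
"""

from niacffa import fit_sequential
from niacffa.synthetic import make_fixture

table, truth = make_fixture("smoke_small")
model = truth["model"]

init = model.copy()
init.set_param("Vmax1", model.pk.Vmax1 * 1.5)  # start 50% off the truth

fit = fit_sequential(
    table, init, stages=("pk",),
    free={"pk": {"theta": ["Vmax1"], "omega": ["Vmax1"], "sigma": ["prop_NiAc"]}},
    maxiter=15,
)

print(f"generating Vmax1: {model.pk.Vmax1:.1f} umol/kg/h")
print(f"initial Vmax1:    {init.pk.Vmax1:.1f} umol/kg/h")
print(f"estimated Vmax1:  {fit.estimates['Vmax1']:.1f} umol/kg/h")
print(f"objective:        {fit.objective:.3f}  (converged: {fit.converged})")
print("per-subject random-effect modes (EBEs):")
for sid, eta in fit.ebes["pk"].items():
    print(f"  {sid}: " + ", ".join(f"{k}={v:+.3f}" for k, v in eta.items()))
print()
print("With only two subjects the estimate carries sampling noise, but the")
print("optimizer pulls the capacity back from the perturbed start toward")
print("the generating value; the absorption-rate mode stays at zero because")
print("intravenous data carry no absorption information.")
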