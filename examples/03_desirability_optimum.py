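"""Integrate body fat and fertility into one desirability surface.

Uses the reference response surfaces to evaluate the overall
desirability R = (d_Bf * d_F)^(1/2) under the four goal scenarios and
locates the optimum of each over the sampled design region.  Scenario I
(high body fat, low fertility) is the disease-model condition; the
script also reports R at the selected treatment S=35 g/dL sucrose,
P=3 g/dL yeast, D=6 d.
"""

import numpy as np

import dietrsm as dr

models = {r: dr.reference_model(r) for r in ("Bf", "F")}

for name, label in [("I", "Bf high, F low  (disease model)"),
                    ("II", "Bf low,  F high"),
                    ("III", "Bf high, F high"),
                    ("IV", "Bf low,  F low")]:
    sc = dr.build_scenario(name, models)
    opt = dr.find_optimum(models, sc)
    s, p, d = opt.actual_levels
    print(f"Scenario {name:<3} ({label}): "
          f"R* = {opt.R:.3f} at S={s:5.1f} g/dL, P={p:4.2f} g/dL, D={d:4.2f} d")

sc1 = dr.build_scenario("I", models)
preds = {r: models[r].predict(np.array([35.0, 3.0, 6.0])) for r in models}
r_sel = dr.overall_desirability(sc1, preds)
print()
print(f"Selected treatment S35 P3 D6: Bf = {preds['Bf']:.1f} nmol/mg, "
      f"F = {preds['F']:.2f} eggs/female/day, R = {r_sel:.3f}")
flat = dr.sucrose_flatness(models, sc1, fixed={"P": 3.0, "D": 6.0})
print(f"relative change of R for S in [35, 59.4] at P=3, D=6: {flat:.3f}")
print()
print("At P=3 the desirability saturates in sucrose above ~35 g/dL "
      "(small relative change), which is why the moderate-sucrose "
      "condition is as effective as the extreme one.")
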