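"""Compute the scalar assay endpoints from raw bench quantities.

Shows the normalizations used to turn raw assay readouts into the
modelled responses: triglyceride concentration to body fat (nmol/mg),
egg counts to fertility (eggs/female/day), the treated:control egg
production ratio, and body-weight-normalized hemolymph glucose.
"""

import dietrsm as dr

# three 5-uL aliquots of one homogenate, 100 uL PBS, 10 mg of flies
bf = dr.body_fat([1.8, 2.0, 2.2], buffer_volume=100.0, body_weight=10.0)
print(f"body fat: mean(1.8, 2.0, 2.2) nmol/uL x 100 uL / 10 mg = {bf:.1f} nmol TG/mg")

f = dr.fertility(egg_count=18, n_females=6, n_days=1.0)
print(f"fertility: 18 eggs / (6 females x 1 d) = {f:.1f} eggs/female/day")

ratio = dr.inhibition_ratio(f_treated=0.79, f_control=10.08)
print(f"egg-production inhibition ratio at day 6: 0.79 / 10.08 = {ratio:.3f}")

glc = dr.hemolymph_glucose(glucose_mass=35.1, body_weight=10.0)
print(f"hemolymph glucose: 35.1 ug / 10 mg = {glc:.2f} ug/mg")

print()
print("An inhibition ratio of ~0.08 means egg laying under the "
      "high-sucrose treatment is reduced to ~8% of its control level.")
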