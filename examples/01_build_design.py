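"""Build the 20-run central composite design over diet factors.

Constructs the rotatable three-factor CCD used throughout the package:
sucrose S = 30 +/- 17.5 g/dL, yeast protein P = 2 +/- 1 g/dL, and
treatment duration D = 5 +/- 2 d, with six replicated center points.
"""

import dietrsm as dr

design = dr.study_design()
print(design.runs.to_string(index=False,
                            float_format=lambda v: f"{v:.3f}"))
print()
print(f"runs: {design.n_runs}  (8 factorial + 6 axial + 6 center)")
print(f"star dilation alpha = {design.alpha:.4f}  (= 2^(3/4), rotatable)")
print()
print("Each row is one treatment condition; coded columns are the "
      "dimensionless levels (cube faces at +/-1, star points at "
      "+/-alpha), actual columns the levels in g/dL or days.")
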