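"""Emulate a replicate-level study and refit the quadratic surfaces.

Draws a full synthetic two-response study (4-7 replicate vials per run,
calibrated noise) from the reference body-fat and fertility surfaces,
collapses replicates to per-run means, fits the full second-order model
for each response, screens for outlying runs by externally studentized
residual, and prints the fit diagnostics.
"""

import dietrsm as dr

study = dr.emulate_study(seed=42)

for resp in ("Bf", "F"):
    fit = dr.fit_response(study[resp], resp)
    outliers = dr.flag_outliers(fit, threshold=3.0)
    if outliers:
        fit = dr.refit_excluding(study[resp], resp, outliers)
    report = dr.anova(fit)
    print(f"--- {resp} ---")
    print(f"datapoints: {fit.n_points} run means "
          f"({len(study[resp].data)} replicates)")
    print(f"runs excluded (|ESR| > 3): {outliers or 'none'}")
    print(f"R2 = {report.r2:.3f}, adjusted R2 = {report.r2_adjusted:.3f}, "
          f"predicted R2 = {report.r2_predicted:.3f}")
    print(f"overall F p-value = {report.overall_p:.2e}, "
          f"adequate precision = {report.adequate_precision:.1f}")
    coded = fit.model.to_representation("coded")
    print(f"coded S x P interaction = {coded.interaction_between('S','P'):+.3f} "
          f"(true {dr.reference_model(resp).to_representation('coded').interaction_between('S','P'):+.3f})")
    print()

print("Adjusted R2 near 0.97/0.99 and adequate precision >> 4 mean the "
      "fitted surfaces are reliable enough to navigate the design space; "
      "the coded interaction shows how strongly sucrose's effect depends "
      "on dietary protein.")
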