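"""Generate a synthetic ICB cohort and check that scoring recovers the
planted latent structure (truth is stored alongside the data).
"""

import numpy as np

import tmescore as tm

spec = tm.SyntheticCohortSpec(seed=1, n_samples=80, latent_corr=-0.3,
                              beta1=2.0, censor_rate=0.3)
cohort = tm.simulate_cohort(spec)
print(f"simulated {cohort.expression.n_genes} genes x "
      f"{cohort.expression.n_samples} samples; "
      f"responders: {int(cohort.clinical.response.sum())}, "
      f"censoring: {1 - cohort.clinical.event.mean():.2f} "
      f"(requested {spec.censor_rate})")

table = tm.compute_signature_scores(cohort.expression, cohort.signatures)
result = tm.compute_tmescore(table, cohort.signatures)

r = np.corrcoef(result.tmescore, cohort.truth["contrast"])[0, 1]
ra = np.corrcoef(result.tmescore_a, cohort.truth["latent_immune"])[0, 1]
rb = np.corrcoef(result.tmescore_b, cohort.truth["latent_stromal"])[0, 1]
print(f"corr(TMEscore,  latent immune-stromal contrast) = {r:.3f}")
print(f"corr(TMEscoreA, latent immune factor)           = {ra:.3f}")
print(f"corr(TMEscoreB, latent stromal factor)          = {rb:.3f}")

print("\nCorrelations near 1 show each score arm tracks the latent factor "
      "its signature genes load on — the structure the scoring method "
      "assumes in real tumors, here known exactly by construction.")
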