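"""Screen binary mutation calls for association with a continuous TME score
(Mann-Whitney per gene, BH-corrected), and test subtype enrichment of the
dichotomized score with Fisher's exact test.
"""

import numpy as np
import pandas as pd

import tmescore as tm

cohort = tm.simulate_cohort(tm.SyntheticCohortSpec(
    seed=5, n_samples=150, mut_genes=30, mut_assoc_slope=1.5))
table = tm.compute_signature_scores(cohort.expression, cohort.signatures)
score = tm.compute_tmescore(table, cohort.signatures).tmescore

screen = tm.score_mutation_screen(score, cohort.mutations, min_mutated=5)
print(f"{len(screen)} genes tested; top associations:")
print(screen.head(5).to_string(index=False))

# subtype enrichment: dichotomize the score and cross it with an
# immune-hot/cold grouping derived from the simulation truth
labels = tm.classify_by_cutoff(score, cutoff=float(np.median(score)))
subtype = pd.Series(np.where(cohort.truth["latent_immune"] > 0, "hot", "cold"),
                    index=cohort.truth.index)
res, counts = tm.subtype_enrichment(labels, subtype, test="fisher")
print("\ncontingency table (subtype x score class):")
print(counts)
print(f"Fisher exact p = {res.p:.2e}, odds ratio = {res.estimate:.2f}")

print("\nGenes whose mutations are drawn with probability increasing in the "
      "immune latent factor surface at the top of the screen with q far "
      "below 0.05; the enrichment p confirms score-high tumors concentrate "
      "in the immune-hot subtype.")
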