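"""Score a NanoString-style cohort: housekeeping normalization, PC1
signature scores, and the TMEscore assembly.

Builds the packaged deterministic fixture cohort (linear counts on the
synthetic A/B panel), normalizes it, and prints the first samples' scores.
"""

import tmescore as tm

expr, panel, clinical = tm.make_fixture_panel()
print(f"cohort: {expr.n_genes} genes x {expr.n_samples} samples "
      f"(scale={expr.scale})")

normalized, report = tm.normalize_housekeeping(expr, tm.HOUSEKEEPING_GENES)
print(f"housekeeping scale factors span "
      f"{report.scale_factor.min():.3f}-{report.scale_factor.max():.3f}")

table = tm.compute_signature_scores(normalized, panel, method="pca_pc1")
result = tm.compute_tmescore(table, panel).classify(cutoff=0.0)

print(result.to_frame().head(6).round(3))
print("\nTMEscore = TMEscoreA - TMEscoreB per sample; positive values mean "
      "immune signature activity exceeds stromal activity, the profile that "
      "tracks checkpoint-blockade response.  'high'/'low' dichotomizes at "
      "the chosen cutoff (boundary goes to 'low').")
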