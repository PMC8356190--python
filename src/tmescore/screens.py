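"""Association screens: score vs mutations, molecular subtypes, and other
signature scores.

These are the genome-/signature-wide sweeps used to ask what a continuous
TME score tracks: which binary mutation calls separate high- from low-score
tumors (Mann-Whitney per gene, BH across the tested genes), whether the
dichotomized score is enriched in a molecular-subtype grouping (Fisher or
chi-square on the 2x2 table), and which other signature scores correlate
with it (Spearman per column, BH across columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import ValidationError
from .scoring import SignatureScoreTable
from .stats import TestResult, bh_adjust, fisher_exact_2x2, mann_whitney, spearman_corr


@dataclass
class MutationMatrix:
    """Genes x samples binary mutation calls (1 = mutated)."""

    calls: pd.DataFrame  # index = gene_ids, columns = sample_ids

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise ValidationError("mutation matrix ids must be unique")
        vals = set(pd.unique(self.calls.to_numpy().ravel()).tolist())
        if not vals <= {0, 1, 0.0, 1.0, True, False}:
            raise ValidationError(f"mutation calls must be binary, got {sorted(vals)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)


def score_mutation_screen(score: pd.Series, mutations: MutationMatrix,
                          min_mutated: int = 5) -> pd.DataFrame:
    """Per-gene Mann-Whitney test of score by mutation status.

    Only genes with >= ``min_mutated`` mutated AND >= ``min_mutated``
    wild-type samples (among samples carrying a score) are tested; BH
    q-values are computed over exactly that tested set.  Rows are sorted by
    (q, p, gene).  ``direction`` is the sign of the median score difference
    (mutated - wild-type).
    """
    if min_mutated < 1:
        raise ValidationError("min_mutated must be >= 1")
    missing = [s for s in score.index if s not in mutations.calls.columns]
    if missing:
        raise ValidationError(f"samples with score but no mutation calls: {missing[:5]}")
    calls = mutations.calls[score.index]
    rows = []
    for gene in calls.index:
        mut = calls.loc[gene].to_numpy().astype(bool)
        if mut.sum() < min_mutated or (~mut).sum() < min_mutated:
            continue
        x = score.to_numpy(dtype=float)
        res = mann_whitney(x[mut], x[~mut])
        diff = float(np.median(x[mut]) - np.median(x[~mut]))
        rows.append({
            "feature_id": gene,
            "statistic": res.statistic,
            "p": res.p,
            "direction": "higher_in_mutated" if diff >= 0 else "lower_in_mutated",
            "n_mutated": int(mut.sum()),
            "n_wildtype": int((~mut).sum()),
        })
    if not rows:
        warnings.warn("no gene passed the min_mutated filter; empty association table")
        return pd.DataFrame(columns=["feature_id", "statistic", "p", "q",
                                     "direction", "n_mutated", "n_wildtype"])
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["q", "p", "feature_id"], kind="stable").reset_index(drop=True)
    return out[["feature_id", "statistic", "p", "q", "direction",
                "n_mutated", "n_wildtype"]]


def subtype_enrichment(class_label: pd.Series, subtype: pd.Series,
                       test: str = "fisher") -> tuple[TestResult, pd.DataFrame]:
    """2x2 enrichment of a binary class (e.g. responder, or TMEscore-high)
    across a two-level subtype grouping.

    The caller must group multi-level subtypes (e.g. {EBV, MSI-H} vs
    {CIN, GS}) into two levels first.  ``test`` is "fisher" (exact) or
    "chisq" (with Yates continuity correction).
    """
    shared = class_label.index.intersection(subtype.index)
    if len(shared) == 0:
        raise ValidationError("no shared samples between class and subtype")
    cl = class_label.loc[shared]
    st = subtype.loc[shared].astype(str)
    levels = sorted(st.unique())
    if len(levels) != 2:
        raise ValidationError(
            f"subtype has {len(levels)} levels {levels}; group them into exactly 2 first")
    table = pd.crosstab(st, cl)
    counts = table.to_numpy()
    if test == "fisher":
        res = fisher_exact_2x2(counts)
    elif test == "chisq":
        chi2, p, _, _ = sps.chi2_contingency(counts, correction=True)
        res = TestResult(statistic=float(chi2), p=float(p),
                         method="chi-square (Yates)", n=tuple(counts.sum(axis=1)))
    else:
        raise ValidationError("test must be 'fisher' or 'chisq'")
    return res, table


def signature_correlation_screen(score: pd.Series,
                                 table: SignatureScoreTable) -> pd.DataFrame:
    """Spearman correlation of a score against every signature column,
    with BH adjustment across the tested columns."""
    shared = score.index.intersection(table.scores.index)
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared samples")
    x = score.loc[shared].to_numpy(dtype=float)
    rows = []
    for name in table.signature_names:
        y = table.scores.loc[shared, name].to_numpy(dtype=float)
        if np.unique(y).size == 1:
            warnings.warn(f"dropping constant signature column {name!r}")
            continue
        res = spearman_corr(x, y)
        rows.append({"feature_id": name, "statistic": res.statistic, "p": res.p,
                     "direction": "positive" if res.statistic >= 0 else "negative",
                     "n": len(shared)})
    if not rows:
        raise ValidationError("no non-constant signature column to test")
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["q", "p", "feature_id"], kind="stable").reset_index(drop=True)
    return out[["feature_id", "statistic", "p", "q", "direction", "n"]]
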