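"""Signature scoring and TMEscore assembly.

The TMEscore summarizes the tumor microenvironment of a bulk expression
profile as the difference between immune-associated and stromal-associated
signature activity::

    TMEscore = sum_i PC1_i  -  sum_j PC1_j

where i ranges over signatures with direction +1 ("A", immune, favorable
under checkpoint blockade) and j over direction -1 ("B", stromal /
immune-exclusion).  Each per-signature score is the projection of the
z-standardized signature-gene submatrix onto the leading eigenvector of its
gene-gene covariance (PC1), which concentrates the score on the largest
block of co-varying genes in the set and down-weights genes that do not
track the rest.

Alternative per-signature scorers are provided: a single-sample gene-set
enrichment statistic (ssGSEA; rank-weighted cumulative enrichment, so it is
invariant to monotone per-sample transforms of expression) and the mean of
the z-scored signature genes.

NanoString-style linear counts are normalized to the log2 scale with
:func:`normalize_housekeeping` before scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._exceptions import CoverageError, ValidationError
from .io import ExpressionMatrix, GeneSignature, SignatureCollection

logger = logging.getLogger(__name__)

ScoreMethod = Literal["pca_pc1", "ssgsea", "zscore_mean"]


@dataclass
class NormalizationReport:
    """Per-sample scale factors and the housekeeping genes actually used."""

    sample_ids: list[str]
    scale_factor: np.ndarray
    housekeeping_used: list[str]
    missing_housekeeping: list[str]


@dataclass
class SsgseaConfig:
    """Rank-weight exponent and optional cross-sample range normalization."""

    alpha: float = 0.25
    normalize: bool = False

    def __post_init__(self) -> None:
        if not self.alpha >= 0:
            raise ValidationError("ssGSEA alpha must be >= 0")


@dataclass
class SignatureScoreTable:
    """Samples x signatures score matrix plus the method that produced it."""

    scores: pd.DataFrame  # index = sample_id, columns = signature names
    method: str

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValidationError("score table ids must be unique")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("score table contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class TMEscoreResult:
    """Per-sample TMEscoreA / TMEscoreB / TMEscore, optionally dichotomized."""

    tmescore_a: pd.Series
    tmescore_b: pd.Series
    tmescore: pd.Series
    class_label: pd.Series | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if (self.class_label is None) != (self.cutoff is None):
            raise ValidationError("class_label present iff cutoff present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tmescore.index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "TMEscoreA": self.tmescore_a,
            "TMEscoreB": self.tmescore_b,
            "TMEscore": self.tmescore,
        })
        if self.class_label is not None:
            df["TMEscore_class"] = self.class_label
        return df

    def classify(self, cutoff: float) -> "TMEscoreResult":
        """Return a copy with high/low labels at ``cutoff`` (score <= cutoff -> low)."""
        return TMEscoreResult(
            self.tmescore_a, self.tmescore_b, self.tmescore,
            class_label=classify_by_cutoff(self.tmescore, cutoff),
            cutoff=cutoff,
        )


def normalize_housekeeping(
    matrix: ExpressionMatrix, housekeeping: Sequence[str]
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Housekeeping-gene normalization of linear counts to the log2 scale.

    With a +1 offset applied to every count, each sample's scale factor is
    the cohort mean of the per-sample housekeeping geometric means divided by
    that sample's housekeeping geometric mean; normalized values are
    ``log2(factor * (count + 1))``.  After normalization the housekeeping
    geometric means (linear scale) are identical across samples, and
    re-applying the procedure is the identity.
    """
    if matrix.scale != "linear_counts":
        raise ValidationError("normalize_housekeeping expects scale='linear_counts'")
    present = [g for g in housekeeping if g in matrix.gene_ids]
    missing = [g for g in housekeeping if g not in matrix.gene_ids]
    if len(present) < 0.5 * len(housekeeping):
        raise CoverageError(
            f"only {len(present)}/{len(housekeeping)} housekeeping genes present; "
            f"missing: {missing}"
        )
    hk = matrix.subset_genes(present).values  # hk genes x samples
    allzero = np.all(hk == 0, axis=0)
    if allzero.any():
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(allzero)]
        raise ValidationError(f"sample(s) with all-zero housekeeping counts: {bad}")
    geomeans = np.exp(np.mean(np.log(hk + 1.0), axis=0))  # per sample
    factors = geomeans.mean() / geomeans
    normalized = np.log2(factors[np.newaxis, :] * (matrix.values + 1.0))
    out = ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids),
                           normalized, scale="log2")
    report = NormalizationReport(list(matrix.sample_ids), factors, present, missing)
    return out, report


def standardize_genes(
    matrix: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    zero_variance: Literal["error", "drop"] = "drop",
) -> ExpressionMatrix:
    """Z-score each gene row to mean 0, sample SD 1 (denominator n-1).

    ``genes`` restricts to a subset (order preserved); genes absent from the
    matrix are ignored here — coverage policy is the scorer's concern.
    """
    if matrix.n_samples < 3:
        raise ValidationError("standardization needs at least 3 samples")
    if genes is None:
        keep = list(matrix.gene_ids)
    else:
        keep = [g for g in genes if g in matrix.gene_ids]
        if not keep:
            raise ValidationError("none of the requested genes are in the matrix")
    sub = matrix.subset_genes(keep)
    sd = sub.values.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        flat_genes = [keep[i] for i in np.flatnonzero(flat)]
        if zero_variance == "error":
            raise ValidationError(f"zero-variance gene(s): {flat_genes}")
        logger.warning("dropping %d zero-variance gene(s): %s", len(flat_genes), flat_genes)
        keep = [g for g, f in zip(keep, flat) if not f]
        if not keep:
            raise ValidationError("all requested genes have zero variance")
        sub = matrix.subset_genes(keep)
        sd = sub.values.std(axis=1, ddof=1)
    z = (sub.values - sub.values.mean(axis=1, keepdims=True)) / sd[:, np.newaxis]
    return ExpressionMatrix(keep, list(matrix.sample_ids), z, scale="zscored")


def _orient(v: np.ndarray, genes: Sequence[str]) -> np.ndarray:
    """Resolve the eigenvector sign: component sum > 0, alphabetical tiebreak."""
    s = v.sum()
    if s > 0:
        return v
    if s < 0:
        return -v
    first = int(np.argsort(np.asarray(genes, dtype=object))[0])
    return v if v[first] >= 0 else -v


def pc1_signature_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    min_coverage: float = 0.5,
) -> pd.Series:
    """PC1 signature score: projection of z-scored signature genes onto the
    unit-norm leading covariance eigenvector.

    Scores have mean 0 across samples and variance equal to the leading
    eigenvalue.  The eigenvector is oriented so its component sum is positive
    (alphabetically-first gene non-negative on an exact tie), which makes
    "high score" mean "high signature-gene expression" and the output
    independent of gene ordering and linear-algebra backend.
    """
    if matrix.n_samples < 3:
        raise ValidationError("PC1 scoring needs at least 3 samples")
    z = standardize_genes(matrix, signature.genes, zero_variance="drop")
    found, wanted = z.n_genes, len(signature.genes)
    if found < min_coverage * wanted:
        raise CoverageError(
            f"signature {signature.name!r}: {found}/{wanted} usable genes, "
            f"below min_coverage={min_coverage}"
        )
    X = z.values.T  # samples x genes, columns already mean 0 / SD 1
    if found == 1:
        warnings.warn(f"signature {signature.name!r}: single usable gene; "
                      "PC1 score degenerates to that gene's z-scores")
        return pd.Series(X[:, 0], index=matrix.sample_ids, name=signature.name)
    pca = PCA(n_components=1, svd_solver="full")
    pca.fit(X)
    v = _orient(pca.components_[0], z.gene_ids)
    scores = X @ v
    return pd.Series(scores, index=matrix.sample_ids, name=signature.name)


def ssgsea_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    config: SsgseaConfig | None = None,
) -> pd.Series:
    """Single-sample gene-set enrichment score per sample.

    For each sample the genes are ordered by decreasing expression (ties
    broken by gene id, ascending, for determinism).  Walking down that list,
    the score accumulates the difference between the weighted in-set ECDF
    (weight ``rank^alpha``, where the top-expressed gene carries the largest
    rank) and the unweighted out-of-set ECDF.  Because only ranks enter, the
    score is invariant under strictly monotone per-sample transforms.
    """
    config = config or SsgseaConfig()
    genes = np.asarray(matrix.gene_ids, dtype=object)
    in_set = np.isin(genes, np.asarray(signature.genes, dtype=object))
    if not in_set.any():
        raise ValidationError(f"no gene of signature {signature.name!r} is in the matrix")
    if in_set.all():
        raise ValidationError(f"signature {signature.name!r} covers every gene "
                              "(empty complement)")
    n = matrix.n_genes
    n_in = int(in_set.sum())
    scores = np.empty(matrix.n_samples)
    # stable sort on gene id (asc) then expression (desc) -> deterministic ties
    id_order = np.argsort(genes.astype(str), kind="stable")
    for s in range(matrix.n_samples):
        x = matrix.values[:, s]
        order = id_order[np.argsort(-x[id_order], kind="stable")]
        member = in_set[order]
        rank_weight = (np.arange(n, 0, -1, dtype=float)) ** config.alpha
        w_in = np.where(member, rank_weight, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~member) / (n - n_in)
        scores[s] = float(np.sum(p_in - p_out))
    if config.normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return pd.Series(scores, index=matrix.sample_ids, name=signature.name)


def zscore_mean_score(matrix: ExpressionMatrix, signature: GeneSignature,
                      min_coverage: float = 0.5) -> pd.Series:
    """Mean of the z-scored signature genes per sample."""
    z = standardize_genes(matrix, signature.genes, zero_variance="drop")
    if z.n_genes < min_coverage * len(signature.genes):
        raise CoverageError(
            f"signature {signature.name!r}: {z.n_genes}/{len(signature.genes)} usable "
            f"genes, below min_coverage={min_coverage}"
        )
    return pd.Series(z.values.mean(axis=0), index=matrix.sample_ids, name=signature.name)


def compute_signature_scores(
    matrix: ExpressionMatrix,
    collection: SignatureCollection,
    method: ScoreMethod = "pca_pc1",
    min_coverage: float = 0.5,
    ssgsea_config: SsgseaConfig | None = None,
    permissive: bool = False,
) -> SignatureScoreTable:
    """Score every signature in ``collection`` (one column each, in order).

    With ``permissive=True`` a signature that fails (e.g. coverage) is dropped
    with a warning instead of aborting the whole table.
    """
    if len(collection) == 0:
        raise ValidationError("empty signature collection")
    cols: dict[str, pd.Series] = {}
    for sig in collection:
        try:
            if method == "pca_pc1":
                col = pc1_signature_score(matrix, sig, min_coverage=min_coverage)
            elif method == "ssgsea":
                col = ssgsea_score(matrix, sig, ssgsea_config)
            elif method == "zscore_mean":
                col = zscore_mean_score(matrix, sig, min_coverage=min_coverage)
            else:
                raise ValidationError(f"unknown scoring method {method!r}")
        except (ValidationError, CoverageError):
            if not permissive:
                raise
            warnings.warn(f"dropping signature {sig.name!r}: scoring failed")
            continue
        cols[sig.name] = col
    if not cols:
        raise ValidationError("no signature could be scored")
    return SignatureScoreTable(pd.DataFrame(cols), method=method)


def compute_tmescore(
    table: SignatureScoreTable,
    collection: SignatureCollection,
    rescale_signatures: bool = False,
) -> TMEscoreResult:
    """Assemble TMEscoreA (sum of +1 signatures), TMEscoreB (sum of -1) and
    TMEscore = TMEscoreA - TMEscoreB, summing in collection order.

    ``rescale_signatures`` z-standardizes each score column first so that
    signatures contribute on a common scale regardless of panel size.
    """
    directions: dict[str, int] = {s.name: s.direction for s in collection}
    missing = [n for n in table.signature_names if n not in directions]
    if missing:
        raise ValidationError(f"no direction for signature(s): {missing}")
    scores = table.scores
    if rescale_signatures:
        scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    pos = [s.name for s in collection if s.direction == +1 and s.name in scores.columns]
    neg = [s.name for s in collection if s.direction == -1 and s.name in scores.columns]
    if not pos and not neg:
        raise ValidationError("no scored signature has a direction")
    zero = pd.Series(0.0, index=scores.index)
    a = scores[pos].sum(axis=1) if pos else zero.copy()
    b = scores[neg].sum(axis=1) if neg else zero.copy()
    return TMEscoreResult(tmescore_a=a.rename("TMEscoreA"),
                          tmescore_b=b.rename("TMEscoreB"),
                          tmescore=(a - b).rename("TMEscore"))


def classify_by_cutoff(scores: pd.Series | np.ndarray, cutoff: float) -> pd.Series:
    """Dichotomize: score > cutoff -> "high", score <= cutoff -> "low"."""
    s = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    if not np.all(np.isfinite(s.to_numpy(dtype=float))):
        raise ValidationError("scores must be finite")
    return pd.Series(np.where(s.to_numpy(dtype=float) > cutoff, "high", "low"),
                     index=s.index, name="class")
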