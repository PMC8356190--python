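"""Synthetic ICB cohorts with the statistical structure the scoring method
assumes.

The generative model: two correlated latent factors per sample — immune
activity ``a_s`` and stromal activity ``b_s`` (bivariate standard normal,
correlation ``latent_corr``; the default is negative, emulating the
immune-excluded phenotype where stromal activation accompanies low immune
infiltration).  Signature-A genes load on ``a_s``, signature-B genes on
``b_s``, background genes are pure noise; all on the log2 scale.  Treatment
response is Bernoulli with logit ``beta0 + beta1 * t_s`` on the latent
contrast ``t_s = a_s - b_s`` (immune-high / stromal-low tumors respond);
survival is exponential with hazard ``baseline_hazard * exp(-hazard_gamma *
t_s)`` (high contrast = lower hazard) under independent uniform censoring
tuned to the requested censoring fraction; mutation calls are Bernoulli
with logit ``logit(0.2) + mut_assoc_slope * a_s`` (immune-hot tumors carry
more of the score-associated mutations, as with ARID1A/PIK3CA-like genes).

Everything is reproducible from the mandatory seed; each component draws
from its own spawned substream, so e.g. the mutation draws never perturb
the expression draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._exceptions import ValidationError
from .io import ClinicalTable, ExpressionMatrix, SignatureCollection
from .panel import HOUSEKEEPING_GENES, load_panel
from .screens import MutationMatrix


@dataclass
class SyntheticCohortSpec:
    """Parameters of the generative model.  ``seed`` is mandatory.

    Defaults are the package's reference study conditions: panel sizes 25/19,
    unit loadings and noise, response slope beta1 = 2 on the latent contrast,
    intercept beta0 = -1 (about a 25-30% responder rate, typical for ICB in
    advanced gastric cancer), latent correlation -0.3, 30% censoring.
    """

    seed: int
    n_samples: int = 60
    n_sig_a: int = 25
    n_sig_b: int = 19
    n_background: int = 56
    loading_a: float = 1.0
    loading_b: float = 1.0
    noise_sd: float = 1.0
    latent_corr: float = -0.3
    beta0: float = -1.0
    beta1: float = 2.0
    hazard_gamma: float = 1.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    mut_genes: int = 20
    mut_assoc_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValidationError("n_samples must be >= 10")
        if not (-1.0 < self.latent_corr < 1.0):
            raise ValidationError("latent_corr must be in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.loading_a < 0 or self.loading_b < 0:
            raise ValidationError("loadings must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        if not (0.0 < self.censor_rate < 1.0):
            raise ValidationError("censor_rate must be strictly between 0 and 1")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationMatrix
    truth: pd.DataFrame  # latent_immune, latent_stromal, contrast per sample
    signatures: SignatureCollection = field(default=None)  # A/B sets used

    @property
    def sample_ids(self) -> list[str]:
        return list(self.truth.index)


def _tuned_uniform_censoring(rates: np.ndarray, censor_rate: float,
                             rng: np.random.Generator,
                             times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Censoring C ~ U(0, u) with u solved so the expected censored fraction
    over the cohort's hazard rates equals ``censor_rate``."""

    def expected_censored(u: float) -> float:
        lu = rates * u
        return float(np.mean((1.0 - np.exp(-lu)) / lu))

    lo, hi = 1e-9, 1.0
    while expected_censored(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            raise ValidationError("could not tune censoring horizon")
    u = brentq(lambda v: expected_censored(v) - censor_rate, lo, hi)
    c = rng.uniform(0.0, u, size=len(times))
    observed = np.minimum(times, c)
    event = (times <= c).astype(int)
    return observed, event


def simulate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort (expression + clinical + mutations + truth)."""
    ss = np.random.SeedSequence(spec.seed)
    rng_latent, rng_expr, rng_resp, rng_surv, rng_mut = (
        np.random.default_rng(child) for child in ss.spawn(5))

    n = spec.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    cov = np.array([[1.0, spec.latent_corr], [spec.latent_corr, 1.0]])
    lat = rng_latent.multivariate_normal([0.0, 0.0], cov, size=n)
    a, b = lat[:, 0], lat[:, 1]
    t = a - b

    genes_a = [f"SIGA_{i + 1:03d}" for i in range(spec.n_sig_a)]
    genes_b = [f"SIGB_{i + 1:03d}" for i in range(spec.n_sig_b)]
    genes_bg = [f"BG_{i + 1:03d}" for i in range(spec.n_background)]
    mu = rng_expr.normal(7.0, 1.0, size=len(genes_a) + len(genes_b) + len(genes_bg))
    blocks = []
    k = 0
    for glist, loading, latent in ((genes_a, spec.loading_a, a),
                                   (genes_b, spec.loading_b, b),
                                   (genes_bg, 0.0, np.zeros(n))):
        noise = rng_expr.normal(0.0, spec.noise_sd, size=(len(glist), n))
        blocks.append(mu[k:k + len(glist), None] + loading * latent[None, :] + noise)
        k += len(glist)
    expr = ExpressionMatrix(genes_a + genes_b + genes_bg, samples,
                            np.vstack(blocks), scale="log2")

    response = rng_resp.binomial(1, expit(spec.beta0 + spec.beta1 * t))
    rates = spec.baseline_hazard * np.exp(-spec.hazard_gamma * t)
    latent_times = rng_surv.exponential(1.0 / rates)
    time, event = _tuned_uniform_censoring(rates, spec.censor_rate, rng_surv,
                                           latent_times)
    clinical = ClinicalTable(pd.DataFrame(
        {"response": response, "time": time, "event": event},
        index=pd.Index(samples, name="sample_id")))

    mut_ids = [f"MUT_{i + 1:03d}" for i in range(spec.mut_genes)]
    p_mut = expit(logit(0.2) + spec.mut_assoc_slope * a)
    calls = rng_mut.binomial(1, p_mut[None, :], size=(spec.mut_genes, n))
    mutations = MutationMatrix(pd.DataFrame(calls, index=mut_ids, columns=samples))

    truth = pd.DataFrame({"latent_immune": a, "latent_stromal": b, "contrast": t},
                         index=pd.Index(samples, name="sample_id"))
    from .io import GeneSignature  # local to avoid a cycle in type checkers
    sigs = SignatureCollection([
        GeneSignature("tme_signature_a", genes_a, +1),
        GeneSignature("tme_signature_b", genes_b, -1),
    ])
    return SyntheticCohort(expression=expr, clinical=clinical, mutations=mutations,
                           truth=truth, signatures=sigs)


def make_fixture_panel(seed: int = 11, n_samples: int = 24
                       ) -> tuple[ExpressionMatrix, SignatureCollection, ClinicalTable]:
    """Small deterministic NanoString-style cohort on the packaged panel.

    Expression is returned as linear counts (Poisson draws around per-sample
    library-size-scaled means) so that housekeeping normalization can be
    exercised; the signature collection is the packaged synthetic A/B panel.
    """
    panel = load_panel()
    sig_a = panel["tme_signature_a"]
    sig_b = panel["tme_signature_b"]
    ss = np.random.SeedSequence(seed)
    rng_latent, rng_expr, rng_clin = (np.random.default_rng(c) for c in ss.spawn(3))

    n = n_samples
    samples = [f"GC{i + 1:03d}" for i in range(n)]
    cov = np.array([[1.0, -0.3], [-0.3, 1.0]])
    lat = rng_latent.multivariate_normal([0.0, 0.0], cov, size=n)
    a, b = lat[:, 0], lat[:, 1]
    t = a - b

    genes = sig_a.genes + sig_b.genes + HOUSEKEEPING_GENES
    log2_expr = np.empty((len(genes), n))
    row = 0
    for glist, latent in ((sig_a.genes, a), (sig_b.genes, b)):
        mu = rng_expr.normal(7.0, 1.0, size=len(glist))
        log2_expr[row:row + len(glist)] = (
            mu[:, None] + latent[None, :]
            + rng_expr.normal(0.0, 0.8, size=(len(glist), n)))
        row += len(glist)
    mu_hk = rng_expr.uniform(9.0, 12.0, size=len(HOUSEKEEPING_GENES))
    log2_expr[row:] = mu_hk[:, None]  # housekeeping: flat across samples

    # per-sample library-size factor then Poisson counting noise
    lib = np.exp(rng_expr.normal(0.0, 0.25, size=n))
    counts = rng_expr.poisson(lib[None, :] * np.exp2(log2_expr)).astype(float)
    expr = ExpressionMatrix(genes, samples, counts, scale="linear_counts")

    response = rng_clin.binomial(1, expit(-1.0 + 2.0 * t))
    rates = 0.1 * np.exp(-1.0 * t)
    latent_times = rng_clin.exponential(1.0 / rates)
    time, event = _tuned_uniform_censoring(rates, 0.3, rng_clin, latent_times)
    clinical = ClinicalTable(pd.DataFrame(
        {"response": response, "time": time, "event": event},
        index=pd.Index(samples, name="sample_id")))
    return expr, panel, clinical
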