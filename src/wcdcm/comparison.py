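"""Group-level Bayesian model selection and model averaging.

Operates on evidence tables F (N subjects x K models, variational free
energies in nats):

* fixed-effects (FFX) comparison via group Bayes factors — log evidences
  sum over subjects, posterior model probabilities are a softmax of the
  column sums;
* random-effects (RFX) comparison via the variational Dirichlet scheme:
  subject-wise model assignments and Dirichlet counts are iterated to
  convergence, and exceedance probabilities (the probability that a model
  is the most frequent in the population) are estimated by seeded
  Monte-Carlo sampling of the posterior Dirichlet;
* protected exceedance probabilities, which shrink the exceedance
  probabilities toward chance by the Bayesian omnibus risk (BOR) — the
  posterior probability of the null hypothesis that all model frequencies
  are equal;
* family-level inference with the prior re-normalized so every family
  carries equal prior mass; and
* Bayesian model averaging (BMA) of connectivity parameters over models,
  weighted by posterior model probabilities.

The conventional "strong evidence" threshold is a log Bayes factor of
about 3 or more (a factor of about 20 in evidence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

from .exceptions import InvalidParameterError, ShapeError

__all__ = [
    "EvidenceTable",
    "FFXResult",
    "RFXResult",
    "BMAResult",
    "STRONG_EVIDENCE_LOGBF",
    "ffx_compare",
    "rfx_infer",
    "exceedance",
    "protect",
    "family_level",
    "bma",
]

STRONG_EVIDENCE_LOGBF = 3.0


@dataclass
class EvidenceTable:
    """Per-subject log model evidences (free energies, nats)."""

    F: np.ndarray                 # (N, K)
    model_labels: tuple = ()
    family_labels: tuple = ()     # optional, one family name per model

    def __post_init__(self):
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if not np.all(np.isfinite(self.F)):
            raise InvalidParameterError("evidence table has non-finite entries")
        if not self.model_labels:
            self.model_labels = tuple(f"m{k + 1}"
                                      for k in range(self.F.shape[1]))
        if len(self.model_labels) != self.F.shape[1]:
            raise ShapeError("model_labels length != number of models")

    @property
    def n_subjects(self) -> int:
        return self.F.shape[0]

    @property
    def n_models(self) -> int:
        return self.F.shape[1]


@dataclass
class FFXResult:
    group_log_evidence: np.ndarray   # column sums of F
    posterior: np.ndarray            # softmax of group log evidence
    log_gbf: np.ndarray              # (K, K) pairwise log group Bayes factors
    strong: np.ndarray               # (K, K) bool, log-GBF >= 3

    def best(self) -> int:
        return int(np.argmax(self.posterior))


@dataclass
class RFXResult:
    dirichlet_alpha: np.ndarray
    expected: np.ndarray
    exceedance: np.ndarray
    protected_exceedance: np.ndarray
    bor: float

    def best(self) -> int:
        return int(np.argmax(self.expected))


def ffx_compare(table: EvidenceTable, prior=None) -> FFXResult:
    """Fixed-effects model comparison by group Bayes factors.

    Group log evidence per model is the column sum of F; posterior model
    probabilities are proportional to ``prior * exp(group log evidence)``
    (uniform prior by default).
    """
    g = table.F.sum(axis=0)
    logp = g - g.max()
    if prior is not None:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != g.shape:
            raise ShapeError("prior length != number of models")
        if not np.isclose(prior.sum(), 1.0):
            raise InvalidParameterError("model prior must sum to 1")
        with np.errstate(divide="ignore"):
            logp = logp + np.log(prior)
    p = np.exp(logp - logsumexp(logp))
    log_gbf = g[:, None] - g[None, :]
    return FFXResult(group_log_evidence=g, posterior=p, log_gbf=log_gbf,
                     strong=log_gbf >= STRONG_EVIDENCE_LOGBF)


def exceedance(alpha, n_samples: int = 100_000, seed: int = 0) -> np.ndarray:
    """Pr(x_k = max) under Dirichlet(alpha), by seeded Monte Carlo.

    For K = 2 this equals the regularized incomplete beta function
    ``Pr(Beta(a1, a2) > 1/2)``, used as a cross-check in the tests.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise InvalidParameterError("Dirichlet parameters must be positive")
    rng = np.random.default_rng(seed)
    g = rng.standard_gamma(alpha, size=(n_samples, len(alpha)))
    winners = np.argmax(g, axis=1)
    return np.bincount(winners, minlength=len(alpha)) / n_samples


def exceedance_beta2(alpha) -> np.ndarray:
    """Closed-form exceedance for K = 2 via the incomplete beta function."""
    a1, a2 = float(alpha[0]), float(alpha[1])
    phi2 = betainc(a1, a2, 0.5)   # Pr(x1 < 1/2)
    return np.array([1.0 - phi2, phi2])


def _dirichlet_vb(F: np.ndarray, alpha0: np.ndarray, tol: float = 1e-6,
                  max_iter: int = 10_000):
    """Variational Dirichlet scheme for RFX-BMS.

    Iterates u_nk ~ exp(F_nk + digamma(a_k) - digamma(sum a)) and
    a = a0 + sum_n u_nk until the alpha change falls below ``tol``.
    Returns (alpha, u).
    """
    N, K = F.shape
    alpha = alpha0.copy()
    u = np.full((N, K), 1.0 / K)
    for _ in range(max_iter):
        logu = F + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        logu = logu - logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u


def _rfx_free_energy(F, alpha0, alpha, u) -> float:
    """Evidence lower bound of the Dirichlet random-effects model."""
    a_sum = alpha.sum()
    E_lnr = digamma(alpha) - digamma(a_sum)
    acc = float(np.sum(u * F))
    ent_m = -float(np.sum(u[u > 0] * np.log(u[u > 0])))
    e_prior_m = float(np.sum(u * E_lnr[None, :]))
    ln_b = lambda a: float(np.sum(gammaln(a)) - gammaln(np.sum(a)))
    e_prior_r = -ln_b(alpha0) + float(np.sum((alpha0 - 1) * E_lnr))
    ent_r = ln_b(alpha) - float(np.sum((alpha - 1) * E_lnr))
    return acc + e_prior_m + e_prior_r + ent_m + ent_r


def _null_free_energy(F: np.ndarray) -> float:
    """Log evidence of the null model: all model frequencies fixed equal."""
    K = F.shape[1]
    return float(np.sum(logsumexp(F, axis=1) - np.log(K)))


def protect(exceedance_prob: np.ndarray, table: EvidenceTable,
            alpha0=None) -> tuple:
    """Protected exceedance probabilities and the Bayesian omnibus risk.

    BOR is the posterior probability of the null hypothesis that all
    model frequencies are equal, computed from the free energies of the
    null and the Dirichlet alternative; the protected probabilities are
    ``phi * (1 - BOR) + BOR / K``.
    """
    phi = np.asarray(exceedance_prob, dtype=float)
    K = table.n_models
    if len(phi) != K:
        raise ShapeError("exceedance vector length != number of models")
    if alpha0 is None:
        alpha0 = np.ones(K)
    alpha, u = _dirichlet_vb(table.F, alpha0)
    f1 = _rfx_free_energy(table.F, alpha0, alpha, u)
    f0 = _null_free_energy(table.F)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    return phi * (1.0 - bor) + bor / K, bor


def rfx_infer(table: EvidenceTable, alpha0=None, n_samples: int = 100_000,
              seed: int = 0) -> RFXResult:
    """Random-effects BMS: posterior Dirichlet over model frequencies,
    with expected, exceedance and protected exceedance probabilities."""
    K = table.n_models
    if K < 2:
        raise InvalidParameterError("need at least two models to compare")
    if alpha0 is None:
        alpha0 = np.ones(K)
    alpha0 = np.asarray(alpha0, dtype=float)
    alpha, _ = _dirichlet_vb(table.F, alpha0)
    expected = alpha / alpha.sum()
    phi = exceedance(alpha, n_samples=n_samples, seed=seed)
    pxp, bor = protect(phi, table, alpha0=alpha0)
    return RFXResult(dirichlet_alpha=alpha, expected=expected,
                     exceedance=phi, protected_exceedance=pxp, bor=bor)


def family_level(table: EvidenceTable, partition, mode: str = "ffx",
                 n_samples: int = 100_000, seed: int = 0) -> dict:
    """Family-level inference under a family-uniform prior adjustment.

    FFX: the model prior is re-normalized so each family carries equal
    prior mass; the family posterior sums its members' posteriors.
    RFX: the Dirichlet prior gives each model ``1/|family|`` so families
    start exchangeable; family exceedance sums Dirichlet samples within
    families.
    """
    labels = list(partition.labels)
    families = list(partition.families)
    K = table.n_models
    if len(labels) != K:
        raise ShapeError("partition does not cover the model set")
    sizes = {fam: labels.count(fam) for fam in families}
    if any(sz == 0 for sz in sizes.values()):
        raise InvalidParameterError("empty family")
    nf = len(families)
    if mode == "ffx":
        prior = np.array([1.0 / (nf * sizes[lab]) for lab in labels])
        res = ffx_compare(table, prior=prior)
        fam_post = {fam: float(np.sum(res.posterior[[i for i in range(K)
                                                     if labels[i] == fam]]))
                    for fam in families}
        return {"mode": "ffx", "families": families,
                "posterior": np.array([fam_post[f] for f in families]),
                "model_result": res}
    if mode == "rfx":
        alpha0 = np.array([1.0 / sizes[lab] for lab in labels])
        alpha, _ = _dirichlet_vb(table.F, alpha0)
        rng = np.random.default_rng(seed)
        g = rng.standard_gamma(alpha, size=(n_samples, K))
        g /= g.sum(axis=1, keepdims=True)
        fam_mass = np.stack([g[:, [i for i in range(K) if labels[i] == fam]]
                             .sum(axis=1) for fam in families], axis=1)
        winners = np.argmax(fam_mass, axis=1)
        fam_xp = np.bincount(winners, minlength=nf) / n_samples
        fam_expected = np.array(
            [alpha[[i for i in range(K) if labels[i] == fam]].sum()
             for fam in families])
        fam_expected /= alpha.sum()
        return {"mode": "rfx", "families": families,
                "expected": fam_expected, "exceedance": fam_xp,
                "dirichlet_alpha": alpha}
    raise InvalidParameterError(f"unknown mode {mode!r}")


@dataclass
class BMAResult:
    parameter_names: list
    mean: np.ndarray
    sign_probability: np.ndarray
    significant: np.ndarray
    threshold: float

    def as_dict(self) -> dict:
        return {n: (float(m), float(p)) for n, m, p in
                zip(self.parameter_names, self.mean, self.sign_probability)}


def bma(posteriors, model_probabilities, threshold: float = 0.95) -> BMAResult:
    """Bayesian model averaging of connectivity parameters.

    ``posteriors`` is a list of :class:`~wcdcm.inversion.Posterior`; the
    union of their parameter names defines the averaged table. A model in
    which a parameter is structurally absent contributes value 0 with all
    its probability mass at 0. The sign probability of a parameter is the
    model-averaged ``max(Pr(theta > 0), Pr(theta < 0))``; parameters are
    flagged significant above ``threshold``.
    """
    p = np.asarray(model_probabilities, dtype=float)
    if len(p) != len(posteriors):
        raise ShapeError("one probability per posterior required")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise InvalidParameterError("model probabilities must sum to 1")
    names = []
    for post in posteriors:
        for n in post.names:
            if n not in names:
                names.append(n)
    mean = np.zeros(len(names))
    signp = np.zeros(len(names))
    for post, pm in zip(posteriors, p):
        sp = post.sign_probability()
        for j, n in enumerate(post.names):
            i = names.index(n)
            mean[i] += pm * post.mean[j]
            signp[i] += pm * sp[j]
        # absent parameters: mass at 0 contributes sign probability 0
    return BMAResult(parameter_names=names, mean=mean,
                     sign_probability=signp, significant=signp > threshold,
                     threshold=threshold)
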