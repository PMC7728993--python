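"""Validation harness: SNR sweeps, connection-detection ROC, parameter and
model recovery.

The harness emulates the synthetic-validation design used to probe
robustness of the inversion: data are generated from the bilinear
ground-truth network at a range of signal-to-noise ratios, inverted under
both neuronal variants, and compared by explained variance, flat-line
counts, and the ability to detect which connections were present in the
generator (ROC/AUC over posterior presence probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, ShapeError, UndefinedMetricError
from .generative import (InputTimeline, make_ground_truth_network,
                         simulate_dataset)
from .hemodynamics import HemodynamicParams
from .inversion import InversionOptions, invert
from .neuronal import ModelSpec, NeuronalParams

__all__ = ["ROCResult", "SweepResult", "connection_roc", "snr_sweep",
           "recovery_metrics", "model_recovery", "saturated_spec",
           "edge_scores"]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class SweepResult:
    """Explained variance and flat-line statistics per (SNR, variant)."""

    snr_grid: np.ndarray
    variants: tuple
    ev: dict           # variant -> (n_snr, n_real) explained variance
    flatline: dict     # variant -> (n_snr,) counts
    failures: dict     # variant -> (n_snr,) inversion failures
    scores: dict       # variant -> (n_snr, n_real, n_candidate_edges)
    edge_truth: np.ndarray
    seeds: np.ndarray

    def mean_ev(self, variant) -> np.ndarray:
        return np.nanmean(self.ev[variant], axis=1)

    def sem_ev(self, variant) -> np.ndarray:
        e = self.ev[variant]
        n = np.sum(np.isfinite(e), axis=1)
        return np.nanstd(e, axis=1, ddof=1) / np.sqrt(np.maximum(n, 1))


def connection_roc(scores, truth, thresholds=None) -> ROCResult:
    """ROC over per-connection presence probabilities.

    A connection is predicted present iff its score exceeds the
    threshold. A predicted edge absent from the generator is a false
    positive; a generator edge not predicted is a false negative. The
    curve sweeps the threshold from strict to lenient and always includes
    the endpoints (fpr, tpr) = (0, 0) and (1, 1); AUC is the trapezoidal
    area under the path.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise ShapeError("scores and truth must be index-aligned")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "AUC undefined without both present and absent connections")
    if thresholds is None:
        thresholds = np.unique(scores)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for th in thresholds:
        pred = scores > th
        tpr.append(np.sum(pred & truth) / n_pos)
        fpr.append(np.sum(pred & ~truth) / n_neg)
    tpr.append(1.0)
    fpr.append(1.0)
    tpr = np.asarray(tpr)
    fpr = np.asarray(fpr)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def saturated_spec(spec: ModelSpec, variant: str | None = None) -> ModelSpec:
    """The fully connected version of ``spec``: all inter-regional
    connections present (modulation and input masks unchanged). Fitting
    this saturated structure once per dataset yields presence scores for
    every candidate edge without refitting the whole model space."""
    l = spec.n_regions
    A_mask = np.ones((l, l), dtype=bool)
    return ModelSpec(spec.region_names, A_mask, spec.B_masks, spec.C_mask,
                     variant=variant or spec.variant, states=spec.states)


def edge_scores(posterior, sat: ModelSpec):
    """Presence probability for each off-diagonal connection of the
    saturated spec, from the posterior sign probabilities."""
    l = sat.n_regions
    rn = sat.region_names
    sp = posterior.sign_probability()
    out = {}
    for i in range(l):
        for j in range(l):
            if i == j:
                continue
            name = f"A[{rn[i]}<-{rn[j]}]"
            out[(i, j)] = float(sp[posterior.names.index(name)])
    return out


def snr_sweep(snr_grid, n_real: int, seed: int,
              variants=("bilinear", "wilson_cowan"),
              duration: float = 180.0, TR: float = 2.0, dt: float = 0.25,
              opts: InversionOptions | None = None,
              generator_kwargs: dict | None = None) -> SweepResult:
    """Generate bilinear ground-truth data per SNR and invert under both
    neuronal variants, recording explained variance, flat-line flags and
    per-edge presence scores from the saturated fit.

    Each (SNR, realization) cell uses a deterministic child seed, so the
    whole table is reproducible bit-for-bit from ``seed``. Inversion
    failures are recorded per cell, not fatal.
    """
    from .generative import default_input_timeline

    snr_grid = np.asarray(list(snr_grid), dtype=float)
    if np.any(snr_grid <= 0):
        raise InvalidParameterError("SNR grid must be positive")
    gk = generator_kwargs or {}
    spec, npar, hp = make_ground_truth_network(variant="bilinear", **gk)
    tl = default_input_timeline(duration, dt=dt)
    if opts is None:
        opts = InversionOptions(max_iter=32)
    l = spec.n_regions
    edges = [(i, j) for i in range(l) for j in range(l) if i != j]
    edge_truth = np.array([spec.A_mask[i, j] for (i, j) in edges])
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(snr_grid) * n_real).reshape(
        len(snr_grid), n_real) % (2 ** 31)
    ev = {v: np.full((len(snr_grid), n_real), np.nan) for v in variants}
    flat = {v: np.zeros(len(snr_grid), dtype=int) for v in variants}
    fails = {v: np.zeros(len(snr_grid), dtype=int) for v in variants}
    scores = {v: np.full((len(snr_grid), n_real, len(edges)), np.nan)
              for v in variants}
    for a, snr in enumerate(snr_grid):
        for r in range(n_real):
            ds = simulate_dataset(spec, npar, hp, tl, snr=snr, n_real=1,
                                  seed=int(seeds[a, r]), TR=TR)
            data = ds.noisy[0]
            for v in variants:
                sat = saturated_spec(spec, variant=v)
                try:
                    post = invert(data, tl, sat, opts=opts)
                except Exception:
                    fails[v][a] += 1
                    continue
                ev[v][a, r] = post.explained_variance
                flat[v][a] += int(post.flatline)
                es = edge_scores(post, sat)
                scores[v][a, r] = [es[e] for e in edges]
    return SweepResult(snr_grid=snr_grid, variants=tuple(variants), ev=ev,
                       flatline=flat, failures=fails, scores=scores,
                       edge_truth=edge_truth, seeds=seeds)


def sweep_roc(sweep: SweepResult, variant: str, snr_index: int) -> ROCResult:
    """ROC over all edge scores pooled across realizations at one SNR."""
    sc = sweep.scores[variant][snr_index]
    ok = np.all(np.isfinite(sc), axis=1)
    sc = sc[ok]
    truth = np.tile(sweep.edge_truth, (sc.shape[0], 1))
    return connection_roc(sc.ravel(), truth.ravel())


def recovery_metrics(true_params: NeuronalParams, posterior,
                     spec: ModelSpec) -> dict:
    """Bias, RMSE and correlation between true and posterior-mean nonzero
    couplings: every A, B and C entry allowed by the masks (self-connections
    included — they are nonzero couplings of the generator)."""
    rn = spec.region_names
    names, truth = [], []
    for i, j in np.argwhere(spec.A_mask):
        names.append(f"A[{rn[i]}<-{rn[j]}]")
        truth.append(true_params.A[i, j])
    for k, i, j in np.argwhere(spec.B_masks):
        names.append(f"B{k + 1}[{rn[i]}<-{rn[j]}]")
        truth.append(true_params.B[k, i, j])
    for i, j in np.argwhere(spec.C_mask):
        names.append(f"C[{rn[i]}<-u{j + 1}]")
        truth.append(true_params.C[i, j])
    truth = np.asarray(truth)
    est = np.array([posterior.get(n) for n in names])
    bias = est - truth
    out = {"names": names, "true": truth, "estimated": est, "bias": bias,
           "rmse": float(np.sqrt(np.mean(bias ** 2)))}
    if len(names) >= 3 and np.std(truth) > 0 and np.std(est) > 0:
        out["correlation"] = float(np.corrcoef(truth, est)[0, 1])
    else:
        out["correlation"] = None
    return out


def model_recovery(specs, params_list, hp: HemodynamicParams,
                   inputs: InputTimeline, snr: float, n_real: int,
                   seed: int, TR: float = 2.0,
                   opts: InversionOptions | None = None) -> np.ndarray:
    """Confusion matrix of model selection over a small model set.

    Entry (i, j) counts the realizations generated under model i for
    which model j attains the highest free energy. Rows sum to
    ``n_real`` when no inversion fails.
    """
    K = len(specs)
    if K < 2:
        raise InvalidParameterError("need at least two models")
    if opts is None:
        opts = InversionOptions(max_iter=32)
    conf = np.zeros((K, K), dtype=int)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(K * n_real).reshape(K, n_real) % (2 ** 31)
    for i, (gen_spec, gen_par) in enumerate(zip(specs, params_list)):
        for r in range(n_real):
            ds = simulate_dataset(gen_spec, gen_par, hp, inputs, snr=snr,
                                  n_real=1, seed=int(seeds[i, r]), TR=TR)
            data = ds.noisy[0]
            Fs = np.full(K, -np.inf)
            for j, fit_spec in enumerate(specs):
                try:
                    post = invert(data, inputs, fit_spec, opts=opts)
                    Fs[j] = post.free_energy
                except Exception:
                    continue
            if np.any(np.isfinite(Fs)):
                conf[i, int(np.argmax(Fs))] += 1
    return conf
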