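"""Forward (generative) model: neuronal + hemodynamic cascade to BOLD.

The full model integrates, per region, the neuronal state equation
(bilinear or Wilson-Cowan, one or two states) together with the four
balloon-model states on a microtime grid much finer than the scan
repetition time, then samples the BOLD observation equation at TR.
Integration is fixed-step classical Runge-Kutta (RK4) with the inputs
held piecewise-constant over each microtime step.

The module also provides the three-region ground-truth network used for
synthetic validation (one driving input into region 1, feedforward
connections 1->2, 1->3 and 3->2, contextual modulation on 1->3 and 3->2)
and a seeded generator of noisy datasets at controlled SNR, where SNR is
defined per region as sd(signal)/sd(noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DivergenceError, InvalidParameterError, ShapeError
from .hemodynamics import HemodynamicParams
from .neuronal import ModelSpec, NeuronalParams

__all__ = [
    "InputTimeline",
    "BOLDSeries",
    "SyntheticDataset",
    "integrate",
    "make_ground_truth_network",
    "default_input_timeline",
    "simulate_dataset",
]


@dataclass
class InputTimeline:
    """Experimental inputs sampled on the microtime grid.

    ``u`` has shape (m, T_micro); column k holds the input values on
    ``[k*dt, (k+1)*dt)``. Boxcars are 0/1 unless amplitudes are given.
    """

    dt: float
    u: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if not np.all(np.isfinite(self.u)):
            raise InvalidParameterError("input timeline contains non-finite values")
        if not self.names:
            self.names = tuple(f"u{j + 1}" for j in range(self.u.shape[0]))

    @property
    def n_inputs(self) -> int:
        return self.u.shape[0]

    @property
    def duration(self) -> float:
        return self.u.shape[1] * self.dt

    @classmethod
    def from_events(cls, events, dt: float, duration: float, names=None):
        """Compile (name, onset_s, duration_s[, amplitude]) events to the grid.

        Overlapping events of one input are merged (amplitudes take the
        element-wise maximum). Compilation is idempotent: recompiling the
        sampled form through :meth:`to_events` round-trips for 0/1 boxcars.
        """
        if names is None:
            names = []
            for ev in events:
                if ev[0] not in names:
                    names.append(ev[0])
        T = int(round(duration / dt))
        u = np.zeros((len(names), T))
        for ev in events:
            name, onset, dur = ev[0], float(ev[1]), float(ev[2])
            amp = float(ev[3]) if len(ev) > 3 else 1.0
            if onset < 0:
                raise InvalidParameterError(f"negative onset {onset} for {name}")
            j = list(names).index(name)
            i0 = int(round(onset / dt))
            i1 = min(int(round((onset + dur) / dt)), T)
            u[j, i0:i1] = np.maximum(u[j, i0:i1], amp)
        return cls(dt=dt, u=u, names=tuple(names))

    def resample(self, dt_new: float) -> "InputTimeline":
        """Zero-order-hold resampling onto a new microtime step."""
        if np.isclose(dt_new, self.dt):
            return self
        T_new = int(round(self.duration / dt_new))
        idx = np.minimum((np.arange(T_new) * dt_new / self.dt).astype(int),
                         self.u.shape[1] - 1)
        return InputTimeline(dt=dt_new, u=self.u[:, idx], names=self.names)


@dataclass
class BOLDSeries:
    """Region-averaged BOLD time series sampled at TR.

    ``y`` has shape (T, l): one row per scan, one column per region, in
    % signal change.
    """

    TR: float
    y: np.ndarray
    region_names: tuple = ()

    def __post_init__(self):
        if self.TR <= 0:
            raise InvalidParameterError("TR must be positive")
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if not self.region_names:
            self.region_names = tuple(f"R{i + 1}" for i in range(self.y.shape[1]))
        if len(self.region_names) != self.y.shape[1]:
            raise ShapeError("region_names length != number of columns")

    @property
    def n_regions(self) -> int:
        return self.y.shape[1]

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]


@dataclass
class SyntheticDataset:
    """A clean simulated series plus seeded noisy realizations at one SNR."""

    spec: ModelSpec
    neuronal: NeuronalParams
    hemo: HemodynamicParams
    inputs: InputTimeline
    clean: BOLDSeries
    noisy: list
    snr: float
    seed: int


# ---------------------------------------------------------------------------
# batched fixed-step RK4 integration of the full cascade
# ---------------------------------------------------------------------------

_MAX_INPUT_COMBOS = 256


def _stack_params(spec: ModelSpec, params_list, hemo_scale_list, hp):
    """Stack a list of NeuronalParams (+ per-region hemo log-scalings) into
    batched arrays for simultaneous integration."""
    l, m = spec.n_regions, spec.n_inputs
    Bsz = len(params_list)
    P = {}
    if spec.states == "one":
        P["A"] = np.stack([p.A for p in params_list])
        P["B"] = np.stack([p.B for p in params_list])
        P["C"] = np.stack([p.C for p in params_list])
        if spec.variant == "wilson_cowan":
            P["alpha"] = np.stack([p.alpha for p in params_list])
    else:
        for name in ("w_ee", "w_se", "w_si", "w_ie", "w_ei", "C"):
            P[name] = np.stack([getattr(p, name) for p in params_list])
        P["b_ee"] = np.stack(
            [p.b_ee if p.b_ee is not None else np.zeros((m, l, l))
             for p in params_list])
        P["b_ie"] = np.stack(
            [p.b_ie if p.b_ie is not None else np.zeros((m, l))
             for p in params_list])
        if spec.variant == "wilson_cowan":
            P["alpha_e"] = np.stack([p.alpha_e for p in params_list])
            P["alpha_i"] = np.stack([p.alpha_i for p in params_list])
    if hemo_scale_list is None:
        kappa = np.full((Bsz, l), hp.kappa)
        tau = np.full((Bsz, l), hp.tau_h)
    else:
        kappa = np.stack([hp.kappa * np.exp(hs[0]) for hs in hemo_scale_list])
        tau = np.stack([hp.tau_h * np.exp(hs[1]) for hs in hemo_scale_list])
    P["kappa"], P["tau"] = kappa, tau
    return P


def _integrate_batch(spec, P, hp, u, dt, n_steps, sample_stride,
                     store_latents=False):
    """Integrate a batch of parameter sets sharing one input timeline.

    Returns (bold, first_bad, latents): ``bold`` has shape
    (n_samples, Bsz, l) with NaN after a member diverges; ``first_bad[b]``
    is the first bad microtime index (or -1); ``latents`` covers batch
    member 0 only.
    """
    l = spec.n_regions
    two = spec.states == "two"
    wc = spec.variant == "wilson_cowan"
    Bsz = P["C"].shape[0]
    n_state = 6 if two else 5

    # inputs are piecewise constant; precompute effective couplings per
    # distinct input vector
    ucols = u.T[:n_steps]
    if len(ucols) < n_steps:
        ucols = np.vstack([ucols, np.zeros((n_steps - len(ucols), u.shape[0]))])
    uniq, inv = np.unique(ucols, axis=0, return_inverse=True)
    if len(uniq) > _MAX_INPUT_COMBOS:
        # continuous-valued inputs: treat every step as its own combo
        uniq, inv = ucols, np.arange(n_steps)
    if two:
        W = P["w_ee"].copy()
        idx = np.arange(l)
        W[:, idx, idx] = 0.0
        Weff = W[None] + np.einsum("km,bmij->kbij", uniq, P["b_ee"])
        Weff[:, :, idx, idx] = 0.0
        wie_eff = P["w_ie"][None] + np.einsum("km,bml->kbl", uniq, P["b_ie"])
        cu = np.einsum("blm,km->kbl", P["C"], uniq)
        w_se, w_si, w_ei = P["w_se"], P["w_si"], P["w_ei"]
        if wc:
            ae, ai = P["alpha_e"], P["alpha_i"]
    else:
        Aeff = P["A"][None] + np.einsum("km,bmij->kbij", uniq, P["B"])
        cu = np.einsum("blm,km->kbl", P["C"], uniq)
        if wc:
            alpha = P["alpha"]
    kappa, tau, gamma = P["kappa"], P["tau"], hp.gamma
    rho, ia = hp.rho, 1.0 / hp.alpha_g
    om = 1.0 - rho

    y = np.zeros((Bsz, l, n_state))
    y[..., -3:] = 1.0  # f, v, q rest at 1
    hz = n_state - 4  # index where hemodynamic block starts is hz+0 (s)

    def drift(yy, c):
        out = np.empty_like(yy)
        if two:
            zE, zI = yy[..., 0], yy[..., 1]
            xE = (Weff[c] @ zE[..., None])[..., 0] + w_se * zE \
                * (1.0 if wc else -1.0) - wie_eff[c] * zI + cu[c]
            xI = w_ei * zE - w_si * zI
            if wc:
                out[..., 0] = -zE + 0.5 * np.tanh(0.5 * ae * xE)
                out[..., 1] = -zI + 0.5 * np.tanh(0.5 * ai * xI)
            else:
                out[..., 0] = xE
                out[..., 1] = xI
            z = zE
        else:
            z = yy[..., 0]
            x = (Aeff[c] @ z[..., None])[..., 0] + cu[c]
            out[..., 0] = (-z + 0.5 * np.tanh(0.5 * alpha * x)) if wc else x
        s, f, v, q = yy[..., hz], yy[..., hz + 1], yy[..., hz + 2], yy[..., hz + 3]
        E = 1.0 - om ** (1.0 / f)
        fv = v ** ia
        out[..., hz] = z - kappa * s - gamma * (f - 1.0)
        out[..., hz + 1] = s
        out[..., hz + 2] = (f - fv) / tau
        out[..., hz + 3] = (f * E / rho - fv * q / v) / tau
        return out

    n_samples = n_steps // sample_stride + 1
    bold = np.full((n_samples, Bsz, l), np.nan)
    first_bad = np.full(Bsz, -1, dtype=int)
    good = np.ones(Bsz, dtype=bool)
    latents = None
    if store_latents:
        latents = np.empty((n_steps + 1, l, n_state))
        latents[0] = y[0]

    def observe(yy):
        v, q = yy[..., hz + 2], yy[..., hz + 3]
        return hp.V0 * (hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v)
                        + hp.k3 * (1.0 - v))

    bold[0, good] = observe(y[good])
    half = 0.5 * dt
    sixth = dt / 6.0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for k in range(n_steps):
            c = inv[k]
            k1 = drift(y, c)
            k2 = drift(y + half * k1, c)
            k3 = drift(y + half * k2, c)
            k4 = drift(y + dt * k3, c)
            y_new = y + sixth * (k1 + 2.0 * (k2 + k3) + k4)
            ok = np.isfinite(y_new.reshape(Bsz, -1)).all(axis=1)
            ok &= (y_new[..., -3:].reshape(Bsz, -1) > 0.0).all(axis=1)
            ok &= (np.abs(y_new.reshape(Bsz, -1)) < 1e9).all(axis=1)
            newly_bad = good & ~ok
            if newly_bad.any():
                first_bad[newly_bad] = k + 1
                y_new[newly_bad] = y[newly_bad]
                good &= ok
            y = y_new
            if store_latents:
                latents[k + 1] = y[0]
            if (k + 1) % sample_stride == 0:
                i = (k + 1) // sample_stride
                if i < n_samples:
                    bold[i, good] = observe(y[good])
    return bold, first_bad, latents


def integrate(spec: ModelSpec, neuronal: NeuronalParams,
              hemo: HemodynamicParams, inputs: InputTimeline,
              duration: float, TR: float, hemo_scale=None,
              store_latents: bool = True):
    """Integrate the full neuronal + hemodynamic cascade and sample BOLD.

    Parameters
    ----------
    duration : float
        Simulated time in seconds; must be a multiple of TR.
    TR : float
        Sampling interval of the output series (s); must be an integer
        multiple of the input timeline's microtime step ``dt``.
    hemo_scale : (2, l) array, optional
        Per-region log-scaling factors on (kappa, tau_h).

    Returns
    -------
    latents : dict with keys ``t`` (microtime axis), ``z`` (single-state)
        or ``zE``/``zI`` (two-state), and ``hemo`` (n_steps+1, l, 4).
    bold : BOLDSeries
        Sampled at t = 0, TR, 2 TR, ... (% signal change).

    Raises
    ------
    DivergenceError
        If the state becomes non-finite (possible for unstable bilinear
        systems); carries the first bad microtime index.
    """
    neuronal.validate(spec)
    dt = inputs.dt
    stride = int(round(TR / dt))
    if stride < 1 or not np.isclose(stride * dt, TR, rtol=1e-9):
        raise InvalidParameterError(
            f"TR={TR} must be an integer multiple of dt={dt}")
    n_steps = int(round(duration / dt))
    if not np.isclose(n_steps * dt, duration, rtol=1e-9):
        raise InvalidParameterError("duration must be a multiple of dt")
    P = _stack_params(spec, [neuronal],
                      None if hemo_scale is None else [np.asarray(hemo_scale)],
                      hemo)
    bold, first_bad, lat = _integrate_batch(
        spec, P, hemo, inputs.u, dt, n_steps, stride,
        store_latents=store_latents)
    if first_bad[0] >= 0:
        raise DivergenceError(
            f"state became non-finite at microtime index {first_bad[0]} "
            f"(t={first_bad[0] * dt:.3f} s)", int(first_bad[0]))
    series = BOLDSeries(TR=TR, y=bold[:, 0, :], region_names=spec.region_names)
    latents = None
    if store_latents:
        t = np.arange(n_steps + 1) * dt
        if spec.states == "two":
            latents = {"t": t, "zE": lat[:, :, 0], "zI": lat[:, :, 1],
                       "hemo": lat[:, :, 2:]}
        else:
            latents = {"t": t, "z": lat[:, :, 0], "hemo": lat[:, :, 1:]}
    return latents, series


# ---------------------------------------------------------------------------
# ground-truth network and synthetic datasets
# ---------------------------------------------------------------------------

def make_ground_truth_network(variant: str = "bilinear",
                              self_coupling: float = -0.5,
                              forward: float = 0.4,
                              modulation: float = 0.2,
                              driving: float = 0.5,
                              alpha: float = 4.0):
    """Three-region validation network.

    Region 1 receives the driving input; fixed connections are the
    feedforward edges 1->2 and 1->3 plus 3->2; a second, contextual input
    modulates 1->3 and 3->2. Returns ``(spec, neuronal, hemo)`` with
    default numeric values that can be overridden via keyword arguments.
    """
    l, m = 3, 2
    A_mask = np.eye(l, dtype=bool)
    for tgt, src in [(1, 0), (2, 0), (1, 2)]:
        A_mask[tgt, src] = True
    B_masks = np.zeros((m, l, l), dtype=bool)
    B_masks[1, 2, 0] = True  # contextual input gates 1->3
    B_masks[1, 1, 2] = True  # and 3->2
    C_mask = np.zeros((l, m), dtype=bool)
    C_mask[0, 0] = True
    spec = ModelSpec(("R1", "R2", "R3"), A_mask, B_masks, C_mask,
                     variant=variant, states="one")
    A = np.diag(np.full(l, self_coupling))
    for tgt, src in [(1, 0), (2, 0), (1, 2)]:
        A[tgt, src] = forward
    B = np.zeros((m, l, l))
    B[B_masks] = modulation
    C = np.zeros((l, m))
    C[0, 0] = driving
    neuronal = NeuronalParams(A=A, B=B, C=C, alpha=np.full(l, float(alpha)))
    return spec, neuronal, HemodynamicParams()


def default_input_timeline(duration: float = 360.0, dt: float = 0.125):
    """Standard two-input fixture: a 20 s-on / 20 s-off driving boxcar and
    a slower 60 s-period (30 s-on / 30 s-off) contextual boxcar."""
    events = []
    t = 20.0
    while t < duration:
        events.append(("driving", t, min(20.0, duration - t)))
        t += 40.0
    t = 30.0
    while t < duration:
        events.append(("context", t, min(30.0, duration - t)))
        t += 60.0
    return InputTimeline.from_events(events, dt=dt, duration=duration,
                                     names=("driving", "context"))


def simulate_dataset(spec: ModelSpec, neuronal: NeuronalParams,
                     hemo: HemodynamicParams, inputs: InputTimeline,
                     snr: float, n_real: int, seed: int,
                     duration: float | None = None,
                     TR: float = 2.0) -> SyntheticDataset:
    """Simulate a clean series and ``n_real`` noisy realizations at one SNR.

    Noise is white Gaussian per region with standard deviation
    ``sd(clean_region) / snr``; ``snr = inf`` returns the clean series as
    every realization. Fully reproducible from ``seed``.
    """
    if not (snr > 0):
        raise InvalidParameterError(f"snr must be positive, got {snr}")
    if n_real < 1:
        raise InvalidParameterError("n_real must be >= 1")
    if duration is None:
        duration = inputs.duration
    _, clean = integrate(spec, neuronal, hemo, inputs, duration, TR,
                         store_latents=False)
    noisy = []
    if np.isinf(snr):
        noisy = [BOLDSeries(TR=TR, y=clean.y.copy(),
                            region_names=clean.region_names)
                 for _ in range(n_real)]
    else:
        rng = np.random.default_rng(seed)
        sd = clean.y.std(axis=0) / snr
        for _ in range(n_real):
            eps = rng.standard_normal(clean.y.shape) * sd
            noisy.append(BOLDSeries(TR=TR, y=clean.y + eps,
                                    region_names=clean.region_names))
    return SyntheticDataset(spec=spec, neuronal=neuronal, hemo=hemo,
                            inputs=inputs, clean=clean, noisy=noisy,
                            snr=snr, seed=seed)
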