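"""Neuronal state equations for single- and two-state DCM.

Four drift functions are provided, all pure: the classical bilinear form

    dz/dt = (A + sum_j u_j B^j) z + C u

and its Wilson-Cowan counterpart, in which the linear synaptic drive x is
passed through a zero-centred sigmoid and the state relaxes toward it,

    dz/dt = -z + S(x),   S(x) = 1/(1 + exp(-alpha x)) - 1/2,

plus the analogous pair for the two-state (excitatory/inhibitory) model.
The sigmoid is centred so the origin is a fixed point of every variant;
state variables are deviations from the resting baseline, so negative
values are meaningful (activity below baseline).

Orientation convention: ``A[i, j]`` is the connection FROM region ``j``
TO region ``i`` (rows index the target region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, ShapeError

__all__ = [
    "ModelSpec",
    "NeuronalParams",
    "sigmoid",
    "bilinear_drift",
    "wc_drift",
    "two_state_bilinear_drift",
    "two_state_wc_drift",
]

VARIANTS = ("bilinear", "wilson_cowan")
STATES = ("one", "two")


@dataclass(frozen=True)
class ModelSpec:
    """Structural definition of one DCM.

    Parameters
    ----------
    region_names : list of str
        Labels for the l regions.
    A_mask : (l, l) bool array
        True where a fixed connection is allowed. The diagonal
        (self-connections) is always present.
    B_masks : (m, l, l) bool array
        True where modulatory input j may gate a connection. Every true
        entry must also be true in ``A_mask``.
    C_mask : (l, m) bool array
        True where input j drives region i directly.
    variant : {"bilinear", "wilson_cowan"}
    states : {"one", "two"}
    """

    region_names: tuple
    A_mask: np.ndarray
    B_masks: np.ndarray
    C_mask: np.ndarray
    variant: str = "wilson_cowan"
    states: str = "one"

    def __post_init__(self):
        object.__setattr__(self, "region_names", tuple(self.region_names))
        A = np.asarray(self.A_mask, dtype=bool)
        B = np.asarray(self.B_masks, dtype=bool)
        C = np.asarray(self.C_mask, dtype=bool)
        l = len(self.region_names)
        if l < 1:
            raise InvalidParameterError("need at least one region")
        if A.shape != (l, l):
            raise ShapeError(f"A_mask shape {A.shape} != ({l}, {l})")
        if B.ndim != 3 or B.shape[1:] != (l, l) or B.shape[0] < 1:
            raise ShapeError(f"B_masks shape {B.shape} inconsistent with l={l}")
        m = B.shape[0]
        if C.shape != (l, m):
            raise ShapeError(f"C_mask shape {C.shape} != ({l}, {m})")
        if not A.diagonal().all():
            raise InvalidParameterError("A_mask diagonal must be all true "
                                        "(self-connections are always present)")
        if (B & ~A[None, :, :]).any():
            raise InvalidParameterError(
                "modulation allowed on a connection absent from A_mask")
        if self.variant not in VARIANTS:
            raise InvalidParameterError(f"unknown variant {self.variant!r}")
        if self.states not in STATES:
            raise InvalidParameterError(f"unknown states flag {self.states!r}")
        object.__setattr__(self, "A_mask", A)
        object.__setattr__(self, "B_masks", B)
        object.__setattr__(self, "C_mask", C)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_inputs(self) -> int:
        return self.B_masks.shape[0]

    def edge_set(self) -> set:
        """Off-diagonal support of A_mask as (target, source) pairs (0-based)."""
        l = self.n_regions
        return {(i, j) for i in range(l) for j in range(l)
                if i != j and self.A_mask[i, j]}

    def with_variant(self, variant: str) -> "ModelSpec":
        return ModelSpec(self.region_names, self.A_mask, self.B_masks,
                         self.C_mask, variant=variant, states=self.states)


@dataclass
class NeuronalParams:
    """Numeric coupling parameters for one ModelSpec.

    Single-state fields: ``A`` (l, l), ``B`` (m, l, l), ``C`` (l, m), all in
    Hz, and ``alpha`` (l,) dimensionless sigmoid slopes (used only by the
    Wilson-Cowan variant).

    Two-state fields: ``w_ee`` (l, l) extrinsic E->E coupling (off-diagonal;
    the diagonal is ignored), per-region intrinsic weights ``w_se``, ``w_si``,
    ``w_ie``, ``w_ei`` (l,), modulatory parts ``b_ee`` (m, l, l) and ``b_ie``
    (m, l), input matrix ``C`` and slopes ``alpha_e``, ``alpha_i`` (l,).
    All w's are non-negative magnitudes; the equations carry the signs
    (inhibition enters E negatively, E drives I positively).
    """

    A: np.ndarray | None = None
    B: np.ndarray | None = None
    C: np.ndarray | None = None
    alpha: np.ndarray | None = None
    # two-state
    w_ee: np.ndarray | None = None
    w_se: np.ndarray | None = None
    w_si: np.ndarray | None = None
    w_ie: np.ndarray | None = None
    w_ei: np.ndarray | None = None
    b_ee: np.ndarray | None = None
    b_ie: np.ndarray | None = None
    alpha_e: np.ndarray | None = None
    alpha_i: np.ndarray | None = None

    def __post_init__(self):
        for name in ("A", "B", "C", "alpha", "w_ee", "w_se", "w_si", "w_ie",
                     "w_ei", "b_ee", "b_ie", "alpha_e", "alpha_i"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def validate(self, spec: ModelSpec) -> None:
        """Check shapes and mask consistency against ``spec``."""
        l, m = spec.n_regions, spec.n_inputs
        if spec.states == "one":
            for name, shape in (("A", (l, l)), ("B", (m, l, l)), ("C", (l, m))):
                v = getattr(self, name)
                if v is None:
                    raise InvalidParameterError(f"missing {name} for "
                                                "single-state model")
                if v.shape != shape:
                    raise ShapeError(f"{name} shape {v.shape} != {shape}")
            if np.any(self.A[~spec.A_mask] != 0):
                raise InvalidParameterError("nonzero A entry outside A_mask")
            if np.any(self.B[~spec.B_masks] != 0):
                raise InvalidParameterError("nonzero B entry outside B_masks")
            if np.any(self.C[~spec.C_mask] != 0):
                raise InvalidParameterError("nonzero C entry outside C_mask")
            if spec.variant == "wilson_cowan":
                if self.alpha is None or self.alpha.shape != (l,):
                    raise InvalidParameterError("alpha must be length-l for "
                                                "the Wilson-Cowan variant")
                if np.any(self.alpha <= 0):
                    raise InvalidParameterError("alpha must be positive")
        else:
            needed = ["w_ee", "w_se", "w_si", "w_ie", "w_ei", "C"]
            if spec.variant == "wilson_cowan":
                needed += ["alpha_e", "alpha_i"]
            for name in needed:
                if getattr(self, name) is None:
                    raise InvalidParameterError(
                        f"missing two-state weight {name}")
            for name in ("w_se", "w_si", "w_ie", "w_ei"):
                if getattr(self, name).shape != (l,):
                    raise ShapeError(f"{name} must have shape ({l},)")
            if self.w_ee.shape != (l, l):
                raise ShapeError(f"w_ee shape {self.w_ee.shape} != ({l}, {l})")
            if self.C.shape != (l, m):
                raise ShapeError(f"C shape {self.C.shape} != ({l}, {m})")
            if spec.variant == "wilson_cowan":
                for name in ("alpha_e", "alpha_i"):
                    a = getattr(self, name)
                    if a.shape != (l,):
                        raise ShapeError(f"{name} must have shape ({l},)")
                    if np.any(a <= 0):
                        raise InvalidParameterError(f"{name} must be positive")


def sigmoid(x, alpha):
    """Zero-centred sigmoid ``1/(1 + exp(-alpha*x)) - 1/2``.

    Odd in x, bounded in (-1/2, 1/2). Evaluated as ``tanh(alpha*x/2)/2``,
    which is overflow-free for arbitrarily large ``|alpha*x|``.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise InvalidParameterError("sigmoid slope alpha must be positive")
    return 0.5 * np.tanh(0.5 * alpha * np.asarray(x, dtype=float))


def _synaptic_drive(z, u, p: NeuronalParams):
    """x = (A + sum_j u_j B^j) z + C u, the linear drive of Eq.-1 form."""
    z = np.asarray(z, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    A, B, C = p.A, p.B, p.C
    if z.shape[-1] != A.shape[0]:
        raise ShapeError(f"state length {z.shape[-1]} != {A.shape[0]} regions")
    if u.shape[-1] != C.shape[1]:
        raise ShapeError(f"input length {u.shape[-1]} != {C.shape[1]} inputs")
    A_eff = A + np.tensordot(u, B, axes=(-1, 0))
    return A_eff @ z + C @ u


def bilinear_drift(z, u, p: NeuronalParams) -> np.ndarray:
    """Classical bilinear neuronal drift ``(A + sum_j u_j B^j) z + C u``."""
    return _synaptic_drive(z, u, p)


def wc_drift(z, u, p: NeuronalParams) -> np.ndarray:
    """Wilson-Cowan neuronal drift ``-z + S(x)`` with per-region slope.

    ``x`` is the same linear synaptic drive as in the bilinear form; the
    relaxation time constant is fixed to 1 s.
    """
    z = np.asarray(z, dtype=float)
    x = _synaptic_drive(z, u, p)
    return -z + sigmoid(x, p.alpha)


def _two_state_drives(zE, zI, u, p: NeuronalParams, sign_se: float):
    """Linear drives (xE, xI) shared by both two-state variants.

    ``sign_se`` is +1 for the Wilson-Cowan form (excitatory self-drive
    enters the sigmoid argument positively) and -1 for the bilinear form
    (self-decay).
    """
    zE = np.asarray(zE, dtype=float)
    zI = np.asarray(zI, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    l = p.w_se.shape[0]
    if zE.shape[-1] != l or zI.shape[-1] != l:
        raise ShapeError("two-state state vectors must have length l")
    W = p.w_ee.copy()
    np.fill_diagonal(W, 0.0)  # extrinsic coupling only between regions
    if p.b_ee is not None:
        Bmod = np.tensordot(u, p.b_ee, axes=(-1, 0))
        np.fill_diagonal(Bmod, 0.0)
        W = W + Bmod
    w_ie = p.w_ie + (np.tensordot(u, p.b_ie, axes=(-1, 0))
                     if p.b_ie is not None else 0.0)
    cu = p.C @ u
    xE = W @ zE + sign_se * p.w_se * zE - w_ie * zI + cu
    xI = p.w_ei * zE - p.w_si * zI
    return xE, xI


def two_state_bilinear_drift(zE, zI, u, p: NeuronalParams):
    """Two-state bilinear drift.

    Excitatory: extrinsic E->E coupling minus intrinsic self-decay minus
    inhibition plus driving input; inhibitory: E drive minus self-decay.
    """
    xE, xI = _two_state_drives(zE, zI, u, p, sign_se=-1.0)
    return xE, xI


def two_state_wc_drift(zE, zI, u, p: NeuronalParams):
    """Two-state Wilson-Cowan drift ``(-zE + S_E(xE), -zI + S_I(xI))``.

    The excitatory self-term enters the sigmoid argument with positive
    sign (recurrent excitation); decay comes from the leading ``-z``.
    """
    if p.alpha_e is None or p.alpha_i is None:
        raise InvalidParameterError("two-state Wilson-Cowan needs alpha_e "
                                    "and alpha_i")
    xE, xI = _two_state_drives(zE, zI, u, p, sign_se=+1.0)
    zE = np.asarray(zE, dtype=float)
    zI = np.asarray(zI, dtype=float)
    return (-zE + sigmoid(xE, p.alpha_e), -zI + sigmoid(xI, p.alpha_i))
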