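"""Independent brute-force oracles used by the tests.

These deliberately avoid the vectorized code paths of the package:
drifts are computed with explicit Python loops and the textbook sigmoid
expression, so agreement is a genuine cross-check.
"""

import math

import numpy as np


def sigmoid_scalar(x, alpha):
    return 1.0 / (1.0 + math.exp(-alpha * x)) - 0.5


def naive_bilinear_drift(z, u, A, B, C):
    l = len(z)
    m = len(u)
    out = np.zeros(l)
    for i in range(l):
        acc = 0.0
        for j in range(l):
            aij = A[i][j]
            for k in range(m):
                aij += u[k] * B[k][i][j]
            acc += aij * z[j]
        for k in range(m):
            acc += C[i][k] * u[k]
        out[i] = acc
    return out


def naive_wc_drift(z, u, A, B, C, alpha):
    x = naive_bilinear_drift(z, u, A, B, C)
    return np.array([-z[i] + sigmoid_scalar(x[i], alpha[i])
                     for i in range(len(z))])


def naive_two_state_bilinear(zE, zI, u, w_ee, w_se, w_si, w_ie, w_ei,
                             b_ee, b_ie, C):
    l = len(zE)
    m = len(u)
    dE = np.zeros(l)
    dI = np.zeros(l)
    for i in range(l):
        acc = 0.0
        for j in range(l):
            if i == j:
                continue
            w = w_ee[i][j]
            for k in range(m):
                w += u[k] * b_ee[k][i][j]
            acc += w * zE[j]
        wie = w_ie[i]
        for k in range(m):
            wie += u[k] * b_ie[k][i]
        cu = sum(C[i][k] * u[k] for k in range(m))
        dE[i] = acc - w_se[i] * zE[i] - wie * zI[i] + cu
        dI[i] = w_ei[i] * zE[i] - w_si[i] * zI[i]
    return dE, dI


def naive_two_state_wc(zE, zI, u, w_ee, w_se, w_si, w_ie, w_ei,
                       b_ee, b_ie, C, alpha_e, alpha_i):
    l = len(zE)
    m = len(u)
    dE = np.zeros(l)
    dI = np.zeros(l)
    for i in range(l):
        acc = 0.0
        for j in range(l):
            if i == j:
                continue
            w = w_ee[i][j]
            for k in range(m):
                w += u[k] * b_ee[k][i][j]
            acc += w * zE[j]
        wie = w_ie[i]
        for k in range(m):
            wie += u[k] * b_ie[k][i]
        cu = sum(C[i][k] * u[k] for k in range(m))
        xE = acc + w_se[i] * zE[i] - wie * zI[i] + cu
        xI = w_ei[i] * zE[i] - w_si[i] * zI[i]
        dE[i] = -zE[i] + sigmoid_scalar(xE, alpha_e[i])
        dI[i] = -zI[i] + sigmoid_scalar(xI, alpha_i[i])
    return dE, dI


def random_single_state_instance(rng, wc=False):
    """Random ModelSpec-consistent single-state parameter set."""
    from wcdcm.neuronal import ModelSpec, NeuronalParams

    l = int(rng.integers(1, 5))
    m = int(rng.integers(1, 4))
    A_mask = np.eye(l, dtype=bool) | (rng.random((l, l)) < 0.6)
    B_masks = (rng.random((m, l, l)) < 0.4) & A_mask[None]
    C_mask = rng.random((l, m)) < 0.5
    spec = ModelSpec(tuple(f"R{i}" for i in range(l)), A_mask, B_masks,
                     C_mask, variant="wilson_cowan" if wc else "bilinear")
    A = rng.normal(0, 0.5, (l, l)) * A_mask
    B = rng.normal(0, 0.3, (m, l, l)) * B_masks
    C = rng.normal(0, 0.5, (l, m)) * C_mask
    alpha = rng.uniform(0.5, 8.0, l) if wc else None
    z = rng.normal(0, 1.0, l)
    u = rng.normal(0, 1.0, m)
    return spec, NeuronalParams(A=A, B=B, C=C, alpha=alpha), z, u


def random_two_state_instance(rng, wc=False):
    from wcdcm.neuronal import NeuronalParams

    l = int(rng.integers(1, 4))
    m = int(rng.integers(1, 3))
    w_ee = np.abs(rng.normal(0, 0.5, (l, l)))
    w_se, w_si, w_ie, w_ei = (np.abs(rng.normal(0.5, 0.3, l)) + 0.01
                              for _ in range(4))
    b_ee = rng.normal(0, 0.2, (m, l, l))
    b_ie = rng.normal(0, 0.2, (m, l))
    C = rng.normal(0, 0.5, (l, m))
    ae = rng.uniform(0.5, 8.0, l) if wc else None
    ai = rng.uniform(0.5, 8.0, l) if wc else None
    p = NeuronalParams(w_ee=w_ee, w_se=w_se, w_si=w_si, w_ie=w_ie,
                       w_ei=w_ei, b_ee=b_ee, b_ie=b_ie, C=C,
                       alpha_e=ae, alpha_i=ai)
    zE = rng.normal(0, 1.0, l)
    zI = rng.normal(0, 1.0, l)
    u = rng.normal(0, 1.0, m)
    return p, zE, zI, u
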