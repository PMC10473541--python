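"""Combinatorial Hill-function regulation logic.

Transcription of a target gene responds to its regulating TF proteins
through Hill occupancy curves that are aggregated by the gene's logic
gates into a combinatorial activation term ``C_A`` and repression term
``C_R``, which the regulation function maps — together with the basal
fraction ``f0`` — onto a transcription fraction in [0, 1]:

    f = f0 + f0·(C_A − 1)·(1 − C_R) + (1 − f0)·C_A·C_R

With no activators ``C_A = 0`` and with no repressors ``C_R = 1``: the
unique empty-set convention under which an unregulated gene transcribes
at exactly ``f0``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hill_activation",
    "hill_repression",
    "combinatorial_term",
    "regulation_function",
    "transcription_fraction",
]

# (p/T)**k is clipped here so the ratio form r/(1+r) never produces inf/inf.
_RATIO_CAP = 1e300


def hill_activation(p, t_half, k):
    """Hill occupancy of an activating TF: ``p**k / (p**k + T**k)``.

    Strictly increasing in ``p``, equals 0.5 at ``p = T``, bounded in [0, 1).

    Parameters
    ----------
    p : float or array
        TF protein abundance, ``>= 0``.
    t_half : float or array
        Half-occupation abundance ``T > 0``.
    k : float or array
        Hill coefficient (cooperativity), ``> 0``.
    """
    p = np.asarray(p, dtype=float)
    t_half = np.asarray(t_half, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(t_half <= 0):
        raise ValueError("half-occupation abundance T must be positive")
    if np.any(k <= 0):
        raise ValueError("Hill coefficient k must be positive")
    if np.any(p < 0):
        raise ValueError("protein abundance must be non-negative")
    with np.errstate(over="ignore"):
        r = np.minimum((p / t_half) ** k, _RATIO_CAP)
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def hill_repression(p, t_half, k):
    """Complementary occupancy of a repressing TF: ``1 - hill_activation``."""
    out = 1.0 - np.asarray(hill_activation(p, t_half, k))
    return out if out.ndim else float(out)


def combinatorial_term(activations, mode: str, role: str):
    """Aggregate the Hill occupancies of one gene's regulators of one role.

    - independent activators:  ``C_IA = 1 - prod(1 - S)``
    - independent repressors:  ``C_IR = prod(1 - S)``
    - synergistic activators:  ``C_SA = prod(S)``
    - synergistic repressors:  ``C_SR = 1 - prod(S)``

    Empty regulator sets follow the convention ``C_A = 0`` (no activation)
    and ``C_R = 1`` (no repression) regardless of ``mode``.
    """
    if mode not in ("independent", "synergistic"):
        raise ValueError(f"unknown mode {mode!r}")
    if role not in ("activator", "repressor"):
        raise ValueError(f"unknown role {role!r}")
    s = np.asarray(list(activations), dtype=float)
    if s.size and (np.any(s < 0) or np.any(s > 1)):
        raise ValueError("Hill occupancies must lie in [0, 1]")
    if s.size == 0:
        return 0.0 if role == "activator" else 1.0
    if role == "activator":
        if mode == "independent":
            return float(1.0 - np.prod(1.0 - s))
        return float(np.prod(s))
    if mode == "independent":
        return float(np.prod(1.0 - s))
    return float(1.0 - np.prod(s))


def regulation_function(c_a, c_r, f0):
    """Transcription fraction produced by combinatorial terms and basal f0.

    Returns ``f0`` when exactly one of activation/repression is saturated
    against the other (``(0, 1)`` or ``(1, 0)``), 1 when both are present
    (``(1, 1)``), and 0 when both are absent (``(0, 0)``).
    """
    c_a = np.asarray(c_a, dtype=float)
    c_r = np.asarray(c_r, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    for name, v in (("C_A", c_a), ("C_R", c_r), ("f0", f0)):
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = f0 + f0 * (c_a - 1.0) * (1.0 - c_r) + (1.0 - f0) * c_a * c_r
    return out if out.ndim else float(out)


def combinatorial_terms_batch(p, am, lg, t_matrix, k):
    """Combinatorial activation/repression terms for batches.

    Same layout as :func:`transcription_fraction`; returns ``(c_a, c_r)``
    each of shape (B, n, S), applying the logic gates and the empty-set
    conventions (``C_A = 0`` without activators, ``C_R = 1`` without
    repressors).
    """
    p4 = np.asarray(p, dtype=float)[:, None, :, :]
    t4 = np.asarray(t_matrix, dtype=float)[None, :, :, None]
    k4 = np.asarray(k, dtype=float)[None, :, None, None]
    with np.errstate(over="ignore"):
        r = np.minimum((p4 / t4) ** k4, _RATIO_CAP)
    s_act = r / (1.0 + r)
    one_minus = 1.0 - s_act

    act = (am > 0)[..., None]
    rep = (am < 0)[..., None]
    n_act = act.sum(axis=2)
    n_rep = rep.sum(axis=2)

    prod_act_off = np.prod(np.where(act, one_minus, 1.0), axis=2)
    prod_act_on = np.prod(np.where(act, s_act, 1.0), axis=2)
    prod_rep_off = np.prod(np.where(rep, one_minus, 1.0), axis=2)
    prod_rep_on = np.prod(np.where(rep, s_act, 1.0), axis=2)

    syn_a = (lg[:, 0, :] == 1)[..., None]
    syn_r = (lg[:, 1, :] == 1)[..., None]
    c_a = np.where(syn_a, prod_act_on, 1.0 - prod_act_off)
    c_r = np.where(syn_r, 1.0 - prod_rep_on, prod_rep_off)
    c_a = np.where(n_act == 0, 0.0, c_a)
    c_r = np.where(n_rep == 0, 1.0, c_r)
    return c_a, c_r


def transcription_fraction(p, am, lg, f0, t_matrix, k, *, validate: bool = False):
    """Vectorized transcription fraction for batches of architectures/states.

    Parameters
    ----------
    p : (B, n, S) array
        Protein abundances for ``B`` architectures and ``S`` system states.
    am : (B, n, n) array
        Trinary adjacency matrices (row = target, column = regulator).
    lg : (B, 2, n) array
        Logic gates (row 0 activator flags, row 1 repressor flags).
    f0 : (B, n) array
        Basal fractions, clipped into [0, 1] for evaluation (out-of-range
        estimates are penalized upstream, not propagated into dynamics).
    t_matrix : (n, n) array
        Half-occupation abundances per (target, regulator) pair.
    k : (n,) array
        Hill coefficient per target gene.

    Returns
    -------
    (B, n, S) array of transcription fractions in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if validate:
        if np.any(p < 0):
            raise ValueError("protein abundance must be non-negative")
        if np.any(t_matrix <= 0) or np.any(k <= 0):
            raise ValueError("T and k must be positive")

    c_a, c_r = combinatorial_terms_batch(p, am, lg, t_matrix, k)
    f0c = np.clip(f0, 0.0, 1.0)[:, :, None]
    return f0c + f0c * (c_a - 1.0) * (1.0 - c_r) + (1.0 - f0c) * c_a * c_r
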