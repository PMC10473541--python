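"""Steady-state estimation of the unmeasured kinetic parameters.

The measured quantities are the maximal transcription rate, the translation
rate and the two degradation rates; the remaining parameters
(``V_min``, ``T``, ``k``, ``f0``) are obtained by inverting the ODE system
under the assumption that every input profile is at steady state:

- ``V_min``: a gene's minimal observed expression corresponds to its
  transcriptional floor, ``V_min = D_mRNA · min_j I``.
- ``T``: with no prior knowledge a TF is taken to be equally likely "on" or
  "off" across conditions, so its half-occupation abundance is the protein
  image of its average mRNA level, ``T = V_trl · mean_j I / D_protein``.
- ``k``: the profiles are assumed to include fully activated genes; the
  Hill coefficient is chosen so occupancy reaches a near-saturating level
  (default 0.95) at the TF's maximal observed protein abundance.
- ``f0``: closed-form inversion of the regulation function per profile,
  averaged across the profiles where it is identifiable.

These estimators are deliberately simple, qualitative inversions; the
whole set sits behind one interface so that independently measured or more
sophisticated estimates can be substituted via a parameter table.
"""

from __future__ import annotations

import warnings

import numpy as np

from .architecture import KineticParameters, NetworkArchitecture
from .profiles import ExpressionProfileSet
from .regulation import combinatorial_terms_batch

__all__ = [
    "EstimationWarning",
    "estimate_vmin",
    "estimate_T",
    "estimate_k",
    "estimate_f0",
    "estimate_f0_batch",
    "estimate_all",
]

#: half-occupation floor assigned to a TF that is never expressed
T_FLOOR = 1e-6
#: |C_A + C_R - 2 C_A C_R| below this makes f0 unidentifiable for a profile
F0_DENOM_TOL = 1e-6
DEFAULT_K = 2.0
K_MIN, K_MAX = 1.0, 10.0


class EstimationWarning(UserWarning):
    """A parameter estimator fell back to a guarded default."""


def estimate_vmin(profiles: ExpressionProfileSet, d_mrna, v_max=None) -> np.ndarray:
    """Per-gene minimal transcription rate, ``D_mRNA · min_j I_{i,j}``.

    If ``v_max`` is given, estimates exceeding it are capped with a warning.
    """
    d_mrna = np.asarray(d_mrna, dtype=float)
    v_min = d_mrna * profiles.minima
    if v_max is not None:
        v_max = np.asarray(v_max, dtype=float)
        over = v_min > v_max
        if over.any():
            genes = [profiles.gene_names[i] for i in np.flatnonzero(over)]
            warnings.warn(
                f"estimated V_min exceeds V_max for {genes}; capping at V_max "
                "(minimal observed expression is above the open-loop maximum)",
                EstimationWarning, stacklevel=2,
            )
            v_min = np.minimum(v_min, v_max)
    return v_min


def estimate_T(profiles: ExpressionProfileSet, v_trl, d_protein) -> np.ndarray:
    """Per-TF half-occupation abundance from the average expression level.

    ``T_i = V_trl,i · mean_j I_{i,j} / D_protein,i`` — the steady-state
    protein abundance at the TF's mean mRNA level, so the TF is "on"
    whenever it sits above its own average.
    """
    v_trl = np.asarray(v_trl, dtype=float)
    d_protein = np.asarray(d_protein, dtype=float)
    if np.any(v_trl <= 0) or np.any(d_protein <= 0):
        raise ValueError("rates must be strictly positive")
    t = v_trl * profiles.values.mean(axis=1) / d_protein
    zero = t < T_FLOOR
    if zero.any():
        genes = [profiles.gene_names[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"TF(s) {genes} have (near-)zero mean expression; setting T to the "
            f"floor {T_FLOOR} (a never-expressed TF cannot regulate)",
            EstimationWarning, stacklevel=2,
        )
        t = np.where(zero, T_FLOOR, t)
    return t


def estimate_k(profiles: ExpressionProfileSet, t_half_occ, *, v_trl, d_protein,
               saturation: float = 0.95,
               anet: NetworkArchitecture | None = None) -> np.ndarray:
    """Per-gene Hill coefficients from a near-saturation condition.

    For each TF, ``k`` is chosen so that its occupancy reaches
    ``saturation`` at the TF's maximal observed protein abundance:
    ``k_TF = ln(s / (1 - s)) / ln(P_max / T)``.  A TF whose maximum does
    not exceed its half-occupation abundance falls back to the default
    ``k = 2`` with a warning.  Each gene's coefficient is the mean over its
    regulators' values when an architecture is given, otherwise the mean
    over all TFs; the result is clipped into [1, 10] and genes without
    regulators receive the inert default 2.
    """
    if not 0.5 < saturation < 1.0:
        raise ValueError("saturation must lie strictly between 0.5 and 1")
    t_half_occ = np.asarray(t_half_occ, dtype=float)
    v_trl = np.asarray(v_trl, dtype=float)
    d_protein = np.asarray(d_protein, dtype=float)
    p_max = v_trl * profiles.maxima / d_protein
    with np.errstate(divide="ignore", invalid="ignore"):
        k_tf = np.log(saturation / (1.0 - saturation)) / np.log(p_max / t_half_occ)
    bad = ~(p_max > t_half_occ)
    if bad.any():
        genes = [profiles.gene_names[i] for i in np.flatnonzero(bad)]
        warnings.warn(
            f"TF(s) {genes}: maximal protein abundance does not exceed T; "
            f"using the default Hill coefficient {DEFAULT_K}",
            EstimationWarning, stacklevel=2,
        )
        k_tf = np.where(bad, DEFAULT_K, k_tf)

    n = profiles.n_genes
    k_gene = np.full(n, DEFAULT_K)
    if anet is not None:
        for i in range(n):
            regs = np.flatnonzero(anet.am[i] != 0)
            if regs.size:
                k_gene[i] = k_tf[regs].mean()
    else:
        k_gene[:] = k_tf.mean()
    return np.clip(k_gene, K_MIN, K_MAX)


def _target_fractions(profiles: ExpressionProfileSet, params: KineticParameters):
    """Implied transcription fractions f* per gene and profile, clipped to [0, 1]."""
    i_mat = profiles.values
    num = params.d_mrna[:, None] * i_mat - params.v_min[:, None]
    span = (params.v_max - params.v_min)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = np.where(span > 0, num / span, 0.5)
    return np.clip(f_star, 0.0, 1.0)


def estimate_f0_batch(am3, lg3, profiles: ExpressionProfileSet,
                      params: KineticParameters):
    """Vectorized basal-fraction estimation for a stack of architectures.

    For each architecture ``b``, gene ``i`` and profile ``j`` the regulation
    function is solved for ``f0``:

        f0 = (f* − C_A·C_R) / (C_A + C_R − 2·C_A·C_R)

    using the combinatorial terms implied by the profile's steady-state
    protein levels.  Profiles with a near-zero denominator (e.g. activation
    and repression both saturated) are unidentifiable and skipped; the
    estimate is the unweighted mean over the remaining profiles.  A gene
    with no identifiable profile receives 0.5 and an invalid flag; a mean
    outside [0, 1] is returned unclipped with its flag false so that the
    inference penalty can act on it.

    Returns ``(f0, valid)`` of shapes (B, n).
    """
    p_prof = params.v_trl[:, None] * profiles.values / params.d_protein[:, None]
    t_matrix = params.effective_t_matrix()
    c_a, c_r = combinatorial_terms_batch(
        p_prof[None], np.asarray(am3), np.asarray(lg3), t_matrix, params.k
    )  # (B, n, m) via broadcast of the shared profile proteins
    f_star = _target_fractions(profiles, params)[None]
    prod = c_a * c_r
    denom = c_a + c_r - 2.0 * prod
    identifiable = np.abs(denom) > F0_DENOM_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        f0_prof = np.where(identifiable, (f_star - prod) / denom, 0.0)
    counts = identifiable.sum(axis=2)
    sums = (f0_prof * identifiable).sum(axis=2)
    with np.errstate(invalid="ignore"):
        f0 = np.where(counts > 0, sums / np.maximum(counts, 1), 0.5)
    valid = (counts > 0) & (f0 >= 0.0) & (f0 <= 1.0)
    return f0, valid


def estimate_f0(anet: NetworkArchitecture, profiles: ExpressionProfileSet,
                params: KineticParameters):
    """Basal fraction per gene for one architecture; see
    :func:`estimate_f0_batch` for the closed form and validity rules.

    Returns ``(f0, valid)`` of shapes (n,).
    """
    if params.v_min is None or params.t_half_occ is None or params.k is None:
        raise ValueError("estimate V_min, T and k before f0")
    f0, valid = estimate_f0_batch(anet.am[None], anet.lg[None], profiles, params)
    return f0[0], valid[0]


def estimate_all(anet: NetworkArchitecture, profiles: ExpressionProfileSet,
                 params: KineticParameters, *,
                 saturation: float = 0.95) -> KineticParameters:
    """Run the full estimation chain (V_min → T → k → f0) and return a
    completed parameter set; f0 values are clipped into [0, 1] here since
    this entry point is for forward simulation, not for the penalty logic.
    """
    v_min = estimate_vmin(profiles, params.d_mrna, params.v_max)
    t = estimate_T(profiles, params.v_trl, params.d_protein)
    out = params.with_estimates(v_min=v_min, t_half_occ=t)
    k = estimate_k(profiles, t, v_trl=params.v_trl, d_protein=params.d_protein,
                   saturation=saturation, anet=anet)
    out = out.with_estimates(k=k)
    f0, _valid = estimate_f0(anet, profiles, out)
    return out.with_estimates(f0=np.clip(f0, 0.0, 1.0))
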