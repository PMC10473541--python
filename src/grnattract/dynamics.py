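"""Numerical integration of the GRN ODE system and attractor analysis.

The dynamic system couples, per gene, one mRNA and one protein equation:

    dR_i/dt = V_min,i + (V_max,i − V_min,i) · f(P; A_net, Θ) − D_mRNA,i · R_i
    dP_i/dt = V_trl,i · R_i − D_protein,i · P_i

integrated with the classical fixed-step 4th-order Runge–Kutta scheme.
Endpoints are classified as fixed-point attractors (converged), bounded
non-converged/oscillatory, or diverged (non-finite).  Distances between a
simulated endpoint and a measured profile use the per-gene-max-normalized
mean absolute difference (``attractor_distance``), the same scale on which
the matching cutoff 0.16 is defined.

Everything here is vectorized over a batch axis ``B`` (architectures) and a
state axis ``S`` (initial conditions) so that an evolutionary-algorithm
generation integrates in a handful of array operations per RK4 step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import KineticParameters, NetworkArchitecture
from .profiles import ExpressionProfileSet, PerturbationSpec
from .regulation import transcription_fraction

__all__ = [
    "SystemState",
    "AttractorResult",
    "attractor_distance",
    "perturb_state",
    "integrate_rk4",
    "integrate_batch",
    "simulate_trajectory",
    "ode_rhs",
    "match_endpoint",
    "find_attractors_global",
    "default_t_max",
    "suggested_dt",
]

#: consecutive sub-tolerance steps required before declaring convergence
CONSECUTIVE_STEPS = 50
#: normalized residual tolerance, max_i |dR_i| / max(I_{i,*}) per step
CONVERGENCE_TOL = 1e-6
#: attractor endpoints closer than this (attractor distance) are merged
MERGE_RADIUS = 0.01
#: matching cutoff below which a simulated endpoint counts as one of the
#: measured attractors (calibrated so a uniform null model rarely matches)
MATCH_CUTOFF = 0.16


@dataclass
class SystemState:
    """mRNA (``r``) and protein (``p``) abundance vectors at time ``t``."""

    r: np.ndarray
    p: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.shape != self.p.shape:
            raise ValueError("mRNA and protein vectors must have the same shape")
        if np.any(self.r < 0) or np.any(self.p < 0):
            raise ValueError("abundances must be non-negative")


@dataclass
class AttractorResult:
    """Endpoint of one integration with its convergence classification."""

    final_state: SystemState
    converged: bool
    oscillatory: bool
    diverged: bool = False
    steps_taken: int = 0
    matched_profile_index: int | None = None
    distance: float | None = None

    def __post_init__(self):
        if self.converged and self.oscillatory:
            raise ValueError("converged and oscillatory are mutually exclusive")


def default_t_max(params: KineticParameters) -> float:
    """Integration horizon: ~36 half-lives of the slowest first-order decay.

    The slowest of the mRNA and protein degradation rates sets the
    relaxation bottleneck; 25 / min(D) comfortably covers the decay of the
    normalized residual to the convergence tolerance.
    """
    d_slow = min(float(params.d_mrna.min()), float(params.d_protein.min()))
    return 25.0 / d_slow


def suggested_dt(params: KineticParameters) -> float:
    """A step size resolving the fastest degradation rate (0.3 / max D) —
    well inside the RK4 stability region for these production-bounded
    systems while keeping step counts modest."""
    d_fast = max(float(params.d_mrna.max()), float(params.d_protein.max()))
    return 0.3 / d_fast


def attractor_distance(state, target, maxima) -> float:
    """Per-gene-max-normalized mean absolute difference between two profiles.

    ``(1/n) · Σ_i |state_i − target_i| / max(I_{i,*})`` — a scaled L1 metric:
    zero iff the vectors coincide, symmetric, and obeying the triangle
    inequality.
    """
    state = np.asarray(state, dtype=float)
    target = np.asarray(target, dtype=float)
    maxima = np.asarray(maxima, dtype=float)
    if np.any(maxima <= 0):
        raise ValueError("per-gene maxima must be strictly positive")
    return float(np.mean(np.abs(state - target) / maxima))


def perturb_state(profile, power, maxima, rng, params: KineticParameters,
                  clamp=None) -> SystemState:
    """Initial state near a measured profile.

    mRNA: ``clip(I_i + U(−power, power) · max(I_{i,*}), 0, ∞)``; clamped
    genes are then pinned at their clamp value.  Protein is initialized at
    its steady-state image of the mRNA, ``V_trl · R / D_protein``, so the
    initial state is internally consistent with the steady-state reading of
    the profile.  ``power = 0`` returns the profile exactly.
    """
    if power < 0:
        raise ValueError("perturbation power must be non-negative")
    profile = np.asarray(profile, dtype=float)
    maxima = np.asarray(maxima, dtype=float)
    if power == 0:
        r = profile.copy()
    else:
        r = profile + rng.uniform(-power, power, size=profile.shape) * maxima
        r = np.clip(r, 0.0, None)
    if clamp is not None:
        clamp = np.asarray(clamp, dtype=float)
        mask = np.isfinite(clamp)
        r[mask] = clamp[mask]
    p = params.v_trl * r / params.d_protein
    return SystemState(r=r, p=p)


def _batch_rhs(r, p, am3, lg3, f02, t_matrix, k, params, clamp_mask):
    """Right-hand side for (B, n, S) state arrays (inputs clipped at 0)."""
    r_pos = np.maximum(r, 0.0)
    p_pos = np.maximum(p, 0.0)
    f = transcription_fraction(p_pos, am3, lg3, f02, t_matrix, k)
    v_min = params.v_min[None, :, None]
    v_max = params.v_max[None, :, None]
    dr = v_min + (v_max - v_min) * f - params.d_mrna[None, :, None] * r_pos
    dp = params.v_trl[None, :, None] * r_pos - params.d_protein[None, :, None] * p_pos
    if clamp_mask is not None:
        dr = np.where(clamp_mask, 0.0, dr)
    return dr, dp


def integrate_batch(am3, lg3, f02, params: KineticParameters, r0, p0, *,
                    clamp=None, dt: float, t_max: float, norm_max,
                    tol: float = CONVERGENCE_TOL,
                    consecutive: int = CONSECUTIVE_STEPS,
                    t_matrix=None, k=None):
    """Integrate a batch of GRN systems to their endpoints.

    Parameters
    ----------
    am3, lg3, f02 : (B, n, n), (B, 2, n), (B, n) arrays
        Stacked architectures and basal fractions.
    r0, p0 : (B, n, S) arrays
        Initial mRNA/protein states (broadcastable over ``B``).
    clamp : (n, S) or (B, n, S) array, optional
        Clamp values with NaN where a gene is free; clamped genes keep
        their mRNA fixed (zero derivative).
    norm_max : (n,) array
        Per-gene normalization (observed maxima) for the convergence
        residual, measured on the same scale as the attractor distance.

    Returns
    -------
    dict with ``r``, ``p`` (B, n, S) endpoints, boolean (B, S) masks
    ``converged``, ``oscillatory``, ``diverged``, and (B, S) ``steps``.
    """
    if dt <= 0 or t_max <= dt:
        raise ValueError("need dt > 0 and t_max > dt")
    am3 = np.asarray(am3, dtype=np.int8)
    if am3.ndim != 3:
        raise ValueError("am3 must be a (B, n, n) stack")
    B, n = am3.shape[0], am3.shape[1]
    r0 = np.asarray(r0, dtype=float)
    r = np.array(np.broadcast_to(r0, (B, n, r0.shape[-1])), dtype=float)
    p = np.array(np.broadcast_to(np.asarray(p0, dtype=float), r.shape), dtype=float)
    S = r.shape[-1]
    if t_matrix is None:
        t_matrix = params.effective_t_matrix()
    if k is None:
        k = params.k
    norm = np.asarray(norm_max, dtype=float)[None, :, None]

    clamp_mask = None
    if clamp is not None:
        clamp = np.asarray(clamp, dtype=float)
        if clamp.ndim == 2:
            clamp = clamp[None]
        clamp_mask = np.broadcast_to(np.isfinite(clamp), r.shape)
        r = np.where(clamp_mask, np.nan_to_num(clamp), r)

    max_steps = int(np.ceil(t_max / dt))
    consec = np.zeros((B, S), dtype=np.int32)
    frozen = np.zeros((B, S), dtype=bool)       # converged, stop updating
    diverged = np.zeros((B, S), dtype=bool)
    steps = np.full((B, S), max_steps, dtype=np.int32)

    args = (am3, lg3, f02, t_matrix, k, params, clamp_mask)
    half = dt / 2.0
    for step in range(1, max_steps + 1):
        k1r, k1p = _batch_rhs(r, p, *args)
        k2r, k2p = _batch_rhs(r + half * k1r, p + half * k1p, *args)
        k3r, k3p = _batch_rhs(r + half * k2r, p + half * k2p, *args)
        k4r, k4p = _batch_rhs(r + dt * k3r, p + dt * k3p, *args)
        rn = np.clip(r + (dt / 6.0) * (k1r + 2 * k2r + 2 * k3r + k4r), 0.0, None)
        pn = np.clip(p + (dt / 6.0) * (k1p + 2 * k2p + 2 * k3p + k4p), 0.0, None)

        active = ~(frozen | diverged)
        upd = active[:, None, :]
        r = np.where(upd, rn, r)
        p = np.where(upd, pn, p)

        bad = ~(np.isfinite(r).all(axis=1) & np.isfinite(p).all(axis=1))
        newly_bad = bad & ~diverged
        if newly_bad.any():
            diverged |= newly_bad
            steps[newly_bad] = step

        res = np.abs(k1r / norm).max(axis=1)
        ok = (res < tol) & active
        consec = np.where(ok, consec + 1, 0)
        newly_conv = (consec >= consecutive) & ~frozen
        if newly_conv.any():
            frozen |= newly_conv
            steps[newly_conv] = step
        if (frozen | diverged).all():
            break

    converged = frozen
    oscillatory = ~frozen & ~diverged
    return {
        "r": r, "p": p, "converged": converged, "oscillatory": oscillatory,
        "diverged": diverged, "steps": steps,
    }


def _stack_single(anet: NetworkArchitecture, params: KineticParameters):
    params.require_complete()
    am3 = anet.am[None]
    lg3 = anet.lg[None]
    f02 = params.f0[None]
    return am3, lg3, f02


def _clamp_vector(clamps: PerturbationSpec | None, anet: NetworkArchitecture,
                  overexpression_levels=None) -> np.ndarray | None:
    if clamps is None or clamps.is_empty:
        return None
    name_to_idx = {g: i for i, g in enumerate(anet.gene_names)}
    vec = np.full(anet.n_genes, np.nan)
    for g in clamps.knockouts:
        vec[name_to_idx[g]] = 0.0
    for g in clamps.overexpressions:
        if overexpression_levels is None:
            raise ValueError(
                "overexpression clamps need per-gene maximal levels "
                "(pass overexpression_levels or use profile-aware helpers)"
            )
        vec[name_to_idx[g]] = overexpression_levels[name_to_idx[g]]
    return vec


def ode_rhs(state: SystemState, anet: NetworkArchitecture,
            params: KineticParameters, clamps: PerturbationSpec | None = None,
            overexpression_levels=None):
    """Per-gene derivatives ``(dR, dP)`` at one state.

    Clamped genes (knockout/overexpression) return zero mRNA derivative;
    their protein equation still evolves from the clamped mRNA level.
    """
    if state.r.shape[0] != anet.n_genes:
        raise ValueError("state dimension does not match the network")
    am3, lg3, f02 = _stack_single(anet, params)
    vec = _clamp_vector(clamps, anet, overexpression_levels)
    clamp_mask = None
    r = state.r.copy()
    if vec is not None:
        clamp_mask = np.isfinite(vec)[None, :, None]
        r[np.isfinite(vec)] = vec[np.isfinite(vec)]
    dr, dp = _batch_rhs(r[None, :, None], state.p[None, :, None],
                        am3, lg3, f02, params.effective_t_matrix(), params.k,
                        params, clamp_mask)
    return dr[0, :, 0], dp[0, :, 0]


def integrate_rk4(anet: NetworkArchitecture, params: KineticParameters,
                  initial: SystemState, dt: float = 1.0,
                  t_max: float | None = None,
                  clamps: PerturbationSpec | None = None, *,
                  norm_max=None, overexpression_levels=None,
                  tol: float = CONVERGENCE_TOL,
                  consecutive: int = CONSECUTIVE_STEPS) -> AttractorResult:
    """Integrate one system state to its endpoint and classify it.

    Convergence requires the normalized mRNA residual
    ``max_i |dR_i| / max(I_{i,*})`` to stay below ``tol`` for
    ``consecutive`` steps; a bounded trajectory failing this by ``t_max``
    is classified oscillatory/non-converged, a non-finite one as diverged.
    """
    if t_max is None:
        t_max = default_t_max(params)
    am3, lg3, f02 = _stack_single(anet, params)
    if norm_max is None:
        norm_max = params.v_max / params.d_mrna
    vec = _clamp_vector(clamps, anet, overexpression_levels)
    clamp = vec[:, None] if vec is not None else None
    out = integrate_batch(
        am3, lg3, f02, params,
        initial.r[None, :, None], initial.p[None, :, None],
        clamp=clamp, dt=dt, t_max=t_max, norm_max=norm_max,
        tol=tol, consecutive=consecutive,
    )
    steps = int(out["steps"][0, 0])
    return AttractorResult(
        final_state=SystemState(out["r"][0, :, 0], out["p"][0, :, 0],
                                t=steps * dt),
        converged=bool(out["converged"][0, 0]),
        oscillatory=bool(out["oscillatory"][0, 0]),
        diverged=bool(out["diverged"][0, 0]),
        steps_taken=steps,
    )


def simulate_trajectory(anet: NetworkArchitecture, params: KineticParameters,
                        initial: SystemState, dt: float, n_steps: int,
                        clamps: PerturbationSpec | None = None, *,
                        overexpression_levels=None, record_every: int = 1):
    """Record a full RK4 trajectory: ``(times, R, P)`` with one row per
    recorded step (step 0 included).  Intended for plotting and export via
    :func:`grnattract.io.write_trajectory`."""
    if dt <= 0 or n_steps < 1:
        raise ValueError("need dt > 0 and n_steps >= 1")
    am3, lg3, f02 = _stack_single(anet, params)
    vec = _clamp_vector(clamps, anet, overexpression_levels)
    clamp_mask = None
    r = initial.r.copy()
    if vec is not None:
        m = np.isfinite(vec)
        r[m] = vec[m]
        clamp_mask = m[None, :, None]
    p = initial.p.copy()
    t_matrix = params.effective_t_matrix()
    args = (am3, lg3, f02, t_matrix, params.k, params, clamp_mask)
    half = dt / 2.0
    times, rs, ps = [0.0], [r.copy()], [p.copy()]
    rb, pb = r[None, :, None], p[None, :, None]
    for step in range(1, n_steps + 1):
        k1r, k1p = _batch_rhs(rb, pb, *args)
        k2r, k2p = _batch_rhs(rb + half * k1r, pb + half * k1p, *args)
        k3r, k3p = _batch_rhs(rb + half * k2r, pb + half * k2p, *args)
        k4r, k4p = _batch_rhs(rb + dt * k3r, pb + dt * k3p, *args)
        rb = np.clip(rb + (dt / 6.0) * (k1r + 2 * k2r + 2 * k3r + k4r), 0.0, None)
        pb = np.clip(pb + (dt / 6.0) * (k1p + 2 * k2p + 2 * k3p + k4p), 0.0, None)
        if step % record_every == 0 or step == n_steps:
            times.append(step * dt)
            rs.append(rb[0, :, 0].copy())
            ps.append(pb[0, :, 0].copy())
    return np.array(times), np.array(rs), np.array(ps)


def match_endpoint(result: AttractorResult, profiles: ExpressionProfileSet,
                   origin_index: int | None = None,
                   cutoff: float = MATCH_CUTOFF):
    """Compare an endpoint against the measured attractors.

    Regular initial states (``origin_index`` given) are scored against
    their own origin profile; auxiliary or novel states against the nearest
    input profile, ties broken deterministically toward the lower index.
    Returns ``(matched_index, distance, matched_flag)`` with
    ``matched_flag = distance < cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if profiles.n_conditions == 0:
        raise ValueError("empty profile set")
    endpoint = result.final_state.r
    maxima = profiles.maxima
    if origin_index is not None:
        d = attractor_distance(endpoint, profiles.values[:, origin_index], maxima)
        idx = int(origin_index)
    else:
        dists = np.abs(endpoint[:, None] - profiles.values) / maxima[:, None]
        per_profile = dists.mean(axis=0)
        idx = int(np.argmin(per_profile))
        d = float(per_profile[idx])
    result.matched_profile_index = idx
    result.distance = d
    return idx, d, d < cutoff


def _polish_fixed_point(r_end, anet: NetworkArchitecture,
                        params: KineticParameters, free, clamp_vec):
    """Refine an integration endpoint to a machine-precision fixed point.

    Solves the steady-state conditions for the unclamped mRNA levels (with
    protein slaved to its steady-state map) starting from the endpoint; the
    refined point is kept only when the solver converges to a nearby
    non-negative state, otherwise the raw endpoint is returned.
    """
    from scipy.optimize import root

    r_end = np.asarray(r_end, dtype=float)
    if not free.any():
        return r_end

    def residual(r_free):
        r = r_end.copy()
        r[free] = r_free
        p = params.v_trl * np.maximum(r, 0.0) / params.d_protein
        f = transcription_fraction(
            p[None, :, None], anet.am[None], anet.lg[None], params.f0[None],
            params.effective_t_matrix(), params.k)[0, :, 0]
        g = (params.v_min + (params.v_max - params.v_min) * f) / params.d_mrna
        return (g - r)[free]

    sol = root(residual, r_end[free], method="hybr")
    if not sol.success:
        return r_end
    polished = r_end.copy()
    polished[free] = sol.x
    scale = np.maximum(np.abs(r_end[free]), 1.0)
    if np.any(polished < -1e-9) or \
            np.max(np.abs(sol.x - r_end[free]) / scale) > 0.05:
        return r_end
    return np.maximum(polished, 0.0)


def _grid_states(levels_per_gene) -> np.ndarray:
    """Cartesian product of per-gene level arrays → (n, S) state matrix."""
    mesh = np.meshgrid(*levels_per_gene, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=0)


def find_attractors_global(anet: NetworkArchitecture, params: KineticParameters,
                           *, levels: int = 3, bounds=None,
                           clamps: PerturbationSpec | None = None,
                           maxima=None, cap: int = 20000,
                           dt: float | None = None, t_max: float | None = None,
                           merge_radius: float = MERGE_RADIUS):
    """Systematic global search for fixed-point attractors.

    Integrates from every corner of a per-gene grid of ``levels`` equally
    spaced mRNA levels spanning ``bounds`` (default: 0 to the open-loop
    maximum ``V_max / D_mRNA`` per gene), deduplicates converged endpoints
    within ``merge_radius`` (attractor distance), and returns fixed points
    only, ordered by discovery after sorting grid corners lexicographically.

    Returns
    -------
    attractors : (n_attractors, n) array of mRNA levels
    info : dict with ``residuals``, ``n_states``, ``n_converged``,
        ``n_oscillatory``, ``n_diverged``
    """
    if levels < 2:
        raise ValueError("need at least 2 levels per gene")
    params.require_complete()
    n = anet.n_genes
    if bounds is None:
        lo = np.zeros(n)
        hi = params.v_max / params.d_mrna
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if maxima is None:
        maxima = np.where(hi > 0, hi, 1.0)
    maxima = np.asarray(maxima, dtype=float)

    vec = _clamp_vector(clamps, anet, overexpression_levels=hi)
    level_arrays = []
    for i in range(n):
        if vec is not None and np.isfinite(vec[i]):
            level_arrays.append(np.array([vec[i]]))
        else:
            level_arrays.append(np.linspace(lo[i], hi[i], levels))
    total = int(np.prod([len(a) for a in level_arrays]))
    if total > cap:
        raise ValueError(
            f"global search grid has {total} states, above the cap of {cap}; "
            "reduce levels or raise cap"
        )
    r0 = _grid_states(level_arrays)
    p0 = params.v_trl[:, None] * r0 / params.d_protein[:, None]
    am3, lg3, f02 = _stack_single(anet, params)
    if dt is None:
        dt = suggested_dt(params)
    if t_max is None:
        t_max = default_t_max(params)
    clamp = vec[:, None] if vec is not None else None
    out = integrate_batch(
        am3, lg3, f02, params, r0[None], p0[None],
        clamp=clamp, dt=dt, t_max=t_max, norm_max=maxima,
    )
    conv = out["converged"][0]
    endpoints = out["r"][0][:, conv].T        # (n_conv, n)

    free = np.ones(n, dtype=bool) if vec is None else ~np.isfinite(vec)
    attractors: list[np.ndarray] = []
    for e in endpoints:
        e = _polish_fixed_point(e, anet, params, free, vec)
        if not any(attractor_distance(e, a, maxima) < merge_radius
                   for a in attractors):
            attractors.append(e)
    att = np.array(attractors) if attractors else np.empty((0, n))

    residuals = []
    for a in att:
        st = SystemState(a, params.v_trl * a / params.d_protein)
        dr, _ = ode_rhs(st, anet, params, clamps,
                        overexpression_levels=hi)
        residuals.append(float(np.abs(dr / maxima).max()))
    info = {
        "residuals": np.array(residuals),
        "n_states": total,
        "n_converged": int(conv.sum()),
        "n_oscillatory": int(out["oscillatory"][0].sum()),
        "n_diverged": int(out["diverged"][0].sum()),
    }
    return att, info
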