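"""Evolutionary search over discrete GRN architectures by attractor matching.

A population of candidate architectures is mutated one Hamming step at a
time; each candidate's basal fractions are re-estimated, the ODE system is
integrated from mildly perturbed copies of every measured profile (plus
auxiliary states that probe independent self-activation), and candidates
are scored by the mean normalized attractor distance between endpoints and
their target profiles, with fixed penalties for non-convergence/oscillation
and for basal fractions outside [0, 1].  A mutated population replaces the
current one only when its population-minimum average distance improves.
Fitness accumulates the reciprocal score every generation; the bottom 20%
of the population is culled and the fittest 20% duplicated.  Independent
runs are combined into a fitness-weighted consensus network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import KineticParameters, NetworkArchitecture
from .dynamics import MATCH_CUTOFF, MERGE_RADIUS, default_t_max, integrate_batch, suggested_dt
from .estimation import estimate_T, estimate_f0_batch, estimate_k, estimate_vmin
from .profiles import ExpressionProfileSet, PerturbationSpec

__all__ = [
    "EvolutionConfig",
    "Population",
    "FitnessLedger",
    "RunResult",
    "ConsensusNetwork",
    "initialize_population",
    "augment_initial_states",
    "evaluate_individual",
    "mutate_population",
    "evolve",
    "build_consensus",
    "complete_parameters",
]

#: distances are floored here before taking reciprocals for fitness
DISTANCE_FLOOR = 1e-6


@dataclass
class EvolutionConfig:
    """Tunable settings of the evolutionary search.

    Penalties are fixed constants chosen to strictly dominate any
    legitimate attractor distance (which is O(1) in the per-gene-max
    normalization): a non-converged or oscillatory endpoint contributes
    ``penalty_nonconvergence`` in place of its distance, and every gene
    whose estimated basal fraction leaves [0, 1] adds ``penalty_f0`` to the
    individual's average distance.
    """

    population_size: int = 100
    generations: int = 800
    hamming_step: int = 1
    perturbation_power: float = 0.1
    cutoff: float = MATCH_CUTOFF
    penalty_nonconvergence: float = 10.0
    penalty_f0: float = 1.0
    dt: float | None = None
    t_max: float | None = None
    chip_zero_weight: float = 0.2
    sparsity_bias: bool = False
    sparsity_to_zero_prob: float = 0.8
    n_runs: int = 30
    consensus_threshold: float = 0.5
    per_individual_acceptance: bool = False
    merge_radius: float = MERGE_RADIUS
    keep_ledger: bool = True

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        if self.hamming_step < 1:
            raise ValueError("hamming_step must be at least 1")
        if self.penalty_nonconvergence <= 1.0:
            raise ValueError(
                "penalty_nonconvergence must exceed any achievable distance (> 1)"
            )
        if not 0 <= self.perturbation_power:
            raise ValueError("perturbation_power must be non-negative")


@dataclass
class Population:
    """Stacked architectures: ``am`` (N, n, n), ``lg`` (N, 2, n), fitness (N,)."""

    am: np.ndarray
    lg: np.ndarray
    fitness: np.ndarray
    gene_names: tuple[str, ...]

    @property
    def size(self) -> int:
        return self.am.shape[0]

    def individual(self, i: int) -> NetworkArchitecture:
        return NetworkArchitecture(self.am[i], self.lg[i], self.gene_names)


@dataclass
class FitnessLedger:
    """Per-generation record: average distances, penalties and fitness."""

    generations: list = field(default_factory=list)

    def record(self, generation, accepted, distances, f0_penalties, fitness):
        self.generations.append({
            "generation": generation,
            "accepted": accepted,
            "min_distance": float(np.min(distances)),
            "mean_distance": float(np.mean(distances)),
            "mean_f0_penalty": float(np.mean(f0_penalties)),
            "max_fitness": float(np.max(fitness)),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.generations)

    @property
    def min_distance_history(self) -> np.ndarray:
        return np.array([g["min_distance"] for g in self.generations])


@dataclass
class RunResult:
    """Outcome of one independent evolutionary run."""

    anet: NetworkArchitecture
    f0: np.ndarray
    fitness: float
    avg_distance: float
    ledger: FitnessLedger
    seed: int | None
    config: EvolutionConfig


@dataclass
class ConsensusNetwork:
    """Fitness-weighted average of the fittest architectures across runs.

    ``scores`` holds the signed per-edge weighted mean in [-1, 1]; ``am``
    is the thresholded trinary matrix (entry = sign of the score where
    |score| >= threshold); ``lg`` is the weighted-majority logic-gate
    consensus.  ``support`` maps each entry value in {-1, 0, +1} to the
    unweighted fraction of runs voting for it.
    """

    scores: np.ndarray
    am: np.ndarray
    lg: np.ndarray
    lg_scores: np.ndarray
    support: dict
    gene_names: tuple[str, ...]
    threshold: float
    total_fitness: float

    def to_architecture(self) -> NetworkArchitecture:
        return NetworkArchitecture(self.am, self.lg, self.gene_names).freeze_logic_gates()


# ---------------------------------------------------------------------------
# parameter completion
# ---------------------------------------------------------------------------

def complete_parameters(profiles: ExpressionProfileSet,
                        params: KineticParameters, *,
                        saturation: float = 0.95) -> KineticParameters:
    """Fill in V_min, T and k from the profiles where not already supplied.

    f0 is left to the per-architecture re-estimation inside the search; a
    placeholder of 0.5 is stored so the parameter set is complete for
    forward simulation.
    """
    out = params
    if out.v_min is None:
        out = out.with_estimates(v_min=estimate_vmin(profiles, out.d_mrna, out.v_max))
    if out.t_half_occ is None:
        out = out.with_estimates(t_half_occ=estimate_T(profiles, out.v_trl, out.d_protein))
    if out.k is None:
        out = out.with_estimates(
            k=estimate_k(profiles, out.t_half_occ, v_trl=out.v_trl,
                         d_protein=out.d_protein, saturation=saturation))
    if out.f0 is None:
        out = out.with_estimates(f0=np.full(out.n_genes, 0.5))
    return out


# ---------------------------------------------------------------------------
# population initialization and mutation
# ---------------------------------------------------------------------------

def _frozen_arrays(frozen: PerturbationSpec | None, gene_names):
    """(mask, values) for adjacency entries held fixed during inference."""
    n = len(gene_names)
    mask = np.zeros((n, n), dtype=bool)
    values = np.zeros((n, n), dtype=np.int8)
    if frozen is not None:
        idx = {g: i for i, g in enumerate(gene_names)}
        for target, regulator, value in frozen.frozen_edges:
            if target not in idx or regulator not in idx:
                raise ValueError(f"frozen edge ({target}, {regulator}) names unknown genes")
            mask[idx[target], idx[regulator]] = True
            values[idx[target], idx[regulator]] = value
    return mask, values


def _edge_probabilities(current: int, prior_supported: bool,
                        config: EvolutionConfig) -> tuple[list[int], np.ndarray]:
    """Candidate new values (excluding the current one) and their probabilities."""
    candidates = [v for v in (-1, 0, 1) if v != current]
    weights = np.ones(len(candidates))
    if prior_supported and 0 in candidates:
        weights[candidates.index(0)] *= config.chip_zero_weight
    return candidates, weights / weights.sum()


def initialize_population(n_genes: int, config: EvolutionConfig,
                          prior: np.ndarray | None = None,
                          rng: np.random.Generator | None = None, *,
                          gene_names=None,
                          frozen: PerturbationSpec | None = None) -> Population:
    """Random starting population with uniform initial fitness 1/N.

    Adjacency entries are i.i.d. uniform over {-1, 0, +1}; with a binding
    prior, supported entries down-weight the zero value by
    ``chip_zero_weight``.  Logic gates are uniform over {0, 1} and then
    frozen to 0 for genes with fewer than two regulators.  Frozen edges are
    set to their fixed values.
    """
    rng = rng if rng is not None else np.random.default_rng()
    gene_names = tuple(gene_names or (f"G{i}" for i in range(n_genes)))
    N = config.population_size
    if prior is not None:
        prior = np.asarray(prior)
        p0 = np.where(prior > 0, config.chip_zero_weight, 1.0)
        probs = np.stack([np.ones_like(p0, dtype=float), p0,
                          np.ones_like(p0, dtype=float)], axis=-1)
        probs /= probs.sum(axis=-1, keepdims=True)
        u = rng.random((N, n_genes, n_genes, 1))
        cdf = np.cumsum(probs[None], axis=-1)
        am = (u > cdf[..., :-1]).sum(axis=-1).astype(np.int8) - 1
    else:
        am = rng.integers(-1, 2, size=(N, n_genes, n_genes), dtype=np.int8)
    lg = rng.integers(0, 2, size=(N, 2, n_genes), dtype=np.int8)

    fmask, fvals = _frozen_arrays(frozen, gene_names)
    if fmask.any():
        am[:, fmask] = fvals[fmask]
    _freeze_lg(am, lg)
    return Population(am=am, lg=lg,
                      fitness=np.full(N, 1.0 / N), gene_names=gene_names)


def _freeze_lg(am: np.ndarray, lg: np.ndarray) -> None:
    """Zero LG flags in-place for genes with fewer than two regulators."""
    few = (am != 0).sum(axis=2) < 2          # (N, n)
    lg[:, 0, :][few] = 0
    lg[:, 1, :][few] = 0


def mutate_population(pop: Population, config: EvolutionConfig,
                      prior: np.ndarray | None = None,
                      rng: np.random.Generator | None = None,
                      frozen: PerturbationSpec | None = None) -> Population:
    """Mutate every individual by exactly ``hamming_step`` adjacency entries
    (and up to ``hamming_step`` logic-gate flips among mutable flags).

    Each selected adjacency entry takes a new value drawn uniformly from
    the other two allowed values; with a binding prior, mutations of
    supported entries to 0 are down-weighted by ``chip_zero_weight``; in
    sparsity mode a selected nonzero entry moves to 0 with probability
    ``sparsity_to_zero_prob``.  Frozen edges never mutate.  Logic gates are
    re-frozen after mutation for genes left with fewer than two regulators.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = pop.am.shape[1]
    fmask, _ = _frozen_arrays(frozen, pop.gene_names)
    free_flat = np.flatnonzero(~fmask.ravel())
    if free_flat.size < config.hamming_step:
        raise ValueError("fewer mutable adjacency entries than the Hamming step")
    prior_mask = None
    if prior is not None:
        prior_mask = np.asarray(prior) > 0

    am = pop.am.copy()
    lg = pop.lg.copy()
    for b in range(pop.size):
        picks = rng.choice(free_flat, size=config.hamming_step, replace=False)
        for flat in picks:
            i, j = divmod(int(flat), n)
            current = int(am[b, i, j])
            if config.sparsity_bias:
                if current != 0:
                    # selected edge goes to 0 with the sparsity probability,
                    # otherwise flips sign (still exactly one Hamming step)
                    am[b, i, j] = 0 if rng.random() < config.sparsity_to_zero_prob \
                        else -current
                else:
                    am[b, i, j] = -1 if rng.random() < 0.5 else 1
                continue
            supported = bool(prior_mask[i, j]) if prior_mask is not None else False
            candidates, probs = _edge_probabilities(current, supported, config)
            am[b, i, j] = candidates[int(rng.choice(len(candidates), p=probs))]

        mutable = np.repeat((am[b] != 0).sum(axis=1) >= 2, 2)  # flags per gene x2
        flags = np.flatnonzero(mutable)
        if flags.size:
            n_flip = min(config.hamming_step, flags.size)
            for flat in rng.choice(flags, size=n_flip, replace=False):
                gene, row = divmod(int(flat), 2)
                lg[b, row, gene] ^= 1
    _freeze_lg(am, lg)
    return Population(am=am, lg=lg, fitness=pop.fitness.copy(),
                      gene_names=pop.gene_names)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _candidate_augmented_states(profiles: ExpressionProfileSet,
                                merge_radius: float):
    """Architecture-independent pool of auxiliary initial states.

    For each input profile ``j`` and gene ``g`` (not clamped in ``j``), the
    profile with gene ``g`` raised to its maximal observed expression —
    kept only if that modified state is not itself (within the merge
    radius) one of the input profiles.  During evaluation the (j, g) state
    is used by exactly those individuals in which gene ``g`` carries an
    independent self-activating edge.
    """
    maxima = profiles.maxima
    out = []
    for j in range(profiles.n_conditions):
        clamp = profiles.clamp_values(j)
        for g in range(profiles.n_genes):
            if np.isfinite(clamp[g]):
                continue
            state = profiles.values[:, j].copy()
            state[g] = maxima[g]
            diffs = np.abs(state[:, None] - profiles.values) / maxima[:, None]
            if diffs.mean(axis=0).min() < merge_radius:
                continue
            out.append((j, g, state))
    return out


def augment_initial_states(anet: NetworkArchitecture,
                           profiles: ExpressionProfileSet,
                           merge_radius: float = MERGE_RADIUS):
    """Auxiliary initial states spawned by independent self-activation.

    Returns a list of ``(origin_profile_index, gene_index, state_vector)``
    for each independent self-activating gene of ``anet`` and each input
    profile whose modified copy is not already an input profile.  Genes
    whose self-activation is synergistic do not qualify.
    """
    sa = set(anet.independent_self_activators().tolist())
    if not sa:
        return []
    return [(j, g, state.copy())
            for j, g, state in _candidate_augmented_states(profiles, merge_radius)
            if g in sa]


def _evaluate(am3, lg3, profiles: ExpressionProfileSet,
              params: KineticParameters, config: EvolutionConfig,
              rng: np.random.Generator):
    """Score a stack of architectures; see module docstring for the rules.

    Returns a dict with per-individual average distances (penalties
    included), basal fractions, validity flags and bookkeeping counts.
    """
    am3 = np.asarray(am3, dtype=np.int8)
    B, n = am3.shape[0], am3.shape[1]
    m = profiles.n_conditions
    maxima = profiles.maxima

    f0, valid = estimate_f0_batch(am3, lg3, profiles, params)
    f0_penalty = (~valid).sum(axis=1) * config.penalty_f0

    aug = _candidate_augmented_states(profiles, config.merge_radius)
    n_aug = len(aug)

    # shared initial states: perturbed profiles, then perturbed aux states
    base = np.empty((n, m + n_aug))
    clamp = np.full((n, m + n_aug), np.nan)
    origin = np.empty(m + n_aug, dtype=int)
    aug_gene = np.full(m + n_aug, -1, dtype=int)
    for j in range(m):
        base[:, j] = profiles.values[:, j]
        clamp[:, j] = profiles.clamp_values(j)
        origin[j] = j
    for s, (j, g, state) in enumerate(aug, start=m):
        base[:, s] = state
        clamp[:, s] = profiles.clamp_values(j)
        origin[s] = j
        aug_gene[s] = g

    power = config.perturbation_power
    r0 = base + rng.uniform(-power, power, size=base.shape) * maxima[:, None]
    r0 = np.clip(r0, 0.0, None)
    cmask = np.isfinite(clamp)
    r0[cmask] = clamp[cmask]
    p0 = params.v_trl[:, None] * r0 / params.d_protein[:, None]

    dt = config.dt if config.dt is not None else suggested_dt(params)
    t_max = config.t_max if config.t_max is not None else default_t_max(params)
    out = integrate_batch(
        am3, lg3, f0, params, r0[None], p0[None],
        clamp=clamp, dt=dt, t_max=t_max, norm_max=maxima,
    )

    endpoints = out["r"]                                   # (B, n, S)
    bad = ~out["converged"]                                # (B, S)

    # distances of every endpoint to every profile, (B, S, m)
    diffs = np.abs(endpoints[:, :, :, None] - profiles.values[None, :, None, :])
    dists = (diffs / maxima[None, :, None, None]).mean(axis=1)

    state_d = np.empty((B, m + n_aug))
    state_d[:, :m] = dists[:, np.arange(m), np.arange(m)]
    if n_aug:
        state_d[:, m:] = dists[:, m:, :].min(axis=2)
    state_d = np.where(bad, config.penalty_nonconvergence, state_d)

    # which auxiliary states each individual uses
    include = np.ones((B, m + n_aug), dtype=bool)
    if n_aug:
        self_act = (np.diagonal(am3, axis1=1, axis2=2) > 0) & (lg3[:, 0, :] == 0)
        include[:, m:] = self_act[:, aug_gene[m:]]
    counts = include.sum(axis=1)
    avg = (state_d * include).sum(axis=1) / counts
    return {
        "avg_distance": avg + f0_penalty,
        "raw_distance": avg,
        "f0": f0,
        "f0_valid": valid,
        "f0_penalty": f0_penalty,
        "n_states": counts,
        "n_nonconverged": (bad & include).sum(axis=1),
    }


def evaluate_individual(anet: NetworkArchitecture,
                        profiles: ExpressionProfileSet,
                        measured_params: KineticParameters,
                        config: EvolutionConfig,
                        rng: np.random.Generator | None = None):
    """Average attractor distance (penalties included) for one architecture.

    Returns ``(avg_distance, penalties, entry)`` where ``penalties`` sums
    the f0 and non-convergence contributions and ``entry`` is the full
    per-individual evaluation record.
    """
    rng = rng if rng is not None else np.random.default_rng()
    params = complete_parameters(profiles, measured_params)
    ev = _evaluate(anet.am[None], anet.lg[None], profiles, params, config, rng)
    entry = {k: (v[0] if isinstance(v, np.ndarray) else v) for k, v in ev.items()}
    pen = float(entry["f0_penalty"]) + float(
        entry["n_nonconverged"] * config.penalty_nonconvergence / entry["n_states"])
    return float(entry["avg_distance"]), pen, entry


# ---------------------------------------------------------------------------
# the evolutionary loop
# ---------------------------------------------------------------------------

def evolve(profiles: ExpressionProfileSet,
           measured_params: KineticParameters,
           config: EvolutionConfig | None = None,
           prior: np.ndarray | None = None,
           frozen: PerturbationSpec | None = None,
           seed: int | None = None) -> RunResult:
    """One full evolutionary run; reproducible from ``seed``.

    Per generation the whole population is mutated and re-scored; the
    mutated population is accepted iff its minimum average distance
    improves on the incumbent's.  Fitness accumulates the reciprocal of
    each individual's (floored) average distance minus nothing further —
    penalties are already folded into the distance.  After fitness
    accumulation the population is sorted and the bottom 20% replaced by
    copies of the top 20%.  Returns the final fittest architecture with
    its basal-fraction estimate.
    """
    config = config or EvolutionConfig()
    rng = np.random.default_rng(seed)
    params = complete_parameters(profiles, measured_params)
    gene_names = profiles.gene_names

    pop = initialize_population(profiles.n_genes, config, prior, rng,
                                gene_names=gene_names, frozen=frozen)
    ev = _evaluate(pop.am, pop.lg, profiles, params, config, rng)
    scores = ev["avg_distance"]
    f0s = ev["f0"]
    f0_pen = ev["f0_penalty"].astype(float)
    best_min = float(scores.min())
    ledger = FitnessLedger()

    n_elite = max(1, int(0.2 * config.population_size))
    for gen in range(1, config.generations + 1):
        mut = mutate_population(pop, config, prior, rng, frozen)
        ev_t = _evaluate(mut.am, mut.lg, profiles, params, config, rng)
        if config.per_individual_acceptance:
            better = ev_t["avg_distance"] < scores
            pop.am[better] = mut.am[better]
            pop.lg[better] = mut.lg[better]
            scores = np.where(better, ev_t["avg_distance"], scores)
            f0s = np.where(better[:, None], ev_t["f0"], f0s)
            f0_pen = np.where(better, ev_t["f0_penalty"], f0_pen)
            accepted = bool(better.any())
            best_min = min(best_min, float(scores.min()))
        else:
            accepted = float(ev_t["avg_distance"].min()) < best_min
            if accepted:
                pop = Population(mut.am, mut.lg, pop.fitness, gene_names)
                scores = ev_t["avg_distance"]
                f0s = ev_t["f0"]
                f0_pen = ev_t["f0_penalty"].astype(float)
                best_min = float(scores.min())

        pop.fitness += 1.0 / np.maximum(scores, DISTANCE_FLOOR)

        order = np.argsort(-pop.fitness, kind="stable")
        pop = Population(pop.am[order], pop.lg[order], pop.fitness[order],
                         gene_names)
        scores = scores[order]
        f0s = f0s[order]
        f0_pen = f0_pen[order]
        pop.am[-n_elite:] = pop.am[:n_elite]
        pop.lg[-n_elite:] = pop.lg[:n_elite]
        pop.fitness[-n_elite:] = pop.fitness[:n_elite]
        scores[-n_elite:] = scores[:n_elite]
        f0s[-n_elite:] = f0s[:n_elite]
        f0_pen[-n_elite:] = f0_pen[:n_elite]

        if config.keep_ledger:
            ledger.record(gen, accepted, scores, f0_pen, pop.fitness)

    best = pop.individual(0)
    return RunResult(
        anet=best, f0=f0s[0].copy(), fitness=float(pop.fitness[0]),
        avg_distance=float(scores[0]), ledger=ledger, seed=seed, config=config,
    )


def build_consensus(run_results, threshold: float = 0.5) -> ConsensusNetwork:
    """Fitness-weighted consensus over the fittest architecture of each run.

    Per-edge score = Σ_r fitness_r · AM_r / Σ_r fitness_r ∈ [-1, 1];
    the thresholded entry is sign(score) where |score| >= threshold, else
    0.  Logic gates take the fitness-weighted majority.  ``support`` holds
    unweighted per-entry vote fractions.
    """
    runs = list(run_results)
    if not runs:
        raise ValueError("need at least one run result")
    gene_names = runs[0].anet.gene_names
    ams = np.stack([r.anet.am for r in runs]).astype(float)
    lgs = np.stack([r.anet.lg for r in runs]).astype(float)
    w = np.array([r.fitness for r in runs], dtype=float)
    if np.any(w < 0):
        raise ValueError("fitness weights must be non-negative")
    if w.sum() == 0:
        w = np.ones_like(w)
    wn = w / w.sum()

    scores = np.tensordot(wn, ams, axes=1)
    lg_scores = np.tensordot(wn, lgs, axes=1)
    am = np.where(np.abs(scores) >= threshold,
                  np.sign(scores), 0).astype(np.int8)
    lg = (lg_scores >= 0.5).astype(np.int8)
    support = {
        v: (np.stack([r.anet.am for r in runs]) == v).mean(axis=0)
        for v in (-1, 0, 1)
    }
    cons = ConsensusNetwork(
        scores=scores, am=am, lg=lg, lg_scores=lg_scores, support=support,
        gene_names=gene_names, threshold=threshold, total_fitness=float(w.sum()),
    )
    # re-freeze LG for the thresholded topology
    frozen = cons.to_architecture()
    cons.am = frozen.am
    cons.lg = frozen.lg
    return cons
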