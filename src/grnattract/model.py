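"""Model/Results front end for attractor-matching GRN inference.

``AttractorMatchingModel`` bundles a steady-state profile set with the
measured kinetic rates and the search configuration; ``fit`` runs the
requested number of independent evolutionary searches and returns an
``AttractorMatchingResults`` carrying the consensus network, per-run
outcomes, edge support, and simulation/prediction helpers.

Example
-------
>>> model = AttractorMatchingModel(profiles, kinetics)
>>> res = model.fit(n_runs=5, seed=1)
>>> print(res.summary())
>>> res.predict_knockout("G2")
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import KineticParameters
from .dynamics import (MATCH_CUTOFF, attractor_distance,
                       find_attractors_global)
from .estimation import estimate_f0
from .inference import (ConsensusNetwork, EvolutionConfig, RunResult,
                        build_consensus, complete_parameters, evolve)
from .profiles import ExpressionProfileSet, PerturbationSpec

__all__ = ["AttractorMatchingModel", "AttractorMatchingResults"]


class AttractorMatchingModel:
    """Attractor-matching inference model over a steady-state profile set.

    Parameters
    ----------
    profiles : ExpressionProfileSet
        Measured steady-state transcriptional profiles (the attractors).
    kinetics : KineticParameters
        Measured rates; unmeasured quantities (V_min, T, k) are estimated
        from the profiles at fit time and f0 per candidate architecture.
    config : EvolutionConfig, optional
        Search settings; defaults follow the method's standard operating
        point (population 100, 800 generations, Hamming step 1,
        perturbation power 0.1, 30-run consensus at threshold 0.5).
    chip_prior : (n, n) array, optional
        TF–DNA binding support; positive entries bias mutations away from
        removing the corresponding edge.
    frozen_edges : PerturbationSpec, optional
        Adjacency entries held fixed throughout the search.
    """

    def __init__(self, profiles: ExpressionProfileSet,
                 kinetics: KineticParameters, *,
                 config: EvolutionConfig | None = None,
                 chip_prior=None,
                 frozen_edges: PerturbationSpec | None = None):
        self.profiles = profiles
        self.kinetics = kinetics
        self.config = config or EvolutionConfig()
        self.chip_prior = None if chip_prior is None else np.asarray(chip_prior)
        self.frozen_edges = frozen_edges
        if kinetics.gene_names is not None and \
                tuple(kinetics.gene_names) != tuple(profiles.gene_names):
            raise ValueError("kinetics and profiles disagree on gene names/order")

    @classmethod
    def from_dataframe(cls, profile_frame: pd.DataFrame,
                       kinetics_frame: pd.DataFrame, *,
                       perturbations=None, **kwargs) -> "AttractorMatchingModel":
        """Build from a genes×conditions expression frame and a per-gene
        kinetics frame with columns V_max, V_trl, D_mRNA, D_protein
        (optional V_min, k, f0)."""
        profiles = ExpressionProfileSet(profile_frame, perturbations=perturbations)
        kf = kinetics_frame.loc[list(profiles.gene_names)]
        kinetics = KineticParameters(
            v_max=kf["V_max"].to_numpy(), v_trl=kf["V_trl"].to_numpy(),
            d_mrna=kf["D_mRNA"].to_numpy(), d_protein=kf["D_protein"].to_numpy(),
            v_min=kf["V_min"].to_numpy() if "V_min" in kf else None,
            k=kf["k"].to_numpy() if "k" in kf else None,
            gene_names=tuple(profiles.gene_names),
        )
        return cls(profiles, kinetics, **kwargs)

    def fit(self, n_runs: int | None = None, seed: int | None = None,
            threshold: float | None = None) -> "AttractorMatchingResults":
        """Run independent evolutionary searches and build the consensus.

        Each run gets its own seed derived from ``seed``; results depend
        only on those seeds, never on execution order.
        """
        n_runs = n_runs if n_runs is not None else self.config.n_runs
        threshold = (threshold if threshold is not None
                     else self.config.consensus_threshold)
        rng = np.random.default_rng(seed)
        run_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_runs)]
        runs = [
            evolve(self.profiles, self.kinetics, self.config,
                   prior=self.chip_prior, frozen=self.frozen_edges, seed=s)
            for s in run_seeds
        ]
        consensus = build_consensus(runs, threshold)
        return AttractorMatchingResults(self, runs, consensus, seed=seed)


class AttractorMatchingResults:
    """Fitted consensus network with per-run diagnostics."""

    def __init__(self, model: AttractorMatchingModel, runs: list[RunResult],
                 consensus: ConsensusNetwork, seed=None):
        self.model = model
        self.runs = runs
        self.consensus = consensus
        self.seed = seed
        self._params = None

    # -- parameter access ------------------------------------------------
    @property
    def params(self) -> KineticParameters:
        """Completed kinetic parameters for the consensus architecture
        (f0 re-estimated on the consensus topology, clipped into [0, 1])."""
        if self._params is None:
            base = complete_parameters(self.model.profiles, self.model.kinetics)
            f0, _ = estimate_f0(self.consensus.to_architecture(),
                                self.model.profiles, base)
            self._params = base.with_estimates(f0=np.clip(f0, 0.0, 1.0))
        return self._params

    @property
    def edge_frequencies(self) -> pd.DataFrame:
        """Long-form per-edge consensus scores and unweighted vote support."""
        genes = self.consensus.gene_names
        rows = []
        for i, tgt in enumerate(genes):
            for j, reg in enumerate(genes):
                rows.append({
                    "target": tgt, "regulator": reg,
                    "score": float(self.consensus.scores[i, j]),
                    "call": int(self.consensus.am[i, j]),
                    "support_act": float(self.consensus.support[1][i, j]),
                    "support_rep": float(self.consensus.support[-1][i, j]),
                })
        return pd.DataFrame(rows)

    @property
    def fitness(self) -> np.ndarray:
        return np.array([r.fitness for r in self.runs])

    @property
    def avg_distances(self) -> np.ndarray:
        return np.array([r.avg_distance for r in self.runs])

    # -- simulation ------------------------------------------------------
    def attractors(self, clamps: PerturbationSpec | None = None,
                   levels: int = 3):
        """Fixed-point attractors of the consensus network, optionally under
        knockout/overexpression clamps."""
        anet = self.consensus.to_architecture()
        maxima = self.model.profiles.maxima
        bounds = (np.zeros(anet.n_genes), maxima)
        att, info = find_attractors_global(anet, self.params, levels=levels,
                                           bounds=bounds, clamps=clamps,
                                           maxima=maxima)
        return att, info

    def predict_knockout(self, genes, cutoff: float = MATCH_CUTOFF,
                         levels: int = 3) -> pd.DataFrame:
        """Attractors of the consensus network with the given genes deleted,
        annotated with the nearest measured profile and its distance."""
        if isinstance(genes, str):
            genes = [genes]
        att, _ = self.attractors(PerturbationSpec(knockouts=tuple(genes)),
                                 levels=levels)
        profiles = self.model.profiles
        rows = []
        for a in att:
            d = [attractor_distance(a, profiles.values[:, j], profiles.maxima)
                 for j in range(profiles.n_conditions)]
            j = int(np.argmin(d))
            rows.append({
                "nearest_profile": profiles.condition_names[j],
                "distance": float(d[j]),
                "matched": bool(d[j] < cutoff),
                **{g: float(v) for g, v in zip(profiles.gene_names, a)},
            })
        return pd.DataFrame(rows)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit report: run statistics and the consensus
        adjacency with edge scores."""
        cons = self.consensus
        genes = cons.gene_names
        lines = []
        lines.append("Attractor-matching GRN inference results")
        lines.append("=" * 56)
        lines.append(f"genes: {len(genes)}   profiles: "
                     f"{self.model.profiles.n_conditions}   runs: {len(self.runs)}")
        lines.append(f"consensus threshold: {cons.threshold:.2f}   "
                     f"total fitness: {cons.total_fitness:.3g}")
        d = self.avg_distances
        lines.append(f"final avg attractor distance per run: "
                     f"min {d.min():.4f}  median {np.median(d):.4f}  "
                     f"max {d.max():.4f}")
        lines.append("")
        lines.append("consensus adjacency (rows = targets; +1 act, -1 rep):")
        frame = pd.DataFrame(cons.am, index=genes, columns=genes)
        lines.append(frame.to_string())
        lines.append("")
        lines.append("edge scores (fitness-weighted mean in [-1, 1]):")
        lines.append(pd.DataFrame(np.round(cons.scores, 3), index=genes,
                                  columns=genes).to_string())
        lines.append("")
        lg = pd.DataFrame(cons.lg, index=["activator_nmer", "repressor_nmer"],
                          columns=genes)
        lines.append("logic-gate consensus (1 = synergistic):")
        lines.append(lg.to_string())
        return "\n".join(lines)

    def __repr__(self):
        return (f"<AttractorMatchingResults: {len(self.runs)} runs, "
                f"{len(self.consensus.gene_names)} genes>")
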