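"""Steady-state expression profile sets and perturbation annotations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["PerturbationSpec", "ExpressionProfileSet"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Genetic perturbations applied while integrating one condition.

    ``knockouts`` clamp a gene's mRNA at 0; ``overexpressions`` clamp it at
    the gene's maximal observed expression.  ``frozen_edges`` are
    ``(target, regulator, value)`` adjacency entries held fixed throughout
    inference (e.g. a promoter whose TF binding site was disrupted).
    """

    knockouts: tuple[str, ...] = ()
    overexpressions: tuple[str, ...] = ()
    frozen_edges: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "knockouts", tuple(self.knockouts))
        object.__setattr__(self, "overexpressions", tuple(self.overexpressions))
        object.__setattr__(self, "frozen_edges",
                           tuple((str(a), str(b), int(v)) for a, b, v in self.frozen_edges))
        clash = set(self.knockouts) & set(self.overexpressions)
        if clash:
            raise ValueError(
                f"genes {sorted(clash)} cannot be knocked out and overexpressed at once"
            )

    @property
    def is_empty(self) -> bool:
        return not (self.knockouts or self.overexpressions)


class ExpressionProfileSet:
    """Matrix of steady-state transcriptional profiles, genes × conditions.

    Each column is read as a fixed-point attractor of the underlying GRN.
    Entries must be non-negative and every gene must be expressed in at
    least one condition (the attractor distance normalizes by per-gene
    maxima, so an everywhere-zero gene cannot be scored).
    """

    def __init__(self, values, gene_names=None, condition_names=None,
                 perturbations: Mapping[str, PerturbationSpec] | None = None):
        if isinstance(values, pd.DataFrame):
            gene_names = gene_names or list(values.index)
            condition_names = condition_names or list(values.columns)
            values = values.to_numpy(dtype=float)
        values = np.atleast_2d(np.asarray(values, dtype=float))
        n, m = values.shape
        if m < 1:
            raise ValueError("profile set needs at least one condition")
        self.gene_names = tuple(str(g) for g in (gene_names or [f"G{i}" for i in range(n)]))
        self.condition_names = tuple(
            str(c) for c in (condition_names or [f"C{j}" for j in range(m)])
        )
        if len(self.gene_names) != n or len(set(self.gene_names)) != n:
            raise ValueError("gene names must be unique and match the row count")
        if len(self.condition_names) != m:
            raise ValueError("condition names must match the column count")
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative expression at gene {self.gene_names[i]!r}, "
                f"condition {self.condition_names[j]!r}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression levels must be finite")
        zero = np.flatnonzero(values.max(axis=1) <= 0)
        if zero.size:
            raise ValueError(
                f"gene {self.gene_names[zero[0]]!r} is never expressed in any "
                "condition and cannot be normalized; remove it before loading"
            )
        self.values = values
        perturbations = dict(perturbations or {})
        unknown = set(perturbations) - set(self.condition_names)
        if unknown:
            raise ValueError(f"perturbation annotations for unknown conditions {sorted(unknown)}")
        self.perturbations = {
            c: perturbations.get(c, PerturbationSpec()) for c in self.condition_names
        }
        for cond, spec in self.perturbations.items():
            bad = (set(spec.knockouts) | set(spec.overexpressions)) - set(self.gene_names)
            if bad:
                raise ValueError(f"condition {cond!r} perturbs unknown genes {sorted(bad)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def maxima(self) -> np.ndarray:
        """Per-gene maximum over conditions, ``max(I_{i,*})`` — strictly positive."""
        return self.values.max(axis=1)

    @property
    def minima(self) -> np.ndarray:
        return self.values.min(axis=1)

    def column(self, j) -> np.ndarray:
        """One profile as a vector; ``j`` may be an index or condition name."""
        return self.values[:, self._index(j)].copy()

    def _index(self, j) -> int:
        if isinstance(j, str):
            return self.condition_names.index(j)
        return int(j)

    def gene_index(self, gene: str) -> int:
        return self.gene_names.index(gene)

    def perturbation(self, j) -> PerturbationSpec:
        return self.perturbations[self.condition_names[self._index(j)]]

    def clamp_values(self, j) -> np.ndarray:
        """Per-gene clamp vector for condition ``j``: the clamp level where a
        gene is knocked out (0) or overexpressed (its max), NaN elsewhere."""
        spec = self.perturbation(j)
        clamp = np.full(self.n_genes, np.nan)
        for g in spec.knockouts:
            clamp[self.gene_index(g)] = 0.0
        for g in spec.overexpressions:
            clamp[self.gene_index(g)] = self.maxima[self.gene_index(g)]
        return clamp

    def subset(self, keep) -> "ExpressionProfileSet":
        """New profile set restricted to the given condition names/indices."""
        idx = [self._index(j) for j in keep]
        names = [self.condition_names[i] for i in idx]
        return ExpressionProfileSet(
            self.values[:, idx], self.gene_names, names,
            {c: self.perturbations[c] for c in names},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_names),
                            columns=list(self.condition_names))

    def __repr__(self) -> str:
        return (f"<ExpressionProfileSet {self.n_genes} genes x "
                f"{self.n_conditions} conditions>")
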