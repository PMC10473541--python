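"""Discrete GRN architecture and kinetic-parameter containers.

A network architecture ``A_net = {AM, LG}`` couples a trinary adjacency
matrix (``+1`` activation, ``-1`` repression, ``0`` no interaction; rows are
target genes, columns are regulating TFs) with per-gene logic gates stating
whether multiple activators (respectively repressors) of a gene act
synergistically (flag ``1``) or independently (flag ``0``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkArchitecture",
    "KineticParameters",
    "architecture_space_size",
]


def architecture_space_size(n_genes: int) -> int:
    """Number of discrete architectures for ``n`` genes: ``3**(n*n) * 2**(2*n)``.

    Every adjacency entry is trinary and every gene carries two binary
    coordination flags, so a 3-gene network admits ``3**9 * 2**6``
    = 1,259,712 configurations.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    return 3 ** (n_genes * n_genes) * 2 ** (2 * n_genes)


@dataclass(frozen=True)
class NetworkArchitecture:
    """Trinary adjacency matrix plus per-gene coordination logic gates.

    Parameters
    ----------
    am : (n, n) array of {-1, 0, +1}
        Entry ``(i, j)`` is the regulatory effect of TF ``j`` on target
        gene ``i``.
    lg : (2, n) array of {0, 1}
        Row 0 holds the activator coordination flag per gene, row 1 the
        repressor flag; ``1`` means synergistic, ``0`` independent.  Genes
        with fewer than two regulating TFs have both flags frozen to 0
        because coordination cannot affect their dynamics.
    gene_names : sequence of str
        Ordered gene identifiers indexing both matrices.
    """

    am: np.ndarray
    lg: np.ndarray
    gene_names: tuple[str, ...]

    def __init__(self, am, lg=None, gene_names=None, *, validate: bool = True):
        am = np.asarray(am, dtype=np.int8)
        n = am.shape[0]
        if lg is None:
            lg = np.zeros((2, n), dtype=np.int8)
        lg = np.asarray(lg, dtype=np.int8)
        if gene_names is None:
            gene_names = tuple(f"G{i}" for i in range(n))
        gene_names = tuple(str(g) for g in gene_names)
        object.__setattr__(self, "am", am)
        object.__setattr__(self, "lg", lg)
        object.__setattr__(self, "gene_names", gene_names)
        if validate:
            self.validate()

    @property
    def n_genes(self) -> int:
        return self.am.shape[0]

    def validate(self) -> None:
        am, lg = self.am, self.lg
        if am.ndim != 2 or am.shape[0] != am.shape[1]:
            raise ValueError("adjacency matrix must be square")
        n = am.shape[0]
        if len(self.gene_names) != n:
            raise ValueError("gene_names length does not match adjacency size")
        if len(set(self.gene_names)) != n:
            raise ValueError("duplicate gene names")
        if not np.isin(am, (-1, 0, 1)).all():
            bad = np.argwhere(~np.isin(am, (-1, 0, 1)))[0]
            raise ValueError(
                f"adjacency entry at ({self.gene_names[bad[0]]}, "
                f"{self.gene_names[bad[1]]}) is not in {{-1, 0, 1}}"
            )
        if lg.shape != (2, n):
            raise ValueError(f"logic gates must have shape (2, {n})")
        if not np.isin(lg, (0, 1)).all():
            raise ValueError("logic-gate flags must be 0 or 1")
        few = self.regulator_counts() < 2
        if (lg[:, few] != 0).any():
            gene = self.gene_names[int(np.flatnonzero(few & (lg != 0).any(axis=0))[0])]
            raise ValueError(
                f"gene {gene!r} has fewer than two regulators; its logic-gate "
                "flags must be 0 (use freeze_logic_gates to repair)"
            )

    def regulator_counts(self) -> np.ndarray:
        """Number of TFs regulating each gene (nonzero entries per row)."""
        return (self.am != 0).sum(axis=1)

    def freeze_logic_gates(self) -> "NetworkArchitecture":
        """Return a copy with LG flags zeroed for genes with <2 regulators."""
        lg = self.lg.copy()
        lg[:, self.regulator_counts() < 2] = 0
        return NetworkArchitecture(self.am, lg, self.gene_names)

    def independent_self_activators(self) -> np.ndarray:
        """Indices of genes with a self-activating edge whose activators act
        independently — the autoregulation pattern that spawns auxiliary
        initial states during inference."""
        self_act = np.diag(self.am) > 0
        independent = self.lg[0] == 0
        return np.flatnonzero(self_act & independent)

    def hamming_distance(self, other: "NetworkArchitecture") -> int:
        """Number of differing discrete entries (AM and LG combined)."""
        return int((self.am != other.am).sum() + (self.lg != other.lg).sum())

    def with_frozen_edges(self, frozen: Sequence[tuple[int, int, int]]) -> "NetworkArchitecture":
        """Return a copy with the given ``(target, regulator, value)`` entries set."""
        am = self.am.copy()
        for i, j, v in frozen:
            am[i, j] = v
        return NetworkArchitecture(am, self.lg, self.gene_names).freeze_logic_gates()


@dataclass
class KineticParameters:
    """Per-gene kinetic rates plus the estimated regulatory parameters.

    Measured quantities (arrays of length ``n``, all strictly positive):

    - ``v_max`` — maximal transcription rate (transcripts/s after any
      gene-length normalization, see :func:`grnattract.io.read_kinetics`);
    - ``v_trl`` — translation rate (proteins per transcript per second);
    - ``d_mrna``, ``d_protein`` — first-order degradation rates (1/s).

    Estimated quantities (``Θ = {f0, T, k}`` plus ``v_min``):

    - ``v_min`` — minimal transcription rate, ``0 <= v_min <= v_max``;
    - ``f0`` — basal fraction of the dynamic transcription range, in [0, 1]
      for any parameter set accepted without penalty;
    - ``k`` — Hill coefficient per target gene, shared by its regulators;
    - ``t_half_occ`` — per-TF protein abundance producing half occupation,
      optionally overridden per (target, regulator) pair via ``t_pair``.
    """

    v_max: np.ndarray
    v_trl: np.ndarray
    d_mrna: np.ndarray
    d_protein: np.ndarray
    v_min: np.ndarray | None = None
    f0: np.ndarray | None = None
    k: np.ndarray | None = None
    t_half_occ: np.ndarray | None = None
    t_pair: np.ndarray | None = None
    gene_length: np.ndarray | None = None
    protein_length: np.ndarray | None = None
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self):
        for name in ("v_max", "v_trl", "d_mrna", "d_protein", "v_min", "f0", "k",
                     "t_half_occ", "gene_length", "protein_length"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))
        if self.t_pair is not None:
            self.t_pair = np.asarray(self.t_pair, dtype=float)
        n = self.v_max.shape[0]
        if self.gene_names is not None:
            self.gene_names = tuple(str(g) for g in self.gene_names)
            if len(self.gene_names) != n:
                raise ValueError("gene_names length does not match parameter arrays")
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.v_max.shape[0]

    def validate(self) -> None:
        for name in ("v_max", "v_trl", "d_mrna", "d_protein"):
            arr = getattr(self, name)
            if arr is None or not np.all(arr > 0):
                raise ValueError(f"{name} must be strictly positive for every gene")
        if self.v_min is not None:
            if np.any(self.v_min < 0) or np.any(self.v_min > self.v_max):
                raise ValueError("v_min must satisfy 0 <= v_min <= v_max")
        if self.k is not None and np.any(self.k <= 0):
            raise ValueError("Hill coefficient k must be positive")
        if self.t_half_occ is not None and np.any(self.t_half_occ <= 0):
            raise ValueError("half-occupation abundance T must be positive")

    @property
    def is_complete(self) -> bool:
        """Whether all estimated quantities are present for forward simulation."""
        return all(
            getattr(self, name) is not None
            for name in ("v_min", "f0", "k", "t_half_occ")
        )

    def require_complete(self) -> None:
        if not self.is_complete:
            missing = [n for n in ("v_min", "f0", "k", "t_half_occ")
                       if getattr(self, n) is None]
            raise ValueError(
                f"kinetic parameters incomplete (missing {missing}); run the "
                "estimation step or supply them directly"
            )

    def effective_t_matrix(self) -> np.ndarray:
        """(n, n) half-occupation matrix: the per-pair override where given,
        otherwise the per-TF value broadcast along targets."""
        n = self.n_genes
        if self.t_pair is not None:
            return self.t_pair
        if self.t_half_occ is None:
            raise ValueError("half-occupation abundances T are not set")
        return np.broadcast_to(self.t_half_occ[None, :], (n, n)).copy()

    def with_estimates(self, *, v_min=None, f0=None, k=None, t_half_occ=None) -> "KineticParameters":
        out = replace(self)
        if v_min is not None:
            out.v_min = np.asarray(v_min, dtype=float)
        if f0 is not None:
            out.f0 = np.asarray(f0, dtype=float)
        if k is not None:
            out.k = np.asarray(k, dtype=float)
        if t_half_occ is not None:
            out.t_half_occ = np.asarray(t_half_occ, dtype=float)
        out.validate()
        return out
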