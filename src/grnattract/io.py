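"""Tabular readers/writers and the run manifest.

All artifacts are plain text: profiles and kinetic parameters as TSV,
network topology and logic gates as CSV (the adjacency table carries gene
names on both axes), consensus matrices as CSV, plus a signed edge-list
export and a JSON run manifest recording seeds, configuration and input
digests so any run can be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import KineticParameters, NetworkArchitecture
from .profiles import ExpressionProfileSet, PerturbationSpec

logger = logging.getLogger("grnattract")

__all__ = [
    "read_profiles", "write_profiles",
    "read_perturbations", "write_perturbations",
    "read_network", "write_network",
    "read_kinetics", "write_kinetics",
    "write_edge_list", "write_trajectory", "write_attractors",
    "write_manifest", "read_manifest", "file_digest",
]

_KINETIC_COLUMNS = ["V_max", "V_min", "V_trl", "D_mRNA", "D_protein",
                    "k", "f0", "gene_length", "protein_length"]
_REQUIRED_KINETICS = ["V_max", "V_trl", "D_mRNA", "D_protein"]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def read_profiles(path, perturbations_path=None) -> ExpressionProfileSet:
    """Load a genes × conditions expression table (TSV/CSV; gene rows).

    Validation errors name the offending gene and condition.  An optional
    sidecar table annotates per-condition knockouts/overexpressions.
    """
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    perturbations = None
    if perturbations_path is not None:
        perturbations = read_perturbations(perturbations_path)
    return ExpressionProfileSet(frame, perturbations=perturbations)


def write_profiles(profiles: ExpressionProfileSet, path) -> None:
    profiles.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene")


def read_perturbations(path) -> dict[str, PerturbationSpec]:
    """Sidecar table with columns condition, knockouts, overexpressions
    (comma-separated gene lists, empty for none)."""
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna("")
    out = {}
    for _, row in frame.iterrows():
        out[row["condition"]] = PerturbationSpec(
            knockouts=tuple(g for g in row.get("knockouts", "").split(",") if g),
            overexpressions=tuple(
                g for g in row.get("overexpressions", "").split(",") if g),
        )
    return out


def write_perturbations(perturbations: dict[str, PerturbationSpec], path) -> None:
    rows = [{"condition": c,
             "knockouts": ",".join(s.knockouts),
             "overexpressions": ",".join(s.overexpressions)}
            for c, s in perturbations.items()]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# network architecture
# ---------------------------------------------------------------------------

def read_network(path_am, path_lg=None) -> NetworkArchitecture:
    """Load a trinary adjacency CSV (gene names on both axes) and, if given,
    the logic-gate CSV with columns gene, activator_nmer, repressor_nmer.

    Logic-gate flags set for genes with fewer than two regulators are
    frozen to 0 with a warning — coordination cannot affect such genes.
    """
    am_frame = pd.read_csv(path_am, sep=_sep_for(path_am), index_col=0)
    genes = [str(g) for g in am_frame.index]
    if [str(c) for c in am_frame.columns] != genes:
        raise ValueError("adjacency table row and column gene names differ")
    am = am_frame.to_numpy()
    bad = np.argwhere(~np.isin(am, (-1, 0, 1)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-trinary adjacency entry at ({genes[i]}, {genes[j]}): {am[i, j]!r}"
        )
    lg = np.zeros((2, len(genes)), dtype=np.int8)
    if path_lg is not None:
        lg_frame = pd.read_csv(path_lg, sep=_sep_for(path_lg)).set_index("gene")
        lg_frame.index = lg_frame.index.astype(str)
        missing = set(genes) - set(lg_frame.index)
        if missing:
            raise ValueError(f"logic-gate table lacks genes {sorted(missing)}")
        lg[0] = lg_frame.loc[genes, "activator_nmer"].to_numpy()
        lg[1] = lg_frame.loc[genes, "repressor_nmer"].to_numpy()
    raw = NetworkArchitecture(am.astype(np.int8), lg, genes, validate=False)
    frozen = raw.freeze_logic_gates()
    if (frozen.lg != lg).any():
        fixed = [genes[i] for i in
                 np.flatnonzero((frozen.lg != lg).any(axis=0))]
        logger.warning(
            "logic-gate flags for %s were set but the genes have fewer than "
            "two regulators; frozen to 0", fixed)
    frozen.validate()
    return frozen


def write_network(anet: NetworkArchitecture, path_am, path_lg=None,
                  f0=None) -> None:
    genes = list(anet.gene_names)
    pd.DataFrame(anet.am, index=genes, columns=genes).to_csv(
        path_am, sep=_sep_for(path_am), index_label="gene")
    if path_lg is not None:
        frame = pd.DataFrame({
            "gene": genes,
            "activator_nmer": anet.lg[0],
            "repressor_nmer": anet.lg[1],
        })
        if f0 is not None:
            frame["f0"] = np.asarray(f0, dtype=float)
        frame.to_csv(path_lg, sep=_sep_for(path_lg), index=False)


def write_edge_list(scores, gene_names, path, threshold: float = 0.0) -> None:
    """Signed edge list (source TF, target gene, sign, score) for graph tools."""
    scores = np.asarray(scores, dtype=float)
    rows = []
    for i, tgt in enumerate(gene_names):
        for j, src in enumerate(gene_names):
            if abs(scores[i, j]) > threshold:
                rows.append({"source": src, "target": tgt,
                             "sign": int(np.sign(scores[i, j])),
                             "score": float(scores[i, j])})
    pd.DataFrame(rows, columns=["source", "target", "sign", "score"]).to_csv(
        path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# kinetic parameters
# ---------------------------------------------------------------------------

def read_kinetics(path, t_path=None, *, convert_lengths: bool = True) -> KineticParameters:
    """Per-gene kinetic table (TSV/CSV), one row per gene.

    Required columns: V_max, V_trl, D_mRNA, D_protein; optional V_min, k,
    f0, gene_length, protein_length.  When lengths are present and
    ``convert_lengths`` is on, polymerization-rate units are converted once
    to per-molecule rates (V_max, V_min divided by gene length; V_trl by
    protein length) and the conversion is logged.  ``t_path`` points to a
    two-column table (gene, T) of per-TF half-occupation abundances.
    """
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    missing = [c for c in _REQUIRED_KINETICS if c not in frame.columns]
    if missing:
        raise ValueError(f"kinetic table lacks required columns {missing}")
    genes = tuple(str(g) for g in frame.index)

    def col(name):
        return frame[name].to_numpy(dtype=float) if name in frame.columns else None

    v_max, v_trl = col("V_max"), col("V_trl")
    v_min = col("V_min")
    gene_length, protein_length = col("gene_length"), col("protein_length")
    if convert_lengths and gene_length is not None:
        logger.info("converting transcription rates to per-transcript units "
                    "(dividing V_max/V_min by gene length)")
        v_max = v_max / gene_length
        if v_min is not None:
            v_min = v_min / gene_length
    if convert_lengths and protein_length is not None:
        logger.info("converting translation rates to per-protein units "
                    "(dividing V_trl by protein length)")
        v_trl = v_trl / protein_length

    t = None
    if t_path is not None:
        t_frame = pd.read_csv(t_path, sep=_sep_for(t_path)).set_index("gene")
        t_frame.index = t_frame.index.astype(str)
        t = t_frame.loc[list(genes), "T"].to_numpy(dtype=float)

    return KineticParameters(
        v_max=v_max, v_trl=v_trl, d_mrna=col("D_mRNA"),
        d_protein=col("D_protein"), v_min=v_min, f0=col("f0"), k=col("k"),
        t_half_occ=t, gene_length=gene_length, protein_length=protein_length,
        gene_names=genes,
    )


def write_kinetics(params: KineticParameters, path, t_path=None) -> None:
    genes = list(params.gene_names or
                 (f"G{i}" for i in range(params.n_genes)))
    data = {"V_max": params.v_max, "V_min": params.v_min,
            "V_trl": params.v_trl, "D_mRNA": params.d_mrna,
            "D_protein": params.d_protein, "k": params.k, "f0": params.f0,
            "gene_length": params.gene_length,
            "protein_length": params.protein_length}
    frame = pd.DataFrame({k: v for k, v in data.items() if v is not None},
                         index=genes)
    frame.to_csv(path, sep=_sep_for(path), index_label="gene")
    if t_path is not None and params.t_half_occ is not None:
        pd.DataFrame({"gene": genes, "T": params.t_half_occ}).to_csv(
            t_path, sep=_sep_for(t_path), index=False)


# ---------------------------------------------------------------------------
# simulation exports
# ---------------------------------------------------------------------------

def write_trajectory(times, r, p, gene_names, path) -> None:
    """Trajectory TSV: time, then one column per gene for mRNA, then protein."""
    cols = {"time": np.asarray(times)}
    for i, g in enumerate(gene_names):
        cols[f"R_{g}"] = np.asarray(r)[:, i]
    for i, g in enumerate(gene_names):
        cols[f"P_{g}"] = np.asarray(p)[:, i]
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


def write_attractors(attractors, residuals, gene_names, path) -> None:
    """Attractor TSV: id, per-gene mRNA levels, residual norm."""
    attractors = np.asarray(attractors)
    frame = pd.DataFrame(attractors, columns=list(gene_names))
    frame.insert(0, "attractor", [f"att{i}" for i in range(len(frame))])
    frame["residual"] = np.asarray(residuals)
    frame.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, config=None, seeds=None, inputs=None,
                   extra=None) -> None:
    """JSON manifest: configuration snapshot, per-run seeds, input digests
    and package version — enough to reproduce a run bit-exactly."""
    from . import __version__
    manifest = {
        "package": "grnattract",
        "version": __version__,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config)
                  else (config or {}),
        "seeds": list(map(int, seeds)) if seeds is not None else None,
        "inputs": {str(p): file_digest(p) for p in (inputs or [])},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
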