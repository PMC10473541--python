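"""Synthetic validation machinery: reference networks, noisy attractor
profiles, the matching null model, knockout-attractor prediction, and
architecture scoring.

Reference GRNs are rejection-sampled so that their ODE systems possess
many distinct fixed-point attractors and no oscillatory grid starts —
the regime in which steady-state transcriptional profiles are informative
about architecture.  Because profiles here are generated by the same ODE
framework that the inference evaluates, self-consistency results are an
upper bound on real-data performance; an external generator can be plugged
in by supplying any :class:`~grnattract.profiles.ExpressionProfileSet`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from .architecture import KineticParameters, NetworkArchitecture
from .dynamics import (MATCH_CUTOFF, attractor_distance, find_attractors_global,
                       integrate_batch, default_t_max, suggested_dt)
from .estimation import estimate_f0
from .inference import (EvolutionConfig, _evaluate, build_consensus,
                        complete_parameters, evolve)
from .profiles import ExpressionProfileSet, PerturbationSpec

__all__ = [
    "default_kinetics",
    "generate_reference_grn",
    "generate_attractor_profiles",
    "null_model",
    "knockout_prediction_experiment",
    "evaluate_architecture",
    "hamming_attractor_scan",
    "dropout_prediction",
]


def default_kinetics(n_genes: int, *, f0=None, k=None, rng=None) -> KineticParameters:
    """Bacterial-scale kinetic defaults for synthetic reference networks.

    Per-molecule rates typical of fast-growing microbes: transcription
    0.05 transcripts/s (a ~1 kb gene at ~50 nt/s), mRNA half-life ~4 min,
    translation 0.06 proteins per transcript per second, protein half-life
    ~12 min (active TF turnover).  The transcriptional floor is 2% of the
    maximum.  Basal fractions default to a low band (multistability needs
    weak basal expression) and Hill coefficients to moderate cooperativity;
    half-occupation sits at 30% of each TF's open-loop maximal abundance.
    """
    rng = rng if rng is not None else np.random.default_rng()
    v_max = np.full(n_genes, 0.05)
    d_mrna = np.full(n_genes, 0.003)
    v_trl = np.full(n_genes, 0.06)
    d_protein = np.full(n_genes, 0.001)
    v_min = 0.02 * v_max
    if f0 is None:
        f0 = rng.uniform(0.03, 0.12, size=n_genes)
    if k is None:
        k = rng.uniform(4.5, 8.0, size=n_genes)
    p_open_max = v_trl * (v_max / d_mrna) / d_protein
    t = 0.4 * p_open_max
    return KineticParameters(
        v_max=v_max, v_trl=v_trl, d_mrna=d_mrna, d_protein=d_protein,
        v_min=v_min, f0=np.asarray(f0, dtype=float),
        k=np.asarray(k, dtype=float), t_half_occ=t,
    )


def _sample_architecture(n: int, rng, allow_autoregulation: bool) -> NetworkArchitecture:
    # off-diagonal edges sparse-ish; diagonal biased toward self-activation,
    # which is what sustains multiple fixed points
    off = rng.choice([-1, 0, 1], size=(n, n), p=[0.2, 0.6, 0.2])
    am = off.astype(np.int8)
    if allow_autoregulation:
        diag = rng.choice([-1, 0, 1], size=n, p=[0.05, 0.2, 0.75])
        am[np.diag_indices(n)] = diag
    else:
        am[np.diag_indices(n)] = 0
    lg = rng.choice([0, 1], size=(2, n), p=[0.8, 0.2]).astype(np.int8)
    return NetworkArchitecture(am, lg, validate=False).freeze_logic_gates()


def generate_reference_grn(n_genes: int, min_attractors: int = 9,
                           rng: np.random.Generator | None = None,
                           allow_autoregulation: bool = True, *,
                           kinetics: KineticParameters | None = None,
                           levels: int | None = None,
                           require_full_range: bool = True,
                           max_candidates: int = 5000):
    """Rejection-sample a reference network with rich fixed-point structure.

    Draws random architectures with default kinetics and keeps the first
    whose systematic global attractor search finds at least
    ``min_attractors`` fixed points with every grid start converging (no
    oscillations, no divergence).  With ``require_full_range`` (default),
    every gene must additionally be exercised over most of its dynamic
    range across the attractor set (minimum below 30% of its maximum) —
    the parameter-estimation chain assumes the profiles contain both the
    transcriptional floor and full activation of each gene, so a network
    whose attractors hold a gene at one level is not a usable benchmark.

    Returns ``(anet, params)``; raises RuntimeError with a budget report
    when ``max_candidates`` draws are exhausted.
    """
    if not 3 <= n_genes <= 12:
        raise ValueError("reference generation supports 3..12 genes "
                         "(global-search cost cap)")
    rng = rng if rng is not None else np.random.default_rng()
    if levels is None:
        levels = 3 if n_genes <= 7 else 2
    for attempt in range(1, max_candidates + 1):
        params = kinetics if kinetics is not None else default_kinetics(n_genes, rng=rng)
        anet = _sample_architecture(n_genes, rng, allow_autoregulation)
        att, info = find_attractors_global(anet, params, levels=levels)
        if info["n_oscillatory"] or info["n_diverged"]:
            continue
        if att.shape[0] < min_attractors:
            continue
        if require_full_range:
            lo, hi = att.min(axis=0), att.max(axis=0)
            if np.any(hi <= 0) or np.any(lo > 0.3 * hi):
                continue
            # each gene's high state must exceed its half-occupation
            # abundance, otherwise the near-saturation Hill-coefficient
            # estimate has nothing to anchor on
            p_hi = params.v_trl * hi / params.d_protein
            if np.any(p_hi < 1.25 * params.t_half_occ):
                continue
        return anet, params
    raise RuntimeError(
        f"no {n_genes}-gene network with >= {min_attractors} attractors and no "
        f"oscillations found in {max_candidates} candidates"
    )


def generate_attractor_profiles(anet: NetworkArchitecture,
                                params: KineticParameters,
                                noise_sd: float = 0.2,
                                rng: np.random.Generator | None = None, *,
                                levels: int | None = None,
                                noise_scale: str = "rms") -> ExpressionProfileSet:
    """Turn a network's fixed-point attractors into a noisy profile matrix.

    The attractors found by the global search become the columns of the
    input matrix; i.i.d. Gaussian noise of standard deviation ``noise_sd``
    is added and the result clipped at zero.  ``noise_sd`` is interpreted
    relative to the root-mean-square of the clean matrix by default
    (``noise_sd = 0.2`` then corresponds to a ~14 dB signal-to-noise
    ratio); alternatives are ``"per-gene-max"`` (scaled by each gene's
    maximum) and ``"absolute"``.  ``noise_sd = 0`` returns the exact
    attractors.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    if levels is None:
        levels = 3 if anet.n_genes <= 7 else 2
    att, info = find_attractors_global(anet, params, levels=levels)
    if att.shape[0] == 0:
        raise RuntimeError("network has no fixed-point attractor")
    values = att.T.copy()                         # genes x attractors
    if noise_sd > 0:
        if noise_scale == "rms":
            scale = float(np.sqrt(np.mean(values**2)))
        elif noise_scale == "per-gene-max":
            scale = values.max(axis=1, keepdims=True)
        elif noise_scale == "absolute":
            scale = 1.0
        else:
            raise ValueError(f"unknown noise_scale {noise_scale!r}")
        values = np.clip(values + rng.normal(0.0, noise_sd, values.shape) * scale,
                         0.0, None)
    names = [f"A{j}" for j in range(values.shape[1])]
    return ExpressionProfileSet(values, anet.gene_names, names)


def null_model(profiles: ExpressionProfileSet, cutoff: float = MATCH_CUTOFF,
               n_draws: int = 100_000,
               rng: np.random.Generator | None = None):
    """Probability that per-gene uniform sampling lands near an attractor.

    Each draw samples gene ``i`` from U(min_j I_ij, max_j I_ij); the
    statistic is the fraction of draws whose minimum attractor distance to
    any input profile falls below ``cutoff``.  Used to calibrate the
    matching cutoff: a cutoff is usable when this probability is small.

    Returns ``(probability, binomial_standard_error)``.
    """
    if n_draws < 1000:
        raise ValueError("need at least 1000 draws for a stable estimate")
    rng = rng if rng is not None else np.random.default_rng()
    lo, hi = profiles.minima, profiles.maxima
    draws = rng.uniform(lo, hi, size=(n_draws, profiles.n_genes))
    # distance of each draw to each profile, normalized by per-gene maxima
    diffs = np.abs(draws[:, :, None] - profiles.values[None]) / hi[None, :, None]
    min_d = diffs.mean(axis=1).min(axis=1)
    p = float(np.mean(min_d < cutoff))
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_draws))
    return p, se


def _pair_attractors(ref_att, inf_att, maxima, cutoff, method="greedy"):
    """Pair attractors across two sets; returns matched pair count.

    Greedy pairing takes globally ascending distances (never reusing an
    attractor — a bijection on the smaller set); the optimal variant solves
    the assignment problem.
    """
    if ref_att.shape[0] == 0 or inf_att.shape[0] == 0:
        return 0, []
    d = np.array([[attractor_distance(a, b, maxima) for b in inf_att]
                  for a in ref_att])
    pairs = []
    if method == "greedy":
        used_r, used_i = set(), set()
        for flat in np.argsort(d, axis=None, kind="stable"):
            i, j = divmod(int(flat), d.shape[1])
            if i in used_r or j in used_i:
                continue
            used_r.add(i)
            used_i.add(j)
            pairs.append((i, j, float(d[i, j])))
            if len(pairs) == min(d.shape):
                break
    elif method == "optimal":
        rows, cols = linear_sum_assignment(d)
        pairs = [(int(i), int(j), float(d[i, j])) for i, j in zip(rows, cols)]
    else:
        raise ValueError(f"unknown pairing method {method!r}")
    matched = sum(1 for _, _, dist in pairs if dist < cutoff)
    return matched, pairs


def knockout_prediction_experiment(reference, inferred, genes_to_delete=None,
                                   cutoff: float = MATCH_CUTOFF, *,
                                   maxima=None, levels: int | None = None,
                                   pairing: str = "greedy") -> pd.DataFrame:
    """Do single-gene deletions reshape both networks' attractors alike?

    For each gene, the gene's mRNA is clamped to zero in both the reference
    and the inferred network, the global attractor search is run on each,
    and attractors are paired across networks by ascending distance; a pair
    closer than ``cutoff`` counts as matched.

    ``reference`` and ``inferred`` are ``(anet, params)`` tuples on the
    same gene set.  Returns one row per deletion with attractor and match
    counts.
    """
    ref_anet, ref_params = reference
    inf_anet, inf_params = inferred
    if ref_anet.gene_names != inf_anet.gene_names:
        raise ValueError("networks must share the same gene set")
    if genes_to_delete is None:
        genes_to_delete = list(ref_anet.gene_names)
    if levels is None:
        levels = 3 if ref_anet.n_genes <= 7 else 2
    if maxima is None:
        maxima = ref_params.v_max / ref_params.d_mrna

    rows = []
    for gene in genes_to_delete:
        clamp = PerturbationSpec(knockouts=(gene,))
        ref_att, _ = find_attractors_global(ref_anet, ref_params, levels=levels,
                                            clamps=clamp, maxima=maxima)
        inf_att, _ = find_attractors_global(inf_anet, inf_params, levels=levels,
                                            clamps=clamp, maxima=maxima)
        matched, _pairs = _pair_attractors(ref_att, inf_att, maxima, cutoff,
                                           method=pairing)
        rows.append({
            "deleted_gene": gene,
            "n_reference_attractors": ref_att.shape[0],
            "n_inferred_attractors": inf_att.shape[0],
            "n_matched": matched,
        })
    return pd.DataFrame(rows)


def _fold_symmetric_scores(scores):
    """Fold (i, j)/(j, i) onto the upper triangle keeping the larger |score|."""
    n = scores.shape[0]
    out = scores.copy()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = scores[i, j], scores[j, i]
            keep = a if abs(a) >= abs(b) else b
            out[i, j] = out[j, i] = keep
    return out


def evaluate_architecture(predicted, reference, threshold: float = 0.5,
                          symmetrize: bool = False,
                          include_diagonal: bool = True, *,
                          sign_aware: bool = True) -> dict:
    """Score a predicted (consensus) network against a reference topology.

    Edge existence is ranked by |score| for AUROC/AUPRC against the
    binarized reference (edge present = nonzero entry).  The F1 score
    thresholds |score| at ``threshold``; a true positive additionally
    requires sign agreement unless ``sign_aware=False``.  The Hamming
    distance counts differing trinary entries of the thresholded matrix.
    Self-edges are excluded when ``include_diagonal=False``; symmetrizing
    folds each (i, j)/(j, i) pair by the larger absolute score.
    """
    scores = np.asarray(getattr(predicted, "scores", predicted), dtype=float)
    ref = np.asarray(getattr(reference, "am", reference))
    if scores.shape != ref.shape:
        raise ValueError("predicted and reference matrices must have the same shape")
    n = ref.shape[0]

    if symmetrize:
        scores = _fold_symmetric_scores(scores)
        ref_f = ref.copy()
        for i in range(n):
            for j in range(i + 1, n):
                entry = ref[i, j] if ref[i, j] != 0 else ref[j, i]
                ref_f[i, j] = ref_f[j, i] = entry
        ref = ref_f
        mask = np.triu(np.ones((n, n), dtype=bool),
                       k=0 if include_diagonal else 1)
    else:
        mask = np.ones((n, n), dtype=bool)
        if not include_diagonal:
            np.fill_diagonal(mask, False)

    s = scores[mask]
    r = ref[mask]
    pred_trinary = np.where(np.abs(s) >= threshold, np.sign(s), 0).astype(int)

    ref_edge = r != 0
    pred_edge = pred_trinary != 0
    if sign_aware:
        tp = int(np.sum(pred_edge & ref_edge & (pred_trinary == r)))
    else:
        tp = int(np.sum(pred_edge & ref_edge))
    fp = int(np.sum(pred_edge)) - tp
    fn = int(np.sum(ref_edge)) - tp
    tn = int(np.sum(~pred_edge & ~ref_edge))

    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    f1 = (2 * precision * recall / (precision + recall)
          if (tp + fp) and (tp + fn) and (precision + recall) > 0 else
          (0.0 if (tp + fn) else float("nan")))

    if ref_edge.any() and not ref_edge.all():
        fpr, tpr, _ = roc_curve(ref_edge, np.abs(s))
        auroc = float(auc(fpr, tpr))
        prec_c, rec_c, _ = precision_recall_curve(ref_edge, np.abs(s))
        auprc = float(auc(rec_c, prec_c))
    else:
        auroc = auprc = float("nan")

    return {
        "f1": f1, "precision": precision, "recall": recall,
        "auroc": auroc, "auprc": auprc,
        "hamming": int(np.sum(pred_trinary != r)),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "n_edges_reference": int(ref_edge.sum()),
        "n_edges_predicted": int(pred_edge.sum()),
    }


def _mutate_exact_hamming(anet: NetworkArchitecture, d: int, rng,
                          max_tries: int = 200) -> NetworkArchitecture:
    """A random architecture at exact combined (AM + LG) Hamming distance d."""
    n = anet.n_genes
    for _ in range(max_tries):
        am = anet.am.copy()
        lg = anet.lg.copy()
        n_slots = n * n + 2 * n
        picks = rng.choice(n_slots, size=d, replace=False)
        for flat in picks:
            if flat < n * n:
                i, j = divmod(int(flat), n)
                others = [v for v in (-1, 0, 1) if v != am[i, j]]
                am[i, j] = others[int(rng.integers(2))]
            else:
                gene, row = divmod(int(flat) - n * n, 2)
                lg[row, gene] ^= 1
        cand = NetworkArchitecture(am, lg, anet.gene_names,
                                   validate=False).freeze_logic_gates()
        if anet.hamming_distance(cand) == d:
            return cand
    raise RuntimeError(f"could not realize Hamming distance {d} in {max_tries} tries")


def hamming_attractor_scan(reference, profiles: ExpressionProfileSet,
                           distances=range(1, 11),
                           mutants_per_distance: int = 100,
                           rng: np.random.Generator | None = None, *,
                           config: EvolutionConfig | None = None) -> pd.DataFrame:
    """Architecture–attractor coupling scan.

    For each Hamming distance ``d``, draws random mutants of the reference
    architecture at exactly that combined AM+LG distance, scores each
    mutant's average attractor distance against the reference profiles
    with the same machinery the evolutionary search uses, and returns the
    long-form table of (hamming, attractor_distance) pairs.
    """
    if mutants_per_distance < 1:
        raise ValueError("mutants_per_distance must be at least 1")
    rng = rng if rng is not None else np.random.default_rng()
    anet, params = reference
    params = complete_parameters(profiles, params)
    config = config or EvolutionConfig()

    rows = []
    for d in distances:
        muts = [_mutate_exact_hamming(anet, d, rng)
                for _ in range(mutants_per_distance)]
        am3 = np.stack([m.am for m in muts])
        lg3 = np.stack([m.lg for m in muts])
        ev = _evaluate(am3, lg3, profiles, params, config, rng)
        for dist in ev["avg_distance"]:
            rows.append({"hamming": int(d), "attractor_distance": float(dist)})
    return pd.DataFrame(rows)


def dropout_prediction(profiles: ExpressionProfileSet, held_out_indices,
                       measured_params: KineticParameters,
                       config: EvolutionConfig | None = None, *,
                       seed: int | None = None, cutoff: float = MATCH_CUTOFF,
                       mode: str = "strict",
                       prior=None) -> pd.DataFrame:
    """Hold-out prediction of unseen genotypes' transcriptional profiles.

    The evolutionary search plus consensus runs on the retained profiles
    only; the held-out genotype's perturbation (its knockout/overexpression
    clamps) is then simulated on the consensus network and the reached
    attractor compared with the held-out truth at ``cutoff``.

    ``mode="strict"`` starts integration from every retained profile (the
    omitted profile is unavailable at prediction time) and reports the best
    match among the reached fixed points; ``mode="oracle"`` starts from the
    omitted profile itself.  A prediction with no converged endpoint is
    reported as ``no attractor`` rather than dropped.
    """
    if mode not in ("strict", "oracle"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or EvolutionConfig()
    held = [profiles._index(j) for j in np.atleast_1d(held_out_indices)]
    retained_idx = [j for j in range(profiles.n_conditions) if j not in held]
    if len(retained_idx) < 2:
        raise ValueError("at least 2 profiles must remain after omission")
    retained = profiles.subset(retained_idx)

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=config.n_runs)
    runs = [evolve(retained, measured_params, config, prior=prior, seed=int(s))
            for s in run_seeds]
    cons = build_consensus(runs, config.consensus_threshold)
    cons_anet = cons.to_architecture()

    params = complete_parameters(retained, measured_params)
    f0, valid = estimate_f0(cons_anet, retained, params)
    params = params.with_estimates(f0=np.clip(f0, 0.0, 1.0))

    dt = config.dt if config.dt is not None else suggested_dt(params)
    t_max = config.t_max if config.t_max is not None else default_t_max(params)
    maxima = profiles.maxima

    rows = []
    for j in held:
        truth = profiles.values[:, j]
        clamp_vec = profiles.clamp_values(j)
        if mode == "oracle":
            starts = truth[:, None].copy()
        else:
            starts = retained.values.copy()
        S = starts.shape[1]
        clamp = np.repeat(clamp_vec[:, None], S, axis=1)
        cmask = np.isfinite(clamp)
        r0 = starts.copy()
        r0[cmask] = clamp[cmask]
        p0 = params.v_trl[:, None] * r0 / params.d_protein[:, None]
        out = integrate_batch(cons_anet.am[None], cons_anet.lg[None],
                              params.f0[None], params, r0[None], p0[None],
                              clamp=clamp, dt=dt, t_max=t_max, norm_max=maxima)
        conv = out["converged"][0]
        if not conv.any():
            rows.append({"held_out": profiles.condition_names[j],
                         "status": "no attractor", "distance": np.nan,
                         "matched": False})
            continue
        endpoints = out["r"][0][:, conv].T
        dists = [attractor_distance(e, truth, maxima) for e in endpoints]
        best = int(np.argmin(dists))
        rows.append({
            "held_out": profiles.condition_names[j],
            "status": "ok",
            "distance": float(dists[best]),
            "matched": bool(dists[best] < cutoff),
            "predicted_profile": endpoints[best],
        })
    return pd.DataFrame(rows)
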