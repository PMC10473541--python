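import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from grnattract import (EvolutionConfig, NetworkArchitecture,
                        attractor_distance, evaluate_architecture,
                        find_attractors_global, generate_attractor_profiles,
                        generate_reference_grn, hamming_attractor_scan,
                        knockout_prediction_experiment, null_model)
from grnattract.benchmark import _pair_attractors, default_kinetics, dropout_prediction
from grnattract.profiles import ExpressionProfileSet


class TestReferenceGeneration:
    def test_single_attractor_requirement_succeeds_quickly(self):
        anet, params = generate_reference_grn(3, min_attractors=1,
                                              rng=np.random.default_rng(0),
                                              require_full_range=False)
        att, info = find_attractors_global(anet, params, levels=3)
        assert att.shape[0] >= 1
        assert info["n_oscillatory"] == 0

    def test_attractor_count_verified_on_finer_grid(self, small_reference):
        """Refinement oracle: a finer grid confirms at least the promised
        attractor count."""
        anet, params = small_reference
        att5, _ = find_attractors_global(anet, params, levels=5)
        assert att5.shape[0] >= 3

    def test_autoregulation_can_be_excluded(self):
        anet, _ = generate_reference_grn(3, min_attractors=1,
                                         rng=np.random.default_rng(1),
                                         allow_autoregulation=False,
                                         require_full_range=False)
        assert (np.diag(anet.am) == 0).all()

    def test_budget_exhaustion_reports(self):
        with pytest.raises(RuntimeError, match="candidates"):
            generate_reference_grn(3, min_attractors=50,
                                   rng=np.random.default_rng(2),
                                   max_candidates=5)


class TestAttractorProfiles:
    def test_noiseless_columns_are_fixed_points(self, small_reference,
                                                small_profiles):
        anet, params = small_reference
        from grnattract import SystemState, ode_rhs
        norm = params.v_max / params.d_mrna
        for j in range(small_profiles.n_conditions):
            r = small_profiles.column(j)
            p = params.v_trl * r / params.d_protein
            dr, _ = ode_rhs(SystemState(r, p), anet, params)
            assert np.max(np.abs(dr) / norm) < 1e-4

    def test_noise_magnitude_matches_folded_normal(self, small_reference):
        """Mean absolute deviation from the clean attractor approaches
        sd·sqrt(2/pi) over many draws (absolute noise scale, modest level
        so clipping at zero is negligible)."""
        anet, params = small_reference
        clean = generate_attractor_profiles(anet, params, 0.0)
        sd = 0.05 * float(clean.values.max())
        devs = []
        rng = np.random.default_rng(3)
        for _ in range(30):
            noisy = generate_attractor_profiles(anet, params, sd, rng=rng,
                                                noise_scale="absolute")
            devs.append(np.abs(noisy.values - clean.values).mean())
        assert np.mean(devs) == pytest.approx(sd * np.sqrt(2 / np.pi), rel=0.1)

    def test_never_negative(self, small_reference):
        anet, params = small_reference
        noisy = generate_attractor_profiles(anet, params, 0.5,
                                            rng=np.random.default_rng(4))
        assert (noisy.values >= 0).all()

    def test_rms_noise_scale_hits_target_snr(self, small_reference):
        """Away from the zero-clipping boundary the injected noise has
        standard deviation 0.2 x rms(signal), i.e. the ~14 dB regime."""
        anet, params = small_reference
        clean = generate_attractor_profiles(anet, params, 0.0)
        sigma = 0.2 * np.sqrt(np.mean(clean.values**2))
        rng = np.random.default_rng(5)
        devs = []
        mask = clean.values > 3 * sigma  # clipping negligible here
        for _ in range(100):
            noisy = generate_attractor_profiles(anet, params, 0.2, rng=rng)
            devs.append((noisy.values - clean.values)[mask])
        assert np.std(np.concatenate(devs)) == pytest.approx(sigma, rel=0.1)


class TestNullModel:
    def _profiles(self):
        rng = np.random.default_rng(0)
        return ExpressionProfileSet(rng.uniform(1, 10, size=(5, 6)))

    def test_huge_cutoff_certain_match(self):
        p, se = null_model(self._profiles(), cutoff=10.0, n_draws=2000,
                           rng=np.random.default_rng(1))
        assert p == 1.0

    def test_zero_measure_cutoff_never_matches(self):
        p, _ = null_model(self._profiles(), cutoff=1e-9, n_draws=2000,
                          rng=np.random.default_rng(2))
        assert p == 0.0

    def test_monotone_in_cutoff(self):
        prof = self._profiles()
        ps = [null_model(prof, c, 5000, np.random.default_rng(3))[0]
              for c in (0.05, 0.1, 0.2, 0.4)]
        assert ps == sorted(ps)

    def test_monte_carlo_self_consistency(self, small_reference, small_profiles):
        """Estimates at 10k and 100k draws agree within 2 binomial SEs."""
        p1, se1 = null_model(small_profiles, 0.16, 10_000,
                             np.random.default_rng(4))
        p2, se2 = null_model(small_profiles, 0.16, 100_000,
                             np.random.default_rng(5))
        assert abs(p1 - p2) < 2 * (se1 + se2)

    def test_min_draws_enforced(self):
        with pytest.raises(ValueError):
            null_model(self._profiles(), n_draws=10)


class TestKnockoutPrediction:
    def test_identity_matches_everything(self, small_reference):
        anet, params = small_reference
        rep = knockout_prediction_experiment((anet, params), (anet, params))
        assert (rep["n_matched"] == rep["n_reference_attractors"]).all()
        assert (rep["n_reference_attractors"] == rep["n_inferred_attractors"]).all()

    def test_greedy_pairing_is_bijective(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 10, (4, 3))
        inf = rng.uniform(0, 10, (6, 3))
        matched, pairs = _pair_attractors(ref, inf, np.full(3, 10.0),
                                          cutoff=10.0)
        assert len(pairs) == 4  # bijection on the smaller set
        assert len({i for i, _, _ in pairs}) == 4
        assert len({j for _, j, _ in pairs}) == 4
        assert matched == 4

    def test_optimal_pairing_minimizes_total_distance(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 10, (5, 3))
        inf = rng.uniform(0, 10, (5, 3))
        maxima = np.full(3, 10.0)
        g, gp = _pair_attractors(ref, inf, maxima, cutoff=np.inf, method="greedy")
        o, op = _pair_attractors(ref, inf, maxima, cutoff=np.inf, method="optimal")
        assert g == o == 5  # with no cutoff every attractor pairs
        assert sum(d for *_, d in op) <= sum(d for *_, d in gp) + 1e-12

    def test_mismatched_gene_sets_rejected(self, small_reference):
        anet, params = small_reference
        other = NetworkArchitecture(np.zeros((3, 3), dtype=np.int8),
                                    gene_names=["X", "Y", "Z"])
        with pytest.raises(ValueError):
            knockout_prediction_experiment((anet, params), (other, params))


class TestArchitectureScoring:
    def test_perfect_prediction(self):
        ref = NetworkArchitecture([[1, -1], [0, 1]])
        rep = evaluate_architecture(ref.am.astype(float), ref)
        assert rep["f1"] == 1.0 and rep["hamming"] == 0 and rep["auroc"] == 1.0

    def test_all_zero_prediction_has_zero_recall(self):
        ref = NetworkArchitecture([[1, -1], [0, 1]])
        rep = evaluate_architecture(np.zeros((2, 2)), ref)
        assert rep["recall"] == 0.0
        assert rep["fn"] == 3

    def test_hand_enumerated_confusion_counts(self):
        """3-gene example with one flipped sign and one missed edge, checked
        against exhaustive manual enumeration of all 9 entries."""
        ref = NetworkArchitecture([[1, 0, -1], [0, 1, 0], [0, 0, 0]])
        pred = np.array([[1.0, 0.0, 1.0],   # (0,2) sign flipped
                         [0.0, 0.0, 0.0],   # (1,1) missed
                         [0.0, 0.0, 0.0]])
        rep = evaluate_architecture(pred, ref, threshold=0.5)
        # entry-by-entry: (0,0) TP; (0,2) predicted + but ref − -> FP and FN;
        # (1,1) missed -> FN; remaining six zeros -> TN except none predicted
        assert (rep["tp"], rep["fp"], rep["fn"], rep["tn"]) == (1, 1, 2, 6)
        assert rep["hamming"] == 2
        assert rep["precision"] == 0.5 and rep["recall"] == pytest.approx(1 / 3)

    def test_sign_blind_mode_counts_flipped_sign_as_hit(self):
        ref = NetworkArchitecture([[0, -1], [0, 0]])
        pred = np.array([[0.0, 1.0], [0.0, 0.0]])
        aware = evaluate_architecture(pred, ref)
        blind = evaluate_architecture(pred, ref, sign_aware=False)
        assert aware["tp"] == 0 and blind["tp"] == 1

    def test_diagonal_exclusion(self):
        ref = NetworkArchitecture([[1, 0], [0, 1]])
        pred = np.eye(2)
        rep = evaluate_architecture(pred, ref, include_diagonal=False)
        assert rep["n_edges_reference"] == 0
        assert np.isnan(rep["auroc"])

    def test_symmetrize_folds_by_max_score(self):
        ref = NetworkArchitecture([[0, 1], [0, 0]])
        pred = np.array([[0.0, 0.2], [0.9, 0.0]])
        rep = evaluate_architecture(pred, ref, symmetrize=True,
                                    include_diagonal=False)
        assert rep["tp"] == 1 and rep["fp"] == 0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        ref_am = rng.choice([-1, 0, 1], size=(4, 4))
        pred = rng.uniform(-1, 1, (4, 4))
        perm = rng.permutation(4)
        a = evaluate_architecture(pred, ref_am)
        b = evaluate_architecture(pred[np.ix_(perm, perm)],
                                  ref_am[np.ix_(perm, perm)])
        for key in ("f1", "auroc", "auprc", "hamming"):
            if np.isnan(a[key]):
                assert np.isnan(b[key])
            else:
                assert a[key] == pytest.approx(b[key])


class TestHammingAttractorScan:
    def test_mutants_at_exact_distance_and_zero_baseline(self, small_reference,
                                                         small_profiles):
        from grnattract.benchmark import _mutate_exact_hamming
        anet, params = small_reference
        rng = np.random.default_rng(0)
        for d in (1, 3, 5):
            for _ in range(20):
                m = _mutate_exact_hamming(anet, d, rng)
                assert anet.hamming_distance(m) == d

    def test_coupling_positive_on_small_reference(self, small_reference,
                                                  small_profiles):
        """Median attractor distance grows with architecture Hamming
        distance (Spearman over the long-form table)."""
        anet, params = small_reference
        table = hamming_attractor_scan((anet, params), small_profiles,
                                       distances=range(1, 6),
                                       mutants_per_distance=30,
                                       rng=np.random.default_rng(1))
        med = table.groupby("hamming")["attractor_distance"].median()
        rho, p = spearmanr(med.index, med.values)
        assert rho > 0


class TestDropoutPrediction:
    def test_holdout_knockout_recovered(self, small_reference, small_profiles):
        """Hold out a knockout genotype generated by the reference network;
        the consensus inferred from the remaining profiles predicts its
        profile within the matching cutoff."""
        anet, params = small_reference
        from grnattract.dynamics import find_attractors_global
        from grnattract.profiles import PerturbationSpec
        ko_gene = anet.gene_names[0]
        ko_att, _ = find_attractors_global(
            anet, params, levels=3,
            clamps=PerturbationSpec(knockouts=(ko_gene,)),
            maxima=small_profiles.maxima)
        vals = np.column_stack([small_profiles.values, ko_att[0]])
        names = list(small_profiles.condition_names) + ["ko"]
        profiles = ExpressionProfileSet(
            vals, small_profiles.gene_names, names,
            {"ko": PerturbationSpec(knockouts=(ko_gene,))})
        cfg = EvolutionConfig(population_size=30, generations=120, n_runs=3)
        rep = dropout_prediction(profiles, ["ko"], params, cfg, seed=12)
        assert rep.loc[0, "status"] == "ok"
        assert rep.loc[0, "matched"]
        assert rep.loc[0, "distance"] < 0.16

    def test_too_few_retained_rejected(self, small_profiles, small_reference):
        _, params = small_reference
        held = list(range(small_profiles.n_conditions - 1))
        with pytest.raises(ValueError, match="at least 2"):
            dropout_prediction(small_profiles, held, params,
                               EvolutionConfig(population_size=4,
                                               generations=1))
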