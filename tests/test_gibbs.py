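"""Annealed Gibbs clustering: scoring, criterion, scan, margins."""

from itertools import product

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from igomeprof._alphabet import AA, N_AA, encode_peptides
from igomeprof.gibbs import (
    ClusteringState,
    GibbsParams,
    PWM,
    corrected_score,
    gibbs_cluster,
    kld_criterion,
    scan_cluster_number,
    score_peptide,
)
from igomeprof.synthetic import SelectionConfig, simulate_selection


def brute_force_best(peptides, G, q, beta):
    """Independent exhaustive oracle: best KLD over all G**n labelings.

    Written from the criterion's definition (size-weighted smoothed-PWM
    information content), separately from the package implementation.
    """
    arr = encode_peptides(peptides)
    n, L = arr.shape
    best = -np.inf
    for labels in product(range(G), repeat=n):
        labels = np.asarray(labels)
        total = 0.0
        for g in range(G):
            members = arr[labels == g]
            if not len(members):
                continue
            counts = np.zeros((L, N_AA))
            for row in members:
                counts[np.arange(L), row] += 1
            f = (counts + beta * q) / (len(members) + beta)
            total += len(members) / n * (f * np.log2(f / q)).sum()
        best = max(best, total)
    return best


class TestScoring:
    def test_uniform_pwm_scores_zero(self, uniform_q):
        pwm = PWM(counts=np.full((7, N_AA), 5.0), n=100, q=uniform_q)
        assert score_peptide(pwm, "ACDEFGH") == pytest.approx(0.0, abs=1e-12)

    def test_matching_one_hot_pwm_is_argmax(self, uniform_q):
        counts = np.zeros((7, N_AA))
        counts[:, AA.index("W")] = 10
        pwm = PWM(counts=counts, n=10, q=uniform_q, beta=1.0)
        per_column_max = pwm.log_odds.max(axis=1).sum()
        assert score_peptide(pwm, "WWWWWWW") == pytest.approx(per_column_max)
        assert score_peptide(pwm, "WWWWWWA") < per_column_max

    def test_additivity_in_single_substitution(self, uniform_q):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 10, (7, N_AA)).astype(float)
        pwm = PWM(counts=counts, n=int(counts[0].sum()), q=uniform_q)
        lo = pwm.log_odds
        s1 = score_peptide(pwm, "AAAAAAA")
        s2 = score_peptide(pwm, "CAAAAAA")
        assert s2 - s1 == pytest.approx(lo[0, AA.index("C")] - lo[0, AA.index("A")])

    def test_length_mismatch_errors(self, uniform_q):
        pwm = PWM(counts=np.zeros((7, N_AA)), n=0, q=uniform_q)
        with pytest.raises(ValueError):
            score_peptide(pwm, "AAA")


class TestGibbsCluster:
    def test_g1_trivial(self, uniform_q):
        st = gibbs_cluster(["AAAAAAA", "CCCCCCC"], 1, seed=0)
        assert st.assignment.tolist() == [0, 0]
        pwm = st.pwm(0)
        assert np.allclose(pwm.freqs.sum(axis=1), 1.0)

    def test_two_disjoint_motifs_perfectly_recovered(self):
        # beta scaled down for the tiny instance: with clusters of 10, heavy
        # smoothing would favor merging the two one-hot motifs
        peps = ["AAAAAAA"] * 10 + ["WWWWWWW"] * 10
        st = gibbs_cluster(peps, 2, GibbsParams(iters=20, restarts=2, beta=2.0), seed=3)
        assert adjusted_rand_score([0] * 10 + [1] * 10, st.assignment) == 1.0

    def test_seed_reproducibility(self):
        cfg = SelectionConfig(K=2, peptides_per_cluster=10, error_rate=0.0)
        _, truth = simulate_selection(cfg, seed=4)
        a = gibbs_cluster(truth.peptides, 2, GibbsParams(iters=15), seed=9)
        b = gibbs_cluster(truth.peptides, 2, GibbsParams(iters=15), seed=9)
        assert np.array_equal(a.assignment, b.assignment)
        assert a.system_kld == b.system_kld

    def test_matches_exhaustive_on_tiny_instance(self, uniform_q):
        cfg = SelectionConfig(K=2, peptides_per_cluster=6, error_rate=0.0)
        _, truth = simulate_selection(cfg, seed=21)
        peps = truth.peptides[:12]
        st = gibbs_cluster(peps, 2, GibbsParams(iters=40, restarts=3), seed=21)
        oracle = brute_force_best(peps, 2, uniform_q, st.beta)
        assert st.system_kld >= oracle * (1 - 1e-9) - 1e-12
        # and never exceeds it (same objective)
        assert st.system_kld <= oracle + 1e-9

    def test_invalid_g_errors(self):
        with pytest.raises(ValueError):
            gibbs_cluster(["AAAAAAA"], 0)


class TestCriterion:
    def test_recomputable_and_label_invariant(self, two_motif_state):
        st = two_motif_state
        assert kld_criterion(st) == pytest.approx(st.system_kld)
        permuted = ClusteringState(
            peptides=st.peptides,
            assignment=1 - st.assignment,
            G=2,
            q=st.q,
            beta=st.beta,
            seed=0,
        )
        assert permuted.system_kld == pytest.approx(st.system_kld)

    def test_identical_peptides_closed_form(self, uniform_q):
        """G=1 with n identical peptides: per closed form, each of the 7
        columns contributes f*log2(f/q) summed over the smoothed column."""
        n, beta = 12, 10.0
        st = gibbs_cluster(["AAAAAAA"] * n, 1, GibbsParams(beta=beta), seed=0)
        q = 1 / 20
        f_hit = (n + beta * q) / (n + beta)
        f_miss = (beta * q) / (n + beta)
        col = f_hit * np.log2(f_hit / q) + 19 * f_miss * np.log2(f_miss / q)
        assert st.system_kld == pytest.approx(7 * col)

    def test_background_peptides_score_low_and_decrease_with_n(self, nnk_bg):
        from igomeprof._alphabet import decode_peptides
        from igomeprof.library_design import sample_background_peptides

        rng = np.random.default_rng(5)
        crits = []
        for n in (40, 200):
            peps = decode_peptides(sample_background_peptides(nnk_bg, n, 7, rng))
            st = gibbs_cluster(
                peps, 2, GibbsParams(iters=25, restarts=2), seed=1, q=nnk_bg.q
            )
            crits.append(st.system_kld)
        # overfitting floor: positive, well below a real motif's information
        # content, and shrinking as the sample grows
        assert 0 <= crits[1] < crits[0] < 4.0


class TestScan:
    def test_single_g_grid(self):
        st = scan_cluster_number(["AAAAAAA"] * 5, [1], seed=0)
        assert st["best_G"] == 1

    def test_curve_matches_returned_states(self):
        cfg = SelectionConfig(K=2, peptides_per_cluster=15, error_rate=0.0)
        _, truth = simulate_selection(cfg, seed=6)
        scan = scan_cluster_number(
            truth.peptides, [2, 3], GibbsParams(iters=15, restarts=1), seed=2
        )
        for G, state in scan["states"].items():
            assert scan["curve"][G] == pytest.approx(kld_criterion(state))

    def test_bad_grid_errors(self):
        with pytest.raises(ValueError):
            scan_cluster_number(["AAAAAAA"], [3, 2])

    def test_planted_k3_recovered(self):
        cfg = SelectionConfig(
            K=3,
            peptides_per_cluster=40,
            background_fraction=0.0,
            error_rate=0.0,
            motif_weight=0.9,
            informative_positions=(3, 4),
        )
        _, truth = simulate_selection(cfg, seed=600)
        scan = scan_cluster_number(
            truth.peptides, [2, 3, 4, 5], GibbsParams(iters=40, restarts=3), seed=600
        )
        assert scan["best_G"] == 3


class TestCorrectedScore:
    def test_g1_returns_own_score(self):
        st = gibbs_cluster(["AAAAAAA"] * 4, 1, seed=0)
        assert corrected_score(st, "AAAAAAA") == pytest.approx(
            st.per_peptide_score[0]
        )

    def test_symmetric_clusters_give_zero_margin(self, uniform_q):
        # a peptide equidistant between two identical-composition clusters
        peps = ["AAAAAAA", "CCCCCCC", "AAAAAAA", "CCCCCCC", "ACACACA"]
        st = ClusteringState(
            peptides=peps,
            assignment=np.array([0, 0, 1, 1, 0]),
            G=2,
            q=uniform_q,
            beta=10.0,
            seed=0,
        )
        # own cluster contains it, rival does not: margin reflects only the
        # leave-one-out asymmetry; with the peptide removed both PWMs match
        assert corrected_score(st, "ACACACA") == pytest.approx(0.0, abs=1e-9)

    def test_planted_members_have_positive_margin(self, two_motif_state):
        margins = [corrected_score(two_motif_state, p) for p in two_motif_state.peptides]
        assert all(m > 0 for m in margins)

    def test_unknown_peptide_errors(self, two_motif_state):
        with pytest.raises(KeyError):
            corrected_score(two_motif_state, "YYYYYYY")


def test_state_json_roundtrip(tmp_path, two_motif_state):
    path = tmp_path / "state.json"
    two_motif_state.to_json(path)
    loaded = ClusteringState.from_json(path)
    assert loaded.peptides == two_motif_state.peptides
    assert np.array_equal(loaded.assignment, two_motif_state.assignment)
    assert loaded.system_kld == pytest.approx(two_motif_state.system_kld)
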