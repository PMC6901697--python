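"""Cluster significance ranking and probe-library construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from igomeprof._alphabet import decode_peptides
from igomeprof.composition import estimate_background
from igomeprof.gibbs import GibbsParams, gibbs_cluster, score_peptides
from igomeprof.library_design import (
    cluster_significance,
    design_c5,
    design_c5p,
    design_ng,
    design_ngr,
    design_rnd,
    design_sym,
    sample_background_peptides,
)
from igomeprof.synthetic import SelectionConfig, simulate_selection


@pytest.fixture(scope="module")
def clustered(nnk_bg_module=None):
    cfg = SelectionConfig(
        K=3,
        peptides_per_cluster=25,
        background_fraction=0.0,
        error_rate=0.0,
        motif_weight=0.9,
        informative_positions=(3, 4),
    )
    _, truth = simulate_selection(cfg, seed=31)
    state = gibbs_cluster(
        truth.peptides, 3, GibbsParams(iters=30, restarts=2), seed=31
    )
    bg = estimate_background("nnk")
    signif = cluster_significance(state, bg, M=10_000, seed=31)
    return state, bg, signif


@pytest.fixture(scope="module")
def loose_state():
    # profile sampling needs clusters loose enough for rejection sampling of
    # background peptides to be feasible
    cfg = SelectionConfig(
        K=2,
        peptides_per_cluster=25,
        background_fraction=0.0,
        error_rate=0.0,
        motif_weight=0.5,
        informative_positions=(2, 2),
    )
    _, truth = simulate_selection(cfg, seed=41)
    state = gibbs_cluster(
        truth.peptides, 2, GibbsParams(iters=25, restarts=2), seed=41
    )
    return state, estimate_background("nnk")


class TestSignificance:
    def test_planted_clusters_significant_and_ranked(self, clustered):
        state, bg, signif = clustered
        assert sum(r.significant for r in signif) >= 2
        ps = [r.p for r in signif]
        assert ps == sorted(ps)
        assert sorted(r.rank for r in signif) == list(range(1, len(signif) + 1))

    def test_forced_p0_one_is_not_significant(self):
        # a cluster whose threshold every background peptide exceeds
        p = float(stats.binom.sf(10 - 1, 1000, 1.0))
        assert p == 1.0

    def test_binomial_tail_example(self):
        # 10 successes in 1000 trials at p0=0.001 is a very unlikely excess
        assert stats.binom.sf(10 - 1, 1000, 0.001) < 1e-6

    def test_m_too_small_errors(self, clustered):
        state, bg, _ = clustered
        with pytest.raises(ValueError):
            cluster_significance(state, bg, M=100)


class TestSym:
    def test_representative_is_cluster_argmax(self, clustered):
        state, bg, signif = clustered
        n_sig = sum(r.significant for r in signif)
        sym = design_sym(state, signif, k_top=n_sig)
        for pep in sym.peptides:
            row = sym.provenance.loc[pep]
            g = int(row["cluster"])
            members = state.encoded[state.assignment == g]
            assert row["score"] == pytest.approx(
                float(score_peptides(state.pwm(g), members).max())
            )

    def test_k_top_one(self, clustered):
        state, _, signif = clustered
        sym = design_sym(state, signif, k_top=1)
        assert len(sym) == 1

    def test_k_top_too_large_errors(self, clustered):
        state, _, signif = clustered
        with pytest.raises(ValueError):
            design_sym(state, signif, k_top=len(signif) + 1)

    def test_controls_added(self, clustered):
        state, bg, signif = clustered
        controls = design_rnd(bg, n=5, seed=1, name="NGR")
        n_sig = sum(r.significant for r in signif)
        sym = design_sym(state, signif, k_top=n_sig, controls=controls)
        assert len(sym) == n_sig + 5
        roles = sym.provenance.loc[sym.peptides, "role"]
        assert (roles == "control:NGR").sum() == 5


class TestNgr:
    def test_anti_selection_orders_by_max_score(self, clustered):
        state, bg, signif = clustered
        ngr = design_ngr(state, bg, n_candidates=20_000, m=50, seed=7)
        n_sig = sum(r.significant for r in signif)
        sym = design_sym(state, signif, k_top=n_sig)
        assert (
            ngr.provenance["score"].mean() < sym.provenance["score"].mean()
        )

    def test_m_exceeding_candidates_errors(self, clustered):
        state, bg, _ = clustered
        with pytest.raises(ValueError):
            design_ngr(state, bg, n_candidates=100, m=101, seed=3)

    def test_w_pwm_prefers_alanine_peptide(self, uniform_q):
        # a single tryptophan-favoring cluster: the all-A peptide must rank
        # far below the all-W peptide on max score
        state = gibbs_cluster(["WWWWWWW"] * 6, 1, seed=0, q=uniform_q)
        a, w = score_peptides(state.pwm(0), np.array([[0] * 7])), score_peptides(
            state.pwm(0), np.array([[18] * 7])
        )
        assert a[0] < w[0]


class TestNg:
    def test_ng2_subset_and_counts(self, clustered):
        state, _, signif = clustered
        ng1, ng2 = design_ng(state, signif, corrected_threshold=5.0)
        assert set(ng2.peptides) <= set(ng1.peptides)
        assert len(ng1) == sum(r.significant for r in signif)

    def test_ng1_member_is_cluster_minimum(self, clustered):
        state, _, signif = clustered
        ng1, _ = design_ng(state, signif)
        for pep in ng1.peptides:
            g = int(ng1.provenance.loc[pep, "cluster"])
            members = state.encoded[state.assignment == g]
            assert ng1.provenance.loc[pep, "score"] == pytest.approx(
                float(score_peptides(state.pwm(g), members).min())
            )


class TestC5:
    def test_whole_cluster_selection(self, clustered):
        state, _, _ = clustered
        lib = design_c5(state, [0, 1])
        expected = {state.peptides[i] for i in np.flatnonzero(np.isin(state.assignment, [0, 1]))}
        assert set(lib.peptides) == expected

    def test_c5p_all_above_median(self, loose_state):
        state, bg = loose_state
        lib = design_c5p(state, [0], bg, per_cluster=20, seed=5)
        assert len(lib) == 20
        members = state.encoded[state.assignment == 0]
        t = float(np.median(score_peptides(state.pwm(0), members)))
        assert (lib.provenance["score"] > t).all()

    def test_c5p_acceptance_rate_consistent_with_p0(self, loose_state):
        state, bg = loose_state
        rng = np.random.default_rng(8)
        members = state.encoded[state.assignment == 0]
        t = float(np.median(score_peptides(state.pwm(0), members)))
        arr = sample_background_peptides(bg, 30_000, 7, rng)
        p0 = (score_peptides(state.pwm(0), arr) > t).mean()
        # members cohere around the motif, so background rarely exceeds
        # the member median
        assert 0 < p0 < 0.2


class TestRnd:
    def test_unique_and_seed_stable(self, clustered):
        _, bg, _ = clustered
        a = design_rnd(bg, n=800, seed=2)
        b = design_rnd(bg, n=800, seed=2)
        assert len(a) == 800
        assert a.peptides == b.peptides

    def test_frequencies_match_background(self, clustered):
        _, bg, _ = clustered
        from igomeprof.composition import residue_frequencies

        lib = design_rnd(bg, n=20_000, seed=3)
        fm = residue_frequencies(lib.peptides, positional=False)
        assert np.abs(fm.f[:, 0] - bg.q).max() < 0.01


def test_library_tsv_roundtrip(tmp_path, clustered):
    state, bg, signif = clustered
    sym = design_sym(state, signif, k_top=2)
    path = tmp_path / "sym.tsv"
    sym.to_tsv(path)
    from igomeprof.library_design import LibraryDesign

    loaded = LibraryDesign.from_tsv(path)
    assert loaded.peptides == sym.peptides
    assert loaded.name == "SYM"
    assert list(loaded.provenance["cluster"]) == list(sym.provenance["cluster"])


def test_all_libraries_are_seven_mers(clustered):
    state, bg, signif = clustered
    libs = [
        design_sym(state, signif, k_top=1),
        design_ngr(state, bg, n_candidates=5000, m=10, seed=1),
        design_rnd(bg, n=10, seed=1),
    ]
    for lib in libs:
        assert all(len(p) == 7 for p in lib.peptides)
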