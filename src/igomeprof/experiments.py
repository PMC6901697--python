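"""Canonical desk-scale validation experiments.

Each function freezes one study condition — the synthetic-data configuration,
problem size and sampler settings under which the pipeline's behavior is
validated — and measures the corresponding quantity by running the package
end to end against planted ground truth or an exact oracle. The acceptance
script and the test suite both call these, so the conditions are defined in
exactly one place. All experiments are deterministic per seed.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from ._alphabet import N_AA
from .composition import BackgroundModel, estimate_background
from .diagnostics import (
    bootstrap_rfeds,
    estimate_profile_capacity,
    filter_features,
    scrambled_null,
    train_eval_classifier,
)
from .gibbs import (
    ClusteringState,
    GibbsParams,
    PWM,
    exhaustive_search,
    gibbs_cluster,
    scan_cluster_number,
    score_peptides,
)
from .library_design import (
    ClusterSignificance,
    design_ngr,
    design_rnd,
    design_sym,
    sample_background_peptides,
)
from .library_eval import mnnd, rank_product
from .peptide_space import zscale_encode
from .reactivity import balance_batches, call_reactivities, combat_adjust
from .synthetic import (
    ReactivityConfig,
    SelectionConfig,
    simulate_reactivity,
    simulate_selection,
)

__all__ = [
    "worked_examples",
    "gibbs_oracle_agreement",
    "rank_product_exact_vs_permutation",
    "p0_exact_vs_montecarlo",
    "scan_recovery",
    "batch_recovery",
    "diagnostics_recovery",
    "design_properties",
]


def _log10_int(n: int) -> float:
    """log10 of an arbitrary-precision integer without float overflow."""
    import math

    return math.log10(n) if n < 10**300 else math.log10(n // 10**100) + 100


def _child_seed(seed: int, tag: int) -> int:
    return int(
        np.random.SeedSequence((seed, tag)).generate_state(1)[0] % (2**31)
    )


# ---------------------------------------------------------------------------
# worked examples: in-study accounting recomputed from its stated inputs


#: patients enrolled per (diagnosis, batch) in the proof-of-principle cohort
PATIENT_TABLE = {
    ("C", "G"): 1, ("C", "P"): 3, ("C", "R"): 4,
    ("GBM", "G"): 2, ("GBM", "P"): 4, ("GBM", "R"): 9,
    ("ML", "G"): 2, ("ML", "P"): 4, ("ML", "R"): 3,
    ("MB", "G"): 0, ("MB", "P"): 0, ("MB", "R"): 2,
}


def worked_examples(seed: int = 0) -> dict:
    """Cohort accounting, probe-library arithmetic and analytic counts.

    Builds the enrolled-cohort metadata from the per-diagnosis/batch table,
    applies the batch-balancing rule (cap GBM batch-R at 5, drop the breast
    cancer cases) to obtain the training cohort; designs a symmetric probe
    library from a 600-cluster model, keeping the top 519 representatives
    plus 75 anti-selected controls; and evaluates the analytic quantities
    (z-scale dimensionality, 7-mer sequence space, profile capacity).
    """
    rows = []
    for (diag, batch), n in PATIENT_TABLE.items():
        for i in range(n):
            rows.append({"sample": f"{diag}_{batch}_{i}", "diagnosis": diag, "batch": batch})
    meta = pd.DataFrame(rows).set_index("sample")
    balanced = balance_batches(
        meta, caps={("GBM", "R"): 5}, exclude_groups=["MB"]
    )

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE0)))
    bg = estimate_background("nnk")
    n_clusters = 600
    members_per = 3
    arr = sample_background_peptides(bg, n_clusters * members_per, 7, rng)
    peptides = []
    seen = set()
    from ._alphabet import decode_peptides

    for p in decode_peptides(arr):
        if p not in seen:
            seen.add(p)
            peptides.append(p)
    while len(peptides) < n_clusters * members_per:
        extra = decode_peptides(sample_background_peptides(bg, 256, 7, rng))
        for p in extra:
            if p not in seen:
                seen.add(p)
                peptides.append(p)
                if len(peptides) == n_clusters * members_per:
                    break
    assignment = np.repeat(np.arange(n_clusters), members_per)
    state = ClusteringState(
        peptides=peptides[: n_clusters * members_per],
        assignment=assignment,
        G=n_clusters,
        q=bg.q,
        beta=10.0,
        seed=seed,
    )
    # ranked significance list for the 600 clusters (ranking inputs; the
    # Monte-Carlo ranking itself is validated in p0_exact_vs_montecarlo)
    signif = [
        ClusterSignificance(
            cluster=g, threshold=0.0, p0=1e-5, k=2, n_members=members_per,
            p=(g + 1) * 1e-7, rank=g + 1, significant=True,
        )
        for g in range(n_clusters)
    ]
    controls = design_rnd(bg, n=75, seed=_child_seed(seed, 1), name="NGR")
    controls.provenance["role"] = "anti-selected"
    sym = design_sym(state, signif, k_top=519, controls=controls)

    return {
        "patients_enumerated": len(meta),
        "patients_training": len(balanced),
        "sym_library_size": len(sym),
        "zscale_dim": zscale_encode(["ACDEFGH"]).shape[1],
        "kmer_space": 20**7,
        "profile_capacity_log10": _log10_int(
            estimate_profile_capacity(500, 28, 111)
        ),
    }


# ---------------------------------------------------------------------------
# oracle-equivalence experiments


def gibbs_oracle_agreement(n_runs: int = 100, seed: int = 0) -> dict:
    """Fraction of tiny instances where annealing attains the exhaustive
    optimum of the KLD criterion (10 peptides from 2 planted motifs, G=2)."""
    hits = 0
    for i in range(n_runs):
        run_seed = _child_seed(seed, 1000 + i)
        cfg = SelectionConfig(
            K=2, peptides_per_cluster=5, background_fraction=0.0, error_rate=0.0
        )
        _, truth = simulate_selection(cfg, seed=run_seed)
        peps = truth.peptides[:10]
        state = gibbs_cluster(
            peps, 2, GibbsParams(iters=40, restarts=3), seed=run_seed
        )
        opt, _ = exhaustive_search(peps, 2)
        hits += state.system_kld >= opt * (1 - 1e-9) - 1e-12
    return {"agreement": hits / n_runs, "n": n_runs}


def rank_product_exact_vs_permutation(seed: int = 0) -> dict:
    """Exact enumeration vs Monte-Carlo rank-product p on 8 libraries x 3
    criteria, for the best-possible-but-one rank tuple (1, 2, 1)."""
    L, k = 8, 3
    ranks = pd.DataFrame(
        {
            "c1": [1, 2, 3, 4, 5, 6, 7, 8],
            "c2": [2, 1, 3, 4, 5, 6, 7, 8],
            "c3": [1, 2, 3, 4, 5, 6, 7, 8],
        },
        index=[f"lib{i}" for i in range(L)],
    )
    exact = rank_product(ranks, max_exact=L**k)
    perm = rank_product(ranks, max_exact=0, n_permutations=100_000, seed=seed)
    p_exact = float(exact.loc["lib0", "p"])
    p_perm = float(perm.loc["lib0", "p"])
    se = np.sqrt(p_exact * (1 - p_exact) / 100_000)
    return {
        "rp_best": float(exact.loc["lib0", "rank_product"]),
        "p_exact": p_exact,
        "p_perm": p_perm,
        "abs_diff": abs(p_exact - p_perm),
        "three_se": 3 * se,
    }


def _two_position_pwm(q: np.ndarray, beta: float = 10.0) -> PWM:
    """A PWM flat everywhere except two information-rich positions.

    Non-informative columns carry counts exactly proportional to the uniform
    background so their log-odds vanish and the score distribution reduces to
    the two informative columns (400 outcomes, exactly enumerable).
    """
    n = 200
    counts = np.full((7, N_AA), n / N_AA)
    counts[2] = 0.0
    counts[2, :2] = n / 2  # A and C favored
    counts[4] = 0.0
    counts[4, 5] = n  # G favored
    return PWM(counts=counts, n=n, q=q, beta=beta)


def p0_exact_vs_montecarlo(M: int = 50_000, seed: int = 0) -> dict:
    """Monte-Carlo exceedance probability vs exact enumeration.

    On a PWM informative at two positions only (uniform background), the
    exact P(score > t) is a sum over the 400 residue pairs of those columns;
    the Monte-Carlo estimate samples M background 7-mers and scores them.
    """
    q = np.full(N_AA, 1.0 / N_AA)
    pwm = _two_position_pwm(q)
    lo = pwm.log_odds
    # exact: only positions 2 and 4 contribute non-zero log-odds
    probs = {}
    for a, b in product(range(N_AA), repeat=2):
        s = lo[2, a] + lo[4, b]
        probs[s] = probs.get(s, 0.0) + q[a] * q[b]
    threshold = float(np.median(list(probs)))
    p_exact = sum(p for s, p in probs.items() if s > threshold)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB0)))
    bg = BackgroundModel(q=q)
    arr = sample_background_peptides(bg, M, 7, rng)
    scores = score_peptides(pwm, arr)
    p_mc = float(np.count_nonzero(scores > threshold)) / M
    se = np.sqrt(p_exact * (1 - p_exact) / M)
    return {
        "p_exact": float(p_exact),
        "p_mc": p_mc,
        "abs_diff": abs(p_exact - p_mc),
        "three_se": 3 * se,
    }


# ---------------------------------------------------------------------------
# parameter-recovery experiments


def scan_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Cluster-number scan on planted K=3 selections (120 peptides each).

    Three separable motifs, 40 member peptides each, no background clones;
    grid {2, 3, 4, 5}. Reports how often the KLD-criterion argmax equals 3.
    """
    hits = 0
    for i in range(n_seeds):
        s = _child_seed(seed, 2000 + i)
        cfg = SelectionConfig(
            K=3,
            peptides_per_cluster=40,
            background_fraction=0.0,
            error_rate=0.0,
            motif_weight=0.9,
            informative_positions=(3, 4),
        )
        _, truth = simulate_selection(cfg, seed=s)
        scan = scan_cluster_number(
            truth.peptides, [2, 3, 4, 5], GibbsParams(iters=40, restarts=3), seed=s
        )
        hits += scan["best_G"] == 3
    return {"recovered": hits, "n_seeds": n_seeds}


def batch_recovery(seed: int = 0) -> dict:
    """ComBat adjustment of a planted two-batch shift with an orthogonal
    diagnosis effect.

    Batch P is offset by +2 log2 units; the GBM group carries a fully
    penetrant 1.5-unit effect on 10 of 120 peptides. Reports the batch-mean
    gap before/after adjustment and the retained fraction of the planted
    effect size.
    """
    cfg = ReactivityConfig(
        panel=120,
        groups={"GBM": 8, "C": 8},
        n_discriminative=10,
        effect_size=1.5,
        effect_coverage=1.0,
        sigma=0.5,
        batch_offsets={"G": 0.0, "P": 2.0},
    )
    mat, truth = simulate_reactivity(cfg, seed=_child_seed(seed, 3000))
    batches = mat.sample_meta["batch"]

    def batch_gap(values):
        means = values.mean(axis=0).groupby(batches).mean()
        return float(abs(means["G"] - means["P"]))

    adj = combat_adjust(mat, preserve_col="diagnosis")
    gbm = mat.sample_meta.index[mat.sample_meta["diagnosis"] == "GBM"]
    rest = mat.sample_meta.index[mat.sample_meta["diagnosis"] != "GBM"]
    effect = (
        adj.values.loc[truth.discriminative, gbm].mean(axis=1)
        - adj.values.loc[truth.discriminative, rest].mean(axis=1)
    ).mean()
    return {
        "gap_before": batch_gap(mat.values),
        "gap_after": batch_gap(adj.values),
        "planted_effect": truth.effect_size,
        "recovered_effect": float(effect),
        "effect_retention": float(effect / truth.effect_size),
    }


#: frozen study conditions of the diagnostics-recovery cohort (28 training
#: + 10 held-out samples, mosaic GBM signature, near-permissive filter)
GBM_COHORT = dict(
    panel=40,
    groups={"GBM": 15, "C": 17},
    n_discriminative=10,
    effect_size=2.2,
    sigma=0.5,
    effect_coverage=0.75,
    spikes_per_feature=1,
    spike_size=6.5,
    batch_offsets={"G": 0.0},
)

GBM_TEST_SAMPLES = [f"GBM_{i:02d}" for i in range(10, 15)] + [
    f"C_{i:02d}" for i in range(12, 17)
]


def diagnostics_recovery_one(seed: int, null_B: int = 100) -> dict:
    """Full filter -> bootstrap -> consensus -> classify pipeline, one cohort.

    The classifier works on two surrogate features obtained by classical MDS
    of the consensus-feature profiles (the construction that keeps a model
    testable with few held-out cases and controls overfitting); the scrambled
    null refits the identical construction per label permutation.
    """
    cfg = ReactivityConfig(**GBM_COHORT)
    mat, truth = simulate_reactivity(cfg, seed=seed)
    labels = mat.sample_meta["diagnosis"] == "GBM"
    test = GBM_TEST_SAMPLES
    train = [c for c in mat.values.columns if c not in test]
    features0 = filter_features(call_reactivities(mat.values))
    report = bootstrap_rfeds(mat.values[train], labels.loc[train], features0=features0)
    n_half = int(np.ceil(len(report.folds) / 2))
    consensus = report.consensus(n_half)
    clf = train_eval_classifier(
        mat.values, consensus, labels, scheme="holdout", test_samples=test,
        mds_dims=2,
    )
    lo, hi, _ = scrambled_null(
        mat.values, consensus, labels, scheme="holdout", test_samples=test,
        B=null_B, seed=seed, mds_dims=2,
    )
    return {
        "n_filtered": len(features0),
        "n_consensus": len(consensus),
        "recovered": len(set(consensus) & set(truth.discriminative)),
        "n_planted": len(truth.discriminative),
        "mcc": clf.mcc,
        "null_05": lo,
        "null_95": hi,
    }


def diagnostics_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Recovery of a planted mosaic signature across seeded cohorts.

    Counts seeds where the consensus set recovers >= 8/10 planted features
    and the holdout MCC exceeds the 95th percentile of the scrambled null.
    """
    ok_consensus = ok_mcc = ok_both = 0
    mccs = []
    for i in range(n_seeds):
        r = diagnostics_recovery_one(_child_seed(seed, 4000 + i))
        c = r["recovered"] >= 8
        m = r["mcc"] > r["null_95"]
        ok_consensus += c
        ok_mcc += m
        ok_both += c and m
        mccs.append(r["mcc"])
    return {
        "consensus_ok": ok_consensus,
        "mcc_ok": ok_mcc,
        "both_ok": ok_both,
        "n_seeds": n_seeds,
        "median_mcc": float(np.median(mccs)),
    }


# ---------------------------------------------------------------------------
# design-property experiments


def _clustered_state(seed: int) -> ClusteringState:
    cfg = SelectionConfig(
        K=4,
        peptides_per_cluster=30,
        background_fraction=0.0,
        error_rate=0.0,
        motif_weight=0.9,
        informative_positions=(3, 4),
    )
    _, truth = simulate_selection(cfg, seed=seed)
    return gibbs_cluster(
        truth.peptides, 4, GibbsParams(iters=40, restarts=2), seed=seed
    )


def design_properties(seed: int = 0) -> dict:
    """Anti-selection and redundancy properties of designed libraries.

    (1) On a clustered synthetic selection, the mean max-PWM score of the
    anti-selected NGR library must fall below the mean score of the SYM
    cluster representatives. (2) On a synthetic reactivity matrix, a library
    of duplicated (correlated-pair) profiles must have a lower MNND than an
    equally sized library of independent profiles.
    """
    from .library_design import cluster_significance

    state = _clustered_state(_child_seed(seed, 5000))
    bg = estimate_background("nnk")
    signif = cluster_significance(state, bg, M=10_000, seed=_child_seed(seed, 5001))
    n_sig = sum(r.significant for r in signif)
    sym = design_sym(state, signif, k_top=n_sig)
    ngr = design_ngr(
        state, bg, n_candidates=100_000, m=100, seed=_child_seed(seed, 5002)
    )
    rep_scores = sym.provenance.loc[sym.peptides, "score"]
    ngr_scores = ngr.provenance.loc[ngr.peptides, "score"]  # max over clusters

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD0)))
    n_samples, half = 12, 30
    base = rng.normal(0.0, 1.0, (half, n_samples))
    redundant = np.vstack([base, base + rng.normal(0.0, 0.15, base.shape)])
    independent = rng.normal(0.0, 1.0, (2 * half, n_samples))
    idx_r = [f"r{i}" for i in range(2 * half)]
    idx_i = [f"i{i}" for i in range(2 * half)]
    values = pd.DataFrame(
        np.vstack([redundant, independent]),
        index=idx_r + idx_i,
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return {
        "n_significant_clusters": n_sig,
        "sym_mean_score": float(rep_scores.mean()),
        "ngr_mean_max_score": float(ngr_scores.mean()),
        "mnnd_redundant": mnnd(values, idx_r, standardize=False),
        "mnnd_independent": mnnd(values, idx_i, standardize=False),
    }
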