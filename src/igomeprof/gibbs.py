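"""Annealed Gibbs clustering of fixed-length peptides.

Ungapped motif clustering in the GibbsCluster spirit: peptides of one fixed
length are partitioned into G clusters, each summarized by a position weight
matrix (PWM); a single-peptide reassignment sampler under a geometric
temperature schedule moves each peptide with probability proportional to its
log2-odds under each cluster's leave-one-out PWM. Clusterings are compared by
the size-weighted information content of the cluster PWMs, a
Kullback-Leibler-divergence (KLD) criterion::

    KLD = sum_g (N_g / N) * sum_pos sum_aa f'_g[pos, aa] * log2(f'_g[pos, aa] / q[aa])

with pseudocount-smoothed frequencies f'. Because smoothing pulls small
clusters toward the background, fragmenting a coherent motif lowers the
criterion, which is what lets a scan over cluster numbers peak at the true
number instead of growing monotonically (the mean per-peptide own-cluster
score does grow monotonically under optimization and is reported separately).

Because all peptides share one length and are anchored, no insertions,
deletions or offsets are considered; this is a deliberate restriction of the
general Gibbs aligner to the display-library setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import json
import numpy as np

from ._alphabet import AA, N_AA, encode_peptides

__all__ = [
    "PWM",
    "ClusteringState",
    "GibbsParams",
    "score_peptide",
    "score_peptides",
    "gibbs_cluster",
    "kld_criterion",
    "scan_cluster_number",
    "corrected_score",
    "exhaustive_search",
]

#: background pseudocounts used to smooth cluster PWMs; comparable to the
#: tens-of-members clusters this package targets, so that splinter clusters
#: are pulled toward the background and penalized by the KLD criterion
DEFAULT_BETA = 10.0


@dataclass
class PWM:
    """Positional count matrix of one cluster plus smoothed/log-odds views.

    ``counts`` has shape (L, 20) in alphabetical residue order; ``n`` is the
    member count. Smoothing mixes ``beta`` background pseudocounts into each
    column: ``f' = (counts + beta*q) / (n + beta)``.
    """

    counts: np.ndarray
    n: int
    q: np.ndarray
    beta: float = DEFAULT_BETA

    @property
    def freqs(self) -> np.ndarray:
        return (self.counts + self.beta * self.q) / (self.n + self.beta)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.freqs / self.q)

    @classmethod
    def from_members(cls, members: np.ndarray, q: np.ndarray, beta: float = DEFAULT_BETA) -> "PWM":
        L = members.shape[1] if members.size else 7
        counts = np.zeros((L, N_AA))
        for pos in range(L):
            if members.shape[0]:
                counts[pos] = np.bincount(members[:, pos], minlength=N_AA)
        return cls(counts=counts, n=members.shape[0], q=q, beta=beta)


def score_peptide(pwm: PWM, peptide: str | np.ndarray) -> float:
    """Sum of the PWM's per-position log2-odds along a peptide."""
    x = encode_peptides([peptide])[0] if isinstance(peptide, str) else np.asarray(peptide)
    if x.shape[0] != pwm.counts.shape[0]:
        raise ValueError(
            f"peptide length {x.shape[0]} does not match PWM length {pwm.counts.shape[0]}"
        )
    lo = pwm.log_odds
    return float(lo[np.arange(x.shape[0]), x].sum())


def score_peptides(pwm: PWM, arr: np.ndarray) -> np.ndarray:
    """Vectorized :func:`score_peptide` over an (n, L) encoded array."""
    lo = pwm.log_odds
    return lo[np.arange(arr.shape[1]), arr].sum(axis=1)


@dataclass
class GibbsParams:
    """Annealing schedule of the sampler.

    ``T0``/``Tfinal`` bound the geometric temperature ladder, one step per
    sweep; ``iters`` is the number of full reassignment sweeps per restart.
    """

    iters: int = 50
    T0: float = 1.5
    Tfinal: float = 0.01
    restarts: int = 3
    beta: float = DEFAULT_BETA


@dataclass
class ClusteringState:
    """Result of one clustering run: assignment, PWMs and the KLD criterion."""

    peptides: list[str]
    assignment: np.ndarray
    G: int
    q: np.ndarray
    beta: float
    seed: int
    system_kld: float = 0.0
    per_peptide_score: np.ndarray = field(default=None)  # type: ignore[assignment]
    params: GibbsParams | None = None

    def __post_init__(self):
        self._arr = encode_peptides(self.peptides)
        if self.per_peptide_score is None:
            self.per_peptide_score = _loo_scores(
                self._arr, self.assignment, self.G, self.q, self.beta
            )
        self.system_kld = _pwm_kld(
            self._arr, self.assignment, self.G, self.q, self.beta
        )

    @property
    def encoded(self) -> np.ndarray:
        return self._arr

    def pwm(self, g: int) -> PWM:
        return PWM.from_members(self._arr[self.assignment == g], self.q, self.beta)

    @property
    def pwms(self) -> list[PWM]:
        return [self.pwm(g) for g in range(self.G)]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.G)

    def to_json(self, path) -> None:
        payload = {
            "peptides": self.peptides,
            "assignment": self.assignment.tolist(),
            "G": self.G,
            "q": self.q.tolist(),
            "beta": self.beta,
            "seed": self.seed,
            "system_kld": self.system_kld,
            "counts": [p.counts.tolist() for p in self.pwms],
            "log_odds": [p.log_odds.tolist() for p in self.pwms],
            "alphabet": AA,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ClusteringState":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            peptides=d["peptides"],
            assignment=np.asarray(d["assignment"], dtype=int),
            G=d["G"],
            q=np.asarray(d["q"]),
            beta=d["beta"],
            seed=d["seed"],
        )


def _counts_from_assignment(arr, assignment, G):
    L = arr.shape[1]
    counts = np.zeros((G, L, N_AA))
    sizes = np.zeros(G)
    for g in range(G):
        members = arr[assignment == g]
        sizes[g] = members.shape[0]
        for pos in range(L):
            if members.shape[0]:
                counts[g, pos] = np.bincount(members[:, pos], minlength=N_AA)
    return counts, sizes


def _loo_scores(arr, assignment, G, q, beta):
    """Per-peptide log2-odds under its own cluster with itself removed."""
    counts, sizes = _counts_from_assignment(arr, assignment, G)
    n = arr.shape[0]
    L = arr.shape[1]
    pos_idx = np.arange(L)
    scores = np.empty(n)
    for i in range(n):
        g = assignment[i]
        c = counts[g, pos_idx, arr[i]] - 1.0
        qx = q[arr[i]]
        f = (c + beta * qx) / (sizes[g] - 1.0 + beta)
        scores[i] = np.log2(f / qx).sum()
    return scores


def _pwm_kld(arr, assignment, G, q, beta):
    """Size-weighted information content (bits) of the cluster PWMs vs q."""
    counts, sizes = _counts_from_assignment(arr, assignment, G)
    N = arr.shape[0]
    total = 0.0
    for g in range(G):
        if sizes[g] == 0:
            continue
        f = (counts[g] + beta * q) / (sizes[g] + beta)
        total += sizes[g] / N * float((f * np.log2(f / q)).sum())
    return total


def kld_criterion(state: ClusteringState) -> float:
    """The KLD clustering criterion, recomputed from the assignment alone.

    Size-weighted sum over clusters of the smoothed PWM's information content
    against the background. Background-like clusters contribute near zero;
    coherent motifs contribute their per-position information. Invariant to
    cluster relabeling.
    """
    return _pwm_kld(state.encoded, state.assignment, state.G, state.q, state.beta)


def _cluster_info(counts, sizes, q, beta):
    """Smoothed PWM information content (bits) per cluster.

    ``counts`` is (..., L, 20), ``sizes`` broadcastable to the leading axes.
    """
    f = (counts + beta * q) / (sizes[..., None, None] + beta)
    return (f * np.log2(f / q)).sum(axis=(-2, -1))


def _anneal_once(arr, G, q, beta, params, rng):
    n, L = arr.shape
    assignment = rng.integers(0, G, size=n)
    counts, sizes = _counts_from_assignment(arr, assignment, G)
    pos_idx = np.arange(L)
    temps = np.geomspace(params.T0, params.Tfinal, params.iters)
    # per-cluster weighted contribution to the criterion, kept incrementally
    contrib = sizes / n * _cluster_info(counts, sizes, q, beta)
    best = (-np.inf, assignment.copy())
    ln2 = np.log(2.0)
    for T in temps:
        order = rng.permutation(n)
        for i in order:
            x = arr[i]
            g_old = assignment[i]
            counts[g_old, pos_idx, x] -= 1.0
            sizes[g_old] -= 1.0
            contrib[g_old] = (
                sizes[g_old] / n * _cluster_info(counts[g_old], sizes[g_old], q, beta)
            )
            # exact criterion value for every candidate destination cluster
            cand = counts.copy()
            cand[:, pos_idx, x] += 1.0
            w_cand = (sizes + 1.0) / n * _cluster_info(cand, sizes + 1.0, q, beta)
            totals = contrib.sum() - contrib + w_cand
            w = (totals - totals.max()) / T
            p = np.exp(w * ln2)  # criterion is in bits
            cum = np.cumsum(p)
            g_new = int(np.searchsorted(cum, rng.random() * cum[-1]))
            assignment[i] = g_new
            counts[g_new, pos_idx, x] += 1.0
            sizes[g_new] += 1.0
            contrib[g_new] = w_cand[g_new]
        crit = contrib.sum()
        if crit > best[0]:
            best = (crit, assignment.copy())
    return best


def gibbs_cluster(
    peptides,
    G: int,
    params: GibbsParams | None = None,
    seed: int = 0,
    q: np.ndarray | None = None,
) -> ClusteringState:
    """Cluster same-length peptides into G groups by annealed Gibbs sampling.

    Each sweep visits every peptide in random order, removes it from its
    cluster and resamples its assignment with probability proportional to
    ``2**(score/T)``, where score is the peptide's log2-odds under each
    cluster's leave-one-out PWM. The best state (by the KLD criterion) across
    all sweeps and ``params.restarts`` independent restarts is returned;
    results are deterministic given the seed. Empty clusters are permitted.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    params = params or GibbsParams()
    peptides = list(peptides)
    arr = encode_peptides(peptides)
    if q is None:
        q = np.full(N_AA, 1.0 / N_AA)
    if G == 1:
        return ClusteringState(
            peptides=peptides,
            assignment=np.zeros(arr.shape[0], dtype=int),
            G=1,
            q=q,
            beta=params.beta,
            seed=seed,
            params=params,
        )
    ss = np.random.SeedSequence(seed)
    best_crit, best_assign = -np.inf, None
    for child in ss.spawn(params.restarts):
        rng = np.random.default_rng(child)
        crit, assign = _anneal_once(arr, G, q, params.beta, params, rng)
        if crit > best_crit:
            best_crit, best_assign = crit, assign
    return ClusteringState(
        peptides=peptides,
        assignment=best_assign.astype(int),
        G=G,
        q=q,
        beta=params.beta,
        seed=seed,
        params=params,
    )


def scan_cluster_number(
    peptides,
    grid,
    params: GibbsParams | None = None,
    seed: int = 0,
    q: np.ndarray | None = None,
) -> dict:
    """Run :func:`gibbs_cluster` for each G in an ascending grid.

    Returns the criterion curve, per-G states and the argmax G (smallest G on
    ties). Each G consumes an independent child seed of ``seed``.
    """
    grid = list(grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be non-empty and strictly ascending")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(grid))]
    states = {}
    curve = {}
    for G, s in zip(grid, child_seeds):
        st = gibbs_cluster(peptides, G, params=params, seed=s, q=q)
        states[G] = st
        curve[G] = st.system_kld
    best_G = max(grid, key=lambda G: (curve[G], -G))
    return {"curve": curve, "states": states, "best_G": best_G}


def corrected_score(state: ClusteringState, peptide: str) -> float:
    """Margin of a member peptide: own-cluster score minus best rival score.

    The own-cluster score uses leave-one-out counts; rival clusters are scored
    with their full PWMs. With G=1 there is no rival and the own score is
    returned. Low margins flag peptides uncertain to belong to any cluster.
    """
    try:
        i = state.peptides.index(peptide)
    except ValueError as exc:
        raise KeyError(f"peptide {peptide!r} not in clustering state") from exc
    own = float(
        _loo_scores(state.encoded, state.assignment, state.G, state.q, state.beta)[i]
    )
    if state.G == 1:
        return own
    x = state.encoded[i]
    rivals = [
        score_peptide(state.pwm(g), x) for g in range(state.G) if g != state.assignment[i]
    ]
    return own - max(rivals)


def exhaustive_search(peptides, G, q=None, beta: float = DEFAULT_BETA):
    """Best assignment by brute force over all G**n labelings (tiny n only).

    Maximizes the same leave-one-out KLD criterion the sampler targets;
    intended as a ground-truth optimum for instances of at most ~15 peptides.
    """
    arr = encode_peptides(list(peptides))
    n = arr.shape[0]
    if G**n > 2_000_000:
        raise ValueError("instance too large for exhaustive search")
    if q is None:
        q = np.full(N_AA, 1.0 / N_AA)
    best = (-np.inf, None)
    for labels in product(range(G), repeat=n):
        a = np.asarray(labels)
        crit = _pwm_kld(arr, a, G, q, beta)
        if crit > best[0]:
            best = (crit, a)
    return best[0], best[1]
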