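"""Rational design of probe libraries from a peptide clustering.

Clusters are ranked by the improbability of their score coherence under the
background (a binomial tail on the number of members exceeding the cluster's
own median PWM score), and probe libraries are drawn from the ranked model:

- SYM: the top-scoring member of each top-ranked significant cluster plus a
  set of negative-control peptides — a symmetric sample of the sequence space;
- NG1/NG2: the weakest member per significant cluster, optionally restricted
  to those with a low corrected (margin) score — uncertainly clustered probes;
- C5 libraries: whole clusters by id (selection by config);
- C5P: random peptides accepted when they score above a cluster's member
  median — tests whether the PWM profile alone captures the reactivity;
- NGR: random peptides anti-selected to score low against every cluster PWM;
- RND: plain background draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._alphabet import N_AA, decode_peptides
from .composition import BackgroundModel
from .gibbs import ClusteringState, corrected_score, score_peptides

log = logging.getLogger(__name__)

__all__ = [
    "LibraryDesign",
    "ClusterSignificance",
    "sample_background_peptides",
    "cluster_significance",
    "design_sym",
    "design_ngr",
    "design_ng",
    "design_c5",
    "design_c5p",
    "design_rnd",
]

SIGNIFICANCE_ALPHA = 1e-4


@dataclass
class LibraryDesign:
    """A named ordered probe set with per-peptide provenance."""

    name: str
    peptides: list[str]
    provenance: pd.DataFrame  # indexed by peptide: cluster, score, rank, role

    def __post_init__(self):
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError(f"library {self.name}: duplicate peptides")
        missing = set(self.peptides) - set(self.provenance.index)
        if missing:
            raise ValueError(f"library {self.name}: peptides without provenance")

    def __len__(self) -> int:
        return len(self.peptides)

    def to_tsv(self, path) -> None:
        out = self.provenance.loc[self.peptides].copy()
        out.insert(0, "library", self.name)
        out.to_csv(path, sep="\t", index_label="peptide")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, pep in enumerate(self.peptides):
                fh.write(f">{self.name}_{i:04d}\n{pep}\n")

    @classmethod
    def from_tsv(cls, path) -> "LibraryDesign":
        df = pd.read_csv(path, sep="\t", index_col="peptide")
        name = str(df["library"].iloc[0])
        return cls(
            name=name,
            peptides=list(df.index),
            provenance=df.drop(columns=["library"]),
        )


@dataclass
class ClusterSignificance:
    cluster: int
    threshold: float  # median member score
    p0: float  # background exceedance probability
    k: int  # members above threshold
    n_members: int
    p: float  # binomial upper tail over all library peptides
    rank: int = -1
    significant: bool = False
    mean_member_score: float = 0.0


def sample_background_peptides(
    bg: BackgroundModel, n: int, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n background peptides as an (n, L) encoded array."""
    out = np.empty((n, length), dtype=np.int8)
    for pos in range(length):
        out[:, pos] = rng.choice(N_AA, size=n, p=bg.q)
    return out


def _member_scores(state: ClusteringState) -> dict[int, np.ndarray]:
    return {
        g: score_peptides(state.pwm(g), state.encoded[state.assignment == g])
        for g in range(state.G)
    }


def cluster_significance(
    state: ClusteringState,
    bg: BackgroundModel,
    M: int = 10_000,
    seed: int = 0,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> list[ClusterSignificance]:
    """Rank clusters by the improbability of their score coherence.

    Per cluster: t is the median member PWM score; p0 the (add-one smoothed)
    probability that one of M seeded background peptides exceeds t; p the
    upper binomial tail of observing >= k members above t among all N library
    peptides. Significant clusters have p < alpha. The returned list is in
    rank order: ascending p, ties broken by larger membership then higher
    mean member score. Empty clusters get p = 1 and are flagged.
    """
    if M < 10_000:
        raise ValueError("M must be >= 10**4 for a stable p0 estimate")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x51)))
    L = state.encoded.shape[1]
    bg_arr = sample_background_peptides(bg, M, L, rng)
    n_total = len(state.peptides)
    member_scores = _member_scores(state)
    results = []
    for g in range(state.G):
        scores = member_scores[g]
        if scores.size == 0:
            results.append(
                ClusterSignificance(
                    cluster=g, threshold=np.nan, p0=1.0, k=0, n_members=0, p=1.0
                )
            )
            continue
        t = float(np.median(scores))
        bg_scores = score_peptides(state.pwm(g), bg_arr)
        p0 = (np.count_nonzero(bg_scores > t) + 1.0) / (M + 1.0)
        k = int(np.count_nonzero(scores > t))
        p = float(stats.binom.sf(k - 1, n_total, p0))
        results.append(
            ClusterSignificance(
                cluster=g,
                threshold=t,
                p0=float(p0),
                k=k,
                n_members=int(scores.size),
                p=p,
                significant=p < alpha,
                mean_member_score=float(scores.mean()),
            )
        )
    results.sort(key=lambda r: (r.p, -r.n_members, -r.mean_member_score))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def _provenance_frame(rows: dict[str, dict]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def design_sym(
    state: ClusteringState,
    signif: list[ClusterSignificance],
    k_top: int = 519,
    controls: LibraryDesign | None = None,
    name: str = "SYM",
) -> LibraryDesign:
    """Top-scoring representative of each of the k_top best-ranked significant
    clusters, plus negative-control peptides.

    If one peptide tops two clusters, the higher-ranked cluster keeps it and
    the other backfills with its next-best member (logged).
    """
    ranked = [r for r in signif if r.significant]
    if k_top > len(ranked):
        raise ValueError(
            f"k_top={k_top} exceeds the {len(ranked)} significant clusters"
        )
    member_scores = _member_scores(state)
    chosen: dict[str, dict] = {}
    for r in ranked[:k_top]:
        members = np.flatnonzero(state.assignment == r.cluster)
        scores = member_scores[r.cluster]
        for j in np.argsort(-scores, kind="stable"):
            pep = state.peptides[members[j]]
            if pep not in chosen:
                chosen[pep] = {
                    "cluster": r.cluster,
                    "score": float(scores[j]),
                    "rank": r.rank,
                    "role": "representative",
                }
                break
            log.warning(
                "representative %s already taken; backfilling cluster %d", pep, r.cluster
            )
    if controls is not None:
        overlap = set(controls.peptides) & set(chosen)
        if overlap:
            raise ValueError(f"controls overlap representatives: {sorted(overlap)[:5]}")
        for pep in controls.peptides:
            chosen[pep] = {
                "cluster": -1,
                "score": float(controls.provenance.loc[pep].get("score", np.nan)),
                "rank": -1,
                "role": f"control:{controls.name}",
            }
    return LibraryDesign(name, list(chosen), _provenance_frame(chosen))


def design_ngr(
    state: ClusteringState,
    bg: BackgroundModel,
    n_candidates: int = 2_000_000,
    m: int = 753,
    seed: int = 0,
    name: str = "NGR",
) -> LibraryDesign:
    """Anti-selected negative library: background peptides whose maximum score
    over all cluster PWMs is lowest."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9E)))
    L = state.encoded.shape[1]
    arr = sample_background_peptides(bg, n_candidates, L, rng)
    peptides = decode_peptides(arr)
    uniq_idx = pd.Index(peptides).drop_duplicates()
    first = {p: i for i, p in reversed(list(enumerate(peptides)))}
    arr = arr[[first[p] for p in uniq_idx]]
    if m > arr.shape[0]:
        raise ValueError(f"m={m} exceeds {arr.shape[0]} unique candidates")
    max_scores = np.full(arr.shape[0], -np.inf)
    for g in range(state.G):
        if (state.assignment == g).any():
            np.maximum(max_scores, score_peptides(state.pwm(g), arr), out=max_scores)
    order = np.argsort(max_scores, kind="stable")[:m]
    rows = {
        str(uniq_idx[i]): {
            "cluster": -1,
            "score": float(max_scores[i]),
            "rank": int(j + 1),
            "role": "anti-selected",
        }
        for j, i in enumerate(order)
    }
    return LibraryDesign(name, list(rows), _provenance_frame(rows))


def design_ng(
    state: ClusteringState,
    signif: list[ClusterSignificance],
    corrected_threshold: float = 5.0,
) -> tuple[LibraryDesign, LibraryDesign]:
    """Weakly clustered probes: NG1 is the minimum-score member per
    significant cluster; NG2 restricts NG1 to corrected (margin) score below
    ``corrected_threshold``."""
    ranked = [r for r in signif if r.significant]
    if not ranked:
        raise ValueError("no significant clusters")
    member_scores = _member_scores(state)
    ng1_rows: dict[str, dict] = {}
    for r in ranked:
        members = np.flatnonzero(state.assignment == r.cluster)
        scores = member_scores[r.cluster]
        for j in np.argsort(scores, kind="stable"):
            pep = state.peptides[members[j]]
            if pep not in ng1_rows:
                ng1_rows[pep] = {
                    "cluster": r.cluster,
                    "score": float(scores[j]),
                    "rank": r.rank,
                    "role": "weakest-member",
                }
                break
    ng1 = LibraryDesign("NG1", list(ng1_rows), _provenance_frame(ng1_rows))
    ng2_rows = {}
    for pep, row in ng1_rows.items():
        margin = corrected_score(state, pep)
        if margin < corrected_threshold:
            ng2_rows[pep] = {**row, "role": "weakest-member-low-margin", "margin": margin}
    ng2 = LibraryDesign("NG2", list(ng2_rows), _provenance_frame(ng2_rows))
    return ng1, ng2


def design_c5(
    state: ClusteringState, cluster_ids: list[int], name: str = "C5_1"
) -> LibraryDesign:
    """Whole-cluster library: every member of the listed clusters."""
    member_scores = _member_scores(state)
    rows: dict[str, dict] = {}
    for g in cluster_ids:
        members = np.flatnonzero(state.assignment == g)
        for j, i in enumerate(members):
            pep = state.peptides[i]
            if pep not in rows:
                rows[pep] = {
                    "cluster": g,
                    "score": float(member_scores[g][j]),
                    "rank": -1,
                    "role": "cluster-member",
                }
    return LibraryDesign(name, list(rows), _provenance_frame(rows))


def design_c5p(
    state: ClusteringState,
    cluster_ids: list[int],
    bg: BackgroundModel,
    per_cluster: int = 150,
    seed: int = 0,
    max_batches: int = 10_000,
    name: str = "C5P",
) -> LibraryDesign:
    """Profile-sampled library: random background peptides accepted when
    scoring above the member-median of the respective cluster."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC5)))
    L = state.encoded.shape[1]
    member_scores = _member_scores(state)
    rows: dict[str, dict] = {}
    for g in cluster_ids:
        if not (state.assignment == g).any():
            raise ValueError(f"cluster {g} is empty")
        t = float(np.median(member_scores[g]))
        pwm = state.pwm(g)
        accepted = 0
        tried = 0
        batch = max(per_cluster * 4, 512)
        for _ in range(max_batches):
            arr = sample_background_peptides(bg, batch, L, rng)
            scores = score_peptides(pwm, arr)
            tried += batch
            for i in np.flatnonzero(scores > t):
                pep = decode_peptides(arr[i : i + 1])[0]
                if pep in rows:
                    continue
                rows[pep] = {
                    "cluster": g,
                    "score": float(scores[i]),
                    "rank": -1,
                    "role": "profile-sampled",
                }
                accepted += 1
                if accepted == per_cluster:
                    break
            if accepted == per_cluster:
                break
            if tried > 1e6 and accepted / tried < 1e-6:
                raise RuntimeError(
                    f"cluster {g}: acceptance rate {accepted / tried:.2e} too low"
                )
        else:
            raise RuntimeError(f"cluster {g}: could not accept {per_cluster} peptides")
    return LibraryDesign(name, list(rows), _provenance_frame(rows))


def design_rnd(
    bg: BackgroundModel,
    n: int = 800,
    length: int = 7,
    seed: int = 0,
    name: str = "RND",
) -> LibraryDesign:
    """n unique random peptides drawn from the background frequencies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x4D)))
    rows: dict[str, dict] = {}
    while len(rows) < n:
        arr = sample_background_peptides(bg, max(n, 256), length, rng)
        for pep in decode_peptides(arr):
            if pep not in rows:
                rows[pep] = {"cluster": -1, "score": np.nan, "rank": -1, "role": "random"}
                if len(rows) == n:
                    break
    return LibraryDesign(name, list(rows), _provenance_frame(rows))
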