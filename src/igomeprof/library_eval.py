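"""Statistics comparing probe libraries on a shared reactivity matrix.

Three criteria measure how well a library probes the reactivity space:
mean serum reactivity of its peptides (higher = more of the repertoire is
engaged), mean nearest-neighbor distance (MNND) of its peptide profiles
(higher = less redundant probes), and the mean Fisher-z-transformed
correlation between patient profiles restricted to the library (lower =
more informative, less collinear sampling of patients). A rank product
combines the per-criterion ranks into one score with an exact or
permutation p-value under independent uniform ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multicomp import pairwise_tukeyhsd

log = logging.getLogger(__name__)

__all__ = [
    "mean_reactivity_contrasts",
    "mnnd",
    "profile_correlation_z",
    "rank_product",
    "evaluate_libraries",
]


def mean_reactivity_contrasts(
    values: pd.DataFrame, library_labels: pd.Series
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-library mean reactivity with all pairwise Tukey-adjusted contrasts.

    The response is each peptide's mean reactivity across samples; a one-way
    fixed-effects model on the library label is followed by simultaneous
    single-step (Tukey HSD) pairwise comparisons. Libraries with fewer than
    two peptides are excluded (logged).
    """
    labels = library_labels.loc[values.index]
    response = values.mean(axis=1)
    sizes = labels.value_counts()
    small = sizes.index[sizes < 2]
    if len(small):
        log.warning("excluding libraries with < 2 peptides: %s", list(small))
        keep = ~labels.isin(small)
        labels, response = labels[keep], response[keep]
    means = response.groupby(labels).mean().sort_values(ascending=False)
    tk = pairwise_tukeyhsd(response.to_numpy(), labels.to_numpy())
    contrasts = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    contrasts["p-adj"] = tk.pvalues
    return means, contrasts


def _standardize_per_sample(values: pd.DataFrame) -> pd.DataFrame:
    z = values.sub(values.mean(axis=0), axis=1)
    return z.div(values.std(axis=0, ddof=1), axis=1)


def mnnd(
    values: pd.DataFrame,
    library_peptides,
    standardize: bool = True,
) -> float:
    """Mean nearest-neighbor Euclidean distance of a library's profiles.

    Each peptide is a point in sample space (per-sample standardized by
    default so shape, not magnitude, is compared); the statistic is the mean
    over the library's peptides of the distance to the closest other peptide
    in the same library. Redundant (correlated) probes depress it.
    """
    peptides = list(library_peptides)
    if len(peptides) < 2:
        raise ValueError("MNND needs >= 2 peptides")
    mat = _standardize_per_sample(values) if standardize else values
    X = mat.loc[peptides].to_numpy(dtype=float)
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean())


def profile_correlation_z(
    values: pd.DataFrame, library_peptides
) -> tuple[float, pd.Series]:
    """Mean Fisher-z-transformed correlation between patient profiles.

    Pearson r between every pair of sample columns restricted to the
    library's peptides, mapped through z = atanh(r). Pairs involving a
    constant sample vector are skipped (logged). Returns the mean z and the
    per-pair values.
    """
    sub = values.loc[list(library_peptides)]
    if sub.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    cols = list(sub.columns)
    zs = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                log.warning("skipping constant sample pair (%s, %s)", a, b)
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
            zs[(a, b)] = float(np.arctanh(r))
    if not zs:
        raise ValueError("no valid sample pairs")
    series = pd.Series(zs)
    return float(series.mean()), series


def rank_product(
    ranks: pd.DataFrame,
    n_permutations: int = 100_000,
    max_exact: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank product and p-value per library over several ranking criteria.

    ``ranks`` is libraries x criteria; each column must be a permutation of
    1..L. RP is the geometric mean of a library's ranks; the p-value is
    P(RP' <= RP) for independent uniform ranks, by exact enumeration over all
    L**k rank tuples when feasible, else by seeded Monte Carlo.
    """
    L, k = ranks.shape
    for c in ranks.columns:
        if sorted(ranks[c]) != list(range(1, L + 1)):
            raise ValueError(f"column {c!r} is not a permutation of 1..{L}")
    rp = np.prod(ranks.to_numpy(dtype=float), axis=1) ** (1.0 / k)
    target_products = np.prod(ranks.to_numpy(dtype=float), axis=1)
    if L**k <= max_exact:
        products = np.fromiter(
            (np.prod(t) for t in product(range(1, L + 1), repeat=k)),
            dtype=float,
            count=L**k,
        )
        pvals = [(products <= tp).mean() for tp in target_products]
        method = "exact"
    else:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x4B)))
        draws = rng.integers(1, L + 1, size=(n_permutations, k)).prod(axis=1)
        pvals = [(draws <= tp).mean() for tp in target_products]
        method = "permutation"
    out = pd.DataFrame(
        {"rank_product": rp, "p": pvals, "method": method}, index=ranks.index
    )
    return out.sort_values("rank_product")


def evaluate_libraries(
    values: pd.DataFrame,
    library_labels: pd.Series,
    rp_seed: int = 0,
) -> dict:
    """Run all three criteria over the libraries present and combine them.

    Ranking directions: rank 1 is the highest mean reactivity, the highest
    MNND, and the lowest mean profile-correlation z.
    """
    libs = sorted(library_labels.unique())
    means, contrasts = mean_reactivity_contrasts(values, library_labels)
    mnnds = pd.Series(
        {
            lib: mnnd(values, library_labels.index[library_labels == lib])
            for lib in libs
        }
    )
    zmeans = pd.Series(
        {
            lib: profile_correlation_z(
                values, library_labels.index[library_labels == lib]
            )[0]
            for lib in libs
        }
    )
    ranks = pd.DataFrame(
        {
            "mean_reactivity": means.rank(ascending=False).astype(int),
            "mnnd": mnnds.rank(ascending=False).astype(int),
            "profile_corr_z": zmeans.rank(ascending=True).astype(int),
        }
    ).loc[libs]
    rp = rank_product(ranks, seed=rp_seed)
    return {
        "mean_reactivity": means,
        "contrasts": contrasts,
        "mnnd": mnnds,
        "profile_corr_z": zmeans,
        "ranks": ranks,
        "rank_product": rp,
    }
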