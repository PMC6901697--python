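"""Classification of short-peptide BLAST hits.

The probes are 7-mers, so protein-database searches use short-sequence
parameters and return marginal alignments; hits are therefore restricted to
near-full-length matches (>= 6 identities, >= 6 positives, no gaps) before a
peptide is classified as immunoglobulin-homologous (any retained hit in an
Ig heavy/light chain — in practice mostly the J/CDR3-proximal segments),
non-immunoglobulin, or no-hit. Library-level category proportions are
compared by chi-square with FDR-adjusted pairwise follow-ups.

Running BLAST itself is external; a suitable command is::

    blastp -task blastp-short -db <nr_subset> -query library.fasta \
        -outfmt '6 qseqid sseqid stitle length nident positive gapopen gaps' \
        -out hits.tsv
"""

from __future__ import annotations

import re

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "REQUIRED_COLUMNS",
    "DEFAULT_IG_PATTERNS",
    "parse_alignment_table",
    "write_alignment_table",
    "filter_hits",
    "classify_peptides",
    "compare_categories",
]

REQUIRED_COLUMNS = [
    "qseqid",
    "sseqid",
    "stitle",
    "length",
    "nident",
    "positive",
    "gapopen",
    "gaps",
]

#: subject-title patterns identifying immunoglobulin chains (case-insensitive)
DEFAULT_IG_PATTERNS = [
    r"immunoglobulin",
    r"\bIg\s+heavy",
    r"\bIg\s+lambda",
    r"\bIg\s+kappa",
    r"\bIGH",
    r"\bIGL",
    r"\bIGK",
]

_INT_COLUMNS = ["length", "nident", "positive", "gapopen", "gaps"]


def parse_alignment_table(path) -> pd.DataFrame:
    """Read a BLAST tabular file (outfmt-6 dialect with named fields).

    Accepts a header line naming the columns or headerless standard order
    (:data:`REQUIRED_COLUMNS`); '#' comment lines are skipped. Missing
    required columns raise, naming them.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return pd.DataFrame(columns=REQUIRED_COLUMNS)
    first = lines[0].rstrip("\n").split("\t")
    if "qseqid" in first:
        header, body = first, lines[1:]
    else:
        header, body = REQUIRED_COLUMNS, lines
    df = pd.DataFrame([ln.rstrip("\n").split("\t") for ln in body], columns=header)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for c in _INT_COLUMNS:
        df[c] = df[c].astype(int)
    return df.reset_index(drop=True)


def write_alignment_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def filter_hits(
    hits: pd.DataFrame, min_positives: int = 6, min_identities: int = 6
) -> pd.DataFrame:
    """Retain near-full-length ungapped hits.

    Keeps rows with positives >= ``min_positives`` AND identities >=
    ``min_identities`` AND zero gaps.
    """
    keep = (
        (hits["positive"] >= min_positives)
        & (hits["nident"] >= min_identities)
        & (hits["gaps"] == 0)
    )
    return hits[keep].reset_index(drop=True)


def classify_peptides(
    filtered_hits: pd.DataFrame,
    queries,
    ig_patterns: list[str] | None = None,
) -> pd.Series:
    """Assign each query peptide to 'Ig', 'non-Ig' or 'no-hit'.

    'Ig' wins if any retained hit's subject title matches any pattern;
    otherwise any retained hit makes the peptide 'non-Ig'; queries absent
    from the table are 'no-hit'. Order of hits is irrelevant.
    """
    patterns = ig_patterns if ig_patterns is not None else DEFAULT_IG_PATTERNS
    if not patterns:
        raise ValueError("ig_patterns must be non-empty")
    regexes = [re.compile(p, re.IGNORECASE) for p in patterns]
    out = {}
    by_query = dict(tuple(filtered_hits.groupby("qseqid"))) if len(filtered_hits) else {}
    for q in queries:
        rows = by_query.get(q)
        if rows is None or rows.empty:
            out[q] = "no-hit"
        elif any(r.search(t) for t in rows["stitle"] for r in regexes):
            out[q] = "Ig"
        else:
            out[q] = "non-Ig"
    return pd.Series(out, name="category")


def compare_categories(counts: pd.DataFrame) -> dict:
    """Chi-square comparison of category proportions across libraries.

    ``counts`` is libraries x categories (e.g. columns Ig / non-Ig / no-hit).
    Returns the overall Pearson chi-square over the full table plus all
    pairwise 2x2 (Ig vs non-Ig) chi-squares with Benjamini-Hochberg
    adjustment. Expected cells below 1 warn but do not abort.
    """
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 libraries")
    table = counts.to_numpy(dtype=float)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        import warnings

        warnings.warn("expected cell count < 1 in the contingency table")
    pairs, raw = [], []
    libs = list(counts.index)
    use_cols = [c for c in ("Ig", "non-Ig") if c in counts.columns]
    if len(use_cols) < 2:
        use_cols = list(counts.columns[:2])
    for i, a in enumerate(libs):
        for b in libs[i + 1 :]:
            sub = counts.loc[[a, b], use_cols].to_numpy(dtype=float)
            c2, pp, _, _ = stats.chi2_contingency(sub, correction=False)
            pairs.append((a, b))
            raw.append(pp)
    adjusted = multipletests(raw, method="fdr_bh")[1] if raw else []
    pairwise = pd.DataFrame(
        {"p_raw": raw, "p_adj": adjusted},
        index=pd.MultiIndex.from_tuples(pairs, names=["lib1", "lib2"]),
    )
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof), "pairwise": pairwise}
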