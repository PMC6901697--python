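"""Amino-acid composition statistics for mimotope sets.

Residue frequencies (overall or by position), background models (uniform,
NNK codon degeneracy of the display library, or observed from an unselected
amplified library), and pseudocount-smoothed log2-odds matrices of the kind
rendered as sequence logos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import AA, N_AA, encode_peptides, nnk_frequencies

__all__ = [
    "BackgroundModel",
    "FreqMatrix",
    "residue_frequencies",
    "estimate_background",
    "log_odds",
    "log_odds_table",
]

#: default Dirichlet-style number of background pseudocounts
DEFAULT_PSEUDOCOUNT = 50.0


@dataclass
class BackgroundModel:
    """Residue background frequencies, overall and optionally per position.

    ``q`` is a 20-vector over the alphabetical residue order; ``q_pa`` an
    optional (20, L) positional background (e.g. from an amplified unselected
    library) used when positional enrichment is of interest.
    """

    q: np.ndarray
    q_pa: np.ndarray | None = None
    source: str = "uniform"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (N_AA,):
            raise ValueError(f"q must have shape (20,), got {self.q.shape}")
        if not np.isclose(self.q.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        if np.any(self.q <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if self.q_pa is not None:
            self.q_pa = np.asarray(self.q_pa, dtype=float)
            if self.q_pa.ndim != 2 or self.q_pa.shape[0] != N_AA:
                raise ValueError("q_pa must have shape (20, L)")
            if not np.allclose(self.q_pa.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError("each positional background column must sum to 1")
            if np.any(self.q_pa <= 0):
                raise ValueError("positional background must be strictly positive")

    def column(self, pos: int | None = None) -> np.ndarray:
        if pos is not None and self.q_pa is not None:
            return self.q_pa[:, pos]
        return self.q


@dataclass
class FreqMatrix:
    """Maximum-likelihood residue frequencies with the supporting count.

    ``f`` is (20, L) for positional mode or (20, 1) for pooled overall mode.
    """

    f: np.ndarray
    n: int
    positional: bool

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2 or self.f.shape[0] != N_AA:
            raise ValueError("f must have shape (20, L)")

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"pos{i + 1}" for i in range(self.f.shape[1])]
            if self.positional
            else ["overall"]
        )
        return pd.DataFrame(self.f, index=list(AA), columns=cols)


def residue_frequencies(peptides, positional: bool = False) -> FreqMatrix:
    """Observed residue frequencies of a peptide set.

    Positional mode returns one column per position; overall mode pools all
    positions into a single column. Non-standard residues raise.
    """
    arr = encode_peptides(peptides)
    if arr.shape[0] == 0:
        raise ValueError("empty peptide set")
    L = arr.shape[1]
    counts = np.zeros((N_AA, L))
    for pos in range(L):
        counts[:, pos] = np.bincount(arr[:, pos], minlength=N_AA)
    if not positional:
        counts = counts.sum(axis=1, keepdims=True)
    return FreqMatrix(f=counts / counts.sum(axis=0), n=arr.shape[0], positional=positional)


def estimate_background(source="uniform", positional: bool = False) -> BackgroundModel:
    """Build a background model.

    ``source`` is ``"uniform"``, ``"nnk"`` (Ph.D.-7 NNK codon degeneracy) or a
    peptide collection observed without ligand selection. For an observed
    source, ``positional`` additionally retains per-position frequencies.
    """
    if isinstance(source, str):
        if source == "uniform":
            return BackgroundModel(q=np.full(N_AA, 1.0 / N_AA), source="uniform")
        if source == "nnk":
            return BackgroundModel(q=nnk_frequencies(), source="theoretical_nnk")
        raise ValueError(f"unknown background source {source!r}")
    fm_pos = residue_frequencies(source, positional=True)
    counts = fm_pos.f * fm_pos.n  # per-position residue counts
    total = counts.sum()
    # add-one smoothing keeps every residue representable in log-odds
    q = (counts.sum(axis=1) + 1.0) / (total + N_AA)
    q_pa = (counts + 1.0) / (fm_pos.n + N_AA) if positional else None
    return BackgroundModel(q=q, q_pa=q_pa, source="observed")


def log_odds(
    f: FreqMatrix, bg: BackgroundModel, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Pseudocount-smoothed log2-odds of observed vs background frequencies.

    For each cell, ``LO = log2(((n*f + beta*q) / (n + beta)) / q)`` where n is
    the supporting sequence count and beta the number of background
    pseudocounts. When the background carries positional frequencies, each
    column is compared against its own background column, which cancels
    positional biases shared with the unselected library.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    L = f.f.shape[1]
    lo = np.empty_like(f.f)
    for pos in range(L):
        q = bg.column(pos if (f.positional and bg.q_pa is not None) else None)
        smoothed = (f.n * f.f[:, pos] + pseudocount * q) / (f.n + pseudocount)
        with np.errstate(divide="ignore"):  # beta=0 with unseen residue -> -inf
            lo[:, pos] = np.log2(smoothed / q)
    return lo


def log_odds_table(lo: np.ndarray, positional: bool = True) -> pd.DataFrame:
    """Log-odds matrix as a residues x positions DataFrame (TSV-ready)."""
    cols = [f"pos{i + 1}" for i in range(lo.shape[1])] if positional else ["overall"]
    return pd.DataFrame(lo, index=list(AA), columns=cols)


def plot_logo(lo: np.ndarray, path=None, ax=None):
    """Render a log-odds matrix as a simple stacked-letter logo.

    Thin optional export (requires matplotlib); the matrices themselves are
    the tested artifact. Positive log-odds stack upward, negative downward,
    letters ordered by magnitude.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * lo.shape[1], 3))
    for pos in range(lo.shape[1]):
        col = lo[:, pos]
        for sign in (1, -1):
            idx = [i for i in np.argsort(-sign * col) if sign * col[i] > 0]
            base = 0.0
            for i in idx:
                h = abs(col[i])
                ax.text(
                    pos + 1, sign * (base + h / 2), AA[i],
                    ha="center", va="center", fontsize=6 + 10 * min(h, 1.5),
                    color="tab:blue" if sign > 0 else "tab:red",
                )
                base += h
    span = np.abs(lo).sum(axis=0).max()
    ax.set_xlim(0.5, lo.shape[1] + 0.5)
    ax.set_ylim(-span, span)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("position")
    ax.set_ylabel("log2 odds (bits)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
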