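"""Physicochemical embedding of peptides and low-dimensional maps.

Each residue is described by the five principal-property z-scales (z1-z5,
Sandberg et al. 1998: roughly hydrophobicity, steric bulk/polarizability,
polarity, and two electronic-property factors), so a 7-mer becomes a
35-dimensional vector. Maps use t-SNE (visualization of sequence space) or
classical (Torgerson) multidimensional scaling (metric-preserving reduction,
also used to build surrogate features for classifiers).
"""

from __future__ import annotations

import numpy as np
from sklearn.manifold import TSNE

from ._alphabet import AA

__all__ = ["ZSCALES", "zscale_encode", "tsne_map", "classical_mds"]

# z1..z5 per residue, Sandberg et al. 1998 (J Med Chem 41:2481), extended
# z-scales for the 20 coded amino acids.
ZSCALES = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
}

_Z = np.array([ZSCALES[a] for a in AA])


def zscale_encode(peptides) -> np.ndarray:
    """Encode equal-length peptides as (n, 5*L) z-scale vectors.

    Position-major layout: columns [0:5] are z1..z5 of position 1, and so on
    (35 columns for 7-mers). Unknown residues raise.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("empty peptide set")
    L = len(peptides[0])
    out = np.empty((len(peptides), 5 * L))
    for i, pep in enumerate(peptides):
        if len(pep) != L:
            raise ValueError(f"peptide {pep!r} has length {len(pep)}, expected {L}")
        try:
            out[i] = np.concatenate([ZSCALES[c] for c in pep])
        except KeyError as exc:
            raise ValueError(f"unknown residue {exc.args[0]!r} in {pep!r}") from None
    return out


def tsne_map(
    matrix: np.ndarray,
    perplexity: float = 30.0,
    iters: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE embedding; deterministic per seed.

    Requires at least 3*perplexity rows (the neighborhood size must be
    supported by the data). Used for visualization only.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 3 * perplexity:
        raise ValueError(
            f"need >= {int(3 * perplexity)} rows for perplexity {perplexity}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iters,
        random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(matrix)


def classical_mds(
    distances: np.ndarray, dims: int = 2, return_stress: bool = False
):
    """Classical (Torgerson) scaling of a symmetric distance matrix.

    Double-centers the squared distances and takes the top ``dims``
    eigenvectors; for Euclidean-realizable distances of rank <= dims, the
    output reproduces the input distances exactly. Optionally returns the
    (raw) stress: sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2).
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[idx], 0.0, None)
    coords = vecs[:, idx] * np.sqrt(lam)
    if not return_stress:
        return coords
    diff = coords[:, None, :] - coords[None, :, :]
    Dhat = np.sqrt((diff**2).sum(axis=2))
    denom = (D**2).sum()
    stress = float(np.sqrt(((D - Dhat) ** 2).sum() / denom)) if denom > 0 else 0.0
    return coords, stress
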