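"""Amino-acid alphabet, integer encoding and NNK codon degeneracy.

All peptide-array code in this package works on 7-mer peptides over the 20
standard residues. Internally peptides are encoded as small integer arrays
indexed into :data:`AA` (alphabetical one-letter order), which keeps PWM
arithmetic vectorizable.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from Bio.Seq import Seq

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
N_AA = 20

#: default 7-mer insert length of the Ph.D.-7 display library
PEPTIDE_LENGTH = 7


def encode_peptides(peptides, length: int | None = None) -> np.ndarray:
    """Encode an iterable of equal-length peptides as an (n, L) int8 array.

    Raises ``ValueError`` on non-standard residues (listing offenders) or
    mixed lengths.
    """
    peptides = list(peptides)
    if not peptides:
        return np.empty((0, length or 0), dtype=np.int8)
    L = length if length is not None else len(peptides[0])
    bad = sorted({p for p in peptides if len(p) != L})
    if bad:
        raise ValueError(f"peptides of mixed length (expected {L}): {bad[:5]}")
    offenders = sorted({c for p in peptides for c in p if c not in AA_INDEX})
    if offenders:
        raise ValueError(f"non-standard residues: {offenders}")
    arr = np.empty((len(peptides), L), dtype=np.int8)
    for i, p in enumerate(peptides):
        arr[i] = [AA_INDEX[c] for c in p]
    return arr


def decode_peptides(arr: np.ndarray) -> list[str]:
    return ["".join(AA[i] for i in row) for row in np.atleast_2d(arr)]


def nnk_codons() -> dict[str, list[str]]:
    """Map residue -> list of NNK codons (N = ACGT, K = G/T; 32 codons, 1 stop)."""
    table: dict[str, list[str]] = {}
    for c1, c2, c3 in product("ACGT", "ACGT", "GT"):
        codon = c1 + c2 + c3
        aa = str(Seq(codon).translate())
        if aa == "*":
            continue
        table.setdefault(aa, []).append(codon)
    return table


def nnk_frequencies(renormalize: bool = True) -> np.ndarray:
    """Per-residue frequency under the NNK degenerate-codon scheme.

    NNK spans 32 codons of which one (TAG) is an amber stop; L/R/S carry 3
    codons each. With ``renormalize`` (default) frequencies are conditioned on
    coding codons (3/31 for L/R/S) so they sum to one, as a background model
    requires; without it they are per-codon fractions out of 32 (3/32, 1/32).
    """
    codons = nnk_codons()
    counts = np.array([len(codons[a]) for a in AA], dtype=float)
    return counts / (counts.sum() if renormalize else 32.0)
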