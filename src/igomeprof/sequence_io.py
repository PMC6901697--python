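"""Read handling for phage-display deep panning.

Amplicon reads (FASTA/FASTQ) carry a short random peptide insert between two
fixed vector flanks. This module recovers the insert, translates it, tallies
copy numbers per unique peptide, and applies the copy-number window filter
that discards singletons/doubletons (sequencing-error floor) and overgrown
phage clones (amplification ceiling).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "CopyTable",
    "InsertLocator",
    "ExtractionReport",
    "read_sequence_records",
    "extract_insert_peptides",
    "tally_copies",
    "filter_copy_window",
]

_STANDARD_TABLE = unambiguous_dna_by_id[1]


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequencing read (or peptide) with optional quality scores."""

    id: str
    seq: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} quality scores "
                f"for {len(self.seq)} bases"
            )


@dataclass
class CopyTable:
    """Unique peptides with copy counts.

    ``counts`` maps each peptide to a positive integer; ``total_reads`` is the
    number of reads the peptides were tallied from (>= sum of counts when some
    reads were dropped upstream).
    """

    counts: dict[str, int]
    total_reads: int = 0

    def __post_init__(self):
        if self.counts:
            lengths = {len(p) for p in self.counts}
            if len(lengths) != 1:
                raise ValueError(f"mixed peptide lengths: {sorted(lengths)}")
            if any(c < 1 for c in self.counts.values()):
                raise ValueError("copy counts must be >= 1")
        if self.total_reads < sum(self.counts.values()):
            self.total_reads = sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("peptide\tcount\n")
            for pep, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{pep}\t{n}\n")

    @classmethod
    def from_tsv(cls, path) -> "CopyTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("peptide"):
                raise ValueError(f"{path}: expected 'peptide\\tcount' header")
            for line in fh:
                pep, n = line.rstrip("\n").split("\t")
                counts[pep] = int(n)
        return cls(counts=counts)


@dataclass(frozen=True)
class InsertLocator:
    """Where the peptide-coding fragment sits in a read.

    Both flanks must occur exactly once; the region between them is translated
    in frame 0 (``frame`` shifts the start within the insert).
    """

    flank_left: str
    flank_right: str
    frame: int = 0

    def __post_init__(self):
        if not self.flank_left or not self.flank_right:
            raise ValueError("locator flanks must be non-empty")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")


@dataclass
class ExtractionReport:
    """Per-reason drop accounting for insert extraction."""

    n_reads: int = 0
    n_recovered: int = 0
    drops: Counter = field(default_factory=Counter)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_reads": self.n_reads,
                    "n_recovered": self.n_recovered,
                    "drops": dict(self.drops),
                },
                indent=2,
            )
        )


def read_sequence_records(path, format: str = "fasta") -> Iterator[SequenceRecord]:
    """Stream records from a FASTA/FASTQ file.

    Malformed records raise a ``ValueError`` naming the file; an empty file
    yields an empty stream.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        for rec in SeqIO.parse(str(path), format):
            quals = rec.letter_annotations.get("phred_quality")
            yield SequenceRecord(
                id=rec.id,
                seq=str(rec.seq),
                qualities=tuple(quals) if quals is not None else None,
            )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {format} record: {exc}") from exc


def _translate(insert: str, amber_suppression: bool) -> tuple[str | None, str | None]:
    """Translate an in-frame insert; return (peptide, drop_reason)."""
    peptide = []
    for i in range(0, len(insert), 3):
        codon = insert[i : i + 3]
        if codon == "TAG" and amber_suppression:
            # supE hosts read the amber stop through as glutamine
            peptide.append("Q")
            continue
        aa = _STANDARD_TABLE.forward_table.get(codon)
        if aa is None:
            if codon in _STANDARD_TABLE.stop_codons:
                return None, "stop_codon"
            return None, "ambiguous_base"
        peptide.append(aa)
    return "".join(peptide), None


def extract_insert_peptides(
    records: Iterable[SequenceRecord],
    locator: InsertLocator,
    amber_suppression: bool = False,
) -> tuple[list[str], ExtractionReport]:
    """Recover translated insert peptides from reads.

    A read contributes a peptide when both flanks occur exactly once, the
    between-flank region has in-frame length divisible by 3 and contains no
    ambiguous base or stop codon. Dropped reads are counted per reason
    (``no_flank``, ``duplicate_flank``, ``bad_frame``, ``ambiguous_base``,
    ``stop_codon``) rather than raised.

    With ``amber_suppression`` the amber stop TAG is read as Q, as in the supE
    E. coli hosts used to propagate Ph.D. display libraries.
    """
    report = ExtractionReport()
    peptides: list[str] = []
    for rec in records:
        report.n_reads += 1
        seq = rec.seq.upper()
        nl = seq.count(locator.flank_left)
        nr = seq.count(locator.flank_right)
        if nl == 0 or nr == 0:
            report.drops["no_flank"] += 1
            continue
        if nl > 1 or nr > 1:
            report.drops["duplicate_flank"] += 1
            continue
        start = seq.index(locator.flank_left) + len(locator.flank_left)
        end = seq.index(locator.flank_right)
        insert = seq[start + locator.frame : end]
        if end <= start or len(insert) % 3 != 0 or not insert:
            report.drops["bad_frame"] += 1
            continue
        peptide, reason = _translate(insert, amber_suppression)
        if reason is not None:
            report.drops[reason] += 1
            continue
        peptides.append(peptide)
        report.n_recovered += 1
    return peptides, report


def tally_copies(peptides: Iterable[str]) -> CopyTable:
    """Count copies of each unique peptide; counts sum to the input length."""
    peptides = list(peptides)
    if peptides and len({len(p) for p in peptides}) != 1:
        raise ValueError("peptides of mixed length")
    return CopyTable(counts=dict(Counter(peptides)), total_reads=len(peptides))


@dataclass
class WindowReport:
    retained: int
    dropped_low: int
    dropped_high: int


def filter_copy_window(
    table: CopyTable, low: int = 2, high: int = 11
) -> tuple[list[str], WindowReport]:
    """Keep peptides whose copy number lies strictly inside (low, high).

    The defaults keep reads seen more than twice (sequencing-error floor) and
    fewer than eleven times (overgrown clones). Returns the retained peptides
    (sorted) and retained/dropped counts.
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    kept = sorted(p for p, n in table.counts.items() if low < n < high)
    dropped_low = sum(1 for n in table.counts.values() if n <= low)
    dropped_high = sum(1 for n in table.counts.values() if n >= high)
    return kept, WindowReport(len(kept), dropped_low, dropped_high)
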