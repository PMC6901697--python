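"""Classify mimotope BLAST hits and compare libraries.

Parses a small BLAST tabular table, applies the short-peptide hit filters
(>= 6 identities, >= 6 positives, no gaps), classifies peptides as
immunoglobulin / non-immunoglobulin / no-hit, and compares two libraries'
proportions by chi-square.
"""

import io
import tempfile
from pathlib import Path

import pandas as pd

from igomeprof.homology import (
    classify_peptides,
    compare_categories,
    filter_hits,
    parse_alignment_table,
)

hits_tsv = """qseqid\tsseqid\tstitle\tlength\tnident\tpositive\tgapopen\tgaps
sym01\tref|1\timmunoglobulin heavy chain junction region\t7\t7\t7\t0\t0
sym01\tref|2\tkinesin family member 5A\t7\t6\t7\t0\t0
sym02\tref|3\tIg kappa chain V-J region\t7\t6\t6\t0\t0
sym03\tref|4\tkeratin type II\t7\t5\t7\t0\t0
rnd01\tref|5\tzinc finger protein\t7\t6\t6\t0\t0
rnd02\tref|6\tcollagen alpha chain\t7\t7\t7\t1\t1
"""
path = Path(tempfile.mkdtemp()) / "hits.tsv"
path.write_text(hits_tsv)

table = parse_alignment_table(path)
filtered = filter_hits(table)
print(f"{len(table)} hits, {len(filtered)} retained after the short-peptide filters")

queries = ["sym01", "sym02", "sym03", "rnd01", "rnd02", "rnd03"]
cats = classify_peptides(filtered, queries)
print(cats.to_string())

libs = pd.Series({q: ("SYM" if q.startswith("sym") else "RND") for q in queries})
counts = pd.crosstab(libs, cats)
print("\ncategory counts by library:\n", counts.to_string())
result = compare_categories(counts)
print(f"\noverall chi-square = {result['chi2']:.2f}, p = {result['p']:.3f} "
      f"(tiny fixture: a real comparison uses hundreds of peptides)")
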