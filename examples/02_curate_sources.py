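"""Curate raw per-database CNV tables into a non-redundant labelled set.

Generates toy tables in the six source dialects (each with rows planted on
both sides of every filter rule), applies the per-database inclusion
filters, then the merge rules: length in [50 bp, 5 Mb], both members of
conflicting pairs at >= 70% reciprocal overlap removed, identical-
coordinate multi-label CNVs removed.
"""

import tempfile
from pathlib import Path

from cnvpatho import (apply_source_filter, dedup_validation,
                      merge_nonredundant, read_cnv_table)
from cnvpatho.simulate import generate_raw_db_tables

outdir = Path(tempfile.mkdtemp())
_, manifest = generate_raw_db_tables(seed=7, outdir=outdir)

filtered = []
for source in manifest["source_filter"]:
    records = read_cnv_table(outdir / f"{source}.tsv", source)
    kept, report = apply_source_filter(records, source)
    filtered.append(kept)
    print(f"{source:16s} in={report.n_input:2d} kept={len(kept):2d} "
          f"excluded={report.exclusions}")

merged, report = merge_nonredundant(filtered)
print(f"\nmerge: {report.n_input} in -> {len(merged)} retained; "
      f"removed per rule: {report.exclusions}")

validation = read_cnv_table(outdir / "validation.bed", "generic_bed")
kept, report = dedup_validation(validation)
print(f"validation dedup: {report.n_input} in -> {len(kept)} kept "
      f"({report.exclusions}); at >=90% reciprocal overlap the shorter "
      f"member of a concordant pair survives")
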