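"""Multi-source CNV curation: per-database filters, non-redundant merge,
validation-set deduplication.

Per-source inclusion rules (applied by :func:`apply_source_filter`):

* clinvar — recognized CNV type; five-tier clinical significance; review
  status among "criteria provided, multiple submitters, no conflicts",
  "criteria provided, single submitter", "reviewed by expert panel",
  "practice guideline".
* dbvar — recognized CNV type; labelled pathogenic / likely pathogenic
  (the combined "pathogenic/likely pathogenic" assertion maps to likely
  pathogenic).
* clingen_region — dosage-sensitive regions: HI or TS score 3 becomes a
  pathogenic CNV of the corresponding type (loss for haploinsufficiency,
  gain for triplosensitivity); score 40 becomes a benign CNV of the same
  correspondence.
* dgv — gold-standard variants with ≥ 2000 samples tested; survivors are
  labelled benign.
* decipher — population CNVs with observations > 0 and frequency > 1%;
  survivors benign.
* gnomad — SVTYPE DEL/DUP, FILTER PASS, AF > 1%, AN > 2000; survivors
  benign.

Merge rules (in order): length filter [50, 5×10^6] bp; symmetric removal
of both members of every same-type pair with reciprocal overlap ≥ 70% and
conflicting pathogenicity (benign/likely-benign vs pathogenic/likely-
pathogenic; uncertain significance conflicts with neither); removal of
identical-coordinate same-type CNVs carrying more than one distinct label.
Conflict detection is decided over the original set and applied once — no
cascading re-evaluation — so the result is order-independent.

Validation deduplication: the 70%-conflict rule, then for same-type pairs
at ≥ 90% reciprocal overlap the shorter member is kept (equal lengths
break by record id), then the length filter.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

from .core import (CNVRecord, CNVType, Label, labels_conflict,
                   reciprocal_overlap)

MIN_LENGTH = 50
MAX_LENGTH = 5_000_000

_CLINVAR_REVIEW_OK = {
    "criteria provided, multiple submitters, no conflicts",
    "criteria provided, single submitter",
    "reviewed by expert panel",
    "practice guideline",
}

_FIVE_TIER = {Label.BENIGN, Label.LIKELY_BENIGN, Label.UNCERTAIN,
              Label.LIKELY_PATHOGENIC, Label.PATHOGENIC}


@dataclass
class CurationReport:
    """Bookkeeping for one curation stage; counts are conserved."""

    source: str
    n_input: int = 0
    n_retained: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)

    def exclude(self, rule: str, n: int = 1) -> None:
        self.exclusions[rule] = self.exclusions.get(rule, 0) + n

    def check_conserved(self) -> bool:
        return self.n_input == self.n_retained + sum(self.exclusions.values())

    def to_dict(self) -> dict:
        return {"source": self.source, "input": self.n_input,
                "retained": self.n_retained, "excluded": dict(self.exclusions)}


def _num(attrs: dict, key: str, default: float = float("nan")) -> float:
    try:
        return float(str(attrs.get(key, "")).strip())
    except ValueError:
        return default


def apply_source_filter(records: list[CNVRecord], source: str
                        ) -> tuple[list[CNVRecord], CurationReport]:
    """Apply one database's inclusion rules; relabel survivors where the
    rules imply a label (ClinGen dosage scores; benign for the population
    databases)."""
    report = CurationReport(source, n_input=len(records))
    retained: list[CNVRecord] = []

    if source == "clinvar":
        for r in records:
            if r.label not in _FIVE_TIER:
                report.exclude("clinical_significance")
            elif str(r.attrs.get("review_status", "")).strip().lower() not in _CLINVAR_REVIEW_OK:
                report.exclude("review_status")
            else:
                retained.append(r)
    elif source == "dbvar":
        for r in records:
            if r.label in (Label.PATHOGENIC, Label.LIKELY_PATHOGENIC):
                retained.append(r)
            else:
                report.exclude("not_pathogenic")
    elif source == "clingen_region":
        for r in records:
            emitted = False
            for key, cnv_type in (("HI_score", CNVType.LOSS), ("TS_score", CNVType.GAIN)):
                code = str(r.attrs.get(key, "")).strip()
                if code == "3":
                    label = Label.PATHOGENIC
                elif code == "40":
                    label = Label.BENIGN
                else:
                    continue
                retained.append(CNVRecord(r.interval, cnv_type, label, source,
                                          f"{r.record_id}_{key[:2]}", dict(r.attrs)))
                emitted = True
            if not emitted:
                report.exclude("not_dosage_sensitive")
        # conservation is over input regions (a region may emit two CNVs):
        # retained counts rows that yielded at least one CNV
        report.n_retained = report.n_input - report.exclusions.get(
            "not_dosage_sensitive", 0)
        return retained, report
    elif source == "dgv":
        for r in records:
            if _num(r.attrs, "sample_count") >= 2000:
                retained.append(_relabel(r, Label.BENIGN))
            else:
                report.exclude("sample_count_lt_2000")
    elif source == "decipher":
        for r in records:
            if _num(r.attrs, "observations", 0) <= 0:
                report.exclude("no_observations")
            elif _num(r.attrs, "frequency") <= 0.01:
                report.exclude("frequency_le_1pct")
            else:
                retained.append(_relabel(r, Label.BENIGN))
    elif source == "gnomad":
        for r in records:
            if str(r.attrs.get("FILTER", "")).strip().upper() != "PASS":
                report.exclude("filter_not_pass")
            elif _num(r.attrs, "AF") <= 0.01:
                report.exclude("af_le_1pct")
            elif _num(r.attrs, "AN") <= 2000:
                report.exclude("an_le_2000")
            else:
                retained.append(_relabel(r, Label.BENIGN))
    else:
        raise ValueError(f"unknown source {source!r}")

    report.n_retained = len(retained)
    return retained, report


def _relabel(r: CNVRecord, label: Label) -> CNVRecord:
    return CNVRecord(r.interval, r.cnv_type, label, r.source, r.record_id, dict(r.attrs))


def _sorted_records(records: list[CNVRecord]) -> list[CNVRecord]:
    # canonical order makes every downstream rule order-independent
    return sorted(records, key=lambda r: (r.interval.chrom, r.interval.start,
                                          r.interval.end, r.cnv_type.value,
                                          r.label.value, r.record_id))


def _length_filter(records, report, rule="length_out_of_range"):
    kept = []
    for r in records:
        if MIN_LENGTH <= r.length <= MAX_LENGTH:
            kept.append(r)
        else:
            report.exclude(rule)
    return kept


def _conflict_pairs(records: list[CNVRecord], threshold: float) -> set[int]:
    """Indices of records in any same-type pair with RO ≥ threshold and
    conflicting labels. Decided over the full set, applied once."""
    doomed: set[int] = set()
    by_key = defaultdict(list)
    for i, r in enumerate(records):
        by_key[(r.cnv_type, r.interval.chrom)].append(i)
    for idxs in by_key.values():
        for i, j in itertools.combinations(idxs, 2):
            a, b = records[i], records[j]
            if labels_conflict(a.label, b.label) and \
                    reciprocal_overlap(a.interval, b.interval) >= threshold:
                doomed.update((i, j))
    return doomed


def merge_nonredundant(record_sets: list[list[CNVRecord]]
                       ) -> tuple[list[CNVRecord], CurationReport]:
    """Merge per-source record lists into one non-redundant labelled set."""
    records = _sorted_records([r for rs in record_sets for r in rs])
    report = CurationReport("merge", n_input=len(records))

    records = _length_filter(records, report)

    doomed = _conflict_pairs(records, 0.70)
    report.exclude("conflict_ro70", len(doomed))
    records = [r for i, r in enumerate(records) if i not in doomed]

    # identical-coordinate same-type CNVs with >1 distinct label
    by_coord = defaultdict(set)
    for r in records:
        by_coord[(r.interval, r.cnv_type)].add(r.label)
    multi = {k for k, labels in by_coord.items() if len(labels) > 1}
    kept = [r for r in records if (r.interval, r.cnv_type) not in multi]
    report.exclude("multiple_significance", len(records) - len(kept))

    report.n_retained = len(kept)
    return kept, report


def dedup_validation(records: list[CNVRecord]
                     ) -> tuple[list[CNVRecord], CurationReport]:
    """Deduplicate a validation set: 70%-conflict rule, then keep the
    shorter member of ≥90%-overlap same-type pairs, then the length filter."""
    records = _sorted_records(records)
    report = CurationReport("dedup_validation", n_input=len(records))

    doomed = _conflict_pairs(records, 0.70)
    report.exclude("conflict_ro70", len(doomed))
    records = [r for i, r in enumerate(records) if i not in doomed]

    # greedy shortest-first: a record is kept unless an already-kept record
    # overlaps it reciprocally at >= 0.90 (implements "select the shorter",
    # with record_id breaking length ties, and handles chains)
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].length, records[i].record_id))
    kept_idx: list[int] = []
    for i in order:
        r = records[i]
        if any(records[j].cnv_type == r.cnv_type and
               reciprocal_overlap(records[j].interval, r.interval) >= 0.90
               for j in kept_idx):
            report.exclude("redundant_ro90")
        else:
            kept_idx.append(i)
    records = [records[i] for i in sorted(kept_idx)]

    records = _length_filter(records, report)
    report.n_retained = len(records)
    return records, report
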