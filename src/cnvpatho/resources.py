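"""Annotation-resource containers and file readers/writers.

A :class:`ResourceBundle` holds the four annotation tracks the feature
engine draws on: genes (with biotype, OMIM/Morbid flags, dosage-sensitivity
codes and gene-level constraint scores), UTRs, site-level deleteriousness
scores (numeric plus categorical predictor calls) and cCRE region classes.

File conventions (all plain text):

* CNV tables — TSV with a header per source dialect; ``generic_bed`` is a
  headerless BED-like file (0-based half-open). Header dialects carry
  1-based inclusive coordinates and are converted on read.
* gene track — TSV: chrom, start, end, gene_id, biotype, is_omim,
  is_morbid, hi_score, ts_score, then one column per gene score. Also
  accepts GFF3 ``gene`` lines with the same information in attributes.
* UTR track — TSV: chrom, start, end, utr_kind, parent_gene.
* site scores — TSV: chrom, pos (1-based), then score columns; columns
  whose name ends in ``_pred`` are categorical, the rest numeric. ``.`` or
  empty cells are explicit missing (never coerced to 0).
* regions — 4-column BED (chrom, start, end, cCRE class), 0-based.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import CNVRecord, CNVType, GenomicInterval, Label, normalize_chrom

DIALECTS = ("clinvar", "dbvar", "clingen_region", "dgv", "decipher", "gnomad", "generic_bed")


class Biotype(str, enum.Enum):
    PROTEIN_CODING = "protein_coding"
    PSEUDOGENE = "pseudogene"
    NCRNA = "ncRNA"
    OTHER = "other"


@dataclass
class GeneRecord:
    interval: GenomicInterval
    gene_id: str
    biotype: Biotype = Biotype.OTHER
    is_omim: bool = False
    is_morbid: bool = False
    hi_score: str = "NA"  # ClinGen dosage codes: 0/1/2/3/40/NA
    ts_score: str = "NA"
    gene_scores: dict[str, float] = field(default_factory=dict)  # absent = missing


@dataclass
class UTRRecord:
    interval: GenomicInterval
    utr_kind: str  # three_prime | five_prime
    parent_gene: str = ""

    def __post_init__(self) -> None:
        if self.utr_kind not in ("three_prime", "five_prime"):
            raise ValueError(f"unknown UTR kind {self.utr_kind!r}")


@dataclass
class SiteScoreRecord:
    chrom: str
    pos: int  # 0-based
    numeric_scores: dict[str, float] = field(default_factory=dict)
    categorical_preds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.pos < 0:
            raise ValueError(f"negative site position {self.pos}")


@dataclass
class RegionRecord:
    interval: GenomicInterval
    region_class: str

    _CLASSES = ("CTCF_bound", "CTCF_only", "dELS", "DNase_H3K4me3", "pELS", "PLS")

    def __post_init__(self) -> None:
        if self.region_class not in self._CLASSES:
            raise ValueError(f"unknown cCRE class {self.region_class!r}")


@dataclass
class ResourceBundle:
    genes: list[GeneRecord] = field(default_factory=list)
    utrs: list[UTRRecord] = field(default_factory=list)
    sites: list[SiteScoreRecord] = field(default_factory=list)
    regions: list[RegionRecord] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CNV table parsing
# ---------------------------------------------------------------------------

_TYPE_MAP = {
    "del": CNVType.LOSS,
    "deletion": CNVType.LOSS,
    "loss": CNVType.LOSS,
    "copy number loss": CNVType.LOSS,
    "dup": CNVType.GAIN,
    "duplication": CNVType.GAIN,
    "gain": CNVType.GAIN,
    "copy number gain": CNVType.GAIN,
}

_LABEL_MAP = {
    "benign": Label.BENIGN,
    "likely benign": Label.LIKELY_BENIGN,
    "likely_benign": Label.LIKELY_BENIGN,
    "uncertain significance": Label.UNCERTAIN,
    "uncertain_significance": Label.UNCERTAIN,
    "vus": Label.UNCERTAIN,
    "likely pathogenic": Label.LIKELY_PATHOGENIC,
    "likely_pathogenic": Label.LIKELY_PATHOGENIC,
    # combined assertion: conservative reading
    "pathogenic/likely pathogenic": Label.LIKELY_PATHOGENIC,
    "pathogenic": Label.PATHOGENIC,
    "unknown": Label.UNKNOWN,
    "": Label.UNKNOWN,
}


def normalize_cnv_type(raw: str) -> Optional[CNVType]:
    return _TYPE_MAP.get(str(raw).strip().lower())


def normalize_label(raw: str) -> Optional[Label]:
    return _LABEL_MAP.get(str(raw).strip().lower())


class TableParseError(ValueError):
    pass


def _mk_record(chrom, start, end, cnv_type, label, source, record_id, attrs, lineno):
    try:
        iv = GenomicInterval(chrom, int(start), int(end))
    except (TypeError, ValueError) as exc:
        raise TableParseError(f"line {lineno}: bad coordinates ({exc})") from exc
    return CNVRecord(iv, cnv_type, label, source, record_id, attrs)


def read_cnv_table(path: str | Path, dialect: str) -> list[CNVRecord]:
    """Parse a per-database CNV table into CNVRecords.

    Rows missing mandatory fields (unrecognized type, unparsable
    coordinates in header dialects) are skipped and counted in the returned
    records' provenance; dialect-specific raw columns (review status, AF,
    AN, FILTER, observations, frequency, sample counts, dosage scores) are
    retained in ``attrs`` for the curation filters.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    records: list[CNVRecord] = []

    if dialect == "generic_bed":
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise TableParseError(f"line {lineno}: expected ≥4 columns")
            cnv_type = normalize_cnv_type(parts[3])
            if cnv_type is None:
                continue  # unsupported SV type, skipped
            label = normalize_label(parts[4]) if len(parts) > 4 else Label.UNKNOWN
            rid = parts[5] if len(parts) > 5 else f"{path.stem}_{lineno}"
            records.append(
                _mk_record(parts[0], parts[1], parts[2], cnv_type, label or Label.UNKNOWN,
                           "generic_bed", rid, {}, lineno)
            )
        return records

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    type_col = "SVTYPE" if dialect == "gnomad" else "type"
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        rid = row_d.get("id", f"{dialect}_{i}")
        chrom, start, end = row_d.get("chrom"), row_d.get("start"), row_d.get("end")
        # header dialects carry 1-based inclusive coordinates
        try:
            start0, end0 = int(start) - 1, int(end)
        except (TypeError, ValueError) as exc:
            raise TableParseError(f"{path}:{i}: unparsable coordinates") from exc
        if dialect == "clingen_region":
            # region rows carry dosage scores, not CNV types; curation turns
            # them into CNVs
            iv = GenomicInterval(chrom, start0, end0)
            records.append(CNVRecord(iv, CNVType.LOSS, Label.UNKNOWN, dialect, rid,
                                     {k: v for k, v in row_d.items()}))
            continue
        cnv_type = normalize_cnv_type(row_d.get(type_col, ""))
        if cnv_type is None:
            continue  # e.g. gnomAD SVTYPE=INS
        # unrecognized significance strings become UNKNOWN so the curation
        # filters (not the parser) decide their fate
        label = normalize_label(row_d.get("clinical_significance", row_d.get("label", ""))) \
            or Label.UNKNOWN
        attrs = {k: v for k, v in row_d.items()
                 if k not in ("chrom", "start", "end", "id")}
        records.append(_mk_record(chrom, start0, end0, cnv_type, label, dialect, rid, attrs, i))
    return records


def write_cnv_table(records: list[CNVRecord], path: str | Path) -> None:
    """Write records as a generic labelled BED-like TSV (0-based half-open)."""
    rows = [
        (r.interval.chrom, r.interval.start, r.interval.end,
         r.cnv_type.value, r.label.value, r.record_id)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "label", "id"])
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Track readers
# ---------------------------------------------------------------------------

def _parse_float(cell: str) -> Optional[float]:
    s = str(cell).strip()
    if s in ("", ".", "NA", "NaN", "nan"):
        return None
    v = float(s)
    if not math.isfinite(v):
        raise ValueError(f"non-finite score {s!r}")
    return v


_BIOTYPE_MAP = {
    "protein_coding": Biotype.PROTEIN_CODING,
    "pseudogene": Biotype.PSEUDOGENE,
    "processed_pseudogene": Biotype.PSEUDOGENE,
    "ncrna": Biotype.NCRNA,
    "lncrna": Biotype.NCRNA,
    "lincrna": Biotype.NCRNA,
    "mirna": Biotype.NCRNA,
}

_META_GENE_COLS = ("chrom", "start", "end", "gene_id", "biotype",
                   "is_omim", "is_morbid", "hi_score", "ts_score")


def _parse_bool(cell: str) -> bool:
    return str(cell).strip().lower() in ("1", "true", "yes", "y")


def read_gene_track(path: str | Path) -> list[GeneRecord]:
    path = Path(path)
    if path.suffix.lower() in (".gff3", ".gff"):
        return _read_gene_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    score_cols = [c for c in df.columns if c not in _META_GENE_COLS]
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            iv = GenomicInterval(d["chrom"], int(d["start"]) - 1, int(d["end"]))
        except (KeyError, ValueError) as exc:
            raise TableParseError(f"{path}:{i}: {exc}") from exc
        scores = {}
        for c in score_cols:
            v = _parse_float(d[c])
            if v is not None:
                scores[c] = v
        genes.append(GeneRecord(
            iv, d.get("gene_id", f"gene_{i}"),
            _BIOTYPE_MAP.get(str(d.get("biotype", "")).lower(), Biotype.OTHER),
            _parse_bool(d.get("is_omim", "")), _parse_bool(d.get("is_morbid", "")),
            str(d.get("hi_score", "NA")) or "NA", str(d.get("ts_score", "NA")) or "NA",
            scores,
        ))
    return genes


def _gff3_attrs(field9: str) -> dict[str, str]:
    out = {}
    for kv in field9.strip().split(";"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gene_gff3(path: Path) -> list[GeneRecord]:
    genes = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise TableParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
        if cols[2] != "gene":
            continue
        attrs = _gff3_attrs(cols[8])
        iv = GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]))  # GFF3 is 1-based
        scores = {}
        for k, v in attrs.items():
            if k.startswith("score_"):
                fv = _parse_float(v)
                if fv is not None:
                    scores[k[len("score_"):]] = fv
        genes.append(GeneRecord(
            iv, attrs.get("ID", f"gene_{lineno}"),
            _BIOTYPE_MAP.get(attrs.get("biotype", "").lower(), Biotype.OTHER),
            _parse_bool(attrs.get("omim", "")), _parse_bool(attrs.get("morbid", "")),
            attrs.get("hi_score", "NA"), attrs.get("ts_score", "NA"), scores,
        ))
    return genes


def read_utr_track(path: str | Path) -> list[UTRRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    utrs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            iv = GenomicInterval(d["chrom"], int(d["start"]) - 1, int(d["end"]))
            utrs.append(UTRRecord(iv, d["utr_kind"], d.get("parent_gene", "")))
        except (KeyError, ValueError) as exc:
            raise TableParseError(f"{path}:{i}: {exc}") from exc
    return utrs


def read_site_scores(path: str | Path) -> list[SiteScoreRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    value_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    cat_cols = [c for c in value_cols if c.endswith("_pred")]
    num_cols = [c for c in value_cols if c not in cat_cols]
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            pos = int(d["pos"]) - 1  # file is 1-based
        except (KeyError, ValueError) as exc:
            raise TableParseError(f"{path}:{i}: {exc}") from exc
        nums = {}
        for c in num_cols:
            v = _parse_float(d[c])
            if v is not None:
                nums[c] = v
        cats = {c: str(d[c]).strip() for c in cat_cols if str(d[c]).strip() not in ("", ".")}
        sites.append(SiteScoreRecord(d["chrom"], pos, nums, cats))
    return sites


def read_region_track(path: str | Path) -> list[RegionRecord]:
    regions = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 4:
            raise TableParseError(f"{path}:{lineno}: expected 4 BED columns")
        iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))  # BED is 0-based
        regions.append(RegionRecord(iv, cols[3]))
    return regions


# ---------------------------------------------------------------------------
# Bundle directory layout
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "genes": "genes.tsv",
    "utrs": "utrs.tsv",
    "sites": "sites.tsv",
    "regions": "regions.bed",
}


def read_bundle(directory: str | Path) -> ResourceBundle:
    d = Path(directory)
    bundle = ResourceBundle(provenance={"dir": str(d)})
    if (d / _BUNDLE_FILES["genes"]).exists():
        bundle.genes = read_gene_track(d / _BUNDLE_FILES["genes"])
    if (d / _BUNDLE_FILES["utrs"]).exists():
        bundle.utrs = read_utr_track(d / _BUNDLE_FILES["utrs"])
    if (d / _BUNDLE_FILES["sites"]).exists():
        bundle.sites = read_site_scores(d / _BUNDLE_FILES["sites"])
    if (d / _BUNDLE_FILES["regions"]).exists():
        bundle.regions = read_region_track(d / _BUNDLE_FILES["regions"])
    return bundle


def write_bundle(bundle: ResourceBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    score_names = sorted({s for g in bundle.genes for s in g.gene_scores})
    rows = []
    for g in bundle.genes:
        row = [g.interval.chrom, g.interval.start + 1, g.interval.end, g.gene_id,
               g.biotype.value, int(g.is_omim), int(g.is_morbid), g.hi_score, g.ts_score]
        row += [g.gene_scores.get(s, ".") for s in score_names]
        rows.append(row)
    pd.DataFrame(rows, columns=list(_META_GENE_COLS) + score_names).to_csv(
        d / _BUNDLE_FILES["genes"], sep="\t", index=False)

    pd.DataFrame(
        [[u.interval.chrom, u.interval.start + 1, u.interval.end, u.utr_kind, u.parent_gene]
         for u in bundle.utrs],
        columns=["chrom", "start", "end", "utr_kind", "parent_gene"],
    ).to_csv(d / _BUNDLE_FILES["utrs"], sep="\t", index=False)

    num_names = sorted({n for s in bundle.sites for n in s.numeric_scores})
    cat_names = sorted({p for s in bundle.sites for p in s.categorical_preds})
    rows = []
    for s in bundle.sites:
        row = [s.chrom, s.pos + 1]
        row += [s.numeric_scores.get(n, ".") for n in num_names]
        row += [s.categorical_preds.get(c, ".") for c in cat_names]
        rows.append(row)
    pd.DataFrame(rows, columns=["chrom", "pos"] + num_names + cat_names).to_csv(
        d / _BUNDLE_FILES["sites"], sep="\t", index=False)

    with open(d / _BUNDLE_FILES["regions"], "w") as fh:
        for r in bundle.regions:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.region_class}\n")
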