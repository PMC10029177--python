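"""Synthetic toy genomes, annotation bundles and labelled CNV sets.

Everything the package needs for end-to-end testing is generated here, with
no downloads: a small genome, gene/UTR/site/region tracks with scores drawn
from their documented ranges, CNV sets with pathogenicity signal planted
the way real data behaves, and raw per-database tables with known
pass/fail counts for every curation rule.

The planted signal mirrors two robust empirical regularities: pathogenic
CNVs are longer than benign ones, and they are enriched for morbid /
dosage-sensitive gene content. Effects are applied monotonically across
the five tiers (benign < likely benign < uncertain < likely pathogenic <
pathogenic in expected length and morbid-gene overlap), which makes
five-tier ordering learnable. A third, weaker effect raises the density of
"Deleterious" categorical site calls inside morbid genes, so the
categorical-count features carry secondary signal.

All randomness flows from one mandatory seed through per-track
``numpy.random.SeedSequence`` spawned streams, so every artifact is
reproducible bit-for-bit and adding records to one track never perturbs
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import CNVRecord, CNVType, GenomicInterval, Label, FIVE_TIER_ORDER
from .registry import (CATEGORICAL_PRED_DEFS, CCRE_CLASSES, DOSAGE_CODES,
                       GENE_SCORE_DEFS, SITE_SCORE_DEFS)
from .resources import (Biotype, GeneRecord, RegionRecord, ResourceBundle,
                        SiteScoreRecord, UTRRecord)
from .curation import MIN_LENGTH, MAX_LENGTH


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    ``length_ratio`` multiplies the median CNV length per unit of
    pathogenicity (benign → pathogenic spans a full factor);
    ``morbid_enrichment`` is the extra probability that a pathogenic CNV is
    centred on a morbid gene; ``site_d_rate_shift`` raises the
    deleterious-call density of sites inside morbid genes. Neutral settings
    (ratio 1, enrichments 0) give label-free data.
    """

    seed: int
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("1", 10_000_000), ("2", 10_000_000)])
    n_genes: int = 400
    n_sites: int = 4000
    n_regions: int = 600
    class_counts: dict[Label, int] = field(default_factory=lambda: {
        Label.BENIGN: 300, Label.LIKELY_BENIGN: 60, Label.UNCERTAIN: 100,
        Label.LIKELY_PATHOGENIC: 80, Label.PATHOGENIC: 250})
    length_ratio: float = 4.0
    morbid_enrichment: float = 0.6
    site_d_rate_shift: float = 0.3
    base_length: float = 20_000.0  # median benign CNV length, bp
    length_sigma: float = 0.8      # log-normal spread of lengths
    noise: float = 0.25            # placement jitter, fraction of CNV length
    base_d_rate: float = 0.15      # baseline deleterious-call probability
    gene_len: tuple[int, int] = (5_000, 50_000)   # bp range per gene
    region_len: tuple[int, int] = (200, 2_000)    # bp range per cCRE
    utr_len: tuple[int, int] = (100, 2_000)       # bp range per UTR

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.length_ratio <= 0:
            raise ValueError("length_ratio must be > 0")
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")

    def _streams(self) -> dict[str, np.random.Generator]:
        names = ("genes", "utrs", "sites", "regions", "cnv_loss", "cnv_gain", "tables")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


_BIOTYPE_P = {Biotype.PROTEIN_CODING: 0.5, Biotype.PSEUDOGENE: 0.2,
              Biotype.NCRNA: 0.2, Biotype.OTHER: 0.1}
_DOSAGE_P = (0.35, 0.2, 0.15, 0.1, 0.1, 0.1)  # codes 0,1,2,3,40,NA


def generate_bundle(spec: FixtureSpec) -> ResourceBundle:
    """Toy annotation bundle: genes, UTRs, scored sites, cCRE regions."""
    rngs = spec._streams()
    genome = spec.genome
    total = sum(l for _, l in genome)
    if spec.n_genes > 0 and total // max(spec.n_genes, 1) < 200:
        raise ValueError("genome too small to place requested gene records")

    rng = rngs["genes"]
    genes: list[GeneRecord] = []
    chrom_names = [c for c, _ in genome]
    chrom_lens = dict(genome)
    weights = np.array([l for _, l in genome], dtype=float) / total
    bts = list(_BIOTYPE_P)
    for i in range(spec.n_genes):
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        lo, hi = spec.gene_len
        length = int(rng.integers(lo, min(hi, chrom_lens[chrom] // 2)))
        start = int(rng.integers(0, max(1, chrom_lens[chrom] - length)))
        biotype = bts[rng.choice(len(bts), p=list(_BIOTYPE_P.values()))]
        is_morbid = bool(rng.random() < 0.10)
        is_omim = is_morbid or bool(rng.random() < 0.10)
        hi = DOSAGE_CODES[rng.choice(len(DOSAGE_CODES), p=_DOSAGE_P)]
        ts = DOSAGE_CODES[rng.choice(len(DOSAGE_CODES), p=_DOSAGE_P)]
        scores = {}
        for name, (_kind, (lo, hi_r)) in GENE_SCORE_DEFS.items():
            if rng.random() >= 0.1:  # ~10% missing per gene score
                scores[name] = float(rng.uniform(lo, hi_r))
        genes.append(GeneRecord(GenomicInterval(chrom, start, start + length),
                                f"G{i:04d}", biotype, is_omim, is_morbid,
                                hi, ts, scores))

    rng = rngs["utrs"]
    utrs: list[UTRRecord] = []
    for g in genes:
        if g.biotype is not Biotype.PROTEIN_CODING:
            continue
        span = g.interval.length
        for kind, anchor in (("five_prime", g.interval.start),
                             ("three_prime", g.interval.end)):
            ulen = int(rng.integers(spec.utr_len[0],
                                    max(spec.utr_len[0] + 1,
                                        min(spec.utr_len[1], span))))
            if kind == "five_prime":
                iv = GenomicInterval(g.interval.chrom, anchor, anchor + ulen)
            else:
                iv = GenomicInterval(g.interval.chrom, anchor - ulen, anchor)
            utrs.append(UTRRecord(iv, kind, g.gene_id))

    # site positions; D-call rate boosted inside morbid genes
    rng = rngs["sites"]
    morbid_ivs = [g.interval for g in genes if g.is_morbid]
    sites: list[SiteScoreRecord] = []
    for i in range(spec.n_sites):
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        pos = int(rng.integers(0, chrom_lens[chrom]))
        in_morbid = any(iv.chrom == chrom and iv.start <= pos < iv.end
                        for iv in morbid_ivs)
        d_rate = spec.base_d_rate + (spec.site_d_rate_shift if in_morbid else 0.0)
        nums = {}
        for name, (_kind, (lo, hi_r)) in SITE_SCORE_DEFS.items():
            if rng.random() >= 0.15:  # ~15% missing per site score
                nums[name] = float(rng.uniform(lo, hi_r))
        cats = {}
        for pred, alphabet in CATEGORICAL_PRED_DEFS.items():
            if rng.random() < 0.1:
                continue  # missing call
            if rng.random() < d_rate:
                cats[pred] = "D"
            else:
                benign_codes = [c for c in alphabet if c != "D"]
                cats[pred] = benign_codes[rng.choice(len(benign_codes))]
        sites.append(SiteScoreRecord(chrom, pos, nums, cats))

    rng = rngs["regions"]
    regions: list[RegionRecord] = []
    for i in range(spec.n_regions):
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        length = int(rng.integers(*spec.region_len))
        start = int(rng.integers(0, max(1, chrom_lens[chrom] - length)))
        regions.append(RegionRecord(GenomicInterval(chrom, start, start + length),
                                    CCRE_CLASSES[rng.choice(len(CCRE_CLASSES))]))

    return ResourceBundle(genes, utrs, sites, regions,
                          provenance={"generator": f"synthetic seed={spec.seed}"})


#: pathogenicity interpolation factor per tier
_TIER_T = {Label.BENIGN: 0.0, Label.LIKELY_BENIGN: 0.25, Label.UNCERTAIN: 0.5,
           Label.LIKELY_PATHOGENIC: 0.75, Label.PATHOGENIC: 1.0}


def generate_cnv_set(spec: FixtureSpec, bundle: ResourceBundle,
                     cnv_types: tuple[CNVType, ...] = (CNVType.LOSS, CNVType.GAIN)
                     ) -> list[CNVRecord]:
    """Labelled CNVs with planted monotone effects, per type independently."""
    if not spec.class_counts:
        raise ValueError("class_counts is empty")
    rngs = spec._streams()
    chrom_names = [c for c, _ in spec.genome]
    chrom_lens = dict(spec.genome)
    total = sum(chrom_lens.values())
    weights = np.array([chrom_lens[c] for c in chrom_names], dtype=float) / total
    morbid = [g.interval for g in bundle.genes if g.is_morbid]
    records: list[CNVRecord] = []

    for cnv_type in cnv_types:
        rng = rngs[f"cnv_{cnv_type.value}"]
        for label in FIVE_TIER_ORDER:
            n = spec.class_counts.get(label, 0)
            t = _TIER_T[label]
            median_len = spec.base_length * spec.length_ratio ** t
            for i in range(n):
                length = int(np.exp(rng.normal(np.log(median_len), spec.length_sigma)))
                length = int(np.clip(length, MIN_LENGTH, MAX_LENGTH))
                if morbid and rng.random() < spec.morbid_enrichment * t:
                    iv = morbid[rng.choice(len(morbid))]
                    centre = (iv.start + iv.end) // 2
                    centre += int(rng.normal(0, spec.noise * length))
                    chrom = iv.chrom
                    length = min(length, chrom_lens[chrom])
                    start = centre - length // 2
                else:
                    chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
                    length = min(length, chrom_lens[chrom])
                    start = int(rng.integers(0, max(1, chrom_lens[chrom] - length + 1)))
                start = int(np.clip(start, 0, chrom_lens[chrom] - length))
                records.append(CNVRecord(
                    GenomicInterval(chrom, start, start + length), cnv_type, label,
                    "synthetic", f"sim_{cnv_type.value}_{label.value}_{i:05d}"))
    return records


# ---------------------------------------------------------------------------
# Raw per-database tables with a ground-truth manifest
# ---------------------------------------------------------------------------

def generate_raw_db_tables(seed: int, outdir: Optional[str | Path] = None
                           ) -> tuple[dict[str, pd.DataFrame], dict]:
    """One table per source dialect, each with known numbers of rows
    passing/failing every curation predicate, plus planted merge/dedup
    cases, recorded in the returned manifest.

    Coordinates in the tables are 1-based inclusive (the header-dialect
    convention). The seed only shuffles row order — the planted cases and
    counts are fixed by construction.
    """
    rng = np.random.default_rng(seed)

    def iv(start0: int, length: int) -> tuple[int, int]:
        # 1-based inclusive coordinates for a 0-based [start0, start0+length)
        return start0 + 1, start0 + length

    clinvar_rows = []
    # 3 fully valid rows (distinct loci, no merge interactions)
    for k, (typ, sig) in enumerate([("copy number loss", "pathogenic"),
                                    ("duplication", "benign"),
                                    ("deletion", "uncertain significance")]):
        s, e = iv(1_000_000 + 300_000 * k, 10_000)
        clinvar_rows.append(("1", s, e, typ, sig,
                             "criteria provided, multiple submitters, no conflicts",
                             f"cv_ok_{k}"))
    # excluded: bad review status; unsupported significance
    s, e = iv(2_000_000, 10_000)
    clinvar_rows.append(("1", s, e, "deletion", "pathogenic",
                         "no assertion criteria provided", "cv_bad_review"))
    s, e = iv(2_100_000, 10_000)
    clinvar_rows.append(("1", s, e, "deletion", "drug response",
                         "criteria provided, single submitter", "cv_bad_sig"))
    # planted conflicting pair, loss, reciprocal overlap 0.75 with merge rule
    s, e = iv(3_000_000, 100_000)
    clinvar_rows.append(("1", s, e, "copy number loss", "pathogenic",
                         "reviewed by expert panel", "cv_conflict_a"))
    s, e = iv(3_025_000, 75_000)  # overlap 75k / lengths 100k,75k -> RO 0.75
    clinvar_rows.append(("1", s, e, "copy number loss", "benign",
                         "practice guideline", "cv_conflict_b"))
    # planted identical-coordinate multi-significance pair (gain)
    s, e = iv(4_000_000, 50_000)
    clinvar_rows.append(("1", s, e, "copy number gain", "benign",
                         "criteria provided, single submitter", "cv_multi_a"))
    clinvar_rows.append(("1", s, e, "copy number gain", "likely benign",
                         "criteria provided, single submitter", "cv_multi_b"))
    # planted length-rule rows: 40 bp and 6 Mb
    s, e = iv(5_000_000, 40)
    clinvar_rows.append(("1", s, e, "deletion", "benign",
                         "criteria provided, single submitter", "cv_short"))
    s, e = iv(1_000_000, 6_000_000)
    clinvar_rows.append(("2", s, e, "duplication", "pathogenic",
                         "criteria provided, single submitter", "cv_long"))
    clinvar = pd.DataFrame(clinvar_rows, columns=[
        "chrom", "start", "end", "type", "clinical_significance",
        "review_status", "id"])

    dbvar_rows = []
    for k, sig in enumerate(["Pathogenic", "Likely pathogenic",
                             "pathogenic/likely pathogenic"]):
        s, e = iv(6_000_000 + 200_000 * k, 20_000)
        dbvar_rows.append(("1", s, e, "copy number loss", sig, f"dv_ok_{k}"))
    s, e = iv(6_800_000, 20_000)
    dbvar_rows.append(("1", s, e, "copy number loss", "Benign", "dv_benign"))
    dbvar = pd.DataFrame(dbvar_rows, columns=[
        "chrom", "start", "end", "type", "clinical_significance", "id"])

    clingen_rows = []
    s, e = iv(7_000_000, 80_000)
    clingen_rows.append(("1", s, e, "3", "NA", "cg_hi3"))     # pathogenic loss
    s, e = iv(7_200_000, 80_000)
    clingen_rows.append(("1", s, e, "NA", "3", "cg_ts3"))     # pathogenic gain
    s, e = iv(7_400_000, 80_000)
    clingen_rows.append(("1", s, e, "40", "40", "cg_benign"))  # benign loss + gain
    s, e = iv(7_600_000, 80_000)
    clingen_rows.append(("1", s, e, "1", "2", "cg_insufficient"))  # excluded
    clingen = pd.DataFrame(clingen_rows, columns=[
        "chrom", "start", "end", "HI_score", "TS_score", "id"])

    dgv_rows = []
    s, e = iv(2_000_000, 30_000)
    dgv_rows.append(("2", s, e, "loss", 2500, "dgv_ok"))
    s, e = iv(2_200_000, 30_000)
    dgv_rows.append(("2", s, e, "loss", 2000, "dgv_edge_ok"))   # boundary retained
    s, e = iv(2_400_000, 30_000)
    dgv_rows.append(("2", s, e, "gain", 1999, "dgv_too_few"))   # excluded
    dgv = pd.DataFrame(dgv_rows, columns=[
        "chrom", "start", "end", "type", "sample_count", "id"])

    decipher_rows = []
    s, e = iv(3_000_000, 25_000)
    decipher_rows.append(("2", s, e, "loss", 12, 0.05, "dc_ok"))
    s, e = iv(3_200_000, 25_000)
    decipher_rows.append(("2", s, e, "loss", 0, 0.05, "dc_no_obs"))     # excluded
    s, e = iv(3_400_000, 25_000)
    decipher_rows.append(("2", s, e, "gain", 5, 0.005, "dc_rare"))      # excluded
    decipher = pd.DataFrame(decipher_rows, columns=[
        "chrom", "start", "end", "type", "observations", "frequency", "id"])

    gnomad_rows = []
    s, e = iv(4_000_000, 15_000)
    gnomad_rows.append(("2", s, e, "DEL", "PASS", 0.05, 5000, "gn_ok"))
    s, e = iv(4_200_000, 15_000)
    gnomad_rows.append(("2", s, e, "INS", "PASS", 0.05, 5000, "gn_ins"))      # skipped at parse
    s, e = iv(4_400_000, 15_000)
    gnomad_rows.append(("2", s, e, "DUP", "LOW_QUAL", 0.05, 5000, "gn_filter"))  # excluded
    s, e = iv(4_600_000, 15_000)
    gnomad_rows.append(("2", s, e, "DUP", "PASS", 0.005, 5000, "gn_rare"))    # excluded
    s, e = iv(4_800_000, 15_000)
    gnomad_rows.append(("2", s, e, "DUP", "PASS", 0.05, 1500, "gn_small_an"))  # excluded
    gnomad = pd.DataFrame(gnomad_rows, columns=[
        "chrom", "start", "end", "SVTYPE", "FILTER", "AF", "AN", "id"])

    # validation-set table (generic BED, 0-based): a concordant pair at
    # RO ~0.95 (keep the shorter), a concordant pair at 0.80 (keep both),
    # a conflicting pair at >=0.70 (drop both), plus independent records
    val_rows = [
        ("1", 100_000, 101_000, "DEL", "pathogenic", "val_short"),
        ("1", 100_000, 101_050, "DEL", "pathogenic", "val_long"),   # RO 1000/1050≈0.952
        ("1", 300_000, 310_000, "DUP", "benign", "val_a80"),
        ("1", 302_000, 312_000, "DUP", "benign", "val_b80"),        # RO 8000/10000=0.80
        ("1", 500_000, 600_000, "DEL", "pathogenic", "val_confl_a"),
        ("1", 510_000, 600_000, "DEL", "benign", "val_confl_b"),    # RO 0.9, conflict
        ("2", 700_000, 705_000, "DUP", "benign", "val_solo"),
    ]
    validation = pd.DataFrame(val_rows, columns=[
        "chrom", "start", "end", "type", "label", "id"])

    tables = {"clinvar": clinvar, "dbvar": dbvar, "clingen_region": clingen,
              "dgv": dgv, "decipher": decipher, "gnomad": gnomad,
              "validation_bed": validation}
    # shuffle row order only; contents are fixed by construction
    for name, df in tables.items():
        tables[name] = df.sample(frac=1.0, random_state=int(rng.integers(2**31))
                                 ).reset_index(drop=True)

    manifest = {
        "source_filter": {
            # rows surviving each per-database filter
            "clinvar": {"input": len(clinvar), "retained": 9},
            "dbvar": {"input": len(dbvar), "retained": 3},
            # 3 of 4 regions are dosage sensitive; they emit 4 CNVs
            "clingen_region": {"input": len(clingen), "retained": 3,
                               "emitted_cnvs": 4},
            "dgv": {"input": len(dgv), "retained": 2},
            "decipher": {"input": len(decipher), "retained": 1},
            # the INS row is skipped at parse time, before filtering
            "gnomad": {"input": len(gnomad), "parsed": 4, "retained": 1},
        },
        "merge": {
            "input": 9 + 3 + 4 + 2 + 1 + 1,
            "length_removed": 2,        # cv_short (40 bp), cv_long (6 Mb)
            "conflict_removed": 2,      # cv_conflict_a/b at RO 0.75
            "multilabel_removed": 2,    # cv_multi_a/b identical coordinates
            "retained": 14,
        },
        "validation": {
            "input": len(validation),
            "conflict_removed": 2,      # val_confl_a/b
            "redundant_removed": 1,     # val_long (shorter val_short kept)
            "retained": 4,
            "kept_ids": ["val_a80", "val_b80", "val_short", "val_solo"],
        },
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            if name == "validation_bed":
                df.to_csv(out / "validation.bed", sep="\t", index=False, header=False)
            else:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        import json
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return tables, manifest
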