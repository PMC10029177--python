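import warnings

import pytest

from cnvpatho.core import CNVRecord, CNVType, GenomicInterval, Label
from cnvpatho.registry import default_registry
from cnvpatho.resources import (Biotype, GeneRecord, RegionRecord,
                                ResourceBundle, SiteScoreRecord, UTRRecord)
from cnvpatho.simulate import FixtureSpec, generate_bundle, generate_cnv_set

warnings.filterwarnings("ignore", message="feature .* entirely missing")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def hand_bundle():
    """Tiny hand-built bundle with known exact feature values."""
    genes = [
        GeneRecord(GenomicInterval("1", 100, 200), "gA", Biotype.PROTEIN_CODING,
                   is_omim=True, is_morbid=True, hi_score="3", ts_score="NA",
                   gene_scores={"pLI": 0.9, "LOEUF": 0.5, "GHIS": 0.6}),
        GeneRecord(GenomicInterval("1", 150, 300), "gB", Biotype.PROTEIN_CODING,
                   is_omim=True, is_morbid=False, hi_score="0", ts_score="40",
                   gene_scores={"pLI": 0.2, "LOEUF": 1.5, "GHIS": 0.4}),
        GeneRecord(GenomicInterval("1", 400, 500), "gC", Biotype.PSEUDOGENE,
                   gene_scores={"pLI": 0.1}),
        GeneRecord(GenomicInterval("2", 100, 200), "gD", Biotype.NCRNA),
    ]
    utrs = [
        UTRRecord(GenomicInterval("1", 100, 120), "five_prime", "gA"),
        UTRRecord(GenomicInterval("1", 180, 200), "three_prime", "gA"),
        UTRRecord(GenomicInterval("1", 280, 300), "three_prime", "gB"),
    ]
    sites = [
        SiteScoreRecord("1", 120, {"REVEL": 0.1, "SIFT": 0.8},
                        {"LRT_pred": "D", "SIFT_pred": "T"}),
        SiteScoreRecord("1", 180, {"REVEL": 0.7, "SIFT": 0.2},
                        {"LRT_pred": "D"}),
        SiteScoreRecord("1", 250, {"REVEL": 0.4}, {"LRT_pred": "N"}),
        SiteScoreRecord("1", 450, {"REVEL": 0.0, "SIFT": 0.9},
                        {"SIFT_pred": "D"}),
        SiteScoreRecord("2", 150, {"REVEL": 0.95},
                        {"LRT_pred": "D", "SIFT_pred": "T",
                         "Polyphen2_HDIV_pred": "B", "Polyphen2_HVAR_pred": "B",
                         "FATHMM_pred": "T", "MutationTaster_pred": "N",
                         "MetaSVM_pred": "T"}),
    ]
    regions = [
        RegionRecord(GenomicInterval("1", 110, 130), "dELS"),
        RegionRecord(GenomicInterval("1", 240, 260), "PLS"),
        RegionRecord(GenomicInterval("2", 140, 160), "CTCF_bound"),
    ]
    return ResourceBundle(genes, utrs, sites, regions)


@pytest.fixture(scope="session")
def toy_spec():
    """Small toy genome for brute-force oracle comparisons (<=100 kb)."""
    return FixtureSpec(
        seed=11,
        genome=[("1", 60_000), ("2", 40_000)],
        n_genes=60, n_sites=120, n_regions=40,
        base_length=2_000.0, gene_len=(500, 5_000),
        class_counts={Label.BENIGN: 30, Label.UNCERTAIN: 10,
                      Label.PATHOGENIC: 30},
    )


@pytest.fixture(scope="session")
def toy_bundle(toy_spec):
    return generate_bundle(toy_spec)


@pytest.fixture(scope="session")
def toy_cnvs(toy_spec, toy_bundle):
    return generate_cnv_set(toy_spec, toy_bundle)


def make_cnv(chrom="1", start=0, end=1000, cnv_type=CNVType.LOSS,
             label=Label.BENIGN, rid="r1"):
    return CNVRecord(GenomicInterval(chrom, start, end), cnv_type, label,
                     "test", rid)
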