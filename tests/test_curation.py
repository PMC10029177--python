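import numpy as np
import pytest

from cnvpatho.core import CNVType, Label, reciprocal_overlap
from cnvpatho.curation import (apply_source_filter, dedup_validation,
                               merge_nonredundant)
from cnvpatho.resources import read_cnv_table
from cnvpatho.simulate import generate_raw_db_tables

from conftest import make_cnv


def _record(rid, start, end, label, cnv_type=CNVType.LOSS, attrs=None):
    r = make_cnv("1", start, end, cnv_type, label, rid)
    r.attrs = attrs or {}
    return r


# ---------------------------------------------------------------------------
# per-source filters
# ---------------------------------------------------------------------------

def test_gnomad_low_frequency_excluded():
    ok = _record("a", 0, 1000, Label.UNKNOWN,
                 attrs={"FILTER": "PASS", "AF": "0.05", "AN": "5000"})
    rare = _record("b", 0, 1000, Label.UNKNOWN,
                   attrs={"FILTER": "PASS", "AF": "0.005", "AN": "5000"})
    kept, rep = apply_source_filter([ok, rare], "gnomad")
    assert [r.record_id for r in kept] == ["a"]
    assert kept[0].label is Label.BENIGN
    assert rep.exclusions == {"af_le_1pct": 1}
    assert rep.check_conserved()


def test_clingen_hi3_becomes_pathogenic_loss_and_ts3_gain():
    hi3 = _record("r1", 0, 1000, Label.UNKNOWN, attrs={"HI_score": "3", "TS_score": "NA"})
    ts3 = _record("r2", 0, 1000, Label.UNKNOWN, attrs={"HI_score": "NA", "TS_score": "3"})
    both40 = _record("r3", 0, 1000, Label.UNKNOWN, attrs={"HI_score": "40", "TS_score": "40"})
    weak = _record("r4", 0, 1000, Label.UNKNOWN, attrs={"HI_score": "1", "TS_score": "2"})
    kept, rep = apply_source_filter([hi3, ts3, both40, weak], "clingen_region")
    by_id = {r.record_id: r for r in kept}
    assert by_id["r1_HI"].cnv_type is CNVType.LOSS
    assert by_id["r1_HI"].label is Label.PATHOGENIC
    assert by_id["r2_TS"].cnv_type is CNVType.GAIN
    assert by_id["r2_TS"].label is Label.PATHOGENIC
    assert by_id["r3_HI"].label is Label.BENIGN and by_id["r3_TS"].label is Label.BENIGN
    assert rep.exclusions == {"not_dosage_sensitive": 1}
    assert rep.check_conserved()


def test_dgv_sample_count_threshold():
    big = _record("a", 0, 1000, Label.UNKNOWN, attrs={"sample_count": "2500"})
    edge = _record("b", 0, 1000, Label.UNKNOWN, attrs={"sample_count": "2000"})
    small = _record("c", 0, 1000, Label.UNKNOWN, attrs={"sample_count": "1999"})
    kept, rep = apply_source_filter([big, edge, small], "dgv")
    assert [r.record_id for r in kept] == ["a", "b"]
    assert all(r.label is Label.BENIGN for r in kept)
    assert rep.exclusions == {"sample_count_lt_2000": 1}


def test_decipher_requires_observations_and_common_frequency():
    ok = _record("a", 0, 1000, Label.UNKNOWN, attrs={"observations": "5", "frequency": "0.05"})
    none = _record("b", 0, 1000, Label.UNKNOWN, attrs={"observations": "0", "frequency": "0.05"})
    rare = _record("c", 0, 1000, Label.UNKNOWN, attrs={"observations": "5", "frequency": "0.001"})
    kept, rep = apply_source_filter([ok, none, rare], "decipher")
    assert [r.record_id for r in kept] == ["a"]
    assert rep.exclusions == {"no_observations": 1, "frequency_le_1pct": 1}


def test_clinvar_review_status_gate():
    ok = _record("a", 0, 1000, Label.PATHOGENIC,
                 attrs={"review_status": "reviewed by expert panel"})
    bad = _record("b", 0, 1000, Label.PATHOGENIC,
                  attrs={"review_status": "no assertion criteria provided"})
    unk = _record("c", 0, 1000, Label.UNKNOWN,
                  attrs={"review_status": "practice guideline"})
    kept, rep = apply_source_filter([ok, bad, unk], "clinvar")
    assert [r.record_id for r in kept] == ["a"]
    assert rep.exclusions == {"review_status": 1, "clinical_significance": 1}


def test_dbvar_keeps_only_pathogenic_tiers():
    p = _record("a", 0, 1000, Label.PATHOGENIC)
    lp = _record("b", 0, 1000, Label.LIKELY_PATHOGENIC)
    b = _record("c", 0, 1000, Label.BENIGN)
    kept, _ = apply_source_filter([p, lp, b], "dbvar")
    assert [r.record_id for r in kept] == ["a", "b"]


def test_unknown_source_rejected():
    with pytest.raises(ValueError, match="unknown source"):
        apply_source_filter([], "ucsc")


# ---------------------------------------------------------------------------
# non-redundant merge
# ---------------------------------------------------------------------------

def test_merge_length_filter():
    short = _record("s", 0, 40, Label.BENIGN)
    ok = _record("m", 10_000, 20_000, Label.BENIGN)
    long = _record("l", 0, 6_000_000, Label.BENIGN)
    kept, rep = merge_nonredundant([[short, ok, long]])
    assert [r.record_id for r in kept] == ["m"]
    assert rep.exclusions["length_out_of_range"] == 2
    assert rep.check_conserved()


def test_merge_conflicting_overlap_removes_both():
    # overlap 900 / lengths 1000, 900 -> reciprocal overlap 0.9
    benign = _record("b", 0, 1000, Label.BENIGN)
    patho = _record("p", 100, 1000, Label.PATHOGENIC)
    assert reciprocal_overlap(benign.interval, patho.interval) == 0.9
    kept, rep = merge_nonredundant([[benign], [patho]])
    assert kept == []
    assert rep.exclusions["conflict_ro70"] == 2


def test_merge_concordant_overlap_retained():
    a = _record("a", 0, 1000, Label.BENIGN)
    b = _record("b", 100, 1000, Label.BENIGN)
    kept, _ = merge_nonredundant([[a], [b]])
    assert len(kept) == 2


def test_vus_conflicts_with_neither_group():
    vus = _record("v", 0, 1000, Label.UNCERTAIN)
    patho = _record("p", 0, 1000, Label.PATHOGENIC)
    kept, _ = merge_nonredundant([[vus], [patho]])
    # identical coordinates with two labels -> multi-significance rule instead
    assert kept == []
    vus2 = _record("v", 0, 1000, Label.UNCERTAIN)
    patho2 = _record("p", 100, 1000, Label.PATHOGENIC)  # RO 0.9, no conflict
    kept2, _ = merge_nonredundant([[vus2], [patho2]])
    assert len(kept2) == 2


def test_cross_type_pairs_never_compared():
    benign = _record("b", 0, 1000, Label.BENIGN, CNVType.LOSS)
    patho = _record("p", 0, 1000, Label.PATHOGENIC, CNVType.GAIN)
    kept, _ = merge_nonredundant([[benign, patho]])
    assert len(kept) == 2


def test_merge_order_independent(toy_cnvs):
    rng = np.random.default_rng(0)
    base = list(toy_cnvs)
    kept1, _ = merge_nonredundant([base])
    shuffled = [base[i] for i in rng.permutation(len(base))]
    kept2, _ = merge_nonredundant([shuffled])
    assert [r.record_id for r in kept1] == [r.record_id for r in kept2]
    # invariant: no surviving same-type pair conflicts at >= 0.70
    for i, a in enumerate(kept1):
        for b in kept1[i + 1:]:
            if a.cnv_type is b.cnv_type:
                from cnvpatho.core import labels_conflict
                assert not (labels_conflict(a.label, b.label) and
                            reciprocal_overlap(a.interval, b.interval) >= 0.70)


# ---------------------------------------------------------------------------
# validation dedup
# ---------------------------------------------------------------------------

def test_dedup_keeps_shorter_of_90pct_pair():
    short = _record("short", 0, 1000, Label.PATHOGENIC)
    long = _record("long", 0, 1200, Label.PATHOGENIC)  # RO 1000/1200 ≈ 0.83
    # need >= 0.90: use 1000 vs 1050
    long = _record("long", 0, 1050, Label.PATHOGENIC)
    kept, rep = dedup_validation([long, short])
    assert [r.record_id for r in kept] == ["short"]
    assert rep.exclusions["redundant_ro90"] == 1


def test_dedup_below_90pct_concordant_pair_kept():
    a = _record("a", 0, 10_000, Label.BENIGN)
    b = _record("b", 2_000, 12_000, Label.BENIGN)  # RO 0.8
    kept, _ = dedup_validation([a, b])
    assert len(kept) == 2


def test_dedup_equal_length_tie_breaks_by_record_id():
    a = _record("zzz", 0, 1000, Label.BENIGN)
    b = _record("aaa", 10, 1010, Label.BENIGN)  # RO 0.99, same length
    kept, _ = dedup_validation([a, b])
    assert [r.record_id for r in kept] == ["aaa"]


def test_dedup_applies_conflict_rule_first():
    p = _record("p", 0, 1000, Label.PATHOGENIC)
    b = _record("b", 50, 1000, Label.BENIGN)  # RO 0.95, conflicting
    kept, rep = dedup_validation([p, b])
    assert kept == []
    assert rep.exclusions["conflict_ro70"] == 2


# ---------------------------------------------------------------------------
# generated raw tables against their manifest
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def raw_tables(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("raw")
    tables, manifest = generate_raw_db_tables(seed=11, outdir=outdir)
    return outdir, tables, manifest


def test_source_filters_match_manifest(raw_tables):
    outdir, _, manifest = raw_tables
    filtered = {}
    for source, expect in manifest["source_filter"].items():
        records = read_cnv_table(outdir / f"{source}.tsv", source)
        kept, rep = apply_source_filter(records, source)
        assert rep.check_conserved(), source
        if source == "clingen_region":
            assert rep.n_retained == expect["retained"]
            assert len(kept) == expect["emitted_cnvs"]
        else:
            assert len(kept) == expect["retained"], source
        filtered[source] = kept
    merged, rep = merge_nonredundant(list(filtered.values()))
    expect = manifest["merge"]
    assert rep.n_input == expect["input"]
    assert rep.exclusions["length_out_of_range"] == expect["length_removed"]
    assert rep.exclusions["conflict_ro70"] == expect["conflict_removed"]
    assert rep.exclusions["multiple_significance"] == expect["multilabel_removed"]
    assert len(merged) == expect["retained"]


def test_validation_dedup_matches_manifest(raw_tables):
    outdir, _, manifest = raw_tables
    records = read_cnv_table(outdir / "validation.bed", "generic_bed")
    kept, rep = dedup_validation(records)
    expect = manifest["validation"]
    assert rep.exclusions["conflict_ro70"] == expect["conflict_removed"]
    assert rep.exclusions["redundant_ro90"] == expect["redundant_removed"]
    assert sorted(r.record_id for r in kept) == sorted(expect["kept_ids"])
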