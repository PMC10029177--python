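"""Feature registry: the ordered, direction-aware feature scheme.

Every feature the annotation engine computes is declared here as a
:class:`FeatureDef` — its aggregation kind (max / min / mean / count /
length), the track it draws from, and the score or category it selects.
Aggregation direction (whether a score is summarized by its maximum or its
minimum over a CNV) encodes deleterious significance: scores where higher is
more deleterious aggregate by max, scores where lower is more deleterious by
min, direction-less scores by mean. Direction is always declared, never
inferred from data.

The default registry has exactly 79 entries. The composition honours every
feature named in the underlying scheme (length, pLI_max, LOEUF_min,
GHIS_mean, Episcore_max, GERP_RS_max, UTR and biotype counts, cCRE class
counts, dosage-sensitivity counts, categorical-prediction counts); the tail
entries use standard dbNSFP / gnomAD score names and are a documented,
user-overridable stand-in — load a config file to replace them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

KINDS = {"max", "min", "mean", "count", "length"}
SOURCES = {
    "gene_scores",
    "site_numeric",
    "site_categorical",
    "genes",
    "utr",
    "regions",
    "dosage",
    "omim_morbid",
    "cnv_itself",
}

_NUMERIC_SOURCES = {"gene_scores", "site_numeric"}
_COUNT_SOURCES = {"site_categorical", "genes", "utr", "regions", "dosage", "omim_morbid"}


@dataclass(frozen=True)
class FeatureDef:
    """One feature: name, aggregation kind, source track, selector key.

    ``selector`` names the score column (numeric sources), predictor
    (site_categorical), biotype (genes), UTR kind (utr), cCRE class
    (regions), HI/TS (dosage) or omim/morbid flag. ``category`` is the
    category code counted for site_categorical features, or the dosage
    score code for dosage features.
    """

    name: str
    kind: str
    source: str
    selector: str = ""
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.source not in SOURCES:
            raise ValueError(f"{self.name}: unknown source {self.source!r}")
        if self.kind in {"max", "min", "mean"} and self.source not in _NUMERIC_SOURCES:
            raise ValueError(
                f"{self.name}: kind {self.kind!r} requires a numeric source, got {self.source!r}"
            )
        if self.kind == "count" and self.source not in _COUNT_SOURCES:
            raise ValueError(
                f"{self.name}: kind 'count' requires a countable source, got {self.source!r}"
            )
        if self.kind == "length" and self.source != "cnv_itself":
            raise ValueError(f"{self.name}: kind 'length' requires source cnv_itself")
        if self.source == "site_categorical" and self.kind == "count" and not self.category:
            raise ValueError(f"{self.name}: site_categorical count needs a category code")


class FeatureRegistry:
    """Ordered collection of FeatureDefs; order fixes feature-matrix columns."""

    def __init__(self, defs: Iterable[FeatureDef]):
        self.defs: list[FeatureDef] = list(defs)
        names = [d.name for d in self.defs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        self._index = {d.name: i for i, d in enumerate(self.defs)}

    def __len__(self) -> int:
        return len(self.defs)

    def __iter__(self):
        return iter(self.defs)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> FeatureDef:
        return self.defs[self._index[name]]

    def index_of(self, name: str) -> int:
        return self._index[name]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def fingerprint(self) -> str:
        """Stable hash of the full definition list; stored in trained models."""
        h = hashlib.sha256()
        for d in self.defs:
            h.update(
                f"{d.name}\t{d.kind}\t{d.source}\t{d.selector}\t{d.category or ''}\n".encode()
            )
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Default registry composition (79 entries)
# ---------------------------------------------------------------------------

# gene-level numeric scores: name -> (direction kind, documented range)
GENE_SCORE_DEFS: dict[str, tuple[str, tuple[float, float]]] = {
    "pLI": ("max", (0.0, 1.0)),
    "Episcore": ("max", (0.0, 1.0)),
    "HIPred": ("max", (0.0, 1.0)),
    "LOEUF": ("min", (0.0, 9.0)),
    "RVIS": ("min", (0.0, 9.0)),
    "oe_lof": ("min", (0.0, 2.0)),
    "oe_mis": ("min", (0.0, 2.0)),
    "oe_syn": ("min", (0.0, 2.0)),
    "HI_index": ("min", (0.0, 1.0)),
    "GHIS": ("mean", (0.0, 1.0)),
}

# site-level numeric scores: name -> (direction kind, documented range)
SITE_SCORE_DEFS: dict[str, tuple[str, tuple[float, float]]] = {
    "REVEL": ("max", (0.0, 1.0)),
    "GERP_RS": ("max", (-12.0, 6.2)),
    "CADD_phred": ("max", (0.0, 99.0)),
    "DANN": ("max", (0.0, 1.0)),
    "MetaSVM_score": ("max", (-2.0, 3.0)),
    "MetaLR_score": ("max", (0.0, 1.0)),
    "M_CAP": ("max", (0.0, 1.0)),
    "MutationAssessor": ("max", (-6.0, 6.0)),
    "MutationTaster": ("max", (0.0, 1.0)),
    "VEST4": ("max", (0.0, 1.0)),
    "phyloP100way": ("max", (-20.0, 10.0)),
    "phyloP20way": ("max", (-20.0, 10.0)),
    "phastCons100way": ("max", (0.0, 1.0)),
    "phastCons20way": ("max", (0.0, 1.0)),
    "SiPhy": ("max", (0.0, 40.0)),
    "GenoCanyon": ("max", (0.0, 1.0)),
    "fitCons": ("max", (0.0, 1.0)),
    "LRT_score": ("max", (0.0, 1.0)),
    "Eigen": ("max", (-5.0, 10.0)),
    "PrimateAI": ("max", (0.0, 1.0)),
    "MVP": ("max", (0.0, 1.0)),
    "SIFT": ("min", (0.0, 1.0)),
    "SIFT4G": ("min", (0.0, 1.0)),
    "FATHMM": ("min", (-17.0, 10.0)),
    "PROVEAN": ("min", (-14.0, 14.0)),
    "CDTS": ("mean", (-20.0, 20.0)),
}

# categorical predictors: predictor -> alphabet of category codes
CATEGORICAL_PRED_DEFS: dict[str, tuple[str, ...]] = {
    "SIFT_pred": ("D", "T"),
    "LRT_pred": ("D", "N", "U"),
    "Polyphen2_HDIV_pred": ("D", "P", "B"),
    "Polyphen2_HVAR_pred": ("D", "P", "B"),
    "FATHMM_pred": ("D", "T"),
    "MutationTaster_pred": ("D", "N"),
    "MetaSVM_pred": ("D", "T"),
}

CCRE_CLASSES = ("CTCF_bound", "CTCF_only", "dELS", "DNase_H3K4me3", "pELS", "PLS")
DOSAGE_CODES = ("0", "1", "2", "3", "40", "NA")
BIOTYPES = ("protein_coding", "pseudogene", "ncRNA", "other")


def _default_defs() -> list[FeatureDef]:
    defs: list[FeatureDef] = [FeatureDef("length", "length", "cnv_itself")]
    # direction-aware numeric aggregations: max first, then min, then mean,
    # genes before sites inside each block
    for block in ("max", "min", "mean"):
        for name, (kind, _rng) in GENE_SCORE_DEFS.items():
            if kind == block:
                defs.append(FeatureDef(f"{name}_{kind}", kind, "gene_scores", name))
        for name, (kind, _rng) in SITE_SCORE_DEFS.items():
            if kind == block:
                defs.append(FeatureDef(f"{name}_{kind}", kind, "site_numeric", name))
    # element counts
    defs += [
        FeatureDef("protein_coding_gene_num", "count", "genes", "protein_coding"),
        FeatureDef("pseudogene_num", "count", "genes", "pseudogene"),
        FeatureDef("ncRNA_num", "count", "genes", "ncRNA"),
        FeatureDef("three_prime_UTR_num", "count", "utr", "three_prime"),
        FeatureDef("five_prime_UTR_num", "count", "utr", "five_prime"),
        FeatureDef("OMIM_gene_num", "count", "omim_morbid", "omim"),
        FeatureDef("Morbid_gene_num", "count", "omim_morbid", "morbid"),
    ]
    # cCRE class counts
    defs += [FeatureDef(f"{c}_num", "count", "regions", c) for c in CCRE_CLASSES]
    # dosage-sensitivity counts: HI and TS genes at each curation code
    for side in ("HI", "TS"):
        defs += [
            FeatureDef(f"{side}_{code}_num", "count", "dosage", side, category=code)
            for code in DOSAGE_CODES
        ]
    # categorical-prediction counts (17): D for every predictor, plus the
    # benign/tolerated codes of SIFT, LRT, both PolyPhen2 variants and FATHMM
    cat_entries = [
        ("SIFT_pred", "D"),
        ("SIFT_pred", "T"),
        ("LRT_pred", "D"),
        ("LRT_pred", "N"),
        ("LRT_pred", "U"),
        ("Polyphen2_HDIV_pred", "D"),
        ("Polyphen2_HDIV_pred", "P"),
        ("Polyphen2_HDIV_pred", "B"),
        ("Polyphen2_HVAR_pred", "D"),
        ("Polyphen2_HVAR_pred", "P"),
        ("Polyphen2_HVAR_pred", "B"),
        ("FATHMM_pred", "D"),
        ("FATHMM_pred", "T"),
        ("MutationTaster_pred", "D"),
        ("MutationTaster_pred", "N"),
        ("MetaSVM_pred", "D"),
        ("MetaSVM_pred", "T"),
    ]
    defs += [
        FeatureDef(f"{pred}_{code}", "count", "site_categorical", pred, category=code)
        for pred, code in cat_entries
    ]
    return defs


def default_registry() -> FeatureRegistry:
    """The built-in 79-entry direction-aware registry."""
    reg = FeatureRegistry(_default_defs())
    assert len(reg) == 79, f"default registry has {len(reg)} entries"
    return reg


# ---------------------------------------------------------------------------
# Config text format: one feature per line
#   name <TAB> kind <TAB> source <TAB> selector [<TAB> category]
# '#' starts a comment; '-' stands for an empty selector.
# ---------------------------------------------------------------------------

def load_feature_registry(path_or_default: str | Path) -> FeatureRegistry:
    """Load a registry from a config file, or the built-in one for ``"default"``."""
    if str(path_or_default) == "default":
        return default_registry()
    path = Path(path_or_default)
    defs = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) not in (3, 4, 5):
            raise ValueError(f"{path}:{lineno}: expected 3-5 fields, got {len(parts)}")
        name, kind, source = parts[:3]
        selector = parts[3] if len(parts) > 3 else ""
        if selector == "-":
            selector = ""
        category = parts[4] if len(parts) > 4 else None
        defs.append(FeatureDef(name, kind, source, selector, category))
    return FeatureRegistry(defs)


def write_feature_registry(registry: FeatureRegistry, path: str | Path) -> None:
    lines = ["# name\tkind\tsource\tselector\tcategory"]
    for d in registry:
        fields = [d.name, d.kind, d.source, d.selector or "-"]
        if d.category is not None:
            fields.append(d.category)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
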