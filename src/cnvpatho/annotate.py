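"""Direction-aware feature annotation of CNVs.

For each CNV and each registry entry, the engine collects the overlapping
records of the selected track and aggregates them according to the entry's
declared kind:

* ``length`` — the CNV's own span in bp;
* ``max`` / ``min`` — the extreme of a numeric score over overlapping genes
  (gene-level scores, one value per overlapping gene) or sites (site-level
  scores, one value per overlapping position); the direction encodes
  whether high or low scores are the more deleterious;
* ``mean`` — arithmetic mean, for scores without a deleterious direction;
* ``count`` — number of overlapping records of the selected class
  (biotype, UTR kind, cCRE class, dosage code, OMIM/Morbid flag, or a
  categorical predictor call equal to the declared category).

A CNV overlapping no scored record yields an explicit missing value for
aggregated features — never a silent 0 — and 0 for counts. Missing cells
are later filled with per-feature medians fitted on the training partition
only (leakage-safe median imputation).

Overlap means any shared base (≥1 bp); sites overlap when their position
falls inside the half-open CNV interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import CNVRecord, GenomicInterval, interval_length
from .registry import FeatureDef, FeatureRegistry
from .resources import ResourceBundle


def aggregate_score(values: Sequence[float], method: str) -> float:
    """max/min/mean of a value list; empty input -> NaN (missing)."""
    if method not in ("max", "min", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    arr = np.sort(np.asarray(list(values), dtype=float))  # order-independent sums
    if arr.size == 0:
        return float("nan")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite entries in score values")
    if method == "max":
        return float(arr.max())
    if method == "min":
        return float(arr.min())
    return float(arr.mean())


class _Track:
    """Per-chromosome coordinate arrays for vectorized overlap queries."""

    def __init__(self, chroms, starts, ends):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        for c in pd.unique(chroms):
            m = chroms == c
            self.by_chrom[c] = (starts[m], ends[m], np.flatnonzero(m))

    def overlapping(self, iv: GenomicInterval) -> np.ndarray:
        """Indices (into original record list) of records overlapping iv."""
        entry = self.by_chrom.get(iv.chrom)
        if entry is None:
            return np.empty(0, dtype=np.int64)
        starts, ends, idx = entry
        return idx[(starts < iv.end) & (ends > iv.start)]


class BundleIndex:
    """Query-ready view of a ResourceBundle (build once, annotate many)."""

    def __init__(self, bundle: ResourceBundle):
        self.bundle = bundle
        g = bundle.genes
        self.gene_track = _Track([x.interval.chrom for x in g],
                                 [x.interval.start for x in g],
                                 [x.interval.end for x in g])
        score_names = sorted({s for gene in g for s in gene.gene_scores})
        self.gene_scores = pd.DataFrame(
            [[gene.gene_scores.get(s, np.nan) for s in score_names] for gene in g],
            columns=score_names, dtype=float)
        self.gene_biotype = np.array([x.biotype.value for x in g], dtype=object)
        self.gene_omim = np.array([x.is_omim for x in g], dtype=bool)
        self.gene_morbid = np.array([x.is_morbid for x in g], dtype=bool)
        self.gene_hi = np.array([x.hi_score for x in g], dtype=object)
        self.gene_ts = np.array([x.ts_score for x in g], dtype=object)

        u = bundle.utrs
        self.utr_track = _Track([x.interval.chrom for x in u],
                                [x.interval.start for x in u],
                                [x.interval.end for x in u])
        self.utr_kind = np.array([x.utr_kind for x in u], dtype=object)

        s = bundle.sites
        # sites are 1-bp positions: model as [pos, pos+1)
        self.site_track = _Track([x.chrom for x in s],
                                 [x.pos for x in s],
                                 [x.pos + 1 for x in s])
        num_names = sorted({n for site in s for n in site.numeric_scores})
        self.site_numeric = pd.DataFrame(
            [[site.numeric_scores.get(n, np.nan) for n in num_names] for site in s],
            columns=num_names, dtype=float)
        cat_names = sorted({p for site in s for p in site.categorical_preds})
        self.site_categorical = pd.DataFrame(
            [[site.categorical_preds.get(p) for p in cat_names] for site in s],
            columns=cat_names, dtype=object)

        r = bundle.regions
        self.region_track = _Track([x.interval.chrom for x in r],
                                   [x.interval.start for x in r],
                                   [x.interval.end for x in r])
        self.region_class = np.array([x.region_class for x in r], dtype=object)


def count_overlapping(cnv: CNVRecord, bundle: Union[ResourceBundle, BundleIndex],
                      fdef: FeatureDef) -> int:
    """Number of records of the selected track/class overlapping the CNV by ≥1 bp."""
    if fdef.kind != "count":
        raise ValueError(f"{fdef.name}: count_overlapping requires kind 'count'")
    idx = bundle if isinstance(bundle, BundleIndex) else BundleIndex(bundle)
    iv = cnv.interval
    if fdef.source == "genes":
        hits = idx.gene_track.overlapping(iv)
        return int(np.sum(idx.gene_biotype[hits] == fdef.selector))
    if fdef.source == "utr":
        hits = idx.utr_track.overlapping(iv)
        return int(np.sum(idx.utr_kind[hits] == fdef.selector))
    if fdef.source == "omim_morbid":
        hits = idx.gene_track.overlapping(iv)
        flags = idx.gene_omim if fdef.selector == "omim" else idx.gene_morbid
        return int(np.sum(flags[hits]))
    if fdef.source == "dosage":
        hits = idx.gene_track.overlapping(iv)
        codes = idx.gene_hi if fdef.selector == "HI" else idx.gene_ts
        return int(np.sum(codes[hits] == fdef.category))
    if fdef.source == "regions":
        hits = idx.region_track.overlapping(iv)
        return int(np.sum(idx.region_class[hits] == fdef.selector))
    if fdef.source == "site_categorical":
        if fdef.selector not in idx.site_categorical.columns:
            raise KeyError(f"predictor {fdef.selector!r} not in bundle site table")
        hits = idx.site_track.overlapping(iv)
        col = idx.site_categorical[fdef.selector].to_numpy(dtype=object)
        return int(np.sum(col[hits] == fdef.category))
    raise ValueError(f"{fdef.name}: source {fdef.source!r} is not countable")


def _feature_value(cnv: CNVRecord, idx: BundleIndex, fdef: FeatureDef) -> float:
    if fdef.kind == "length":
        return float(interval_length(cnv.interval))
    if fdef.kind == "count":
        return float(count_overlapping(cnv, idx, fdef))
    # numeric aggregation; a score column wholly absent from the bundle is
    # treated as all-missing (resources are legitimately sparse)
    if fdef.source == "gene_scores":
        if fdef.selector not in idx.gene_scores.columns:
            return float("nan")
        hits = idx.gene_track.overlapping(cnv.interval)
        vals = idx.gene_scores[fdef.selector].to_numpy()[hits]
    elif fdef.source == "site_numeric":
        if fdef.selector not in idx.site_numeric.columns:
            return float("nan")
        hits = idx.site_track.overlapping(cnv.interval)
        vals = idx.site_numeric[fdef.selector].to_numpy()[hits]
    else:  # pragma: no cover - registry invariants forbid this
        raise ValueError(f"{fdef.name}: bad numeric source {fdef.source!r}")
    return aggregate_score(vals[~np.isnan(vals)], fdef.kind)


@dataclass
class FeatureVector:
    record_id: str
    values: np.ndarray  # float64, NaN marks missing
    registry: FeatureRegistry

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def annotate_cnv(cnv: CNVRecord, bundle: Union[ResourceBundle, BundleIndex],
                 registry: FeatureRegistry) -> FeatureVector:
    """One feature value per registry entry for a single CNV."""
    idx = bundle if isinstance(bundle, BundleIndex) else BundleIndex(bundle)
    vals = np.array([_feature_value(cnv, idx, d) for d in registry], dtype=float)
    return FeatureVector(cnv.record_id, vals, registry)


@dataclass
class FeatureMatrix:
    """CNV-by-feature numeric table; NaN cells are missing (pre-imputation)."""

    registry: FeatureRegistry
    ids: list[str]
    values: np.ndarray  # shape (n, len(registry))
    medians: Optional[dict[str, float]] = None
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.ids), len(self.registry)):
            raise ValueError("feature matrix shape does not match ids × registry")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.registry.names)

    def subset(self, row_idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.registry, [self.ids[i] for i in row_idx],
                             self.values[row_idx], self.medians, dict(self.flags))


def annotate_cnvs(cnvs: Iterable[CNVRecord],
                  bundle: Union[ResourceBundle, BundleIndex],
                  registry: FeatureRegistry) -> FeatureMatrix:
    idx = bundle if isinstance(bundle, BundleIndex) else BundleIndex(bundle)
    cnvs = list(cnvs)
    rows = np.empty((len(cnvs), len(registry)), dtype=float)
    for i, cnv in enumerate(cnvs):
        rows[i] = annotate_cnv(cnv, idx, registry).values
    return FeatureMatrix(registry, [c.record_id for c in cnvs], rows)


# ---------------------------------------------------------------------------
# Median imputation (fit on the training partition only)
# ---------------------------------------------------------------------------

def fit_impute(matrix: FeatureMatrix) -> dict[str, float]:
    """Per-feature medians over non-missing training values.

    A feature entirely missing in training imputes to 0 and triggers a
    warning (recorded in the matrix flags).
    """
    medians: dict[str, float] = {}
    for j, name in enumerate(matrix.registry.names):
        col = matrix.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            medians[name] = 0.0
            matrix.flags[name] = "all_missing_in_training"
            warnings.warn(f"feature {name!r} entirely missing in training; median set to 0")
        else:
            medians[name] = float(np.median(obs))
    return medians


def apply_impute(matrix: FeatureMatrix, medians: dict[str, float]) -> FeatureMatrix:
    """Fill every missing cell with the (training) median; observed cells untouched."""
    missing = [n for n in matrix.registry.names if n not in medians]
    if missing:
        raise KeyError(f"no median for features: {missing}")
    fill = np.array([medians[n] for n in matrix.registry.names])
    values = matrix.values.copy()
    mask = np.isnan(values)
    values[mask] = np.broadcast_to(fill, values.shape)[mask]
    return FeatureMatrix(matrix.registry, list(matrix.ids), values,
                         {n: medians[n] for n in matrix.registry.names},
                         dict(matrix.flags))


# ---------------------------------------------------------------------------
# Matrix I/O (TSV; medians sidecar JSON)
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", na_rep=".")
    if matrix.medians is not None:
        sidecar = path.with_suffix(path.suffix + ".medians.json")
        sidecar.write_text(json.dumps(matrix.medians, indent=1, sort_keys=True))


def read_feature_matrix(path: str | Path, registry: FeatureRegistry) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=["."],
                     keep_default_na=False)
    if list(df.columns) != registry.names:
        raise ValueError("feature matrix columns do not match registry order")
    medians = None
    sidecar = path.with_suffix(path.suffix + ".medians.json")
    if sidecar.exists():
        medians = {k: float(v) for k, v in json.loads(sidecar.read_text()).items()}
    return FeatureMatrix(registry, [str(i) for i in df.index],
                         df.to_numpy(dtype=float), medians)
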