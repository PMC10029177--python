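"""Model interpretation (exact TreeSHAP) and feature-distribution statistics.

SHAP attributions are computed with the tree-path-dependent Tree SHAP
algorithm built into XGBoost (``pred_contribs``): per row, per-feature
additive contributions plus a base value that sum to the model's margin
output. Features are ranked by the sum of absolute attributions over all
rows (and, for multiclass models, over all class margins), ties broken by
registry order.

Distribution statistics mirror the package's analysis workflow:
Mann-Whitney U tests of each pathogenicity group against the benign
reference, Kruskal-Wallis across the five tiers with Bonferroni-corrected
pairwise post hoc comparisons, genomic-element proportions per group, and
a benign-vs-pathogenic differential feature analysis on log10(x+1)
transformed values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import kruskal as _scipy_kruskal
from scipy.stats import norm, rankdata

from .annotate import BundleIndex, FeatureMatrix, apply_impute
from .core import CNVRecord, Label
from .resources import Biotype, ResourceBundle

# ---------------------------------------------------------------------------
# SHAP
# ---------------------------------------------------------------------------

#: additivity tolerance, relative to the attribution scale (unit floor
#: because contributions come back in float32)
ADDITIVITY_RTOL = 1e-6


@dataclass
class AttributionMatrix:
    """Per-row, per-feature Tree SHAP attributions for a fitted model.

    ``values`` has shape (n, features) for binary models and
    (n, classes, features) for multiclass; ``base`` holds the matching
    base value(s); ``margin`` the model's raw margin output.
    """

    feature_names: list[str]
    values: np.ndarray
    base: np.ndarray
    margin: np.ndarray

    def additivity_error(self) -> float:
        """Max |row-sum + base − margin| scaled by max(1, |margin|, Σ|φ|)."""
        s = self.values.sum(axis=-1) + self.base
        scale = np.maximum(1.0, np.maximum(np.abs(self.margin),
                                           np.abs(self.values).sum(axis=-1)))
        return float((np.abs(s - self.margin) / scale).max()) if s.size else 0.0

    def check_additivity(self, rtol: float = ADDITIVITY_RTOL) -> None:
        err = self.additivity_error()
        if err > rtol:
            raise AssertionError(f"SHAP additivity violated: {err:.3e} > {rtol:.0e}")


def shap_attributions(model, matrix: FeatureMatrix) -> AttributionMatrix:
    """Exact TreeSHAP attributions for every row of the matrix."""
    from .model import TrainedModel  # typing/cycle

    if matrix.registry.fingerprint() != model.registry_fingerprint:
        raise ValueError("feature-registry fingerprint mismatch")
    if matrix.missing_mask.any():
        matrix = apply_impute(matrix, model.medians)
    dm = xgb.DMatrix(matrix.values)
    contribs = model.booster.predict(dm, pred_contribs=True).astype(np.float64)
    margin = model.booster.predict(dm, output_margin=True).astype(np.float64)
    values = contribs[..., :-1]
    base = contribs[..., -1]
    return AttributionMatrix(matrix.registry.names, values, base, margin)


def rank_features_by_shap(attr: AttributionMatrix, top_k: int = 20) -> list[str]:
    """Features sorted descending by Σ|attribution| (registry order on ties)."""
    flat = np.abs(attr.values)
    while flat.ndim > 2:
        flat = flat.sum(axis=1)
    totals = flat.sum(axis=0)
    order = sorted(range(len(totals)), key=lambda j: (-totals[j], j))
    return [attr.feature_names[j] for j in order[:top_k]]


def shap_dependence(attr: AttributionMatrix, feature: str,
                    matrix: FeatureMatrix, class_index: int = -1,
                    smooth_window: int = 51
                    ) -> tuple[pd.DataFrame, Optional[float]]:
    """(feature value, attribution) pairs plus a sign-change threshold.

    The threshold is the feature value at which the running-median-smoothed
    attribution (window 51 points) crosses zero, scanned over rows sorted
    by feature value; ``None`` when the smoothed attribution never changes
    sign. For multiclass models ``class_index`` selects the margin
    (default: the most pathogenic class).
    """
    if feature not in attr.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = attr.feature_names.index(feature)
    vals = attr.values if attr.values.ndim == 2 else attr.values[:, class_index, :]
    x = matrix.values[:, matrix.registry.index_of(feature)]
    phi = vals[:, j]
    order = np.argsort(x, kind="stable")
    x, phi = x[order], phi[order]
    pairs = pd.DataFrame({"value": x, "attribution": phi})

    w = min(smooth_window, len(phi))
    if w % 2 == 0:
        w = max(1, w - 1)
    half = w // 2
    smoothed = np.array([np.median(phi[max(0, i - half): i + half + 1])
                         for i in range(len(phi))])
    signs = np.sign(smoothed)
    threshold = None
    nz = np.flatnonzero(signs)
    for a, b in zip(nz[:-1], nz[1:]):
        if signs[a] != signs[b]:
            threshold = float((x[a] + x[b]) / 2.0)
            break
    return pairs, threshold


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

EXACT_LIMIT = 12  # exact enumeration up to this pooled sample size


def _u_from_ranks(rank_sum_x: float, nx: int) -> float:
    return rank_sum_x - nx * (nx + 1) / 2.0


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank ties.

    Returns (U for x, two-sided p). The p-value is exact — by full
    enumeration of group assignments — when n_x+n_y ≤ 12, otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = _u_from_ranks(ranks[:nx].sum(), nx)
    mu = nx * ny / 2.0

    n = nx + ny
    if n <= EXACT_LIMIT:
        dev = abs(u - mu)
        hits = total = 0
        for subset in itertools.combinations(range(n), nx):
            u_s = _u_from_ranks(ranks[list(subset)].sum(), nx)
            total += 1
            if abs(u_s - mu) >= dev - 1e-9:
                hits += 1
        return float(u), hits / total

    # normal approximation with tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0  # all values tied
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    return float(u), float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p with k−1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    with np.errstate(invalid="ignore"):
        try:
            h, p = _scipy_kruskal(*groups)
        except ValueError:  # all values identical across groups
            return 0.0, 1.0
    if np.isnan(h):  # tie correction divides by zero when all values tie
        return 0.0, 1.0
    return float(h), float(p)


def pairwise_posthoc(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """All k(k−1)/2 pairwise Mann-Whitney comparisons, Bonferroni-adjusted
    (p × number of comparisons, capped at 1)."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        u, p = mann_whitney_u(groups[a], groups[b])
        rows.append((a, b, u, p, min(1.0, p * m)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p", "p_bonferroni"])


@dataclass
class GroupStats:
    """Per-feature distribution tests of each group against the benign
    reference, plus the across-group Kruskal-Wallis summary."""

    feature: str
    reference: str
    tests: pd.DataFrame          # group, U, p (vs reference)
    kruskal_h: float
    kruskal_p: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def feature_group_stats(matrix: FeatureMatrix, labels: Sequence[Label],
                        feature: str, reference: Label = Label.BENIGN
                        ) -> GroupStats:
    """Mann-Whitney of every non-reference group vs benign, two-sided, plus
    Kruskal-Wallis and Bonferroni post hoc over all groups."""
    col = matrix.values[:, matrix.registry.index_of(feature)]
    lab = np.array([Label(l).value for l in labels], dtype=object)
    groups = {l: col[(lab == l) & ~np.isnan(col)]
              for l in dict.fromkeys(lab)}
    groups = {k: v for k, v in groups.items() if len(v) > 0}
    if reference.value not in groups:
        raise ValueError(f"reference group {reference.value!r} empty")
    rows = []
    for name, vals in groups.items():
        if name == reference.value:
            continue
        u, p = mann_whitney_u(vals, groups[reference.value])
        rows.append((name, u, p))
    h, p_kw = kruskal_wallis(list(groups.values()))
    return GroupStats(feature, reference.value,
                      pd.DataFrame(rows, columns=["group", "U", "p"]),
                      h, p_kw, pairwise_posthoc(groups))


# ---------------------------------------------------------------------------
# Genomic-element proportions
# ---------------------------------------------------------------------------

ELEMENT_CATEGORIES = ("pseudogene", "OMIM_gene", "Morbid_gene", "RNA_gene",
                      "protein_coding_gene")


def element_proportions(cnvs: Sequence[CNVRecord], bundle: ResourceBundle,
                        group_by=None) -> pd.DataFrame:
    """Per-group fractions of overlapped genomic elements.

    Categories: pseudogene, OMIM gene, Morbid gene, RNA gene,
    protein-coding gene. One gene may contribute to several categories
    (e.g. an OMIM protein-coding gene). Fractions per group sum to 1;
    groups overlapping no element get NaN rows (flagged undefined).
    ``group_by`` maps a CNVRecord to its group key (default: label value).
    """
    group_by = group_by or (lambda r: r.label.value)
    idx = BundleIndex(bundle)
    counts: dict[str, np.ndarray] = {}
    for r in cnvs:
        hits = idx.gene_track.overlapping(r.interval)
        row = counts.setdefault(group_by(r), np.zeros(len(ELEMENT_CATEGORIES)))
        row[0] += np.sum(idx.gene_biotype[hits] == Biotype.PSEUDOGENE.value)
        row[1] += np.sum(idx.gene_omim[hits])
        row[2] += np.sum(idx.gene_morbid[hits])
        row[3] += np.sum(idx.gene_biotype[hits] == Biotype.NCRNA.value)
        row[4] += np.sum(idx.gene_biotype[hits] == Biotype.PROTEIN_CODING.value)
    df = pd.DataFrame(counts, index=ELEMENT_CATEGORIES).T
    totals = df.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = df.div(totals, axis=0)
    frac[totals == 0] = np.nan  # undefined groups
    return frac


# ---------------------------------------------------------------------------
# Differential feature analysis (benign vs pathogenic)
# ---------------------------------------------------------------------------

def differential_top_features(matrix: FeatureMatrix, labels: Sequence[Label],
                              top_k: int = 10, rank_by: str = "mann_whitney"
                              ) -> tuple[list[str], pd.DataFrame]:
    """Top-k discriminative features between benign and pathogenic rows.

    Values are log10(x+1)-transformed (count features are legitimately 0),
    features ranked by two-group Mann-Whitney p (or |median difference|
    with ``rank_by="median_diff"``); constant features rank last. Rows
    whose selected-feature values are all 0 are removed from the returned
    transformed sub-matrix.
    """
    lab = np.array([Label(l).value for l in labels], dtype=object)
    mask_b = lab == Label.BENIGN.value
    mask_p = lab == Label.PATHOGENIC.value
    if not mask_b.any() or not mask_p.any():
        raise ValueError("need both benign and pathogenic rows")
    vals = np.log10(matrix.values + 1.0)
    keys = []
    for j, name in enumerate(matrix.registry.names):
        col = vals[:, j]
        b = col[mask_b & ~np.isnan(col)]
        p = col[mask_p & ~np.isnan(col)]
        if len(b) == 0 or len(p) == 0 or (np.unique(np.concatenate([b, p])).size == 1):
            keys.append((2.0, j))  # degenerate/constant: rank last
            continue
        if rank_by == "median_diff":
            keys.append((-abs(np.median(p) - np.median(b)), j))
        else:
            _, pval = mann_whitney_u(p, b)
            keys.append((pval, j))
    order = sorted(range(len(keys)), key=lambda j: keys[j])
    selected = [matrix.registry.names[j] for j in order[:top_k]]
    cols = [matrix.registry.index_of(n) for n in selected]
    sub = vals[np.ix_(np.arange(len(lab)), cols)]
    keep = ~(np.nan_to_num(sub) == 0).all(axis=1)
    out = pd.DataFrame(sub[keep], columns=selected,
                       index=[matrix.ids[i] for i in np.flatnonzero(keep)])
    out.insert(0, "label", list(lab[keep]))
    return selected, out
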