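"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — python loops, explicit position
sets, pair enumeration — and shares no code with the implementation it
checks.
"""

from __future__ import annotations

import itertools
import math

from cnvpatho.core import CNVRecord, GenomicInterval
from cnvpatho.registry import FeatureRegistry
from cnvpatho.resources import ResourceBundle


def brute_shared_positions(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def _cnv_positions(cnv: CNVRecord) -> set[int]:
    return set(range(cnv.interval.start, cnv.interval.end))


def _overlaps(cnv: CNVRecord, chrom: str, start: int, end: int,
              positions: set[int]) -> bool:
    return chrom == cnv.interval.chrom and bool(positions & set(range(start, end)))


def naive_annotate(cnv: CNVRecord, bundle: ResourceBundle,
                   registry: FeatureRegistry) -> list[float]:
    """Per-position-scan re-implementation of the feature vector.

    Only usable on toy genomes (position sets are materialized)."""
    pos = _cnv_positions(cnv)
    values: list[float] = []
    for d in registry:
        if d.kind == "length":
            values.append(float(len(pos)))
            continue
        if d.source == "gene_scores":
            vals = [g.gene_scores[d.selector] for g in bundle.genes
                    if d.selector in g.gene_scores
                    and _overlaps(cnv, g.interval.chrom, g.interval.start,
                                  g.interval.end, pos)]
            values.append(_agg(vals, d.kind))
        elif d.source == "site_numeric":
            vals = [s.numeric_scores[d.selector] for s in bundle.sites
                    if d.selector in s.numeric_scores
                    and s.chrom == cnv.interval.chrom and s.pos in pos]
            values.append(_agg(vals, d.kind))
        elif d.source == "site_categorical":
            n = sum(1 for s in bundle.sites
                    if s.chrom == cnv.interval.chrom and s.pos in pos
                    and s.categorical_preds.get(d.selector) == d.category)
            values.append(float(n))
        elif d.source == "genes":
            n = sum(1 for g in bundle.genes if g.biotype.value == d.selector
                    and _overlaps(cnv, g.interval.chrom, g.interval.start,
                                  g.interval.end, pos))
            values.append(float(n))
        elif d.source == "utr":
            n = sum(1 for u in bundle.utrs if u.utr_kind == d.selector
                    and _overlaps(cnv, u.interval.chrom, u.interval.start,
                                  u.interval.end, pos))
            values.append(float(n))
        elif d.source == "regions":
            n = sum(1 for r in bundle.regions if r.region_class == d.selector
                    and _overlaps(cnv, r.interval.chrom, r.interval.start,
                                  r.interval.end, pos))
            values.append(float(n))
        elif d.source == "dosage":
            n = sum(1 for g in bundle.genes
                    if (g.hi_score if d.selector == "HI" else g.ts_score) == d.category
                    and _overlaps(cnv, g.interval.chrom, g.interval.start,
                                  g.interval.end, pos))
            values.append(float(n))
        elif d.source == "omim_morbid":
            n = sum(1 for g in bundle.genes
                    if (g.is_omim if d.selector == "omim" else g.is_morbid)
                    and _overlaps(cnv, g.interval.chrom, g.interval.start,
                                  g.interval.end, pos))
            values.append(float(n))
        else:  # pragma: no cover
            raise AssertionError(d.source)
    return values


def _agg(vals: list[float], kind: str) -> float:
    if not vals:
        return math.nan
    if kind == "max":
        return max(vals)
    if kind == "min":
        return min(vals)
    return sum(vals) / len(vals)


def brute_auc(scores, labels) -> float:
    """All-pairs concordance with 0.5 credit for tied scores."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = len(pos) * len(neg)
    c = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                c += 1.0
            elif p == n:
                c += 0.5
    return c / total


def brute_mannwhitney(x, y) -> tuple[float, float]:
    """U by pair counting; exact two-sided p by full enumeration of the
    C(nx+ny, nx) group assignments, using the symmetric-deviation
    definition p = P(|U − nx·ny/2| ≥ |u_obs − nx·ny/2|)."""

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    pooled = list(x) + list(y)
    nx = len(x)
    mu = nx * (len(pooled) - nx) / 2.0
    u_obs = u_stat(x, y)
    dev = abs(u_obs - mu)
    hits = total = 0
    for subset in itertools.combinations(range(len(pooled)), nx):
        sset = set(subset)
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in sset]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= dev - 1e-9:
            hits += 1
    return u_obs, hits / total
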