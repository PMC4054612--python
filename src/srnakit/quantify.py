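"""Annotation of mapped tags against feature models and fractional
quantification of small non-coding RNAs.

Rules, in order:

* a tag is excluded outright when ANY of its retained alignments overlaps
  a coding exon on either strand (the strictest reading of coding-exon
  exclusion, applied at tag level);
* each remaining alignment is assigned to the same-strand ncRNA feature
  that covers at least half of the tag, preferring classes in the order
  miRNA > snoRNA > tRNA_fragment > other_ncRNA (ties within a class:
  larger overlap, then lexicographic feature id);
* alignments covering no feature are intergenic;
* a tag with count ``c`` retained at ``L`` loci contributes ``c/L`` per
  locus, so multi-mapped reads are split fractionally; intergenic loci
  absorb their share without creating features.

NEVs (normalised expression values) are reads-per-million by default
(``rpm``), or counts divided by DESeq median-of-ratios size factors
(``size_factor``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import AlignmentHit
from .collapse import UniTag
from .io import NCRNA_CLASSES, FeatureAnnotation

CLASS_PRIORITY = {"miRNA": 0, "snoRNA": 1, "tRNA_fragment": 2, "other_ncRNA": 3}


@dataclass
class TagAssignment:
    """Per-tag outcome of annotation."""

    sequence: str
    excluded: bool  # overlapped a coding exon at some locus
    n_loci: int  # retained loci (post-stratum alignments)
    features: list[str] = field(default_factory=list)  # one entry per assigned locus
    feature_classes: list[str] = field(default_factory=list)
    intergenic_loci: int = 0


@dataclass
class AnnotationStats:
    """Per-library read mass by annotation outcome (Fig-1-style table)."""

    table: pd.DataFrame  # rows: libraries; cols: mapped, sncRNA, miRNA, coding_excluded, intergenic
    class_breakdown: pd.DataFrame  # rows: libraries; cols: ncRNA classes


class FeatureIndex:
    """Interval lookup over the annotation, stranded for ncRNA classes."""

    def __init__(self, annotation: list[FeatureAnnotation]):
        self._ncrna: dict[tuple[str, str], IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        self.features: dict[str, str] = {}  # feature_id -> class
        for f in annotation:
            if f.feature_class == "coding_exon":
                self._exons.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
            elif f.feature_class in NCRNA_CLASSES:
                self._ncrna.setdefault((f.chrom, f.strand), IntervalTree()).addi(
                    f.start, f.end, f
                )
                self.features[f.feature_id] = f.feature_class

    def overlaps_exon(self, hit: AlignmentHit) -> bool:
        tree = self._exons.get(hit.chrom)
        return bool(tree is not None and tree.overlap(hit.start, hit.end))

    def assign(self, hit: AlignmentHit, overlap_fraction: float) -> FeatureAnnotation | None:
        tree = self._ncrna.get((hit.chrom, hit.strand))
        if tree is None:
            return None
        L = hit.end - hit.start
        best: tuple[int, int, str] | None = None
        best_f: FeatureAnnotation | None = None
        for iv in tree.overlap(hit.start, hit.end):
            f: FeatureAnnotation = iv.data
            overlap = min(hit.end, f.end) - max(hit.start, f.start)
            if overlap < overlap_fraction * L:
                continue
            key = (CLASS_PRIORITY[f.feature_class], -overlap, f.feature_id)
            if best is None or key < best:
                best, best_f = key, f
        return best_f


def assign_tags(
    hits_by_tag: dict[str, list[AlignmentHit]],
    annotation: list[FeatureAnnotation],
    overlap_fraction: float = 0.5,
) -> dict[str, TagAssignment]:
    """Annotate every mapped tag; unmapped tags (no hits) are skipped."""
    index = FeatureIndex(annotation)
    out: dict[str, TagAssignment] = {}
    for seq, hits in hits_by_tag.items():
        if not hits:
            continue
        if any(index.overlaps_exon(h) for h in hits):
            out[seq] = TagAssignment(seq, excluded=True, n_loci=len(hits))
            continue
        a = TagAssignment(seq, excluded=False, n_loci=len(hits))
        for h in hits:
            f = index.assign(h, overlap_fraction)
            if f is None:
                a.intergenic_loci += 1
            else:
                a.features.append(f.feature_id)
                a.feature_classes.append(f.feature_class)
        out[seq] = a
    return out


def fractional_count(
    assignments: dict[str, TagAssignment],
    tags: list[UniTag],
    libraries: list[str],
    annotation: list[FeatureAnnotation],
) -> tuple[pd.DataFrame, AnnotationStats]:
    """Build the feature x library fractional CountMatrix.

    Mass conservation: for every library, assigned + intergenic +
    coding-excluded mass equals the summed counts of its aligned tags.
    """
    feature_ids: list[str] = []
    feature_class: dict[str, str] = {}
    for f in annotation:
        if f.feature_class in NCRNA_CLASSES and f.feature_id not in feature_class:
            feature_class[f.feature_id] = f.feature_class
            feature_ids.append(f.feature_id)

    counts = pd.DataFrame(0.0, index=feature_ids, columns=libraries)
    mapped = pd.Series(0.0, index=libraries)
    excluded = pd.Series(0.0, index=libraries)
    intergenic = pd.Series(0.0, index=libraries)
    by_class = pd.DataFrame(0.0, index=libraries, columns=list(NCRNA_CLASSES))

    tag_lookup = {t.sequence: t for t in tags}
    for seq, a in assignments.items():
        tag = tag_lookup.get(seq)
        if tag is None or a.n_loci == 0:
            continue
        for lib, c in tag.counts.items():
            mapped[lib] += c
            if a.excluded:
                excluded[lib] += c
                continue
            share = c / a.n_loci
            intergenic[lib] += share * a.intergenic_loci
            for fid, fclass in zip(a.features, a.feature_classes):
                counts.loc[fid, lib] += share
                by_class.loc[lib, fclass] += share

    stats_table = pd.DataFrame(
        {
            "mapped": mapped,
            "sncRNA": by_class.sum(axis=1),
            "miRNA": by_class["miRNA"],
            "coding_excluded": excluded,
            "intergenic": intergenic,
        }
    )
    return counts, AnnotationStats(stats_table, by_class)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq median-of-ratios size factors.

    For each library j, s_j is the median over features (with nonzero
    geometric mean across libraries) of k_ij / geomean_i.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(arr)
    finite = np.all(np.isfinite(log), axis=1)
    if not finite.any():
        raise ValueError(
            "no feature has nonzero counts in every library; "
            "cannot compute size factors"
        )
    logmeans = log[finite].mean(axis=1)
    ratios = np.exp(log[finite] - logmeans[:, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def normalize(
    counts: pd.DataFrame,
    mode: str = "rpm",
    library_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Compute NEVs from the fractional CountMatrix.

    ``rpm``: 10^6 * k_ij / T_j where T_j is the library's total mapped
    mass when ``library_totals`` is given (so NEV column sums equal 10^6
    times the mapped-to-feature fraction), else the column sum of assigned
    counts.  ``size_factor``: k_ij / s_j with median-of-ratios s_j.
    """
    zero = counts.sum(axis=0) == 0
    if zero.any():
        raise ValueError(f"all-zero library: {', '.join(counts.columns[zero])}")
    if mode == "rpm":
        denom = (
            library_totals.reindex(counts.columns)
            if library_totals is not None
            else counts.sum(axis=0)
        )
        return 1e6 * counts.div(denom, axis=1)
    if mode == "size_factor":
        return counts.div(size_factors(counts), axis=1)
    raise ValueError(f"unknown normalization mode {mode!r}")


def log2_fold_change(
    control_nev: float, cancer_nev: float, pseudo: float = 0.1
) -> float:
    """log2(cancer/control); a zero group mean is floored at ``pseudo``
    for display, and NaN is returned when both means are zero."""
    if control_nev == 0 and cancer_nev == 0:
        return math.nan
    c = control_nev if control_nev > 0 else pseudo
    t = cancer_nev if cancer_nev > 0 else pseudo
    return math.log2(t / c)
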