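"""Candidate-marker screening: the six-criterion filter and KASP-region
validation.

The filter reduces a raw variant set to high-quality fingerprinting
candidates: (1) biallelic SNPs only, (2) fourfold-degenerate sites,
(3) heterozygosity rate < 0.2, (4) missing rate < 0.05, (5) minor allele
frequency > 0.3, (6) no other variant (SNP or InDel) within the 100 bp
flanking region. All threshold comparisons are strict, so boundary
values are rejected. A record is attributed to its FIRST failing
criterion in the order above, but the surviving set is the intersection
of the per-criterion pass sets and hence order-independent.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .degeneracy import DegeneracyClassifier, SiteFoldClass
from .divstats import marker_stats
from .io import GenomeSequence
from .model import GenotypeMatrix, MarkerRecord

CRITERIA_ORDER = (
    "biallelic",
    "fourfold",
    "heterozygosity",
    "missing",
    "maf",
    "flank",
)


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the candidate filter; fraction thresholds are
    exclusive bounds (strict comparisons)."""

    require_biallelic: bool = True
    require_4d: bool = True
    max_heterozygosity: float = 0.2
    max_missing: float = 0.05
    min_maf: float = 0.3
    clean_flank_bp: int = 100

    def __post_init__(self):
        for name in ("max_heterozygosity", "max_missing", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.clean_flank_bp < 0:
            raise ValueError("clean_flank_bp must be >= 0")


@dataclass
class FilterReport:
    input_count: int
    surviving_count: int
    rejections: dict[str, int]
    rejected_markers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        total = self.surviving_count + sum(self.rejections.values())
        if total != self.input_count:
            raise ValueError(
                f"inconsistent report: {self.input_count} in, "
                f"{self.surviving_count} survived + "
                f"{sum(self.rejections.values())} rejected"
            )


@dataclass(frozen=True)
class VariantSite:
    """Position-level view of any variant (SNP or InDel) used for the
    flank-cleanliness check; `span_end` covers deleted reference bases."""

    chrom: str
    pos: int
    ref: str = "N"
    alt: str = "N"

    @property
    def span_end(self) -> int:
        return self.pos + max(len(self.ref) - 1, 0)


def _as_sites(all_variants) -> list[VariantSite]:
    if all_variants is None:
        return []
    if isinstance(all_variants, GenotypeMatrix):
        return [
            VariantSite(m.chrom, m.pos, m.ref, m.alt) for m in all_variants.markers
        ]
    out = []
    for v in all_variants:
        if isinstance(v, VariantSite):
            out.append(v)
        elif isinstance(v, MarkerRecord):
            out.append(VariantSite(v.chrom, v.pos, v.ref, v.alt))
        else:
            chrom, pos = v[0], v[1]
            ref = v[2] if len(v) > 2 else "N"
            alt = v[3] if len(v) > 3 else "N"
            out.append(VariantSite(chrom, int(pos), ref, alt))
    return out


class _NeighborIndex:
    """Sorted per-chromosome variant spans for fast window queries."""

    def __init__(self, sites: Iterable[VariantSite]):
        self._by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for s in sites:
            self._by_chrom.setdefault(s.chrom, []).append((s.pos, s.span_end, s.pos))
        for spans in self._by_chrom.values():
            spans.sort()

    def has_other_variant(self, chrom: str, pos: int, flank: int) -> bool:
        """True if any variant other than the one anchored at (chrom, pos)
        overlaps [pos - flank, pos + flank]."""
        spans = self._by_chrom.get(chrom, ())
        if not spans:
            return False
        lo, hi = pos - flank, pos + flank
        # spans are short; scan from the first candidate start
        i = bisect.bisect_left(spans, (lo - 1000, -1, -1))
        for start, end, anchor in spans[i:]:
            if start > hi:
                break
            if end >= lo and anchor != pos:
                return True
        return False


def evaluate_criteria(
    matrix: GenotypeMatrix,
    criteria: FilterCriteria,
    fold_classes: Mapping[tuple[str, int], SiteFoldClass]
    | DegeneracyClassifier
    | None,
    all_variants=None,
) -> dict[str, dict[str, bool]]:
    """Per-marker, per-criterion pass/fail map (True = passes).

    NaN statistics (e.g. all-missing columns) fail their criterion.
    """
    if criteria.require_4d and fold_classes is None:
        raise ValueError(
            "criteria require fourfold-degenerate sites but no "
            "annotation-derived fold classes were supplied"
        )
    index = _NeighborIndex(_as_sites(all_variants))

    def is_4d(m: MarkerRecord) -> bool:
        if isinstance(fold_classes, DegeneracyClassifier):
            return fold_classes.is_4d(m.chrom, m.pos)
        sf = fold_classes.get((m.chrom, m.pos))
        return sf is not None and sf.is_4d

    out: dict[str, dict[str, bool]] = {}
    for m in matrix.markers:
        st = marker_stats(matrix.column(m.id))
        out[m.id] = {
            "biallelic": (not criteria.require_biallelic) or m.is_biallelic_snp,
            "fourfold": (not criteria.require_4d) or is_4d(m),
            # NaN heterozygosity (all-missing column) is not evidence of
            # excess heterozygosity; the missing criterion rejects it.
            # NaN MAF cannot be shown to exceed the bound, so it fails.
            "heterozygosity": not (st.het_obs >= criteria.max_heterozygosity),
            "missing": bool(st.missing_rate < criteria.max_missing),
            "maf": bool(st.maf > criteria.min_maf),
            "flank": not index.has_other_variant(
                m.chrom, m.pos, criteria.clean_flank_bp
            ),
        }
    return out


def filter_candidates(
    matrix: GenotypeMatrix,
    criteria: FilterCriteria | None = None,
    fold_classes: Mapping[tuple[str, int], SiteFoldClass]
    | DegeneracyClassifier
    | None = None,
    all_variants=None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the candidate filter; returns the surviving matrix and a
    report attributing each rejected marker to its first failing
    criterion.

    `all_variants` supplies the full raw variant set (including InDels
    and variants not in `matrix`) for the flank-cleanliness criterion;
    when omitted, only markers within `matrix` are mutual neighbors.
    """
    criteria = criteria or FilterCriteria()
    if all_variants is None:
        all_variants = matrix
    verdicts = evaluate_criteria(matrix, criteria, fold_classes, all_variants)
    survivors: list[str] = []
    rejections = {c: 0 for c in CRITERIA_ORDER}
    rejected_markers: dict[str, str] = {}
    for mid, passed in verdicts.items():
        failing = [c for c in CRITERIA_ORDER if not passed[c]]
        if failing:
            rejections[failing[0]] += 1
            rejected_markers[mid] = failing[0]
        else:
            survivors.append(mid)
    report = FilterReport(
        input_count=matrix.n_markers,
        surviving_count=len(survivors),
        rejections=rejections,
        rejected_markers=rejected_markers,
    )
    return matrix.select_markers(survivors), report


# -- KASP candidate validation ----------------------------------------------

@dataclass(frozen=True)
class KaspCandidate:
    """Flanking-region screen of one candidate marker for KASP assay
    design: GC content of the site window, absence of interfering
    variants in the flanks, and window uniqueness in the genome."""

    marker: MarkerRecord
    flank_up: str
    flank_down: str
    gc_content: float
    flank_clean: bool
    unique_in_genome: bool
    truncated_at_edge: bool
    product_max_bp: int
    max_gc: float

    @property
    def window(self) -> str:
        return self.flank_up + self.marker.ref + self.flank_down

    @property
    def designable(self) -> bool:
        return (
            self.gc_content < self.max_gc
            and self.flank_clean
            and self.unique_in_genome
        )


def _count_occurrences(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return n
        n += 1
        start = idx + 1


def validate_kasp_candidate(
    marker: MarkerRecord,
    genome: GenomeSequence,
    all_variants=None,
    flank_bp: int = 100,
    max_gc: float = 0.60,
    product_max_bp: int = 120,
) -> KaspCandidate:
    """Extract the +/- `flank_bp` window around a marker and screen it.

    GC content is computed over the whole window (both flanks plus the
    site). `unique_in_genome` is an exact forward-strand substring
    search of the window across all chromosomes — a deterministic
    stand-in for an alignment-based specificity screen. Markers closer
    than `flank_bp` to a contig edge are flagged, not fatal.
    `product_max_bp` is recorded for downstream primer design but does
    not enter the designable predicate (primers are out of scope).
    """
    chrom_len = genome.length(marker.chrom)
    up_start = max(1, marker.pos - flank_bp)
    down_end = min(chrom_len, marker.pos + flank_bp)
    truncated = up_start != marker.pos - flank_bp or down_end != marker.pos + flank_bp
    flank_up = genome.fetch(marker.chrom, up_start, marker.pos - 1) if marker.pos > 1 else ""
    flank_down = (
        genome.fetch(marker.chrom, marker.pos + 1, down_end)
        if marker.pos < chrom_len
        else ""
    )
    window = flank_up + genome.fetch(marker.chrom, marker.pos, marker.pos) + flank_down
    gc = sum(b in "GC" for b in window) / len(window)

    index = _NeighborIndex(_as_sites(all_variants))
    clean = not index.has_other_variant(marker.chrom, marker.pos, flank_bp)

    hits = sum(_count_occurrences(genome.sequence(c), window) for c in genome.chroms)
    return KaspCandidate(
        marker=marker,
        flank_up=flank_up,
        flank_down=flank_down,
        gc_content=gc,
        flank_clean=clean,
        unique_in_genome=hits == 1,
        truncated_at_edge=truncated,
        product_max_bp=product_max_bp,
        max_gc=max_gc,
    )
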