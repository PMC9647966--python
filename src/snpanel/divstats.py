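"""Per-marker and panel-level diversity statistics.

For a biallelic locus with alternate-allele frequency p (q = 1 - p):

    gene diversity (expected heterozygosity)  He  = 1 - p^2 - q^2
    polymorphism information content          PIC = He - 2 p^2 q^2

the biallelic closed form of the Botstein PIC; both are bounded by 0.5
and PIC <= He with equality only when one allele is fixed. Frequencies
are estimated from called alleles only (complete case, no small-sample
correction). Undefined statistics (all-missing columns, zero
transversions) are reported as NaN rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Call, GenotypeMatrix, MarkerRecord

TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})
VARIANT_PAIRS = ("A/G", "C/T", "A/T", "A/C", "G/T", "C/G")


def gene_diversity_biallelic(p: float) -> float:
    """Expected heterozygosity 1 - p^2 - q^2 of a biallelic locus."""
    q = 1.0 - p
    return 1.0 - p * p - q * q


def pic_biallelic(p: float) -> float:
    """Botstein polymorphism information content, biallelic closed form."""
    q = 1.0 - p
    return gene_diversity_biallelic(p) - 2.0 * p * p * q * q


def _counts(column: np.ndarray) -> tuple[int, int, int, int]:
    column = np.asarray(column)
    n_homref = int(np.sum(column == Call.HOM_REF))
    n_het = int(np.sum(column == Call.HET))
    n_homalt = int(np.sum(column == Call.HOM_ALT))
    n_missing = int(np.sum(column == Call.MISSING))
    return n_homref, n_het, n_homalt, n_missing


def allele_freq(column: np.ndarray) -> float:
    """Alternate-allele frequency of one marker column.

    MISSING calls are excluded from both numerator and denominator; an
    all-missing column yields NaN.
    """
    _, n_het, n_homalt, n_missing = _counts(column)
    n_called = len(column) - n_missing
    if n_called == 0:
        return float("nan")
    return (2 * n_homalt + n_het) / (2 * n_called)


@dataclass(frozen=True)
class MarkerStats:
    maf: float
    pic: float
    het_obs: float
    gene_diversity: float
    missing_rate: float
    n_called: int


def marker_stats(column: np.ndarray) -> MarkerStats:
    """All per-marker statistics of one call column.

    maf = min(p, 1-p); het_obs = n_het / n_called; missing_rate is over
    all samples. Values are full precision; Table-style display rounds
    to 3 decimals.
    """
    _, n_het, _, n_missing = _counts(column)
    n = len(column)
    n_called = n - n_missing
    p = allele_freq(column)
    if n_called == 0:
        nan = float("nan")
        return MarkerStats(nan, nan, nan, nan, 1.0, 0)
    return MarkerStats(
        maf=min(p, 1.0 - p),
        pic=pic_biallelic(p),
        het_obs=n_het / n_called,
        gene_diversity=gene_diversity_biallelic(p),
        missing_rate=n_missing / n,
        n_called=n_called,
    )


@dataclass(frozen=True)
class VariantSpectrum:
    """Counts (or percentages — the ratio is scale-free) of the six
    unordered biallelic substitution types."""

    counts: Mapping[str, float]

    def __post_init__(self):
        unknown = set(self.counts) - set(VARIANT_PAIRS)
        if unknown:
            raise ValueError(f"unknown variant pair(s): {sorted(unknown)}")

    @property
    def n_transitions(self) -> float:
        return sum(
            v for k, v in self.counts.items() if frozenset(k.split("/")) in TRANSITIONS
        )

    @property
    def n_transversions(self) -> float:
        return sum(
            v
            for k, v in self.counts.items()
            if frozenset(k.split("/")) not in TRANSITIONS
        )

    @property
    def ts_tv_ratio(self) -> float:
        tv = self.n_transversions
        if tv == 0:
            return float("nan")
        return self.n_transitions / tv


def _canonical_pair(ref: str, alt: str) -> str:
    for pair in VARIANT_PAIRS:
        if frozenset(pair.split("/")) == frozenset((ref, alt)):
            return pair
    raise ValueError(f"not a SNP substitution pair: {ref}/{alt}")


def variant_spectrum(markers: Iterable[MarkerRecord]) -> VariantSpectrum:
    """Tally the six substitution types over biallelic SNP markers."""
    counts = {pair: 0.0 for pair in VARIANT_PAIRS}
    for m in markers:
        if not m.is_biallelic_snp:
            raise ValueError(f"marker {m.id} is not a biallelic SNP")
        counts[_canonical_pair(m.ref, m.alt)] += 1
    return VariantSpectrum(counts)


def stats_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """One row of statistics per marker, in matrix order."""
    rows = []
    for m in matrix.markers:
        st = marker_stats(matrix.column(m.id))
        rows.append(
            {
                "marker": m.id,
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "maf": st.maf,
                "pic": st.pic,
                "het_obs": st.het_obs,
                "gene_diversity": st.gene_diversity,
                "missing_rate": st.missing_rate,
                "n_called": st.n_called,
            }
        )
    return pd.DataFrame(rows)


def panel_summary(
    stats: Sequence[MarkerStats] | pd.DataFrame,
    band: tuple[float, float] = (0.4, 0.5),
) -> dict:
    """Mean/min/max of each statistic over a marker panel plus the
    fraction of markers whose gene diversity lies in `band` (inclusive
    at both ends)."""
    if isinstance(stats, pd.DataFrame):
        df = stats
    else:
        df = pd.DataFrame([s.__dict__ for s in stats])
    if df.empty:
        raise ValueError("panel_summary requires at least one marker")
    cols = ["maf", "pic", "het_obs", "gene_diversity", "missing_rate"]
    cols = [c for c in cols if c in df.columns]
    out: dict = {}
    for c in cols:
        out[c] = {
            "mean": float(df[c].mean()),
            "min": float(df[c].min()),
            "max": float(df[c].max()),
        }
    lo, hi = band
    gd = df["gene_diversity"]
    out["gene_diversity_band"] = {
        "lo": lo,
        "hi": hi,
        "fraction": float(((gd >= lo) & (gd <= hi)).mean()),
    }
    out["n_markers"] = int(len(df))
    return out
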