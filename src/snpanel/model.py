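"""Core data model: genotype calls, marker records and the genotype matrix.

The matrix is the substrate every other module operates on: a dense
samples x markers array of diploid call states plus per-marker allele
metadata. Coordinates are 1-based inclusive throughout the public API,
matching VCF and GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

NUCLEOTIDES = ("A", "C", "G", "T")


class Call(IntEnum):
    """Diploid biallelic call state.

    Partially missing genotypes (e.g. "./1") are coerced to MISSING and
    phase is dropped on import: fingerprinting is phase-insensitive.
    """

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3

    @staticmethod
    def from_alleles(alleles: Sequence[int | None]) -> "Call":
        """Map a genotype allele-index tuple to a call state."""
        if not alleles or any(a is None for a in alleles):
            return Call.MISSING
        if all(a == 0 for a in alleles):
            return Call.HOM_REF
        if len(set(alleles)) == 1:
            return Call.HOM_ALT
        return Call.HET

    @staticmethod
    def from_gt_string(gt: str) -> "Call":
        """Parse a VCF GT field ("0/1", "1|0", "./.", ...)."""
        sep = "|" if "|" in gt else "/"
        parts = gt.split(sep)
        alleles: list[int | None] = []
        for p in parts:
            alleles.append(None if p in (".", "") else int(p))
        return Call.from_alleles(alleles)

    def to_gt_string(self) -> str:
        return _GT_OUT[self]


_GT_OUT = {
    Call.HOM_REF: "0/0",
    Call.HET: "0/1",
    Call.HOM_ALT: "1/1",
    Call.MISSING: "./.",
}


@dataclass(frozen=True)
class MarkerRecord:
    """One variant record.

    The model is permissive on construction so that raw VCF content
    (multi-allelic records, InDels) can ride through to the filter stage,
    where `is_biallelic_snp` gates them out. `alt` is the first ALT allele;
    `alts` carries the full tuple.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"marker position must be >= 1, got {self.pos}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}_{self.pos}")

    @property
    def alt(self) -> str:
        return self.alts[0] if self.alts else "."

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and self.ref in NUCLEOTIDES and all(
            len(a) == 1 and a in NUCLEOTIDES for a in self.alts
        )

    @property
    def is_biallelic_snp(self) -> bool:
        return self.is_biallelic and self.is_snp and self.ref != self.alt

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def with_id(self, marker_id: str) -> "MarkerRecord":
        return replace(self, id=marker_id)


@dataclass(frozen=True)
class CdsSegment:
    """One CDS feature: a 1-based inclusive genomic interval with strand
    and phase, attached to its transcript."""

    chrom: str
    start: int
    end: int
    strand: str
    phase: int
    transcript_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"CDS segment start {self.start} > end {self.end} "
                f"({self.transcript_id})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenotypeMatrix:
    """Dense samples x markers call matrix.

    `calls[i, j]` is the Call state of sample i at marker j, stored as an
    int8 array of Call values. Sample and marker identifiers are unique.
    """

    def __init__(
        self,
        samples: Sequence[str],
        markers: Sequence[MarkerRecord],
        calls: np.ndarray,
    ):
        samples = list(samples)
        markers = list(markers)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(samples)} samples, {len(markers)} markers)"
            )
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise ValueError(f"duplicate sample names: {dupes}")
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate marker ids: {dupes}")
        if calls.size and (calls.min() < 0 or calls.max() > 3):
            raise ValueError("call codes must be in 0..3")
        self.samples = samples
        self.markers = markers
        self.calls = calls
        self._marker_index = {m.id: j for j, m in enumerate(markers)}
        self._sample_index = {s: i for i, s in enumerate(samples)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def marker(self, marker_id: str) -> MarkerRecord:
        return self.markers[self.marker_column_index(marker_id)]

    def marker_column_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id: {marker_id!r}") from None

    def column(self, marker_id: str) -> np.ndarray:
        """Calls of all samples at one marker."""
        return self.calls[:, self.marker_column_index(marker_id)]

    def row(self, sample: str) -> np.ndarray:
        try:
            i = self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample: {sample!r}") from None
        return self.calls[i, :]

    # -- subsetting ----------------------------------------------------------

    def select_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.marker_column_index(m) for m in marker_ids]
        return GenotypeMatrix(
            self.samples, [self.markers[j] for j in idx], self.calls[:, idx]
        )

    def select_samples(self, samples: Iterable[str]) -> "GenotypeMatrix":
        idx = []
        for s in samples:
            if s not in self._sample_index:
                raise KeyError(f"unknown sample: {s!r}")
            idx.append(self._sample_index[s])
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.markers, self.calls[idx, :]
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(
            range(self.n_markers),
            key=lambda j: (self.markers[j].chrom, self.markers[j].pos),
        )
        return GenotypeMatrix(
            self.samples, [self.markers[j] for j in order], self.calls[:, order]
        )

    # -- equality ------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_samples} samples x "
            f"{self.n_markers} markers)"
        )
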