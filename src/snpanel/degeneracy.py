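"""Codon-degeneracy classification of genomic sites.

A site is fourfold degenerate (4D) when every nucleotide at its codon
position encodes the same amino acid, so substitutions there are
synonymous and approximately neutral — the property the marker filter
relies on. Classification reconstructs the codon around a site from the
reference genome and the CDS annotation, respecting strand and phase,
including codons that span CDS segment boundaries (phase-adjusted
concatenation of the spliced sequence).

Only the standard genetic code (translation table 1) is supported; stop
codons count as their own "amino acid" for synonymy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io import GenomeSequence, group_by_transcript
from .model import NUCLEOTIDES, CdsSegment

# codon -> amino acid (one letter; '*' for stops), standard code
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"


class FoldClass(Enum):
    NONCODING = "noncoding"
    NONDEGENERATE = "nondegenerate"
    TWOFOLD = "twofold"
    THREEFOLD = "threefold"
    FOURFOLD = "fourfold"
    CONFLICT = "conflict"


_FOLD_BY_COUNT = {
    1: FoldClass.NONDEGENERATE,
    2: FoldClass.TWOFOLD,
    3: FoldClass.THREEFOLD,
    4: FoldClass.FOURFOLD,
}


def fold_of_codon(codon: str, codon_pos: int) -> FoldClass:
    """Degeneracy of position `codon_pos` (0, 1 or 2) of `codon`.

    The fold is the number of nucleotides at that position encoding the
    codon's amino acid. Ambiguity codes make the codon NONDEGENERATE.
    """
    codon = codon.upper()
    if len(codon) != 3 or codon_pos not in (0, 1, 2):
        raise ValueError(f"bad codon/position: {codon!r}/{codon_pos}")
    if any(b not in NUCLEOTIDES for b in codon):
        return FoldClass.NONDEGENERATE
    aa = CODON_TO_AA[codon]
    n_same = sum(
        CODON_TO_AA[codon[:codon_pos] + b + codon[codon_pos + 1 :]] == aa
        for b in NUCLEOTIDES
    )
    return _FOLD_BY_COUNT[n_same]


@dataclass(frozen=True)
class SiteFoldClass:
    chrom: str
    pos: int
    fold: FoldClass
    transcripts: tuple[str, ...] = ()

    @property
    def is_4d(self) -> bool:
        return self.fold is FoldClass.FOURFOLD


class TranscriptFrameError(ValueError):
    """Raised when a transcript's phase-adjusted CDS length is not a
    multiple of three."""


@dataclass
class _SplicedCds:
    """Spliced coding sequence of one transcript with a map from genomic
    position to coding offset (0-based, 5'->3' in transcription order)."""

    transcript_id: str
    strand: str
    phase: int
    seq: str
    coding_offset: dict[int, int]  # genomic pos -> offset into seq


def _splice(segments: Sequence[CdsSegment], genome: GenomeSequence) -> _SplicedCds:
    segs = sorted(segments, key=lambda s: s.start)
    tid = segs[0].transcript_id
    strand = segs[0].strand
    if any(s.strand != strand for s in segs):
        raise ValueError(f"transcript {tid} mixes strands")
    plus = "".join(genome.fetch(s.chrom, s.start, s.end) for s in segs)
    positions = [p for s in segs for p in range(s.start, s.end + 1)]
    if strand == "+":
        seq = plus
        phase = segs[0].phase
    else:
        seq = str(Seq(plus).reverse_complement())
        positions = positions[::-1]
        phase = segs[-1].phase  # first segment in transcription order
    if (len(seq) - phase) % 3 != 0:
        raise TranscriptFrameError(
            f"transcript {tid}: phase-adjusted CDS length "
            f"{len(seq) - phase} is not a multiple of 3"
        )
    offsets = {pos: i for i, pos in enumerate(positions)}
    return _SplicedCds(tid, strand, phase, seq, offsets)


class DegeneracyClassifier:
    """Classifies sites against a genome + CDS annotation.

    Splicing and frame checks are done once per transcript at
    construction; frame violations are recorded and raised only when a
    queried site actually falls in the broken transcript.
    """

    def __init__(self, cds_segments: Iterable[CdsSegment], genome: GenomeSequence):
        self.genome = genome
        self._spliced: dict[str, _SplicedCds] = {}
        self._frame_errors: dict[str, TranscriptFrameError] = {}
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for tid, segs in group_by_transcript(cds_segments).items():
            try:
                self._spliced[tid] = _splice(segs, genome)
            except TranscriptFrameError as exc:
                self._frame_errors[tid] = exc
            for s in segs:
                self._by_chrom.setdefault(s.chrom, []).append((s.start, s.end, tid))
        for spans in self._by_chrom.values():
            spans.sort()

    def _covering_transcripts(self, chrom: str, pos: int) -> list[str]:
        found = []
        for start, end, tid in self._by_chrom.get(chrom, ()):
            if start <= pos <= end and tid not in found:
                found.append(tid)
        return found

    def classify_site(self, chrom: str, pos: int) -> SiteFoldClass:
        """Fold class of one genomic site (1-based).

        Sites covered by no CDS are NONCODING; sites whose covering
        transcripts disagree are CONFLICT; a covering transcript with a
        broken reading frame raises TranscriptFrameError naming it.
        """
        tids = self._covering_transcripts(chrom, pos)
        if not tids:
            return SiteFoldClass(chrom, pos, FoldClass.NONCODING)
        folds = []
        for tid in tids:
            if tid in self._frame_errors:
                raise self._frame_errors[tid]
            sp = self._spliced[tid]
            off = sp.coding_offset[pos]
            if off < sp.phase:
                # inside the 5' partial codon trimmed by phase
                folds.append(FoldClass.NONDEGENERATE)
                continue
            rel = off - sp.phase
            codon = sp.seq[sp.phase :][rel - rel % 3 : rel - rel % 3 + 3]
            folds.append(fold_of_codon(codon, rel % 3))
        fold = folds[0] if len(set(folds)) == 1 else FoldClass.CONFLICT
        return SiteFoldClass(chrom, pos, fold, tuple(tids))

    def is_4d(self, chrom: str, pos: int) -> bool:
        return self.classify_site(chrom, pos).is_4d

    def classify_sites(
        self, sites: Iterable[tuple[str, int]]
    ) -> dict[tuple[str, int], SiteFoldClass]:
        return {(c, p): self.classify_site(c, p) for c, p in sites}


def write_4d_bed(
    classified: Mapping[tuple[str, int], SiteFoldClass],
    path: str | os.PathLike,
) -> int:
    """Export all FOURFOLD sites as BED (0-based half-open). Returns the
    number of sites written."""
    rows = sorted(
        (c.chrom, c.pos) for c in classified.values() if c.is_4d
    )
    with open(path, "w") as fh:
        for chrom, pos in rows:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")
    return len(rows)
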