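"""Readers and writers for the standard formats the toolkit consumes.

VCF 4.x via pysam, FASTA random access via pyfaidx, GFF3 CDS features via
gffutils, plus a tab-separated genotype-table dialect. All coordinates in
the public API are 1-based inclusive.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pysam
from pyfaidx import Fasta

from .model import Call, CdsSegment, GenotypeMatrix, MarkerRecord


class VcfParseError(ValueError):
    pass


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    lo, hi = span.split("-", 1)
    return chrom, int(lo.replace(",", "")), int(hi.replace(",", ""))


def read_vcf(path: str | os.PathLike, region: str | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix.

    All records are retained, including multi-allelic and non-SNP ones
    (the filter stage rejects them); phase is dropped and partially
    missing genotypes become MISSING. `region` is "chrom" or
    "chrom:start-end" (1-based inclusive).

    Raises VcfParseError on malformed input or a missing GT FORMAT field,
    and ValueError on duplicate sample names.
    """
    path = os.fspath(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise VcfParseError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vf.header.samples)
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise ValueError(f"{path}: duplicate sample names: {dupes}")
        want = _parse_region(region) if region else None

        markers: list[MarkerRecord] = []
        columns: list[np.ndarray] = []
        n_done = 0
        try:
            for rec in vf:
                n_done += 1
                if want is not None:
                    chrom, lo, hi = want
                    if rec.chrom != chrom:
                        continue
                    if lo is not None and not (lo <= rec.pos <= hi):
                        continue
                alts = tuple(a for a in (rec.alts or ()) if a is not None)
                markers.append(
                    MarkerRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref or ".",
                        alts=alts,
                        id=rec.id or "",
                    )
                )
                col = np.empty(len(samples), dtype=np.int8)
                for i, s in enumerate(samples):
                    col[i] = Call.from_alleles(rec.samples[s].get("GT") or ())
                columns.append(col)
        except (OSError, ValueError) as exc:
            raise VcfParseError(
                f"{path}: malformed VCF near data record "
                f"{n_done + 1}: {exc}"
            ) from exc
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, markers, calls)


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 with GT-only
    FORMAT, records sorted by (chrom, pos)."""
    path = os.fspath(path)
    matrix = matrix.sorted_by_position()
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[
        ("ID", "GT"), ("Number", "1"), ("Type", "String"),
        ("Description", "Genotype"),
    ])
    chrom_max: dict[str, int] = {}
    for m in matrix.markers:
        end = m.pos + len(m.ref) - 1
        chrom_max[m.chrom] = max(chrom_max.get(m.chrom, 0), end)
    for chrom in sorted(chrom_max):
        header.contigs.add(chrom, length=chrom_max[chrom] + 1000)
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, m in enumerate(matrix.markers):
            rec = out.new_record(
                contig=m.chrom,
                start=m.pos - 1,
                alleles=(m.ref,) + (m.alts if m.alts else (".",)),
                id=m.id,
            )
            for i, s in enumerate(matrix.samples):
                state = Call(int(matrix.calls[i, j]))
                if state is Call.MISSING:
                    rec.samples[s]["GT"] = (None, None)
                elif state is Call.HOM_REF:
                    rec.samples[s]["GT"] = (0, 0)
                elif state is Call.HET:
                    rec.samples[s]["GT"] = (0, 1)
                else:
                    rec.samples[s]["GT"] = (1, 1)
            out.write(rec)


class GenomeSequence:
    """Random access to a reference FASTA; fetch is 1-based inclusive and
    always uppercase."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._fa = Fasta(self.path, sequence_always_upper=True)

    @property
    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Nucleotides of [start, end], 1-based inclusive."""
        if chrom not in self._fa:
            raise KeyError(f"unknown chromosome: {chrom!r}")
        if start < 1 or end > self.length(chrom) or start > end:
            raise ValueError(
                f"invalid interval {chrom}:{start}-{end} "
                f"(chrom length {self.length(chrom)})"
            )
        return str(self._fa[chrom][start - 1 : end]).upper()

    def sequence(self, chrom: str) -> str:
        return str(self._fa[chrom][:]).upper()


def read_genome(path: str | os.PathLike) -> GenomeSequence:
    return GenomeSequence(path)


def read_cds(path: str | os.PathLike) -> list[CdsSegment]:
    """Read CDS features (with strand and phase) from a GFF3 file,
    attributed to their parent transcript."""
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    segments = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise ValueError(
                f"{path}: CDS feature at {feat.seqid}:{feat.start} has no "
                "Parent or ID attribute"
            )
        frame = feat.frame
        if frame in (None, "."):
            raise ValueError(
                f"{path}: CDS feature at {feat.seqid}:{feat.start} "
                "is missing its phase"
            )
        segments.append(
            CdsSegment(
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                phase=int(frame),
                transcript_id=parents[0],
            )
        )
    return segments


def group_by_transcript(
    segments: Iterable[CdsSegment],
) -> dict[str, list[CdsSegment]]:
    """Group CDS segments by transcript, in genomic order."""
    out: dict[str, list[CdsSegment]] = {}
    for seg in segments:
        out.setdefault(seg.transcript_id, []).append(seg)
    for tid, segs in out.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping CDS segments in transcript {tid}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
    return out


def check_chrom_names(
    genome: GenomeSequence, segments: Iterable[CdsSegment]
) -> None:
    """Raise if the annotation references chromosomes absent from the
    genome, listing the offending names."""
    missing = sorted({s.chrom for s in segments} - set(genome.chroms))
    if missing:
        raise ValueError(
            "annotation chromosomes not present in genome FASTA: "
            + ", ".join(missing)
        )


# -- delimited genotype tables ----------------------------------------------

def write_genotype_table(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    orient: str = "samples-rows",
) -> None:
    """Write a TSV genotype table with call tokens 0/0, 0/1, 1/1, ./..

    orient="samples-rows": one row per sample, one column per marker id.
    orient="markers-rows": one row per marker, one column per sample
    (the fingerprint-matrix layout).
    """
    tokens = np.array([c.to_gt_string() for c in Call])
    grid = tokens[matrix.calls]
    with open(path, "w") as fh:
        if orient == "samples-rows":
            fh.write("sample\t" + "\t".join(matrix.marker_ids) + "\n")
            for i, s in enumerate(matrix.samples):
                fh.write(s + "\t" + "\t".join(grid[i, :]) + "\n")
        elif orient == "markers-rows":
            fh.write("marker\t" + "\t".join(matrix.samples) + "\n")
            for j, m in enumerate(matrix.markers):
                fh.write(m.id + "\t" + "\t".join(grid[:, j]) + "\n")
        else:
            raise ValueError(f"unknown orient: {orient!r}")


def read_genotype_table(
    path: str | os.PathLike,
    markers: Sequence[MarkerRecord] | None = None,
    orient: str = "samples-rows",
) -> GenotypeMatrix:
    """Read a TSV genotype table written by `write_genotype_table`.

    The table stores call tokens only; allele metadata is taken from
    `markers` when given (matched by id), else placeholder A/T records on
    chromosome "unknown" are created.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty genotype table")
    header = lines[0].split("\t")
    body = [ln.split("\t") for ln in lines[1:]]
    if orient == "samples-rows":
        marker_ids = header[1:]
        samples = [row[0] for row in body]
        grid = [row[1:] for row in body]
    elif orient == "markers-rows":
        samples = header[1:]
        marker_ids = [row[0] for row in body]
        grid = (
            [[row[1 + i] for row in body] for i in range(len(samples))]
            if body
            else [[] for _ in samples]
        )
    else:
        raise ValueError(f"unknown orient: {orient!r}")

    by_id = {m.id: m for m in markers} if markers else {}
    recs = []
    for k, mid in enumerate(marker_ids):
        recs.append(
            by_id.get(mid)
            or MarkerRecord(chrom="unknown", pos=k + 1, ref="A", alts=("T",), id=mid)
        )
    calls = np.array(
        [[Call.from_gt_string(tok) for tok in row] for row in grid],
        dtype=np.int8,
    ).reshape(len(samples), len(marker_ids))
    return GenotypeMatrix(samples, recs, calls)
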