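"""Synthetic fixture generator: toy genome + annotation + genotypes with
fully known planted structure.

The generator emulates the two cohorts of a cultivar-fingerprinting
study — near-homozygous inbred lines (the screening panel) and
market hybrids (the fingerprinted cohort, high heterozygosity, cloned
duplicate cultivars) — on a toy chromosome where every marker sits at a
codon position of known degeneracy. Every planted property (target
frequencies, filter violations, duplicate groups, decoy variants in
flanks) is recorded in a ground-truth manifest so downstream modules
can be checked exactly.

Genotype columns are built by exact composition by default: the
genotype counts deterministically hit the target frequencies and only
their assignment to samples is randomized, so a plan fully determines
filter and fingerprint outcomes. An "iid" mode draws genotypes
independently per sample for sampling-theory tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from . import io as _io
from .model import Call, GenotypeMatrix, MarkerRecord

NUC = "ACGT"

# codon prefixes whose third position is fourfold degenerate
FOURFOLD_PREFIXES = ("GC", "GG", "CC", "CT", "GT", "AC", "TC", "CG")

VIOLATION_KINDS = ("heterozygosity", "missing", "maf", "multiallelic")


@dataclass(frozen=True)
class SynthPlan:
    """Recipe for one synthetic fixture.

    Defaults describe a market-hybrid fingerprinting cohort: 329
    samples, 41 markers, observed heterozygosity around 0.39, ~3%
    missing data, and two large cloned duplicate groups (12 and 11
    cultivars). `inbred` gives a near-homozygous screening panel.
    """

    n_samples: int = 329
    n_markers: int = 41
    maf: float | None = None  # None: per-marker U(0.35, 0.48)
    het_rate: float = 0.39
    missing_rate: float = 0.03
    duplicate_groups: tuple[int, ...] = (12, 11)
    n_decoy_variants: int = 0
    fraction_4d: float = 1.0
    planted_violations: tuple[str, ...] = ()
    composition: str = "exact"
    seed: int = 0
    chrom: str = "chr1"
    spacing: int = 300

    def __post_init__(self):
        object.__setattr__(self, "duplicate_groups", tuple(self.duplicate_groups))
        object.__setattr__(self, "planted_violations", tuple(self.planted_violations))
        for name in ("het_rate", "missing_rate", "fraction_4d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.composition not in ("exact", "iid"):
            raise ValueError(f"unknown composition: {self.composition!r}")
        if self.maf is not None and not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf target must be in (0, 0.5], got {self.maf}")
        bad = set(self.planted_violations) - set(VIOLATION_KINDS)
        if bad:
            raise ValueError(f"unknown planted violations: {sorted(bad)}")
        if sum(self.duplicate_groups) > self.n_samples:
            raise ValueError("duplicate group sizes exceed sample count")
        if any(g < 2 for g in self.duplicate_groups):
            raise ValueError("duplicate groups must have size >= 2")
        n_special = (
            self.n_decoy_variants
            + round((1 - self.fraction_4d) * self.n_markers)
            + len(self.planted_violations)
        )
        if n_special > self.n_markers:
            raise ValueError(
                f"plan infeasible: {n_special} special markers > "
                f"{self.n_markers} markers"
            )

    @classmethod
    def inbred(cls, **kw) -> "SynthPlan":
        """Near-homozygous screening-panel preset (153 lines)."""
        defaults = dict(
            n_samples=153,
            het_rate=0.08,
            missing_rate=0.02,
            duplicate_groups=(),
        )
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def hybrid(cls, **kw) -> "SynthPlan":
        """Market-hybrid fingerprinting-cohort preset (the default)."""
        return cls(**kw)


@dataclass
class MarkerTruth:
    id: str
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    is_4d: bool
    strand: str | None  # host-gene strand, None for intergenic sites
    target_maf: float
    target_het: float
    target_missing: float
    violation: str | None  # filter criterion this marker is planted to fail


@dataclass
class SynthFixture:
    fasta: Path
    gff3: Path
    vcf: Path
    manifest_path: Path
    manifest: dict
    matrix: GenotypeMatrix


def _next_base(base: str, offset: int = 1) -> str:
    return NUC[(NUC.index(base) + offset) % 4]


def _background(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


# -- genome -------------------------------------------------------------------

def make_genome(plan: SynthPlan, outdir: str | os.PathLike):
    """Write the toy FASTA + GFF3 and return (fasta_path, gff3_path,
    list[MarkerTruth]) with per-site fold-class ground truth.

    Marker i sits at position 200 + i*spacing. Fourfold sites live at
    the third position of a 4D-family codon inside a small synthetic
    gene (strand alternates); the remaining sites are intergenic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(plan.seed)
    length = plan.n_markers * plan.spacing + 400
    seq = _background(rng, length)  # 0..3 codes, 0-based

    n_non4d = round((1 - plan.fraction_4d) * plan.n_markers)
    # deterministic assignment of special roles to marker indices
    flank_idx = list(range(plan.n_decoy_variants))
    non4d_idx = list(range(plan.n_decoy_variants, plan.n_decoy_variants + n_non4d))
    viol_start = plan.n_decoy_variants + n_non4d
    viol_idx = {
        viol_start + j: v for j, v in enumerate(plan.planted_violations)
    }

    truths: list[MarkerTruth] = []
    gff_lines = ["##gff-version 3"]
    for i in range(plan.n_markers):
        pos = 200 + i * plan.spacing  # 1-based
        is_4d = i not in non4d_idx
        strand: str | None = None
        if is_4d:
            strand = "+" if i % 2 == 0 else "-"
            prefix = FOURFOLD_PREFIXES[i % len(FOURFOLD_PREFIXES)]
            third = NUC[i % 4]
            codon = prefix + third
            if strand == "+":
                # site = third position of the CDS's first codon
                cds_start, cds_end = pos - 2, pos + 9
                for k, b in enumerate(codon):
                    seq[pos - 3 + k] = NUC.index(b)
            else:
                # transcription reads the reverse complement; the first
                # codon's third position maps back to genomic `pos`
                cds_start, cds_end = pos - 9, pos + 2
                rc = str(Seq(codon).reverse_complement())
                for k, b in enumerate(rc):
                    seq[pos - 1 + k] = NUC.index(b)
            gid = f"gene{i:04d}"
            gff_lines.append(
                f"{plan.chrom}\tsynth\tgene\t{cds_start}\t{cds_end}\t.\t{strand}\t.\tID={gid}"
            )
            gff_lines.append(
                f"{plan.chrom}\tsynth\tmRNA\t{cds_start}\t{cds_end}\t.\t{strand}\t.\tID={gid}.1;Parent={gid}"
            )
            gff_lines.append(
                f"{plan.chrom}\tsynth\tCDS\t{cds_start}\t{cds_end}\t.\t{strand}\t0\tID={gid}.1.cds;Parent={gid}.1"
            )
        ref = NUC[seq[pos - 1]]
        alts: tuple[str, ...] = (_next_base(ref),)
        violation = viol_idx.get(i)
        if i in flank_idx:
            violation = "flank"
        elif i in non4d_idx:
            violation = "fourfold"
        if violation == "multiallelic":
            alts = (_next_base(ref), _next_base(ref, 2))
        target_maf, target_het, target_missing = _targets_for(plan, rng, violation)
        truths.append(
            MarkerTruth(
                id=f"SYN{i + 1:04d}",
                chrom=plan.chrom,
                pos=pos,
                ref=ref,
                alts=alts,
                is_4d=is_4d,
                strand=strand,
                target_maf=target_maf,
                target_het=target_het,
                target_missing=target_missing,
                violation=violation,
            )
        )

    fasta = outdir / "genome.fa"
    _write_fasta(fasta, {plan.chrom: "".join(NUC[b] for b in seq)})
    gff3 = outdir / "annotation.gff3"
    gff3.write_text("\n".join(gff_lines) + "\n")
    return fasta, gff3, truths


def _targets_for(plan: SynthPlan, rng: np.random.Generator, violation: str | None):
    """(target_maf, target_het, target_missing) for one marker; passing
    markers keep a comfortable margin from every threshold."""
    maf = plan.maf if plan.maf is not None else float(rng.uniform(0.35, 0.48))
    het = plan.het_rate
    miss = plan.missing_rate
    if violation == "heterozygosity":
        het = 0.30
    elif violation == "missing":
        miss = 0.12
    elif violation == "maf":
        maf = 0.25
    return maf, het, miss


def _write_fasta(path: Path, chroms: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- genotypes ----------------------------------------------------------------

def _column_exact(
    rng: np.random.Generator, n: int, p: float, het: float, miss: float
) -> np.ndarray:
    """Deterministic genotype composition hitting the targets, randomly
    assigned to samples."""
    n_miss = round(miss * n)
    n_called = n - n_miss
    n_het = round(het * n_called)
    n_homalt = int(round(p * n_called - n_het / 2))
    n_homalt = max(0, min(n_called - n_het, n_homalt))
    n_homref = n_called - n_het - n_homalt
    col = np.concatenate(
        [
            np.full(n_homref, Call.HOM_REF, dtype=np.int8),
            np.full(n_het, Call.HET, dtype=np.int8),
            np.full(n_homalt, Call.HOM_ALT, dtype=np.int8),
            np.full(n_miss, Call.MISSING, dtype=np.int8),
        ]
    )
    rng.shuffle(col)
    return col


def _column_iid(
    rng: np.random.Generator, n: int, p: float, het: float, miss: float
) -> np.ndarray:
    p_homalt = max(0.0, min(1.0 - het, p - het / 2))
    p_homref = max(0.0, 1.0 - het - p_homalt)
    probs = np.array([p_homref, het, p_homalt])
    probs = probs / probs.sum()
    col = rng.choice(
        np.array([Call.HOM_REF, Call.HET, Call.HOM_ALT], dtype=np.int8),
        size=n,
        p=probs,
    )
    col[rng.random(n) < miss] = Call.MISSING
    return col


def make_genotypes(
    plan: SynthPlan,
    truths: list[MarkerTruth],
    outdir: str | os.PathLike,
) -> tuple[Path, Path, GenotypeMatrix, dict]:
    """Draw the genotype matrix per the plan, plant decoys and duplicate
    groups, write VCF + manifest, and return everything.

    Duplicate groups are cloned after missing-data masking, so clones
    are exact string duplicates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(plan.seed + 1)
    samples = [f"cv{i + 1:04d}" for i in range(plan.n_samples)]
    draw = _column_exact if plan.composition == "exact" else _column_iid

    markers: list[MarkerRecord] = []
    columns: list[np.ndarray] = []
    for t in truths:
        markers.append(
            MarkerRecord(chrom=t.chrom, pos=t.pos, ref=t.ref, alts=t.alts, id=t.id)
        )
        columns.append(
            draw(rng, plan.n_samples, t.target_maf, t.target_het, t.target_missing)
        )

    # decoy variants inside the flank of designated markers
    decoys: list[dict] = []
    for k in range(plan.n_decoy_variants):
        host = truths[k]
        dpos = host.pos + 50
        if k % 2 == 0:
            ref, alts = host.ref, (_next_base(host.ref),)
            kind = "snp"
        else:
            ref, alts = host.ref + "A", (host.ref,)
            kind = "indel"
        did = f"decoy{k + 1:03d}"
        markers.append(
            MarkerRecord(chrom=host.chrom, pos=dpos, ref=ref, alts=alts, id=did)
        )
        columns.append(_column_iid(rng, plan.n_samples, 0.1, 0.1, 0.0))
        decoys.append(
            {"id": did, "chrom": host.chrom, "pos": dpos, "type": kind, "host": host.id}
        )

    calls = np.stack(columns, axis=1)

    # clone duplicate groups (post-masking, exact duplicates)
    groups: list[list[str]] = []
    cursor = 0
    for size in plan.duplicate_groups:
        member_idx = list(range(cursor, cursor + size))
        cursor += size
        template = calls[member_idx[0], :].copy()
        for i in member_idx[1:]:
            calls[i, :] = template
        groups.append([samples[i] for i in member_idx])

    matrix = GenotypeMatrix(samples, markers, calls)
    vcf = outdir / "genotypes.vcf"
    _io.write_vcf(matrix, vcf)

    manifest = _build_manifest(plan, truths, decoys, groups, matrix)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return vcf, manifest_path, matrix, manifest


_CRITERIA_ORDER = (
    "biallelic", "fourfold", "heterozygosity", "missing", "maf", "flank",
)
_VIOLATION_TO_CRITERION = {
    "multiallelic": "biallelic",
    "fourfold": "fourfold",
    "heterozygosity": "heterozygosity",
    "missing": "missing",
    "maf": "maf",
    "flank": "flank",
}


def _is_screening_plan(plan) -> bool:
    """True when the plan's passing markers are guaranteed to pass the
    candidate filter: exact composition, no cloned duplicates (cloning
    perturbs per-marker counts), and targets on the passing side of
    every threshold. Only then does the manifest carry exact filter
    expectations."""
    return (
        plan.composition == "exact"
        and not plan.duplicate_groups
        and plan.het_rate < 0.2
        and plan.missing_rate < 0.05
        and (plan.maf is None or plan.maf > 0.3)
    )


def _build_manifest(plan, truths, decoys, groups, matrix) -> dict:
    from .divstats import marker_stats  # deferred: avoid import cycle

    screening = _is_screening_plan(plan)
    marker_entries = []
    rejections = {c: 0 for c in _CRITERIA_ORDER}
    survivors = []
    for t in truths:
        st = marker_stats(matrix.column(t.id))
        crit = _VIOLATION_TO_CRITERION.get(t.violation) if t.violation else None
        if screening:
            _assert_planted(t, st, crit)
        if crit is None:
            survivors.append(t.id)
        else:
            rejections[crit] += 1
        marker_entries.append(
            {
                **asdict(t),
                "alts": list(t.alts),
                "realized_maf": st.maf,
                "realized_het": st.het_obs,
                "realized_missing": st.missing_rate,
                "expected_rejection": crit if screening else None,
            }
        )
    expected_filter = (
        {
            "input_count": len(truths),
            "surviving_count": len(survivors),
            "surviving_ids": survivors,
            "rejections": rejections,
        }
        if screening
        else None
    )
    return {
        "plan": {
            **asdict(plan),
            "maf": plan.maf,
            "duplicate_groups": list(plan.duplicate_groups),
            "planted_violations": list(plan.planted_violations),
        },
        "samples": list(matrix.samples),
        "markers": marker_entries,
        "decoys": decoys,
        "duplicate_groups": groups,
        "expected_filter": expected_filter,
    }


def _assert_planted(t: MarkerTruth, st, crit: str | None) -> None:
    """Guarantee that realized statistics land on the intended side of
    every threshold; raises if cloning/rounding broke a guarantee."""
    checks = {
        "heterozygosity": st.het_obs < 0.2,
        "missing": st.missing_rate < 0.05,
        "maf": st.maf > 0.3,
    }
    if crit is None:
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(
                f"plan infeasible: passing marker {t.id} drifted across "
                f"threshold(s) {bad} (het {st.het_obs:.3f}, "
                f"missing {st.missing_rate:.3f}, maf {st.maf:.3f})"
            )
    elif crit in checks and checks[crit]:
        raise ValueError(
            f"plan infeasible: marker {t.id} planted to fail {crit} "
            "but its realized statistic passes"
        )


def generate(plan: SynthPlan, outdir: str | os.PathLike) -> SynthFixture:
    """End-to-end fixture build: genome, annotation, genotypes, manifest."""
    outdir = Path(outdir)
    fasta, gff3, truths = make_genome(plan, outdir)
    vcf, manifest_path, matrix, manifest = make_genotypes(plan, truths, outdir)
    return SynthFixture(
        fasta=fasta,
        gff3=gff3,
        vcf=vcf,
        manifest_path=manifest_path,
        manifest=manifest,
        matrix=matrix,
    )


# -- degeneracy oracle substrate ---------------------------------------------

def make_codon_tiling_genome(outdir: str | os.PathLike):
    """Toy genome carrying all 64 codons in frame on both strands.

    Returns (fasta_path, gff3_path, truth) where truth maps every codon
    position to its genomic site: dicts with chrom, pos (1-based),
    codon, codon_pos (0..2) and strand. 192 sites per strand.
    """
    import itertools

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    codons = ["".join(c) for c in itertools.product(NUC, repeat=3)]
    coding = "".join(codons)  # 192 bp
    pad = "".join(NUC[(i * 7 + 3) % 4] for i in range(100))  # fixed filler
    plus_seq = pad + coding + pad
    minus_seq = pad + str(Seq(coding).reverse_complement()) + pad
    cds_start, cds_end = 101, 100 + len(coding)

    fasta = outdir / "tiling.fa"
    _write_fasta(fasta, {"tileP": plus_seq, "tileM": minus_seq})
    gff3 = outdir / "tiling.gff3"
    lines = ["##gff-version 3"]
    for chrom, strand, tid in (("tileP", "+", "tp"), ("tileM", "-", "tm")):
        lines.append(f"{chrom}\tsynth\tgene\t{cds_start}\t{cds_end}\t.\t{strand}\t.\tID={tid}")
        lines.append(
            f"{chrom}\tsynth\tmRNA\t{cds_start}\t{cds_end}\t.\t{strand}\t.\tID={tid}.1;Parent={tid}"
        )
        lines.append(
            f"{chrom}\tsynth\tCDS\t{cds_start}\t{cds_end}\t.\t{strand}\t0\tID={tid}.1.cds;Parent={tid}.1"
        )
    gff3.write_text("\n".join(lines) + "\n")

    truth = []
    for i, codon in enumerate(codons):
        for j in range(3):
            truth.append(
                {
                    "chrom": "tileP",
                    "pos": cds_start + 3 * i + j,
                    "codon": codon,
                    "codon_pos": j,
                    "strand": "+",
                }
            )
            # on the minus strand, coding offset c maps to genomic
            # position cds_end - c
            truth.append(
                {
                    "chrom": "tileM",
                    "pos": cds_end - (3 * i + j),
                    "codon": codon,
                    "codon_pos": j,
                    "strand": "-",
                }
            )
    return fasta, gff3, truth
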