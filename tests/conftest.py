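import numpy as np
import pytest

import snpanel as sp
from snpanel.model import Call, GenotypeMatrix, MarkerRecord


def build_matrix(call_rows, ref_alts=None, samples=None, chrom="chr1"):
    """Small literal genotype matrix: call_rows is a list of per-sample
    call-code sequences; ref_alts an optional list of (ref, alt)."""
    call_rows = np.asarray(call_rows, dtype=np.int8)
    n_samples, n_markers = call_rows.shape
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    ref_alts = ref_alts or [("A", "G")] * n_markers
    markers = [
        MarkerRecord(chrom=chrom, pos=100 * (j + 1), ref=ra[0], alts=(ra[1],),
                     id=f"m{j + 1}")
        for j, ra in enumerate(ref_alts)
    ]
    return GenotypeMatrix(samples, markers, call_rows)


@pytest.fixture(scope="session")
def tiling_genome(tmp_path_factory):
    """Toy genome carrying all 64 codons in frame on both strands, with
    a per-site (codon, codon position, strand) truth table."""
    outdir = tmp_path_factory.mktemp("tiling")
    fasta, gff3, truth = sp.make_codon_tiling_genome(outdir)
    genome = sp.read_genome(str(fasta))
    classifier = sp.DegeneracyClassifier(sp.read_cds(str(gff3)), genome)
    return genome, classifier, truth


@pytest.fixture(scope="session")
def planted_fixture(tmp_path_factory):
    """Synthetic fixture with 10 markers of which exactly 3 violate one
    filter criterion each (heterozygosity, flank neighbor, triallelic)."""
    outdir = tmp_path_factory.mktemp("planted")
    plan = sp.SynthPlan(
        n_samples=60,
        n_markers=10,
        het_rate=0.08,
        missing_rate=0.02,
        duplicate_groups=(),
        n_decoy_variants=1,
        planted_violations=("heterozygosity", "multiallelic"),
        seed=7,
    )
    fx = sp.generate(plan, outdir)
    genome = sp.read_genome(str(fx.fasta))
    classifier = sp.DegeneracyClassifier(sp.read_cds(str(fx.gff3)), genome)
    matrix = sp.read_vcf(str(fx.vcf))
    return fx, genome, classifier, matrix


def random_matrix(rng, n_samples, n_markers, missing_rate=0.05):
    calls = rng.choice(
        np.array([Call.HOM_REF, Call.HET, Call.HOM_ALT], dtype=np.int8),
        size=(n_samples, n_markers),
    )
    calls[rng.random(calls.shape) < missing_rate] = Call.MISSING
    return build_matrix(calls)
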