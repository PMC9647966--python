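"""Screen a raw variant set down to candidate fingerprinting markers.

Generates a small synthetic screening panel (near-homozygous lines)
with three planted filter violations, classifies every marker site for
codon degeneracy, applies the six-criterion filter and prints the
rejection breakdown. The surviving markers are biallelic SNPs at
fourfold-degenerate sites with low heterozygosity, little missing data,
MAF > 0.3 and clean 100 bp flanks.
"""

import tempfile
from pathlib import Path

import snpanel as sp

with tempfile.TemporaryDirectory() as tmp:
    plan = sp.SynthPlan(
        n_samples=60, n_markers=10, het_rate=0.08, missing_rate=0.02,
        duplicate_groups=(), n_decoy_variants=1,
        planted_violations=("heterozygosity", "multiallelic"), seed=7,
    )
    fx = sp.generate(plan, Path(tmp))
    classifier = sp.DegeneracyClassifier(
        sp.read_cds(str(fx.gff3)), sp.read_genome(str(fx.fasta))
    )
    matrix = sp.read_vcf(str(fx.vcf))
    candidates = matrix.select_markers([m["id"] for m in fx.manifest["markers"]])

    kept, report = sp.filter_candidates(
        candidates, sp.FilterCriteria(), classifier, all_variants=matrix
    )

    print(f"input markers:     {report.input_count}")
    print(f"surviving markers: {report.surviving_count}")
    for criterion, n in report.rejections.items():
        if n:
            print(f"  rejected by {criterion}: {n}")
    # one marker was planted to fail each of: heterozygosity (>0.2),
    # biallelic (a third allele), and flank (a decoy SNP at +50 bp);
    # the seven survivors pass all six criteria.

    # KASP flanking-region screen of the first survivor
    genome = sp.read_genome(str(fx.fasta))
    cand = sp.validate_kasp_candidate(kept.markers[0], genome, matrix)
    print(
        f"\nKASP check {cand.marker.id}: GC={cand.gc_content:.3f}, "
        f"flank_clean={cand.flank_clean}, unique={cand.unique_in_genome}, "
        f"designable={cand.designable}"
    )
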