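# Methods

## Scope and data model

The toolkit operates on a dense samples × markers matrix of diploid
call states (hom-ref, het, hom-alt, missing) read from multi-sample
VCF. Phase is dropped on import and partially missing genotypes
("./1") are coerced to missing: fingerprinting compares unordered
allele pairs, so neither phase nor a half-called genotype carries
usable information, and the conservative coercion avoids inventing an
allele count. Multi-allelic and non-SNP records are retained on import
and rejected by the filter rather than silently skipped, so rejection
counts account for every input record. Duplicate sample names are a
hard error — silently renaming them would corrupt fingerprint
identities. All public coordinates are 1-based inclusive (VCF/GFF3
convention); the BED export converts to 0-based half-open explicitly.

## Codon degeneracy

A site's fold class is the number of nucleotides at its codon position
encoding the codon's amino acid (1 = nondegenerate … 4 = fourfold),
under the standard genetic code only — the toolkit targets nuclear
plant genomes. Stop codons count as their own "amino acid" for
synonymy; codons containing ambiguity codes are classified
nondegenerate so they can never be selected. The codon around a site
is reconstructed from the spliced CDS: segments are concatenated in
transcription order (reverse-complemented for minus-strand
transcripts), the first segment's phase trims the 5' partial codon,
and codons spanning segment boundaries are handled by the
concatenation itself. A transcript whose phase-adjusted CDS length is
not a multiple of three is recorded as broken and raises an error
naming the transcript only when a queried site falls inside it.
Degenerate edge cases: bases inside the 5' partial codon trimmed by
phase are nondegenerate (no complete codon exists for them); a site
covered by several transcripts must receive the same fold class from
all of them, otherwise it is reported as a conflict and is never
fourfold — the conservative choice maximizes the neutrality of
selected markers.

## Candidate filter

Six criteria, with the thresholds as strict inequalities (a marker
with MAF exactly 0.3 or heterozygosity exactly 0.2 is rejected):
biallelic SNP; fourfold-degenerate site; heterozygosity < 0.2; missing
rate < 0.05; MAF > 0.3; no other variant within ±100 bp. Each
statistic is computed independently on the full sample set
(complete-case allele frequencies, no small-sample correction — the
bundled regression table confirms the uncorrected form). Rejections
are attributed to the first failing criterion in the order above, but
the surviving set is the intersection of per-criterion pass sets, so
the outcome is order-independent and filtering is idempotent. The
flank criterion consults the full raw variant set including InDels
(whose deleted-reference span counts, not just the anchor base), since
an unqualified "no variants in the flanks" is what assay primers
require. Undefined statistics propagate as NaN: an all-missing column
cannot demonstrate excess heterozygosity (NaN passes that criterion)
but fails the missing-rate and MAF criteria, so it is always rejected,
attributed to missingness.

KASP-region validation extracts the ±100 bp window around a candidate,
computes GC content over the whole 201-bp window (threshold GC < 0.60),
checks the flanks for interfering variants, and requires the window to
occur exactly once in the genome by exact forward-strand substring
search — a deterministic, dependency-free specificity screen; users
needing homology-aware screening can export the windows as FASTA and
run an aligner. Primer design itself (allele-specific tails, melting
temperature) is out of scope; the recorded `product_max_bp` is
metadata for downstream design software.

## Diversity statistics

For alternate-allele frequency p estimated from called alleles:
gene diversity He = 1 − p² − q², PIC = He − 2p²q² (the biallelic
closed form of the Botstein PIC), observed heterozygosity = het calls
/ called, missing rate over all samples. Values are kept at full
precision; display rounding to 3 decimals matches the bundled
reference table. The panel summary's gene-diversity band [0.4, 0.5] is
inclusive at both ends because markers at the biallelic ceiling reach
exactly 0.500 and belong in the band. The bundled 41-marker table is a
standing regression: recomputing PIC and He from each printed MAF
reproduces all 82 printed cells within 0.001 — exact 3-decimal
rounding identity is unattainable because the printed MAF is itself
rounded, which can move the recomputed value by up to ~0.0007.

## Panel selection

Genotype strings use unordered allele-pair tokens with heterozygotes
alphabetically sorted and "NN" for missing. By default two missing
calls at the same marker match each other (missing is a distinct
symbol), which mirrors literal string joining and keeps discernibility
a simple distinct-count; a "wildcard" mode treats missing as matching
anything for conservative duplicate calling. Wildcard compatibility is
not transitive, so groups are defined as connected components of the
pairwise-compatibility graph and the distinct-genotype count is the
number of components.

The randomized search draws k-subsets uniformly without replacement
within a draw and with possible repeats across draws (no
deduplication), with defaults of 5000 draws per size and 10,000 for
cumulative-efficiency curves. All subsets achieving a size's maximum
are retained, sorted for determinism. The RNG is numpy's PCG64,
seeded; identical seeds give byte-identical output. An exhaustive
mode enumerates all subsets for ≤ 20 markers — an extension used as
the optimum oracle in testing and for small panels. The minimal panel
size scans sizes ascending until the best discernibility equals the
full panel's; the full panel trivially achieves its own score, so the
scan terminates. Per-size best curves can be non-monotone due to
sampling noise; the reported running maximum is non-decreasing by
construction.

## Fingerprint database

Duplicate grouping inherits the panel module's missing-data mode, so
database group counts always equal the corresponding discernibility
numerator. The barcode payload is a documented plain-text scheme
(`FP1|<panel-hash>|<sample>|RHAN...`, one symbol per marker) rather
than an opaque image; the 12-hex-digit SHA-256 panel hash covers
marker ids, positions, alleles and order, and decoding against a
database with a different hash fails loudly. QR rendering of the
payload is deliberately left to external tools.

## Synthetic fixtures

The generator emulates the two cohort types of a cultivar
fingerprinting study: a near-homozygous screening panel (preset: 153
lines, heterozygosity 0.08, 2% missing) and a market-hybrid cohort
(default: 329 cultivars, heterozygosity 0.39, 3% missing, cloned
duplicate groups of 12 and 11 — duplicate cultivars under different
names are a real feature of seed markets). Marker target MAFs default
to U(0.35, 0.48), the range a MAF > 0.3 screen produces. Markers sit
every 300 bp on a toy chromosome; fourfold sites are placed at the
third position of a 4D-family codon inside a small synthetic gene
(strands alternate), remaining sites are intergenic. Planted filter
violations (excess heterozygosity, missingness, low MAF, a third
allele, a decoy variant 50 bp into the flank) each occupy their own
marker with targets far from the thresholds.

Genotype columns are built by exact composition by default: genotype
counts deterministically hit the targets and only their assignment to
samples is randomized, so a screening-type plan fully determines the
filter outcome, which the manifest records (expected survivors and
per-criterion rejection counts, with a generator-side assertion that
realized statistics landed on the intended side of every threshold).
Plans with cloned duplicates or hybrid-level heterozygosity perturb
per-marker counts, so for them the manifest omits filter expectations
rather than state unreliable ones. The "iid" mode draws genotypes
independently per sample (hom/het/hom-alt probabilities chosen to hit
the target allele frequency at the given heterozygosity) for
sampling-theory checks; at Hardy–Weinberg heterozygosity the allele
count is exactly binomial, which is what the MAF-recovery check
assumes. Duplicate groups are cloned after missing-data masking so
clones are exact string duplicates. What the generator does not
emulate: linkage disequilibrium, population structure (a
two-subpopulation mode is out of scope), realistic allele-frequency
spectra, or genotyping-platform error modes — so passing tests
demonstrate algorithmic correctness on known structure, not robustness
to real-data artifacts.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated
data: the oracle-equivalence checks use 8–12 markers (where exhaustive
enumeration is exact), filter exactness uses 10 markers × 60 samples,
MAF recovery uses 10 markers × 500 samples, and fingerprinting uses 15
markers × 50 samples with the planted 12/11 clone groups. These sizes
make every expected outcome computable by brute force while exercising
the same code paths as genome-scale inputs.

## Known limitations

Only the standard genetic code; GFF3 is the only annotation dialect
(GTF conversion is the user's job — GFF3 has single, well-specified
phase semantics); no BCF, structural variants or polyploid genotypes;
window uniqueness is exact-match, not homology-aware; no multi-allelic
PIC, linkage disequilibrium or F-statistics; panel search is
randomized sampling, not integer programming — matching the workflow
it implements.
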