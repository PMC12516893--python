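# Methods

## Overview

`tillseq` implements the analysis of an amplicon TILLING-by-sequencing
screen: M2 families of an EMS-mutagenized population are pooled on a
three-dimensional grid, target-gene amplicons are deep-sequenced per pool,
and induced point mutations are detected as low-allele-fraction variants
whose positive-pool pattern identifies the carrier family.  All coordinates
are 0-based half-open internally; GFF3 and VCF exports convert to their
1-based standards.

## Pooling model

Families occupy cells of a `d × d × d` cube; family *i* sits at
`(r, c, d) = (i // d², (i // d) % d, i % d)` (row-major — the ordering is a
package convention, chosen because it is deterministic and trivially
invertible).  Each axis slice is one pool, so there are `3d` pools and every
family is in exactly three.  Partially filled cubes fill cells in index
order, so trailing pools may be smaller.  Deconvolution intersects, over the
axes that have any positive pool, the union of memberships of that axis's
positive pools; patterns missing an axis are *incomplete*, multi-family
intersections are *ambiguous* and are always reported rather than dropped
(real screens report more candidate families than mutations for exactly this
reason).

## Synthetic data generator

The generator emulates the study conditions and is first-class, tested code:

| parameter | default | meaning |
|---|---|---|
| `n_families`, `cube_dim` | 512, 8 | 24 pools of 64 families |
| `n_amplicons`, `n_genes` | 17, 13 | amplicon panel |
| `length_range` | 452–704 bp | uniform amplicon lengths |
| `divergence` | 0.005 /bp | substitution-only difference between the two parental genomes, never inside primers |
| `freq_kb` | 320 kb | one EMS mutation per 320 kb screened (Poisson) |
| `het_fraction` | 1.0 | detected M2 mutations are heterozygous; homozygous simulation retained as a parameter |
| `coverage` | 11.3× | per family, per pool |
| `error_rate` | 0.002 /base | i.i.d. substitution errors |
| `read_length` | 150 bp | single-end reads |
| `genome_mix` | 0.5 | probability a family haplotype derives from parental genome B |

Mutations are spiked at uniformly random conserved G/C sites (G→A, C→T) in
uniformly random families.  Sites where the parental genomes differ are
excluded from spiking: such sites are masked from calling by construction
(they carry genotype, not mutation), so spiking them would only measure the
mask, not the caller.  Each family's two haplotypes draw their parental
origin once (consistent across the three pools containing the family), and a
heterozygous mutation sits on one haplotype, giving an expected pool variant
allele fraction of `1/(2 × pool size)` = 1/128 at the defaults.

Reads are tiled circularly: fragment starts are evenly spaced around the
amplicon with a random phase per family and pool, wrap-around fragments are
split at the amplicon boundary, and split pieces shorter than 30 bp are
re-extended to 30 bp at the boundary (size selection without losing depth).
This keeps per-position depth essentially uniform at
`coverage × pool size` ≈ 723×, which is what makes per-site power comparable
across the amplicon.  An earlier variant that simply discarded short pieces
produced systematic coverage holes in the first and last 30 bp of every
amplicon and visibly inflated the variance of carrier allele counts.

Not simulated (and therefore not demonstrated by passing tests): PCR bias
and chimeras, indels, quality-score error profiles, pool-to-pool coverage
dispersion (real screens show wide variation between pools), and
contamination between wells.  Real data would also bring primer-site
polymorphisms and mapping ambiguity between paralogs that the simplified
amplicon references cannot produce.

## Read assignment

Reads are placed by an exact 21-mer seed looked up in an index of both
parental sequences of every amplicon, tried at read offsets 0, 21 and 42 and
then on the reverse complement; the first seed hit whose full-length Hamming
mismatch fraction is ≤ 0.1 against the better genome wins.  Multiple seed
offsets matter: a single start-anchored seed loses every read whose first
21 bp contain a sequencing error (~4 % of reads at 0.2 % error) or the
mutation itself (~14 % of mutation-supporting reads), which both costs
detection power and drags mapping efficiency down.  Genome ties break toward
genome A, so the pileup is deterministic; reverse-complement hits are
collapsed to reference-forward orientation before counting.  Gapped
alignment is unnecessary because the parental divergence is
substitution-only and the references are the amplicons themselves.

## Mutation calling and its calibration

For each EMS-consistent test (alternate A at reference G sites, T at C
sites; divergent sites masked) the caller computes per-pool alternate counts
and depths.  The per-pool exact binomial upper tail
`P(X ≥ alt | n = depth, p = e/3)` is reported per supporting pool, with `e`
estimated per amplicon as the median non-reference allele fraction at
unmasked sites (floored at 1e-4).

The decision rule is joint across the three axes.  Let `M_R, M_C, M_D` be
the per-axis maximum alternate counts at the site and `S = M_R + M_C + M_D`.
A site is called when every axis reaches `min_alt` (default 2) and
`S ≥ t*`, where `t*` is the smallest integer such that

    N_tests × P(all three axis maxima ≥ min_alt and S ≥ t* | error-only null) ≤ α

with the null per-pool count Bin(mean depth, e/3), the per-axis maximum over
`d` pools and the three-axis sum computed by exact convolution, and
`N_tests` the number of EMS-consistent unmasked sites in the panel.  This
controls the *expected number of false candidates per run* at α = 0.05
exactly, which a per-pool Bonferroni test cannot do without destroying
power: at 11.3× per family a heterozygous carrier contributes only ~5.7
alternate reads per pool, so any per-pool threshold with a genome-wide-safe
null tail (≥ 7–8 reads) has per-pool power below ~0.6 and three-axis power
below ~0.2.  Pooling the evidence across axes before thresholding is what
makes ≥ 90 % recovery and ≤ 0.05 false candidates per run simultaneously
achievable; at the default conditions `t* = 13` and the calibrated rule
measures ~92 % recovery with no false candidates observed in 20
mutation-free replicates.

`min_alt = 2` rather than 3 is likewise a power choice: requiring 3 reads in
*every* axis pool costs ~5 % of carriers at 11.3× (P(Bin(11, ½) ≥ 3)³ ≈
0.93) while the joint threshold, not the per-pool floor, carries the false-
positive control.

Deconvolution feeds the per-axis *maximal* pools into the set-intersection
deconvolver; count ties between an error pool and the carrier pool on an
axis produce an honest *ambiguous* call listing all compatible families.
Pools at or above `min_alt` are reported as supporting pools alongside.  In
strict mode (default) all three axes are required; permissive mode accepts
two axes and flags the candidate low-confidence (its deconvolution is then a
fiber of the cube, not a family).

Two carriers of the same mutation at the same site (expected about once per
few hundred mutations at the default density) produce two positive pools per
axis; the pool pattern is then genuinely non-identifiable between the two
consistent family pairings and the call is reported ambiguous with all
compatible families.

## Effect annotation

Positions map through the amplicon-local exon model to codons; translation
uses the standard nuclear code.  `cds_offset` is the frame of the first
exonic base; codons truncated by the amplicon edge cannot be classified and
fall back to `noncoding`.  Intronic bases within 2 bp of an exon boundary —
the essential GT donor and AG acceptor dinucleotides — are `splice_site`;
exonic classification wins where both could apply; primer-region positions
are `noncoding`.  Minus-strand amplicons are mirrored into transcript
orientation and classified identically (a tested symmetry).

Rounding conventions are fixed so the platform statistics print in the
conventional form: protein-affecting fraction to one decimal (134/3,935 →
3.4 %), detection accuracy to a whole percent (14/17 → 82 %), and mutation
frequency as "1/X kb" with X rounded to the nearest 10 kb (4,474 kb / 14 →
319.6 → "1/320 kb").  The screened total is treated as kilobases throughout:
17 amplicons × ~514 bp × 512 families ≈ 4,474 kb, and 4,474/14 = 319.6 is
the only reading consistent with "1/320 kb" — a printed "Mbp" unit for that
figure is a unit slip, not a different quantity.

## Marker design

Allele-specific (PACE/KASP-style) primers are grown 5′-ward from the SNP
until both allele variants' melting temperatures enter the window; the two
allele primers are identical except for the fluorophore tail (standard FAM
and HEX universal tails, excluded from Tm) and the 3′-terminal base.  The
common primer is selected on the opposite strand downstream to satisfy the
product-size range.  Tm uses nearest-neighbor thermodynamics with the
unified parameter set at 50 mM monovalent salt and 200 nM primer (CT/4
convention, SantaLucia entropy salt correction); defaults — Tm window
57–63 °C, primer length 18–30 nt, product 60–120 bp — follow common
PACE/KASP practice and are configuration-exposed, since the original assay
conditions are not part of the package's inputs.  Designs are checked to
anneal uniquely within their amplicon; genome-wide off-target search is out
of scope.

Segregation uses the Pearson chi-square with df = 1 and no continuity
correction (the worked 13:12 backcross split gives χ² = 0.04, p ≈ 0.84,
consistent with 1:1); the correction-free form is the conventional choice
for reporting simple ratio fits and is what the closed form
`Σ (obs − exp)²/exp` reproduces exactly.

## Numerical and design notes

- Sequences are handled as uint8 code arrays (A,C,G,T = 0..3; anything else
  4, excluded from base counts, mismatched by the aligner).
- Binomial tails come from `scipy.stats.binom.sf`; tests verify them against
  direct log-space mass summation up to depth 1000.
- The calibration lumps the far tail of the per-pool null at count 200;
  contributions beyond are < 1e-12 at the depths involved.
- All randomness flows from one `numpy` SeedSequence per run, spawned into
  independent streams for references, mutations and reads; fixtures are
  bit-for-bit reproducible under a fixed seed, including FASTQ checksums.
- Replicate studies use the in-memory pipeline (`tillseq.pipeline`); the CLI
  round-trips through FASTA/GFF3/FASTQ/TSV and reproduces identical counts,
  which is itself under test.
- Platform-scale checks use 20 replicates (~15 spiked mutations each) plus
  20 mutation-free replicates; with ~1M reads per replicate this keeps the
  whole suite at a few minutes on one CPU while the binomial uncertainty on
  a 90 % recovery bound stays below ~2 percentage points.

## Known limitations

- The caller assumes one carrier per site when converting pool patterns to
  families; co-located carriers are reported ambiguous rather than resolved.
- The error model is a single uniform substitution rate; context-dependent
  error (e.g. homopolymer or oxidation artifacts) would require a
  position-aware null.
- Marker designs satisfy thermodynamic and uniqueness constraints within the
  amplicon only; no genome-scale specificity screen, multiplexing check, or
  secondary-structure screen is performed.
- Homozygous mutations (double pool VAF) are simulated but the caller is
  tuned for the heterozygous M2 case; WGRS-scale analysis is out of scope.
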