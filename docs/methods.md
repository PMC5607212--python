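# Methods

## The problem

`enumap` re-implements, as a tested pipeline on synthetic data, the
positional-cloning analysis used to identify a recessive, male-limited
meiotic mutation induced by ENU mutagenesis in mice.  The screen mutagenizes
C57BL/6J (B6) males, outcrosses to FVB/NJ (FVB), and "homozygoses" recessive
mutations over three generations.  Because every induced lesion arises on a
B6 chromosome, affected third-generation (G3) males must be homozygous for
B6-derived sequence around the causal site; the analysis finds that region
from SNP-array genotypes, lists candidate lesions from pooled exome calls,
and winnows them by genotyping more animals.  A separate dot-plot module
detects the tandem gene duplication signature that analysis of the
identified gene's locus revealed.

## Breeding and meiosis model

The scheme is: mutagenized B6 male × FVB female → F1 male; F1 × FVB females
→ G2 daughters; G2 × F1 (father) → G3 males, which are phenotyped.  If the
F1 is heterozygous for a lesion, half the G2 daughters are carriers and one
eighth of G3 sons are homozygous.  The simulator conditions on a carrier F1
(rejection sampling) because only carrier lines yield mutants and proceed to
mapping; the 1/2 and 1/8 fractions are defined conditional on that.

Meiosis follows the Haldane model: per chromosome, the crossover count is
Poisson with mean equal to the genetic length in Morgans
(`length_bp × rate / 100 / 1e6`), crossover positions are uniform, and there
is no interference.  The default rate is 0.5 cM/Mbp, a typical sex-averaged
mouse autosomal value.  Haplotypes are ordered ancestry segments (closed,
1-based) plus the set of lesion positions carried; every gamete is
constructible only if its segments tile the chromosome and its lesions sit
inside B6 segments.  Phenotype is fully penetrant and male-limited by
default (`penetrance` is configurable for robustness experiments); females
are left unscreened.

Sex chromosomes are not simulated: the informative-marker criteria restrict
the panel to autosomes anyway.  Crossover interference, real genetic maps
and ENU dose–response are out of scope.

## The simulated genome

One 160-Mbp autosome named `chr2` stands in for mouse chromosome 2, with the
causal A>G lesion planted at 153,727,342 — the coordinate of the rahu
mutation in Dnmt3c — so the locus geometry (a causal site near one
chromosome end) matches the real screen at desk scale.  Defaults: 120
informative panel markers and 300 archived strain polymorphisms on
deterministic grids, and 7 passenger ENU lesions at uniform random positions
per simulated line.  Seven passengers mirrors the candidate load the real
exome analysis faced within one chromosome; genome-wide ENU loads of a few
dozen heterozygous coding lesions scale to single digits on one chromosome.
All counts, lengths, rates and the seed live in `RunConfig` (YAML-loadable).

## Assays

*Panel genotyping* maps haplotype-ancestry pairs to `B6B6`/`HET`/`FVBFVB`;
the only default error mode is missingness (array calls are treated as
reliable; a miscall rate exists for experiments).  *Pooled exome calls*
emit one record per lesion or polymorphism at which the pooled DNA carries
an alternate allele, with Poisson read depth; the zygosity call is `HOM`
only when every pooled animal is homozygous — the pooling rationale of the
original design, where shared homozygosity in three mutants boosts the
causal lesion.  The allele-fraction threshold an actual caller would use is
not modelled; the all-or-mixed rule is this package's contract.  *RFLP
scanning* matches IUPAC patterns (with the standard Hpy188I site TCNGA
stored as data) on both strands; an `N` in the subject sequence never
matches, since an ambiguous base cannot confirm a site.

## Homozygosity mapping

Per chromosome, the mapper reports every maximal run of informative markers
at which all affected animals are `B6B6`, flanked by the nearest marker at
which at least one affected animal is not.  Missing calls are compatible
with homozygosity but never define flanks — a no-call must not break a true
interval.  Interval size is flank-to-flank in Mbp, rounded to two decimals
(the published 33.58 Mbp equals 161,380,222 − 127,800,747 under exactly
this convention).  Runs touching a chromosome end carry an `open_ended`
flag.  Adjacent runs are never merged across a non-`B6B6` marker.

Exclusion by phenotypically normal animals (`exclude_by_normals`) drops an
interval in which some normal animal is explicitly `B6B6` at every core
marker.  The pipeline applies it at the fine-mapping stage only, by
default: with a sparse panel, a normal animal can be B6-homozygous at every
core marker of a narrow interval yet heterozygous at the lesion *between*
markers (one crossover suffices when the markers sit on one side of the
lesion), so coarse-stage exclusion can discard the true interval.  At the
winnow stage genotypes are read at the candidate sites themselves and the
same logic is sound.  `RunConfig.exclude_normals_at_coarse` restores
coarse-stage exclusion for users who want the aggressive variant.

If no marker run survives — the shared region can fall entirely between
markers, which happens in roughly 1% of default-geometry runs — the
pipeline proceeds to fine mapping without a positional restriction (an
open whole-chromosome interval) rather than failing: that is what an
analyst does when the array stage is uninformative.

## Candidate filtering and winnowing

Exome records become candidate lesions when depth ≥ 6 reads, the call is
homozygous, no archived reference-SNP identifier is attached, and the
position lies strictly inside the mapped interval; the flanking sites
themselves are excluded, which is what makes the refined 17.43-Mbp region
contain exactly one of the seven variants (the Rrbp1 change at 143,947,738
is itself the refined left flank).  Each criterion only removes records, so
the filters commute.

Winnowing genotypes are coded relative to the allele that travels with the
B6 haplotype (the alternate allele at a lesion, the B6 base at a strain
polymorphism), so a single rule covers both site classes: a candidate is
excluded if any unaffected animal is `HOM` or any affected animal is `HET`
or `WT` at it; `MISSING` never excludes.  Interval refinement takes the
innermost incompatible sites bracketing *all* still-compatible sites as new
flanks.  An incompatible site interleaved between compatible ones (possible
via double crossovers) is left inside the interval — conservative, and the
causal site is always retained; an error is raised only when no compatible
site remains, which signals genotype/phenotype inconsistency.

The Mendelian segregation check is a chi-square goodness-of-fit test
(scipy) against an expected ratio, with zero-expectation classes required
empty and dropped; the raw p-value is reported without multiple-testing
correction since it is a single planned test.

## Dot plots and duplication calls

Matches are all pairs of window start positions (step 1 bp) whose windows
are identical, case-insensitive; windows containing lowercase (soft-masked
repeat) or `N` bases never match, so inputs should be repeat-masked
beforehand.  Only the forward strand is scanned — the duplication
signatures of interest are direct repeats.  Default window 20 bp; 15 and 13
bp are the conventional choices for cross-species and short-exon scans.

A run of k consecutive same-offset matches certifies k + w − 1 bp of 100%
identity; `longest_identical_stretch` maximizes this over offsets.
Segments group same-offset matches split at gaps larger than `max_gap`
missing windows and discard runs below `min_windows`.  The duplication
classifier calls `duplication_present` when a segment's offset magnitude is
at least `min_offset_fraction` (default 0.5) of the midpoint distance
between the two gene regions *and* the segment connects one region on one
axis to the other region on the other axis; `duplication_absent` when
segments exist but all substantial ones are near-diagonal; `indeterminate`
with no segments at all.

## What the synthetic data does and does not show

The generator reproduces the screen's genetic structure — Mendelian
transmission with Haldane crossovers, B6-linked lesions, strain-informative
markers, archived-vs-novel variant labelling, depth noise — under error-free
genotyping by default.  It does not model array miscalls, alignment or
variant-calling artefacts, segmental duplications confusing exome capture,
reduced penetrance, or phenotyping error; the 100% lesion-recovery result
therefore demonstrates soundness of the analysis logic under the stated
error model, not expected performance on raw real-world data.  Problem
sizes used by the test suite and acceptance script (10,000-animal cohorts
for fraction recovery; 100 simulated screens; 1,000 random mapper instances
against a brute-force oracle; 200 random dot-plot instances; 50 seeds per
duplication fixture class) were chosen to give tight binomial error bars
while keeping a full run in well under a minute each.

## Numerical and degenerate-input choices

Coordinates are 1-based with closed intervals throughout.  Crossover
breakpoints drawn at the same position collapse (an even hit is no net
crossover).  Zero recombination rate transmits whole parental haplotypes.
Zero mean depth yields `NOCALL` records.  Ties between adjacent intervals
are never merged.  All randomness flows from one integer seed through
explicitly passed numpy generators; identical config + seed reproduces
byte-identical output bundles.
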