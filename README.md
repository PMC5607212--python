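# enumap

Positional cloning of recessive ENU-induced mouse mutations: a simulator
and analysis pipeline for homozygosity mapping, exome candidate winnowing,
and dot-plot detection of tandem gene duplications.

## The problem

Forward-genetics screens in the mouse induce random point mutations with
the mutagen ENU in C57BL/6J (B6) males, then outcross to FVB/NJ (FVB) and
breed for three generations to make recessive mutations homozygous: an
F1 founder male is crossed to FVB females, and his G2 daughters are crossed
back to him, so that — if the F1 carries a mutation of interest — 1/2 of G2
daughters are carriers and 1/8 of G3 sons are homozygous.  Because every
induced lesion arises on a B6 chromosome, affected G3 males must be
homozygous for B6-derived sequence around the causal site.  The mapping
analysis exploits exactly that:

1. **Coarse mapping.**  Genotype affected males at informative panel SNPs
   (autosomal, B6 allele ≠ FVB allele, heterozygous in the F1).  Candidate
   regions are maximal marker runs at which *all* affected animals are
   B6-homozygous, flanked by the nearest marker where one is not; interval
   size is flank-to-flank, `(pos_R − pos_L)/10⁶` Mbp.
2. **Candidate lesions.**  Exome-sequence pooled mutants and keep variants
   with depth ≥ 6 reads, a homozygous call, no archived reference-SNP ID,
   and a position strictly inside the mapped interval.
3. **Winnowing.**  Genotype more animals at those sites: a candidate that
   is homozygous in a phenotypically normal animal, or heterozygous /
   wild-type in an affected one, cannot be a fully penetrant recessive
   cause.  The same observations move the interval flanks inward.

The package simulates the whole screen (Haldane meiosis: Poisson crossover
count with uniform positions, no interference), runs the analysis on the
simulated observables, and reports whether the planted lesion is recovered.
A separate module computes windowed-identity dot plots (a dot = 100%
identity in a w-bp window, step 1 bp, masked bases excluded) and classifies
tandem-duplication signatures from off-center diagonal segments connecting
two gene loci.  An IUPAC restriction-site scanner supports RFLP genotyping
design (e.g. an A>G transition creating a novel Hpy188I site, TCNGA).

## Worked example

The package ships an in-memory fixture encoding the published coordinates
of a real screen on mouse chromosome 2.  From a shell:

```sh
enumap fixture --out-dir fx
enumap map --affected fx/affected_calls.tsv --f1 fx/f1_calls.tsv \
           --panel fx/panel.tsv --out intervals.tsv --out-json intervals.json
cat intervals.tsv
```

prints the coarse-mapping result — a single shared-homozygosity cluster:

```
chrom	left_pos	right_pos	size_mbp	left_id	right_id	open_ended
chr2	127800747	161380222	33.58	gnf02.126.027	rs3664408	False
```

i.e. a 33.58-Mbp interval between the heterozygous flanking SNPs
gnf02.126.027 and rs3664408.  Then

```sh
enumap winnow --variants fx/variants.tsv --observations fx/observations.tsv \
              --intervals intervals.json --out winnow.json
```

filters the exome table to **7** candidate variants inside the interval
(decoy records failing one criterion each are rejected), excludes six of
them from the genotyping observations, and refines the interval to
**17.43 Mbp** (left flank moved to the Rrbp1 variant at 143,947,738), which
contains exactly **1** surviving candidate: `chr2:153,727,342` — the A>G
lesion.  A fully simulated screen runs end to end with:

```sh
enumap simulate --seed 1 --out-dir run1
# causal recovered: True (1 surviving candidate(s))
```

writing the pedigree, all intermediate tables and a JSON summary to
`run1/`.  The same machinery is available as a library
(`enumap.run_screen_pipeline(RunConfig(seed=1))`), and
`enumap dotplot seq.fa --self --triangular --window 20 --out-prefix dp`
produces match/segment tables and a text raster for duplication analysis.

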