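"""Pedigree and meiosis simulation for the three-generation screen.

The breeding scheme homozygoses recessive ENU mutations: a mutagenized B6
male is outcrossed to FVB females, each F1 founder male is crossed to FVB
females to produce G2 daughters (half of which carry a given F1-heterozygous
mutation), and G2 daughters are backcrossed to their F1 father so that one
eighth of G3 sons are homozygous for the mutation.  Because the mutations
arise on the B6 background, an affected G3 male is homozygous for B6-derived
sequence around the lesion — the premise of homozygosity mapping.

Meiosis uses the Haldane model: crossover count per chromosome is Poisson
with mean equal to the genetic length in Morgans, crossover positions are
uniform, and there is no interference.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from enumap.genome import B6, FVB, GenomeSpec

Segment = tuple[int, int, str]  # (start, end, ancestry), closed 1-based


@dataclass
class Haplotype:
    """One chromosome copy: ancestry segments plus carried lesion alleles.

    ``segments`` tile ``[1, L]`` without gaps or overlaps, adjacent segments
    have different ancestries, and every carried lesion position lies inside
    a B6-ancestry segment (ENU lesions are B6-linked by construction).
    """

    chrom: str
    segments: list[Segment]
    lesion_alleles: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        # cache segment starts for bisect-based ancestry lookup
        self._starts = [seg[0] for seg in self.segments]

    def validate(self, length: int) -> None:
        if not self.segments:
            raise ValueError("haplotype has no segments")
        if self.segments[0][0] != 1 or self.segments[-1][1] != length:
            raise ValueError("segments do not tile [1, L]")
        for (s1, e1, a1), (s2, e2, a2) in itertools.pairwise(self.segments):
            if s2 != e1 + 1:
                raise ValueError("gap or overlap between segments")
            if a1 == a2:
                raise ValueError("adjacent segments share ancestry")
        for start, end, _ in self.segments:
            if start > end:
                raise ValueError("empty segment")
        for pos in self.lesion_alleles:
            if self.ancestry_at(pos) != B6:
                raise ValueError(f"lesion at {pos} outside a B6 segment")

    def ancestry_at(self, pos: int) -> str:
        idx = bisect_right(self._starts, pos) - 1
        if idx < 0 or pos > self.segments[idx][1]:
            raise ValueError(f"position {pos} outside haplotype")
        return self.segments[idx][2]

    def carries_lesion(self, pos: int) -> bool:
        return pos in self.lesion_alleles


def _uniform_haplotype(spec: GenomeSpec, chrom: str, ancestry: str,
                       lesions: frozenset[int] = frozenset()) -> Haplotype:
    return Haplotype(chrom, [(1, spec.chrom_length(chrom), ancestry)], lesions)


@dataclass
class Individual:
    id: str
    sex: str  # "M" or "F"
    generation: str  # F0_B6, F0_FVB, F1, G2, G3, G4
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    phenotype: str = "unscreened"  # affected / unaffected / unscreened
    dam_id: str | None = None
    sire_id: str | None = None

    def genotype_at(self, chrom: str, pos: int) -> tuple[str, str]:
        """Ancestry pair of the two haplotypes at a position."""
        h1, h2 = self.haplotypes[chrom]
        return h1.ancestry_at(pos), h2.ancestry_at(pos)

    def lesion_dose(self, chrom: str, pos: int) -> int:
        """Number of haplotypes (0, 1 or 2) carrying the lesion allele."""
        h1, h2 = self.haplotypes[chrom]
        return int(h1.carries_lesion(pos)) + int(h2.carries_lesion(pos))

    def is_homozygous_lesion(self, chrom: str, pos: int) -> bool:
        return self.lesion_dose(chrom, pos) == 2


@dataclass
class Pedigree:
    """Id-keyed individuals with parent links; acyclic by construction."""

    individuals: dict[str, Individual] = field(default_factory=dict)
    rng_seed: int | None = None

    def add(self, individual: Individual) -> None:
        if individual.id in self.individuals:
            raise ValueError(f"duplicate individual id {individual.id!r}")
        for parent in (individual.dam_id, individual.sire_id):
            if parent is not None and parent not in self.individuals:
                raise ValueError(f"unknown parent {parent!r}")
        self.individuals[individual.id] = individual

    def by_generation(self, generation: str) -> list[Individual]:
        return [ind for ind in self.individuals.values()
                if ind.generation == generation]


def make_founder(spec: GenomeSpec, strain: str, *, mutagenized: bool = False,
                 individual_id: str = "", sex: str = "M",
                 lesion_zygosity: str = "het",
                 rng: np.random.Generator | None = None) -> Individual:
    """Create an inbred founder; optionally plant all spec lesions on it.

    Mutagenized founders must be B6: the screen mutagenizes B6 males, so
    every ENU lesion is linked to B6 background polymorphisms.  With the
    default heterozygous zygosity, lesions go on one haplotype only.
    """
    if strain not in (B6, FVB):
        raise ValueError(f"unknown strain {strain!r}")
    if mutagenized and strain != B6:
        raise ValueError("only B6 founders are mutagenized")
    if lesion_zygosity not in ("het", "hom"):
        raise ValueError("lesion_zygosity must be 'het' or 'hom'")

    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = {}
    for chrom, _length in spec.chromosomes:
        lesions_here = frozenset(
            lesion.pos for lesion in spec.lesions if lesion.chrom == chrom
        ) if mutagenized else frozenset()
        h1 = _uniform_haplotype(spec, chrom, strain, lesions_here)
        h2 = _uniform_haplotype(
            spec, chrom, strain,
            lesions_here if lesion_zygosity == "hom" else frozenset())
        haplotypes[chrom] = (h1, h2)
    generation = "F0_B6" if strain == B6 else "F0_FVB"
    return Individual(individual_id or f"{generation}_{sex}", sex, generation,
                      haplotypes)


def simulate_meiosis(parent: Individual, chrom: str, spec: GenomeSpec,
                     rng: np.random.Generator) -> Haplotype:
    """Produce one gamete haplotype for a chromosome (Haldane model).

    Crossover count ~ Poisson(genetic length in Morgans); positions uniform;
    the gamete alternates between the two parental haplotypes starting from
    a fair coin.  Segment ancestries and lesion alleles are copied from
    whichever parental haplotype each interval derives from.
    """
    if chrom not in parent.haplotypes:
        raise KeyError(f"parent has no haplotypes for {chrom!r}")
    length = spec.chrom_length(chrom)
    hap_pair = parent.haplotypes[chrom]

    n_xo = int(rng.poisson(spec.genetic_length_morgans(chrom)))
    # a crossover between pos b and b+1; b in [1, L-1]
    breaks = sorted(set(rng.integers(1, length, size=n_xo).tolist())) if n_xo else []
    current = int(rng.integers(0, 2))

    segments: list[Segment] = []
    lesions: set[int] = set()
    start = 1
    for boundary in [*breaks, length]:
        source = hap_pair[current]
        for seg_start, seg_end, ancestry in source.segments:
            lo, hi = max(seg_start, start), min(seg_end, boundary)
            if lo > hi:
                continue
            if segments and segments[-1][2] == ancestry:
                segments[-1] = (segments[-1][0], hi, ancestry)
            else:
                segments.append((lo, hi, ancestry))
        lesions.update(p for p in source.lesion_alleles if start <= p <= boundary)
        start = boundary + 1
        current = 1 - current

    return Haplotype(chrom, segments, frozenset(lesions))


def cross(dam: Individual, sire: Individual, sex: str, spec: GenomeSpec,
          rng: np.random.Generator, *, individual_id: str = "",
          generation: str = "") -> Individual:
    """Mate two individuals; the offspring gets one gamete from each parent."""
    if dam.sex != "F" or sire.sex != "M":
        raise ValueError("cross requires a female dam and a male sire")
    if sex not in ("M", "F"):
        raise ValueError(f"invalid sex {sex!r}")
    haplotypes = {
        chrom: (simulate_meiosis(dam, chrom, spec, rng),
                simulate_meiosis(sire, chrom, spec, rng))
        for chrom, _ in spec.chromosomes
    }
    return Individual(individual_id, sex, generation, haplotypes,
                      dam_id=dam.id, sire_id=sire.id)


def screen_phenotype(individual: Individual, spec: GenomeSpec,
                     rng: np.random.Generator | None = None,
                     penetrance: float = 1.0) -> str:
    """Phenotype a male for the recessive, male-limited defect.

    Affected iff male and homozygous for the causal lesion (subject to
    penetrance, 1.0 by default).  Females are left unscreened.
    """
    if individual.sex != "M":
        return "unscreened"
    causal = spec.causal_lesion
    if individual.is_homozygous_lesion(causal.chrom, causal.pos):
        if penetrance >= 1.0 or (rng is not None and rng.random() < penetrance):
            return "affected"
    return "unaffected"


def run_breeding_scheme(spec: GenomeSpec, n_g2: int, n_g3_per_g2: int,
                        rng: np.random.Generator, *,
                        ensure_f1_carrier: bool = True,
                        penetrance: float = 1.0,
                        max_f1_draws: int = 1000) -> Pedigree:
    """Simulate the full three-generation scheme and phenotype all G3 males.

    Produces the F0 pair, one F1 male, ``n_g2`` G2 females (each from a
    fresh FVB dam crossed to the F1), and ``n_g2 * n_g3_per_g2`` G3 males
    sired by the F1 on his G2 daughters.  With ``ensure_f1_carrier`` the F1
    is redrawn until he carries the causal lesion, mirroring the fact that
    only carrier lines yield mutants and proceed to mapping.
    """
    if n_g2 < 1 or n_g3_per_g2 < 1:
        raise ValueError("cohort sizes must be >= 1")

    pedigree = Pedigree()
    f0_b6 = make_founder(spec, B6, mutagenized=True, individual_id="F0_B6",
                         sex="M")
    f0_fvb = make_founder(spec, FVB, individual_id="F0_FVB", sex="F")
    pedigree.add(f0_b6)
    pedigree.add(f0_fvb)

    causal = spec.causal_lesion
    for attempt in range(max_f1_draws):
        f1 = cross(f0_fvb, f0_b6, "M", spec, rng, individual_id="F1",
                   generation="F1")
        if not ensure_f1_carrier or f1.lesion_dose(causal.chrom, causal.pos) == 1:
            break
    else:
        raise RuntimeError("no F1 carrier drawn")
    pedigree.add(f1)

    g3_counter = 0
    for i in range(n_g2):
        fvb_dam = make_founder(spec, FVB, individual_id=f"FVB_dam_{i}", sex="F")
        pedigree.add(fvb_dam)
        g2 = cross(fvb_dam, f1, "F", spec, rng, individual_id=f"G2_{i}",
                   generation="G2")
        pedigree.add(g2)
        for _ in range(n_g3_per_g2):
            g3 = cross(g2, f1, "M", spec, rng,
                       individual_id=f"G3_{g3_counter}", generation="G3")
            g3.phenotype = screen_phenotype(g3, spec, rng, penetrance)
            pedigree.add(g3)
            g3_counter += 1
    return pedigree
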