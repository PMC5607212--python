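"""Genome specification for the simulated screen.

A :class:`GenomeSpec` bundles everything the simulator needs to know about
the genome it breeds on: chromosome sizes, a uniform sex-averaged
recombination rate, the SNP linkage panel used for coarse mapping, a database
of archived strain polymorphisms (sites where the two parental inbred strains
differ and which carry reference-SNP identifiers), and the ENU lesions
planted on the mutagenized founder.

Coordinates are 1-based and intervals are closed throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

B6 = "B6"
FVB = "FVB"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Marker:
    """One biallelic SNP on the linkage panel.

    ``allele_b6`` / ``allele_fvb`` are the bases fixed in the two parental
    strains; a marker is strain-informative only when they differ.
    """

    id: str
    chrom: str
    pos: int
    allele_b6: str
    allele_fvb: str
    autosomal: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1")
        for allele in (self.allele_b6, self.allele_fvb):
            if allele not in _VALID_BASES:
                raise ValueError(f"marker {self.id}: invalid allele {allele!r}")

    @property
    def informative(self) -> bool:
        return self.autosomal and self.allele_b6 != self.allele_fvb


@dataclass(frozen=True)
class Lesion:
    """An ENU-induced point mutation planted on the mutagenized B6 founder."""

    chrom: str
    pos: int
    ref: str
    alt: str
    label: str = ""
    causal: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"lesion {self.label or self.pos}: ref == alt")
        if self.pos < 1:
            raise ValueError("lesion position must be >= 1")


@dataclass(frozen=True)
class Polymorphism:
    """An archived strain-polymorphic site (B6 reference vs FVB alternate).

    ``archived_id`` is the reference-SNP style identifier that distinguishes
    these sites from novel ENU lesions in exome variant tables.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    archived_id: str

    def __post_init__(self) -> None:
        if not self.archived_id:
            raise ValueError("polymorphism requires an archived id")
        if self.ref == self.alt:
            raise ValueError(f"polymorphism {self.archived_id}: ref == alt")


@dataclass
class GenomeSpec:
    """The simulated genome: chromosomes, panel, polymorphisms, lesions.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp)`` pairs.
    recombination_rate
        Uniform rate in cM per Mbp (default 0.5, a typical sex-averaged
        mouse autosomal value).
    markers, polymorphisms, lesions
        Site annotations; positions must fall within their chromosome and be
        unique per chromosome within each category.
    """

    chromosomes: list[tuple[str, int]]
    recombination_rate: float = 0.5
    markers: list[Marker] = field(default_factory=list)
    polymorphisms: list[Polymorphism] = field(default_factory=list)
    lesions: list[Lesion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("GenomeSpec needs at least one chromosome")
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        for group_name, sites in (
            ("marker", self.markers),
            ("polymorphism", self.polymorphisms),
            ("lesion", self.lesions),
        ):
            seen: set[tuple[str, int]] = set()
            for site in sites:
                if site.chrom not in lengths:
                    raise ValueError(
                        f"{group_name} at {site.chrom}:{site.pos}: unknown chromosome"
                    )
                if not 1 <= site.pos <= lengths[site.chrom]:
                    raise ValueError(
                        f"{group_name} at {site.chrom}:{site.pos}: outside chromosome"
                    )
                key = (site.chrom, site.pos)
                if key in seen:
                    raise ValueError(f"duplicate {group_name} position {key}")
                seen.add(key)
        n_causal = sum(lesion.causal for lesion in self.lesions)
        if self.lesions and n_causal != 1:
            raise ValueError(f"exactly one causal lesion required, got {n_causal}")

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def causal_lesion(self) -> Lesion:
        for lesion in self.lesions:
            if lesion.causal:
                return lesion
        raise ValueError("no causal lesion in spec")

    def genetic_length_morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans under the uniform map."""
        return self.chrom_length(chrom) * self.recombination_rate / 100.0 / 1e6
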