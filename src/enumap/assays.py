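"""Simulated assays: SNP-panel genotyping, pooled exome calls, RFLP scans.

These operations turn simulated individuals into the observable tables a
real screen produces: microarray genotype calls at linkage-panel SNPs,
variant tables from exome sequencing of pooled mutants, and restriction-site
gains/losses used for RFLP genotyping of point mutations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from enumap.genome import B6, FVB, GenomeSpec, Marker
from enumap.pedigree import Individual

MARKER_CALL_COLUMNS = ["individual_id", "marker_id", "chrom", "pos", "genotype"]
VARIANT_COLUMNS = ["CHROM", "POS", "REF", "ALT", "DEPTH", "ZYG", "ID"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class RecognitionPattern:
    """A restriction-enzyme recognition sequence in IUPAC nucleotide codes."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty recognition pattern")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")

    def reverse_complement(self) -> str:
        return self.iupac.upper().translate(_COMPLEMENT)[::-1]


# Recognition sequences kept as data; Hpy188I is the enzyme whose site the
# rahu A-to-G transition creates, enabling RFLP genotyping of the allele.
ENZYMES: dict[str, RecognitionPattern] = {
    "Hpy188I": RecognitionPattern("Hpy188I", "TCNGA"),
}


def _ancestry_genotype(individual: Individual, chrom: str, pos: int) -> str:
    pair = sorted(individual.genotype_at(chrom, pos))
    if pair == [B6, B6]:
        return "B6B6"
    if pair == [FVB, FVB]:
        return "FVBFVB"
    return "HET"


def genotype_panel(individuals: Sequence[Individual], markers: Sequence[Marker],
                   missing_rate: float = 0.0,
                   rng: np.random.Generator | None = None,
                   miscall_rate: float = 0.0) -> pd.DataFrame:
    """Genotype individuals at panel markers from haplotype ancestry.

    Each call is independently masked MISSING with ``missing_rate``.  A
    nonzero ``miscall_rate`` (off by default; array calls are treated as
    reliable) replaces a call with a uniformly drawn wrong genotype, for
    robustness experiments.
    """
    if (missing_rate or miscall_rate) and rng is None:
        raise ValueError("rng required when missing_rate or miscall_rate > 0")
    rows = []
    states = ("B6B6", "HET", "FVBFVB")
    for individual in individuals:
        for marker in markers:
            if marker.chrom not in individual.haplotypes:
                raise KeyError(f"marker {marker.id} off-genome")
            genotype = _ancestry_genotype(individual, marker.chrom, marker.pos)
            if miscall_rate and rng.random() < miscall_rate:
                genotype = states[(states.index(genotype)
                                   + 1 + int(rng.integers(0, 2))) % 3]
            if missing_rate and rng.random() < missing_rate:
                genotype = "MISSING"
            rows.append((individual.id, marker.id, marker.chrom, marker.pos,
                         genotype))
    return pd.DataFrame(rows, columns=MARKER_CALL_COLUMNS)


def simulate_exome(pool: Sequence[Individual], spec: GenomeSpec,
                   mean_depth: float, rng: np.random.Generator) -> pd.DataFrame:
    """Variant calls from exome sequencing of a pooled DNA sample.

    Pooling several mutants boosts the causal lesion (shared, homozygous in
    every pooled animal) relative to incidental variation.  One record is
    emitted per lesion or strain polymorphism at which the pool carries at
    least one alternate allele.  Depth is Poisson(``mean_depth``); the
    zygosity call is HOM only when every pooled individual is homozygous for
    the alternate allele, HET when the pool is mixed, NOCALL at zero depth.
    Archived identifiers are attached to strain polymorphisms only.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")

    rows = []
    for lesion in spec.lesions:
        doses = [ind.lesion_dose(lesion.chrom, lesion.pos) for ind in pool]
        rows.append((lesion.chrom, lesion.pos, lesion.ref, lesion.alt,
                     doses, "."))
    for snp in spec.polymorphisms:
        # the alternate allele is the FVB base relative to the B6 reference
        doses = [sum(a == FVB for a in ind.genotype_at(snp.chrom, snp.pos))
                 for ind in pool]
        rows.append((snp.chrom, snp.pos, snp.ref, snp.alt, doses,
                     snp.archived_id))

    records = []
    for chrom, pos, ref, alt, doses, archived_id in rows:
        if not any(doses):
            continue  # monomorphic reference in the pool: no alt call
        depth = int(rng.poisson(mean_depth))
        if depth == 0:
            zyg = "NOCALL"
        elif all(d == 2 for d in doses):
            zyg = "HOM"
        else:
            zyg = "HET"
        records.append((chrom, pos, ref, alt, depth, zyg, archived_id))
    df = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    return df.sort_values(["CHROM", "POS"], ignore_index=True)


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return seq


def _iupac_regex(pattern: str) -> re.Pattern[str]:
    # N in the subject sequence never matches: an ambiguous base cannot
    # confirm a recognition site.
    body = "".join(f"[{IUPAC[code]}]" for code in pattern.upper())
    return re.compile(f"(?=({body}))")


def find_recognition_sites(seq: str, pattern: RecognitionPattern) -> list[int]:
    """1-based start positions of pattern matches on either strand.

    Matches of the IUPAC pattern and of its reverse complement are both
    reported as forward-strand start positions (overlaps included); for a
    palindromic pattern the two coincide.
    """
    seq = _check_sequence(seq)
    positions: set[int] = set()
    for probe in {pattern.iupac.upper(), pattern.reverse_complement()}:
        regex = _iupac_regex(probe)
        positions.update(m.start() + 1 for m in regex.finditer(seq))
    return sorted(positions)


def rflp_site_gain(wt_seq: str, mut_seq: str,
                   pattern: RecognitionPattern) -> str:
    """Classify a point mutation's effect on recognition-site count.

    Returns ``"gain"`` if the mutant sequence has strictly more sites than
    wild type, ``"loss"`` if fewer, ``"none"`` otherwise.  A gain or loss
    makes the allele genotypable by restriction digest (RFLP).
    """
    if len(wt_seq) != len(mut_seq):
        raise ValueError("sequences must have equal length")
    n_diff = sum(a != b for a, b in zip(wt_seq.upper(), mut_seq.upper()))
    if n_diff > 1:
        raise ValueError("sequences differ at more than one position")
    n_wt = len(find_recognition_sites(wt_seq, pattern))
    n_mut = len(find_recognition_sites(mut_seq, pattern))
    if n_mut > n_wt:
        return "gain"
    if n_mut < n_wt:
        return "loss"
    return "none"
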