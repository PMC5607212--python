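"""Homozygosity mapping: locate shared B6-homozygous intervals.

A recessive lesion induced on the B6 background must lie in a region where
every affected animal is homozygous for B6-derived sequence.  The mapper
finds, per chromosome, every maximal run of informative markers at which all
affected individuals are called B6B6 (missing calls are treated as
compatible), bounded by the nearest marker at which at least one affected
animal is heterozygous or FVB-homozygous.  Interval size is measured
flank-to-flank in Mbp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from enumap.genome import Marker

logger = logging.getLogger(__name__)

Flank = tuple[str | None, int]  # (marker/site id or None at a chromosome end, pos)


@dataclass
class CandidateInterval:
    """A candidate region bounded by non-B6B6 flanking sites."""

    chrom: str
    left_flank: Flank
    right_flank: Flank
    core_markers: list[str] = field(default_factory=list)
    open_left: bool = False
    open_right: bool = False

    def __post_init__(self) -> None:
        if self.left_flank[1] >= self.right_flank[1]:
            raise ValueError("left flank must lie left of right flank")

    @property
    def left_pos(self) -> int:
        return self.left_flank[1]

    @property
    def right_pos(self) -> int:
        return self.right_flank[1]

    @property
    def size_mbp(self) -> float:
        return round((self.right_pos - self.left_pos) / 1e6, 2)

    @property
    def open_ended(self) -> bool:
        return self.open_left or self.open_right

    def contains(self, chrom: str, pos: int) -> bool:
        """Strictly-inside test: the flanking sites themselves are excluded."""
        return chrom == self.chrom and self.left_pos < pos < self.right_pos


def interval_size_mbp(interval: CandidateInterval) -> float:
    """Flank-to-flank span in Mbp, rounded to two decimals."""
    return interval.size_mbp


def select_informative_markers(panel: list[Marker], f1_calls: pd.DataFrame
                               ) -> list[Marker]:
    """Keep markers able to report parental-strain ancestry.

    A marker is informative when it is autosomal, its B6 and FVB alleles
    differ, and the F1 founder is heterozygous at it (confirming both strain
    alleles are present and distinguishable in this cross).  Markers with no
    F1 call are dropped with a warning.  Output is in (chrom, pos) order.
    """
    f1_genotypes = dict(zip(f1_calls["marker_id"], f1_calls["genotype"]))
    kept = []
    for marker in panel:
        if not marker.autosomal or marker.allele_b6 == marker.allele_fvb:
            continue
        call = f1_genotypes.get(marker.id)
        if call is None:
            logger.warning("marker %s: no F1 call, excluded", marker.id)
            continue
        if call == "HET":
            kept.append(marker)
    return sorted(kept, key=lambda m: (m.chrom, m.pos))


def _pivot_calls(calls: pd.DataFrame) -> pd.DataFrame:
    return calls.pivot_table(index="marker_id", columns="individual_id",
                             values="genotype", aggfunc="first")


def shared_homozygosity_intervals(calls_affected: pd.DataFrame,
                                  markers: list[Marker],
                                  chrom_lengths: dict[str, int] | None = None
                                  ) -> list[CandidateInterval]:
    """Maximal runs of markers B6-homozygous in every affected individual.

    MISSING calls are compatible with homozygosity (a no-call cannot break a
    true interval) but never define a flank.  Runs touching a chromosome end
    are reported with the chromosome terminus (or the terminal marker when
    chromosome lengths are unknown) as an open flank.
    """
    if calls_affected.empty:
        raise ValueError("no affected individuals supplied")
    genotypes = _pivot_calls(calls_affected)
    by_chrom: dict[str, list[Marker]] = {}
    for marker in sorted(markers, key=lambda m: (m.chrom, m.pos)):
        by_chrom.setdefault(marker.chrom, []).append(marker)

    intervals: list[CandidateInterval] = []
    for chrom, chrom_markers in by_chrom.items():
        compatible = []
        for marker in chrom_markers:
            if marker.id not in genotypes.index:
                compatible.append(True)  # ungenotyped: non-informative
                continue
            calls = genotypes.loc[marker.id].dropna()
            compatible.append(bool(calls.isin(["B6B6", "MISSING"]).all()))
        n = len(chrom_markers)
        i = 0
        while i < n:
            if not compatible[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and compatible[j + 1]:
                j += 1
            core = [m.id for m in chrom_markers[i:j + 1]]
            if i > 0:
                left: Flank = (chrom_markers[i - 1].id, chrom_markers[i - 1].pos)
                open_left = False
            else:
                left = (None, 1)
                open_left = True
            if j < n - 1:
                right: Flank = (chrom_markers[j + 1].id, chrom_markers[j + 1].pos)
                open_right = False
            else:
                end = (chrom_lengths[chrom] if chrom_lengths
                       else chrom_markers[-1].pos + 1)
                right = (None, end)
                open_right = True
            intervals.append(CandidateInterval(chrom, left, right, core,
                                               open_left=open_left,
                                               open_right=open_right))
            i = j + 1
    return intervals


def exclude_by_normals(intervals: list[CandidateInterval],
                       calls_unaffected: pd.DataFrame
                       ) -> list[CandidateInterval]:
    """Drop intervals shared with phenotypically normal animals.

    A normal animal cannot be homozygous for a fully penetrant recessive
    lesion, so an interval at which some normal individual is explicitly
    B6B6 at every core marker cannot contain it.  MISSING calls in a normal
    animal are not evidence of homozygosity and never trigger exclusion.
    """
    if calls_unaffected.empty:
        return list(intervals)
    genotypes = _pivot_calls(calls_unaffected)
    survivors = []
    for interval in intervals:
        core = [m for m in interval.core_markers if m in genotypes.index]
        excluded = False
        if core:
            sub = genotypes.loc[core]
            excluded = bool((sub == "B6B6").all(axis=0).any())
        if not excluded:
            survivors.append(interval)
    return survivors
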