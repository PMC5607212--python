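"""Worked-example fixture: the mouse chromosome 2 mapping of the rahu lesion.

This module encodes, as in-memory tables, the published coordinates of the
screen that identified the Dnmt3c point mutation: the heterozygous SNPs
flanking the shared-homozygosity cluster (gnf02.126.027 at Chr2:127,800,747
and rs3664408 at Chr2:161,380,222, spanning 33.58 Mbp), the seven novel
homozygous exome variants found inside it, and the manual genotyping
observations that winnowed the interval to 17.43 Mbp containing a single
candidate — the A-to-G transition at Chr2:153,727,342.  The variant table
additionally carries synthetic decoy records, each violating exactly one
exome filter criterion, and the genotype tables for animals other than the
published flank-defining calls are synthetic reconstructions consistent
with the published endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from enumap.assays import MARKER_CALL_COLUMNS, VARIANT_COLUMNS
from enumap.genome import Marker

CHROM = "chr2"

LEFT_FLANK = ("gnf02.126.027", 127_800_747)
RIGHT_FLANK = ("rs3664408", 161_380_222)

# the seven un-annotated homozygous variants inside the mapped region
VARIANT_POSITIONS = {
    "F830045P16Rik": 129_515_815,
    "Pced1a": 130_422_084,
    "Atrn": 130_946_117,
    "Slx4ip": 137_046_739,
    "Esf1": 140_158_720,
    "Rrbp1": 143_947_738,
    "Gm14490": 153_727_342,
}
CAUSAL_POSITION = VARIANT_POSITIONS["Gm14490"]
REFINED_LEFT_FLANK = ("Rrbp1", VARIANT_POSITIONS["Rrbp1"])

AFFECTED_IDS = ["b", "c", "d", "e", "f", "g", "h"]
NORMAL_IDS = ["i", "j"]

# 41-bp synthetic genotyping amplicon: the A-to-G transition at its centre
# creates a novel Hpy188I site (TCNGA), mirroring the rahu RFLP assay
RFLP_WT_AMPLICON = "GGTATTGCCATTGGTATTGCTCTAAGCCATTGGTATTGCCA"
RFLP_MUT_AMPLICON = "GGTATTGCCATTGGTATTGCTCTGAGCCATTGGTATTGCCA"


@dataclass
class WorkedExample:
    markers: list[Marker]
    f1_calls: pd.DataFrame
    affected_calls: pd.DataFrame
    variants: pd.DataFrame
    observations: pd.DataFrame


def _panel_markers() -> list[Marker]:
    # flanking heterozygous SNPs plus core panel SNPs inside the cluster
    core_positions = [128_500_000, 133_000_000, 139_000_000,
                      146_000_000, 152_000_000, 158_000_000]
    markers = [
        Marker(LEFT_FLANK[0], CHROM, LEFT_FLANK[1], "A", "G"),
        Marker(RIGHT_FLANK[0], CHROM, RIGHT_FLANK[1], "A", "G"),
    ]
    markers += [Marker(f"core_{i}", CHROM, pos, "A", "G")
                for i, pos in enumerate(core_positions)]
    return sorted(markers, key=lambda m: m.pos)


def _marker_calls(markers: list[Marker]) -> tuple[pd.DataFrame, pd.DataFrame]:
    f1_rows = [("F1", m.id, m.chrom, m.pos, "HET") for m in markers]
    affected_rows = []
    for ind in AFFECTED_IDS:
        for m in markers:
            genotype = ("HET" if m.id in (LEFT_FLANK[0], RIGHT_FLANK[0])
                        else "B6B6")
            affected_rows.append((ind, m.id, m.chrom, m.pos, genotype))
    return (pd.DataFrame(f1_rows, columns=MARKER_CALL_COLUMNS),
            pd.DataFrame(affected_rows, columns=MARKER_CALL_COLUMNS))


def _variant_table() -> pd.DataFrame:
    rows = [(CHROM, pos, "A", "G", 20, "HOM", ".")
            for pos in sorted(VARIANT_POSITIONS.values())]
    # decoys, one per filter criterion
    rows += [
        (CHROM, 135_000_001, "C", "T", 5, "HOM", "."),          # depth < 6
        (CHROM, 136_000_001, "C", "T", 20, "HET", "."),         # not homozygous
        (CHROM, 138_000_001, "C", "T", 20, "HOM", "rs123456"),  # archived SNP
        (CHROM, 120_000_001, "C", "T", 20, "HOM", "."),         # left of interval
        (CHROM, 165_000_001, "C", "T", 20, "HOM", "."),         # right of interval
        (CHROM, LEFT_FLANK[1], "C", "T", 20, "HOM", "."),       # on the flank itself
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _observations() -> pd.DataFrame:
    """Manual genotyping consistent with the published winnowing endpoint.

    Genotypes are coded relative to the B6-linked allele.  Normal animals
    are homozygous at the two leftmost presumptive lesions; an affected
    animal is heterozygous at the four middle ones, the innermost being the
    Rrbp1 change that becomes the refined left flank; every affected animal
    is homozygous at the Gm14490 site.
    """
    rows = []
    hom_in_normal = ["F830045P16Rik", "Pced1a"]
    het_in_mutant = ["Atrn", "Slx4ip", "Esf1", "Rrbp1"]
    for label in hom_in_normal:
        rows.append(("i", CHROM, VARIANT_POSITIONS[label], "HOM",
                     "unaffected", label))
    for label in het_in_mutant:
        rows.append(("c", CHROM, VARIANT_POSITIONS[label], "HET",
                     "affected", label))
    for ind in AFFECTED_IDS:
        rows.append((ind, CHROM, CAUSAL_POSITION, "HOM", "affected",
                     "Gm14490"))
    for ind in NORMAL_IDS:
        rows.append((ind, CHROM, CAUSAL_POSITION, "HET", "unaffected",
                     "Gm14490"))
    return pd.DataFrame(
        rows, columns=["individual_id", "chrom", "pos", "genotype",
                       "phenotype", "site_id"])


def make_worked_example() -> WorkedExample:
    """Assemble the published-coordinate fixture used by the acceptance runs."""
    markers = _panel_markers()
    f1_calls, affected_calls = _marker_calls(markers)
    return WorkedExample(
        markers=markers,
        f1_calls=f1_calls,
        affected_calls=affected_calls,
        variants=_variant_table(),
        observations=_observations(),
    )
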