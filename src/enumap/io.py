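"""Readers and writers for the package's plain-text interchange formats.

Marker calls and genotype observations travel as TSV, exome variants as a
VCF-like TSV (CHROM, POS, REF, ALT, DEPTH, ZYG, ID), candidate intervals as
BED-like TSV or JSON, pedigrees with their lesion truth as JSON, and
sequences as FASTA (via Biopython).  Every writer/reader pair round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from enumap.genome import Lesion
from enumap.mapping import CandidateInterval
from enumap.pedigree import Haplotype, Individual, Pedigree

INTERVAL_COLUMNS = ["chrom", "left_pos", "right_pos", "size_mbp",
                    "left_id", "right_id", "open_ended"]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_marker_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
    return df.astype({"pos": int})


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "CHROM": str})
    df["ID"] = df["ID"].fillna(".")
    return df.astype({"POS": int, "DEPTH": int})


def read_observations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").astype({"pos": int})


def intervals_to_frame(intervals: list[CandidateInterval]) -> pd.DataFrame:
    rows = [(iv.chrom, iv.left_pos, iv.right_pos, iv.size_mbp,
             iv.left_flank[0] or ".", iv.right_flank[0] or ".",
             iv.open_ended) for iv in intervals]
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_intervals(intervals: list[CandidateInterval],
                    path: str | Path) -> None:
    write_table(intervals_to_frame(intervals), path)


def intervals_to_json(intervals: list[CandidateInterval]) -> list[dict]:
    return [
        {
            "chrom": iv.chrom,
            "left_flank": {"id": iv.left_flank[0], "pos": iv.left_pos},
            "right_flank": {"id": iv.right_flank[0], "pos": iv.right_pos},
            "size_mbp": iv.size_mbp,
            "core_markers": list(iv.core_markers),
            "open_left": iv.open_left,
            "open_right": iv.open_right,
        }
        for iv in intervals
    ]


def intervals_from_json(payload: list[dict]) -> list[CandidateInterval]:
    return [
        CandidateInterval(
            chrom=item["chrom"],
            left_flank=(item["left_flank"]["id"], item["left_flank"]["pos"]),
            right_flank=(item["right_flank"]["id"], item["right_flank"]["pos"]),
            core_markers=list(item["core_markers"]),
            open_left=item["open_left"],
            open_right=item["open_right"],
        )
        for item in payload
    ]


def _haplotype_to_json(hap: Haplotype) -> dict:
    return {
        "chrom": hap.chrom,
        "segments": [list(seg) for seg in hap.segments],
        "lesion_alleles": sorted(hap.lesion_alleles),
    }


def pedigree_to_json(pedigree: Pedigree,
                     truth: Lesion | None = None) -> dict:
    individuals = {}
    for ind in pedigree.individuals.values():
        individuals[ind.id] = {
            "sex": ind.sex,
            "generation": ind.generation,
            "phenotype": ind.phenotype,
            "dam_id": ind.dam_id,
            "sire_id": ind.sire_id,
            "haplotypes": {
                chrom: [_haplotype_to_json(h) for h in pair]
                for chrom, pair in ind.haplotypes.items()
            },
        }
    payload: dict = {"rng_seed": pedigree.rng_seed, "individuals": individuals}
    if truth is not None:
        payload["lesion_truth"] = {
            "chrom": truth.chrom, "pos": truth.pos, "ref": truth.ref,
            "alt": truth.alt, "label": truth.label, "causal": truth.causal,
        }
    return payload


def pedigree_from_json(payload: dict) -> Pedigree:
    pedigree = Pedigree(rng_seed=payload.get("rng_seed"))
    for ind_id, data in payload["individuals"].items():
        haplotypes = {
            chrom: tuple(
                Haplotype(h["chrom"],
                          [tuple(seg) for seg in h["segments"]],
                          frozenset(h["lesion_alleles"]))
                for h in pair
            )
            for chrom, pair in data["haplotypes"].items()
        }
        pedigree.individuals[ind_id] = Individual(
            id=ind_id, sex=data["sex"], generation=data["generation"],
            haplotypes=haplotypes, phenotype=data["phenotype"],
            dam_id=data["dam_id"], sire_id=data["sire_id"])
    return pedigree


def write_json(payload, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load FASTA records as {id: sequence}; case is preserved (soft masks)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
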