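"""Exome candidate filtering and genotype-based winnowing (fine mapping).

Pooled exome calls are reduced to presumptive ENU lesions by three criteria
(sequencing depth of at least six reads, a homozygous call, and absence of
an archived reference-SNP identifier) restricted to the mapped interval.
Candidates are then winnowed by genotyping additional animals: a lesion
homozygous in a phenotypically normal animal, or heterozygous/wild-type in
an affected one, cannot be the fully penetrant recessive cause.  The same
observations refine the interval's flanks.

Genotype observations are coded relative to the allele that travels with
the mutagenized (B6) haplotype: HOM means homozygous for the lesion's
alternate allele at a presumptive lesion, and homozygous for the B6 base at
a strain polymorphism.  Under this coding every affected animal is HOM at
the causal site and at tightly linked sites, so a single rule applies to
both site classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from scipy import stats

from enumap.genome import Lesion
from enumap.mapping import CandidateInterval

OBSERVATION_COLUMNS = ["individual_id", "chrom", "pos", "genotype", "phenotype"]

HOM_IN_NORMAL = "hom_in_normal"
HET_IN_MUTANT = "het_in_mutant"
OUTSIDE_INTERVAL = "outside_interval"


@dataclass
class WinnowResult:
    surviving: pd.DataFrame
    excluded: list[tuple[tuple[str, int], str]]  # ((chrom, pos), reason)
    refined_interval: CandidateInterval | None = None

    @property
    def surviving_sites(self) -> list[tuple[str, int]]:
        return list(zip(self.surviving["CHROM"], self.surviving["POS"]))


def filter_exome_variants(records: pd.DataFrame, interval: CandidateInterval,
                          min_depth: int = 6) -> pd.DataFrame:
    """Apply the three exome filters within the mapped interval.

    Retains records with depth >= ``min_depth``, a HOM zygosity call, no
    archived identifier, and a position strictly inside the interval flanks
    (the flanking sites themselves are not candidates).  Each criterion only
    removes records, so the filters commute.
    """
    df = records.sort_values(["CHROM", "POS"], ignore_index=True)
    no_id = df["ID"].isna() | df["ID"].isin([".", ""])
    inside = df.apply(lambda r: interval.contains(r["CHROM"], r["POS"]), axis=1)
    mask = (df["DEPTH"] >= min_depth) & (df["ZYG"] == "HOM") & no_id & inside
    return df[mask].reset_index(drop=True)


def _check_observations(observations: pd.DataFrame) -> None:
    dup = observations[observations["genotype"] != "MISSING"].groupby(
        ["individual_id", "chrom", "pos"])["genotype"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"contradictory duplicate observations at {bad}")


def winnow_candidates(candidates: pd.DataFrame, observations: pd.DataFrame,
                      interval: CandidateInterval | None = None) -> WinnowResult:
    """Exclude candidates incompatible with a recessive fully penetrant cause.

    A candidate is excluded when any unaffected animal is HOM at it, or any
    affected animal is HET or WT at it.  MISSING observations never exclude.
    When an interval is supplied, candidates outside it are excluded first
    and the interval is refined from the observations.
    """
    _check_observations(observations)
    excluded: list[tuple[tuple[str, int], str]] = []
    keep_rows = []
    for _, row in candidates.iterrows():
        site = (row["CHROM"], row["POS"])
        if interval is not None and not interval.contains(*site):
            excluded.append((site, OUTSIDE_INTERVAL))
            continue
        obs = observations[(observations["chrom"] == site[0])
                           & (observations["pos"] == site[1])]
        normal_hom = ((obs["phenotype"] == "unaffected")
                      & (obs["genotype"] == "HOM")).any()
        mutant_het = ((obs["phenotype"] == "affected")
                      & obs["genotype"].isin(["HET", "WT"])).any()
        if normal_hom:
            excluded.append((site, HOM_IN_NORMAL))
        elif mutant_het:
            excluded.append((site, HET_IN_MUTANT))
        else:
            keep_rows.append(row)
    surviving = (pd.DataFrame(keep_rows).reset_index(drop=True)
                 if keep_rows else candidates.iloc[0:0].copy())
    refined = None
    if interval is not None:
        try:
            refined = refine_interval(interval, observations)
        except ValueError:
            # every observed site in this interval is incompatible: with no
            # surviving candidate the interval is simply ruled out; with a
            # survivor the genotypes genuinely contradict the phenotype
            if len(surviving):
                raise
    return WinnowResult(surviving, excluded, refined)


def refine_interval(interval: CandidateInterval,
                    observations: pd.DataFrame) -> CandidateInterval:
    """Narrow an interval using genotypes of affected animals.

    Any site (strain polymorphism or presumptive lesion) at which some
    affected animal is not homozygous for the B6-derived allele is
    incompatible with containing the lesion and can serve as a new flank.
    The refined flanks are the innermost incompatible sites bracketing all
    remaining compatible sites; flanks are exclusive.
    """
    affected = observations[(observations["phenotype"] == "affected")
                            & (observations["chrom"] == interval.chrom)]
    inside = affected[(affected["pos"] > interval.left_pos)
                      & (affected["pos"] < interval.right_pos)]
    if inside.empty:
        return interval

    incompatible, compatible = set(), set()
    for pos, group in inside.groupby("pos"):
        if group["genotype"].isin(["HET", "WT"]).any():
            incompatible.add(int(pos))
        elif (group["genotype"] == "HOM").any():
            compatible.add(int(pos))
    if not compatible and incompatible:
        raise ValueError(
            "no compatible region remains: genotypes contradict the phenotype")
    if not incompatible:
        return interval

    left, right = interval.left_flank, interval.right_flank
    open_left, open_right = interval.open_left, interval.open_right
    # Bracket ALL compatible sites: an incompatible site interleaved between
    # compatible ones (possible via double crossovers) is left inside the
    # interval — conservative, and the causal site is always retained.
    lo, hi = min(compatible), max(compatible)
    inner_left = [p for p in incompatible if p < lo]
    inner_right = [p for p in incompatible if p > hi]
    if inner_left:
        pos = max(inner_left)
        left, open_left = (_site_id(observations, interval.chrom, pos), pos), False
    if inner_right:
        pos = min(inner_right)
        right, open_right = (_site_id(observations, interval.chrom, pos), pos), False
    return replace(interval, left_flank=left, right_flank=right,
                   open_left=open_left, open_right=open_right)


def _site_id(observations: pd.DataFrame, chrom: str, pos: int) -> str | None:
    if "site_id" not in observations.columns:
        return None
    ids = observations.loc[(observations["chrom"] == chrom)
                           & (observations["pos"] == pos), "site_id"].dropna()
    return str(ids.iloc[0]) if len(ids) else None


def segregation_test(counts: tuple[int, int, int],
                     expected_ratio: tuple[float, float, float]
                     ) -> tuple[float, int, float]:
    """Chi-square goodness of fit of genotype counts to a Mendelian ratio.

    ``counts`` are (wild type, heterozygote, homozygote).  Classes with zero
    expectation are checked to be empty and dropped from the statistic.
    Returns (chi_square, dof, p); the raw p-value is reported without
    multiple-testing correction, as this is a single planned test.
    """
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    total = sum(counts)
    if total == 0:
        raise ValueError("zero total count")
    if abs(sum(expected_ratio) - 1.0) > 1e-9:
        raise ValueError("expected ratio must sum to 1")
    observed, expected = [], []
    for count, frac in zip(counts, expected_ratio):
        if frac == 0:
            if count:
                raise ValueError("observed count in a zero-expectation class")
            continue
        observed.append(count)
        expected.append(total * frac)
    chi2, p = stats.chisquare(observed, expected)
    dof = len(observed) - 1
    return float(chi2), dof, float(p)


def recovery_report(truth: Lesion, result: WinnowResult) -> dict:
    """Compare a winnow outcome against the planted causal lesion."""
    site = (truth.chrom, truth.pos)
    survived = site in result.surviving_sites
    report = {
        "causal_site": {"chrom": truth.chrom, "pos": truth.pos},
        "causal_recovered": bool(survived),
        "n_surviving": int(len(result.surviving)),
        "n_excluded": len(result.excluded),
    }
    if result.refined_interval is not None:
        report["refined_interval_mbp"] = result.refined_interval.size_mbp
    if not survived:
        reasons = [r for s, r in result.excluded if s == site]
        report["failure_reason"] = reasons[0] if reasons else "not_in_candidates"
    return report
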