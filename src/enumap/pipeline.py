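"""End-to-end screen pipeline: simulate, genotype, map, filter, winnow.

One call reproduces the whole positional-cloning workflow on synthetic
data: breed a three-generation pedigree carrying a planted causal lesion,
genotype affected and normal G3 males on the linkage panel, map shared-B6
homozygosity intervals, call pooled exome variants, filter them to
presumptive ENU lesions, winnow with genotypes of additional animals, and
report whether the planted lesion was recovered.  Deterministic given the
config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from enumap import io as eio
from enumap.assays import genotype_panel, simulate_exome
from enumap.config import RunConfig, default_genome_spec
from enumap.genome import B6, GenomeSpec
from enumap.mapping import (CandidateInterval, exclude_by_normals,
                            select_informative_markers,
                            shared_homozygosity_intervals)
from enumap.pedigree import Individual, Pedigree, run_breeding_scheme
from enumap.winnow import (WinnowResult, filter_exome_variants,
                           recovery_report, winnow_candidates)

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    config: RunConfig
    spec: GenomeSpec
    pedigree: Pedigree
    intervals: list[CandidateInterval]
    candidates: pd.DataFrame
    winnow: WinnowResult
    report: dict
    summary: dict = field(default_factory=dict)


class ConfigError(ValueError):
    """Raised before any computation when a config is inconsistent."""


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _collect_cohort(spec: GenomeSpec, config: RunConfig,
                    rng: np.random.Generator
                    ) -> tuple[Pedigree, list[Individual], list[Individual],
                               list[Individual]]:
    """Breed until the screen has enough affected, normal and extra males."""
    needed = config.n_affected
    for factor in (16, 32, 64, 128):
        n_g2 = factor * needed + config.n_normals + config.n_extra_genotyped
        pedigree = run_breeding_scheme(spec, n_g2, 1, rng)
        g3 = pedigree.by_generation("G3")
        affected = [m for m in g3 if m.phenotype == "affected"]
        if len(affected) >= needed:
            break
    else:
        raise RuntimeError("could not breed enough affected G3 males")
    normals = [m for m in g3 if m.phenotype == "unaffected"]
    used = {m.id for m in affected[:needed]} | {m.id
                                               for m in normals[:config.n_normals]}
    extras = [m for m in g3 if m.id not in used][:config.n_extra_genotyped]
    return pedigree, affected[:needed], normals[:config.n_normals], extras


def _b6_linked_genotype(individual: Individual, spec: GenomeSpec,
                        chrom: str, pos: int, is_lesion: bool) -> str:
    if is_lesion:
        dose = individual.lesion_dose(chrom, pos)
    else:
        dose = sum(a == B6 for a in individual.genotype_at(chrom, pos))
    return {2: "HOM", 1: "HET", 0: "WT"}[dose]


def _genotype_observations(animals: list[Individual], spec: GenomeSpec,
                           intervals: list[CandidateInterval]) -> pd.DataFrame:
    """Manually genotype animals at lesion and polymorphism sites in intervals."""
    sites = []
    for lesion in spec.lesions:
        if any(iv.contains(lesion.chrom, lesion.pos) for iv in intervals):
            sites.append((lesion.chrom, lesion.pos, True, lesion.label))
    for snp in spec.polymorphisms:
        if any(iv.contains(snp.chrom, snp.pos) for iv in intervals):
            sites.append((snp.chrom, snp.pos, False, snp.archived_id))
    rows = []
    for animal in animals:
        for chrom, pos, is_lesion, site_id in sites:
            rows.append((animal.id, chrom, pos,
                         _b6_linked_genotype(animal, spec, chrom, pos,
                                             is_lesion),
                         animal.phenotype, site_id))
    return pd.DataFrame(rows, columns=["individual_id", "chrom", "pos",
                                       "genotype", "phenotype", "site_id"])


def run_screen_pipeline(config: RunConfig,
                        out_dir: str | Path | None = None) -> ScreenResult:
    """Run the complete simulate-map-filter-winnow-report workflow."""
    try:
        config.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    rng = np.random.default_rng(config.seed)
    spec = default_genome_spec(config, rng)
    truth = spec.causal_lesion

    pedigree, affected, normals, extras = _collect_cohort(spec, config, rng)
    logger.info("cohort: %d affected, %d normal, %d extra G3 males",
                len(affected), len(normals), len(extras))

    f1 = pedigree.individuals["F1"]
    f1_calls = genotype_panel([f1], spec.markers)
    informative = select_informative_markers(spec.markers, f1_calls)

    calls_affected = genotype_panel(affected, informative,
                                    config.missing_rate, rng)
    calls_normals = genotype_panel(normals, informative,
                                   config.missing_rate, rng)
    chrom_lengths = dict(spec.chromosomes)
    intervals = shared_homozygosity_intervals(calls_affected, informative,
                                              chrom_lengths)
    if config.exclude_normals_at_coarse:
        intervals = exclude_by_normals(intervals, calls_normals)
    if not intervals:
        # the shared homozygous region can fall entirely between panel
        # markers; fine mapping then proceeds without a positional
        # restriction and the flanks come from the genotyped sites
        logger.warning("no shared cluster at panel resolution; "
                       "fine-mapping genome-wide")
        intervals = [
            CandidateInterval(chrom, (None, 1), (None, length), [],
                              open_left=True, open_right=True)
            for chrom, length in spec.chromosomes
        ]

    pool = affected[:config.n_exome_pool]
    exome = simulate_exome(pool, spec, config.mean_depth, rng)

    observations = _genotype_observations(affected + normals + extras, spec,
                                          intervals)

    all_surviving, all_excluded = [], []
    refined = None
    for interval in intervals:
        candidates = filter_exome_variants(exome, interval, config.min_depth)
        if candidates.empty:
            continue
        result = winnow_candidates(candidates, observations, interval)
        all_surviving.append(result.surviving)
        all_excluded.extend(result.excluded)
        if len(result.surviving):
            refined = result.refined_interval
    surviving = (pd.concat(all_surviving, ignore_index=True)
                 if all_surviving else exome.iloc[0:0].copy())
    candidates_all = pd.concat(
        [filter_exome_variants(exome, iv, config.min_depth)
         for iv in intervals], ignore_index=True)
    winnow_result = WinnowResult(surviving, all_excluded, refined)

    report = recovery_report(truth, winnow_result)
    summary = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_intervals": len(intervals),
        "intervals": eio.intervals_to_json(intervals),
        "n_candidates": int(len(candidates_all)),
        "n_surviving": int(len(surviving)),
        "surviving_sites": [[c, int(p)] for c, p
                            in zip(surviving["CHROM"], surviving["POS"])],
        "recovery": report,
    }

    result = ScreenResult(config, spec, pedigree, intervals, candidates_all,
                          winnow_result, report, summary)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), calls_affected, calls_normals,
                      exome, observations)
    return result


def _write_bundle(result: ScreenResult, out_dir: Path,
                  calls_affected: pd.DataFrame, calls_normals: pd.DataFrame,
                  exome: pd.DataFrame, observations: pd.DataFrame) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out_dir / "config.yaml")
    eio.write_table(calls_affected, out_dir / "calls_affected.tsv")
    eio.write_table(calls_normals, out_dir / "calls_normals.tsv")
    eio.write_table(exome, out_dir / "exome_variants.tsv")
    eio.write_table(result.candidates, out_dir / "candidates.tsv")
    eio.write_table(observations, out_dir / "observations.tsv")
    eio.write_intervals(result.intervals, out_dir / "intervals.tsv")
    eio.write_json(eio.pedigree_to_json(result.pedigree,
                                        result.spec.causal_lesion),
                   out_dir / "pedigree.json")
    eio.write_json(result.summary, out_dir / "summary.json")
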