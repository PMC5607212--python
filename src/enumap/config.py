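"""Run configuration and the default simulated genome.

The default genome is a single 160-Mbp autosome standing in for mouse
chromosome 2, with the causal lesion planted at the coordinate of the rahu
A-to-G transition (Chr2:153,727,342), a linkage panel of informative SNPs,
a database of archived strain polymorphisms, and a handful of passenger ENU
lesions segregating alongside the causal one.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from enumap.genome import GenomeSpec, Lesion, Marker, Polymorphism


@dataclass
class RunConfig:
    """Parameters of one simulated screen-and-map run."""

    # genome
    chrom_name: str = "chr2"
    chrom_length: int = 160_000_000
    recombination_rate: float = 0.5  # cM per Mbp
    n_markers: int = 120
    n_polymorphisms: int = 300
    causal_pos: int = 153_727_342
    n_passenger_lesions: int = 7
    # cohort
    n_affected: int = 7
    n_normals: int = 20
    n_extra_genotyped: int = 100
    n_exome_pool: int = 3
    penetrance: float = 1.0
    # assays
    missing_rate: float = 0.0
    mean_depth: float = 30.0
    min_depth: int = 6
    # Apply normal-mouse exclusion already at the coarse array stage?  Off by
    # default: with a sparse panel a normal can be B6-homozygous at every
    # core marker of a narrow interval yet heterozygous at the lesion between
    # them, so coarse exclusion can discard the true interval.  Normals
    # always contribute at the fine-mapping (winnow) stage, where genotypes
    # are read at the candidate sites themselves and exclusion is sound.
    exclude_normals_at_coarse: bool = False
    # dotplot defaults
    dotplot_window: int = 20
    dotplot_min_windows: int = 3
    dotplot_max_gap: int = 0
    # reproducibility
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "chrom_length": self.chrom_length,
            "n_markers": self.n_markers,
            "n_polymorphisms": self.n_polymorphisms,
            "n_affected": self.n_affected,
            "n_exome_pool": self.n_exome_pool,
            "dotplot_window": self.dotplot_window,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_normals", "n_extra_genotyped", "min_depth",
                     "dotplot_min_windows", "dotplot_max_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("recombination_rate", "mean_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missing_rate", "penetrance"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 1 <= self.causal_pos <= self.chrom_length:
            raise ValueError("causal_pos outside the chromosome")
        if self.n_exome_pool > self.n_affected:
            raise ValueError("n_exome_pool cannot exceed n_affected")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _spread(n: int, length: int, phase: int) -> list[int]:
    # deterministic evenly spaced positions with a small phase offset so the
    # marker, polymorphism and lesion grids never collide
    step = length // (n + 1)
    return [i * step + phase for i in range(1, n + 1)]


def default_genome_spec(config: RunConfig | None = None,
                        rng: np.random.Generator | None = None) -> GenomeSpec:
    """Build the study genome described by a :class:`RunConfig`.

    Markers and archived polymorphisms sit on deterministic evenly spaced
    grids.  Passenger-lesion positions are drawn uniformly when an ``rng``
    is supplied (so each simulated line carries its own mutation load) and
    fall on a fixed grid otherwise.
    """
    config = config or RunConfig()
    chrom, length = config.chrom_name, config.chrom_length

    markers = [
        Marker(id=f"m{idx:04d}", chrom=chrom, pos=pos,
               allele_b6="A", allele_fvb="G")
        for idx, pos in enumerate(_spread(config.n_markers, length, phase=0))
    ]
    polymorphisms = [
        Polymorphism(chrom=chrom, pos=pos, ref="C", alt="T",
                     archived_id=f"rs{900000 + idx}")
        for idx, pos in enumerate(
            _spread(config.n_polymorphisms, length, phase=7))
    ]
    taken = ({m.pos for m in markers} | {p.pos for p in polymorphisms}
             | {config.causal_pos})
    n_pass = config.n_passenger_lesions
    if rng is not None:
        passenger_pos: list[int] = []
        while len(passenger_pos) < n_pass:
            pos = int(rng.integers(1, length + 1))
            if pos not in taken:
                passenger_pos.append(pos)
                taken.add(pos)
    else:
        passenger_pos = [p for p in _spread(n_pass, length, phase=13)
                         if p not in taken][:n_pass]
    lesions = [Lesion(chrom=chrom, pos=config.causal_pos, ref="A", alt="G",
                      label="causal", causal=True)]
    lesions += [
        Lesion(chrom=chrom, pos=pos, ref="G", alt="A",
               label=f"passenger_{idx}")
        for idx, pos in enumerate(sorted(passenger_pos))
    ]
    return GenomeSpec(
        chromosomes=[(chrom, length)],
        recombination_rate=config.recombination_rate,
        markers=markers,
        polymorphisms=polymorphisms,
        lesions=lesions,
    )
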