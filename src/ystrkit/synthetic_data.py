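"""Synthetic Y-STR datasets with known structure.

Two kinds of generator:

* :func:`simulate_dataset` — forward Wright–Fisher simulation of haploid
  (Y-chromosomal) lineages under the single-step stepwise mutation model
  (SMM): populations split from a common ancestor, each generation every
  lineage copies a uniformly chosen parent, and each locus copy mutates
  with a per-generation rate, stepping +-1 repeat with equal probability
  (floored at 1 repeat). Divergence time, effective male population size
  and mutation rate are the dials; expected squared allele-size difference
  between populations grows with divergence, which is what Rst measures.

* :func:`make_counts_dataset` — deterministic construction of a dataset
  whose haplotype-count multiset exactly matches a requested profile
  (e.g. 238 singletons plus 4 doubletons), for analytic checks of
  haplotype-level statistics.

* :func:`two_population_fixture` — two monomorphic populations offset by a
  fixed repeat count, giving closed-form Rst (0 if the offset is 0, else 1).

Everything is reproducible byte-identically from an integer seed (PCG64).
The default mutation rate is 2e-3 per locus per generation, a typical
Y-STR order of magnitude; the default ancestral allele is 12 repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .haplotype_io import (
    AlleleValue,
    Haplotype,
    LocusGenotype,
    LocusPanel,
    PopulationDataset,
    builtin_panel,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "make_counts_dataset",
    "two_population_fixture",
]

DEFAULT_MUTATION_RATE = 2e-3
DEFAULT_ANCESTRAL_REPEATS = 12


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the Wright–Fisher / SMM forward simulation."""

    panel: LocusPanel
    n_populations: int = 2
    samples_per_population: tuple[int, ...] = (100, 100)
    divergence_generations: int = 200
    effective_males_per_population: int = 500
    mutation_rate_per_locus: float = DEFAULT_MUTATION_RATE
    ancestral_alleles: Mapping[str, Sequence[int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate_per_locus <= 0.05:
            raise ValueError("mutation rate must be in [0, 0.05]")
        if self.n_populations < 1 or self.effective_males_per_population < 1:
            raise ValueError("population counts must be >= 1")
        if len(self.samples_per_population) != self.n_populations:
            raise ValueError(
                "samples_per_population length must equal n_populations"
            )
        for s in self.samples_per_population:
            if s < 1:
                raise ValueError("sample sizes must be >= 1")
            if s > self.effective_males_per_population:
                raise ValueError(
                    f"cannot sample {s} from effective size "
                    f"{self.effective_males_per_population} without replacement"
                )
        if self.divergence_generations < 0:
            raise ValueError("divergence_generations must be >= 0")


@dataclass
class SimulatedDataset:
    datasets: list[PopulationDataset]
    config: SimulationConfig
    mutation_counts: list[int]  # realized mutations per population


def _ancestral_vector(cfg: SimulationConfig) -> np.ndarray:
    slots: list[int] = []
    for marker, copies in cfg.panel.markers:
        if cfg.ancestral_alleles and marker in cfg.ancestral_alleles:
            vals = list(cfg.ancestral_alleles[marker])
            if len(vals) != copies:
                raise ValueError(
                    f"{marker}: {len(vals)} ancestral alleles for {copies} copies"
                )
        else:
            # distinct defaults per copy so multi-copy sorting stays stable
            vals = [DEFAULT_ANCESTRAL_REPEATS + 2 * c for c in range(copies)]
        slots.extend(int(v) for v in vals)
    return np.array(slots, dtype=np.int64)


def _evolve(
    pool: np.ndarray, generations: int, mu: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Wright–Fisher resampling + SMM mutation for one population."""
    ne, n_loci = pool.shape
    mutations = 0
    for _ in range(generations):
        parents = rng.integers(0, ne, size=ne)
        pool = pool[parents]
        hits = rng.random((ne, n_loci)) < mu
        n_hits = int(hits.sum())
        if n_hits:
            steps = rng.choice((-1, 1), size=n_hits)
            pool = pool.copy()
            pool[hits] += steps
            np.maximum(pool, 1, out=pool)  # repeat counts floored at 1
            mutations += n_hits
    return pool, mutations


def _matrix_to_dataset(
    X: np.ndarray, panel: LocusPanel, population: str, prefix: str
) -> PopulationDataset:
    haplotypes = []
    for i, row in enumerate(X):
        genotypes = []
        pos = 0
        for marker, copies in panel.markers:
            alleles = tuple(
                AlleleValue(int(row[pos + c]) * 10) for c in range(copies)
            )
            genotypes.append(LocusGenotype(marker=marker, alleles=alleles))
            pos += copies
        haplotypes.append(
            Haplotype(sample_id=f"{prefix}{i + 1:04d}", genotypes=tuple(genotypes))
        )
    return PopulationDataset(population=population, haplotypes=haplotypes, panel=panel)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate diverging populations and sample haplotype datasets.

    All populations start as copies of one ancestral pool, evolve
    independently for ``divergence_generations``, then the requested number
    of males is sampled from each without replacement.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestral = _ancestral_vector(cfg)
    ne = cfg.effective_males_per_population
    base_pool = np.tile(ancestral, (ne, 1))
    datasets, mut_counts = [], []
    for p in range(cfg.n_populations):
        pool, n_mut = _evolve(
            base_pool.copy(), cfg.divergence_generations,
            cfg.mutation_rate_per_locus, rng,
        )
        take = rng.choice(ne, size=cfg.samples_per_population[p], replace=False)
        name = f"pop{p + 1}"
        datasets.append(
            _matrix_to_dataset(pool[take], cfg.panel, name, prefix=f"P{p + 1}_")
        )
        mut_counts.append(n_mut)
    return SimulatedDataset(datasets=datasets, config=cfg, mutation_counts=mut_counts)


def make_counts_dataset(
    panel: LocusPanel,
    count_profile: Sequence[tuple[int, int]],
    population: str = "synthetic",
    seed: int = 0,
) -> PopulationDataset:
    """Dataset whose haplotype-count multiset matches ``count_profile`` exactly.

    ``count_profile`` is a list of (multiplicity, number of haplotypes):
    ``[(1, 238), (2, 4)]`` gives 238 singletons plus 4 doubletons (n = 246,
    242 distinct). Distinctness is forced by systematically varying the
    first marker's allele (and a second marker as an overflow counter), so
    the construction is deterministic; ``seed`` is accepted for interface
    symmetry but unused.
    """
    for mult, k in count_profile:
        if mult < 1 or k < 0:
            raise ValueError("multiplicities must be >= 1 and counts >= 0")
    n_distinct = sum(k for _, k in count_profile)
    if n_distinct < 1:
        raise ValueError("profile describes an empty dataset")
    if len(panel.markers) < 2 and n_distinct > 90:
        raise ValueError("panel too small to encode this many distinct haplotypes")

    base = _ancestral_vector(
        SimulationConfig(panel=panel, n_populations=1, samples_per_population=(1,))
    )
    haplotypes: list[Haplotype] = []
    sample = 0
    for serial in range(n_distinct):
        # encode the serial number into the first two single-copy slots,
        # keeping alleles in a realistic 10..99 range
        row = base.copy()
        row[0] = 10 + serial % 90
        row[1] = 10 + serial // 90
        if row[1] >= 100:
            raise ValueError("profile too large to encode distinctly")
        hap_row = row
        mult = _multiplicity_for_serial(count_profile, serial)
        for _ in range(mult):
            sample += 1
            haplotypes.append(
                _row_to_haplotype(hap_row, panel, f"S{sample:05d}")
            )
    return PopulationDataset(
        population=population, haplotypes=haplotypes, panel=panel
    )


def _multiplicity_for_serial(
    profile: Sequence[tuple[int, int]], serial: int
) -> int:
    offset = 0
    for mult, k in profile:
        if serial < offset + k:
            return mult
        offset += k
    raise IndexError(serial)


def _row_to_haplotype(row: np.ndarray, panel: LocusPanel, sample_id: str) -> Haplotype:
    genotypes = []
    pos = 0
    for marker, copies in panel.markers:
        alleles = tuple(AlleleValue(int(row[pos + c]) * 10) for c in range(copies))
        genotypes.append(LocusGenotype(marker=marker, alleles=alleles))
        pos += copies
    return Haplotype(sample_id=sample_id, genotypes=tuple(genotypes))


def two_population_fixture(
    delta_repeats: int,
    n_per_pop: int = 10,
    panel: LocusPanel | None = None,
) -> list[PopulationDataset]:
    """Two monomorphic populations offset by ``delta_repeats`` at every
    single-copy marker: Rst is exactly 0 (delta 0) or 1 (delta > 0)."""
    if delta_repeats < 0:
        raise ValueError("delta_repeats must be >= 0")
    panel = panel or builtin_panel("AGCU37")
    cfg = SimulationConfig(panel=panel, n_populations=1, samples_per_population=(1,))
    base = _ancestral_vector(cfg)
    shifted = base.copy()
    pos = 0
    for marker, copies in panel.markers:
        if copies == 1:
            shifted[pos] += delta_repeats
        pos += copies
    out = []
    for name, row, prefix in (("popA", base, "A"), ("popB", shifted, "B")):
        haps = [
            _row_to_haplotype(row, panel, f"{prefix}{i + 1:04d}")
            for i in range(n_per_pop)
        ]
        out.append(PopulationDataset(population=name, haplotypes=haps, panel=panel))
    return out
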