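"""Forensic summary statistics for Y-STR haplotype datasets.

Haplotype and allele frequencies are obtained by direct counting. Diversity
uses Nei's unbiased estimator

    GD = n (1 - sum p_i^2) / (n - 1)

over a locus's allele frequencies (gene diversity, GD) or over whole-
haplotype frequencies (haplotype diversity, HD). Match probability (MP) is
the probability that two randomly drawn samples share a haplotype,
sum p_i^2 over haplotype frequencies; discrimination capacity (DC) is the
number of distinct haplotypes divided by the sample size.

Multi-copy markers (DYS385a/b etc.) enter both allele-frequency tables and
haplotype identity as canonical sorted allele combinations — one observation
per sample — never as split pseudo-loci. Samples with any missing panel
marker are excluded from that panel's statistics (direct counting requires
complete profiles); exclusions are counted in the summary.

MP at the haplotype level: a per-locus analogue (sum of squared allele
frequencies at one marker) is exposed as :func:`locus_match_probability`.
All internal values are exact; rounding happens only in reporting helpers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .haplotype_io import Haplotype, LocusPanel, PopulationDataset, subset_to_panel

__all__ = [
    "AlleleFrequencyTable",
    "LocusDiversity",
    "ForensicSummary",
    "count_allele_frequencies",
    "gene_diversity",
    "locus_match_probability",
    "haplotype_counts",
    "match_probability",
    "haplotype_diversity",
    "discrimination_capacity",
    "summarize_population",
    "summarize_across_panels",
]

HaplotypeCounts = Mapping[tuple, int]


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Direct allele counts and relative frequencies at one marker.

    For multi-copy markers the key is the canonical sorted combination
    (e.g. ``"13,17"``); each sample contributes exactly one observation.
    """

    marker: str
    counts: dict[str, int]
    n_observations: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {k: c / self.n_observations for k, c in self.counts.items()}

    @property
    def allele_count(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class LocusDiversity:
    marker: str
    gd: float
    n: int
    allele_count: int


@dataclass(frozen=True)
class ForensicSummary:
    """Per-population, per-panel forensic parameters (Table-1 shape)."""

    population: str
    panel_name: str
    n: int
    n_excluded: int  # incomplete profiles dropped for this panel
    distinct_haplotypes: int
    singleton_haplotypes: int
    hd: float
    mp: float
    dc: float
    locus_diversities: tuple[LocusDiversity, ...]

    def rounded(self, mp_digits: int = 4) -> dict:
        """Reporting view: HD/MP/DC to 4 d.p. (MP optionally 5), DC% to 2 d.p."""
        return {
            "population": self.population,
            "panel": self.panel_name,
            "n": self.n,
            "distinct_haplotypes": self.distinct_haplotypes,
            "HD": round(self.hd, 4),
            "MP": round(self.mp, mp_digits),
            "DC": round(self.dc, 4),
            "DC_percent": round(100 * self.dc, 2),
        }


def count_allele_frequencies(ds: PopulationDataset, marker: str) -> AlleleFrequencyTable:
    """Direct counting of alleles (or allelic combinations) at one marker."""
    if marker not in ds.panel:
        raise KeyError(f"marker {marker!r} not in panel {ds.panel.name}")
    pos = ds.panel.marker_names.index(marker)
    counts: Counter[str] = Counter()
    for h in ds.haplotypes:
        g = h.genotypes[pos]
        if g is None:
            continue
        counts[str(g)] += 1
    n = sum(counts.values())
    if n < 1:
        raise ValueError(f"marker {marker}: no observations")
    return AlleleFrequencyTable(marker=marker, counts=dict(counts), n_observations=n)


def _nei_diversity(counts: Sequence[int]) -> float:
    n = sum(counts)
    if n < 2:
        raise ValueError(f"Nei's estimator needs n >= 2, got n={n}")
    # summing in sorted order makes the result independent of count order
    sum_p2 = sum((c / n) ** 2 for c in sorted(counts))
    return n * (1.0 - sum_p2) / (n - 1)


def gene_diversity(freqs: AlleleFrequencyTable) -> LocusDiversity:
    """Nei's GD = n(1 - sum p_i^2)/(n - 1) over one marker's frequencies."""
    gd = _nei_diversity(list(freqs.counts.values()))
    return LocusDiversity(
        marker=freqs.marker,
        gd=gd,
        n=freqs.n_observations,
        allele_count=freqs.allele_count,
    )


def locus_match_probability(freqs: AlleleFrequencyTable) -> float:
    """Sum of squared allele frequencies at one marker (per-locus MP)."""
    n = freqs.n_observations
    return sum((c / n) ** 2 for c in freqs.counts.values())


def haplotype_counts(ds: PopulationDataset) -> tuple[dict[tuple, int], int, int]:
    """Count complete haplotypes; returns (counts, distinct, singletons)."""
    counter: Counter[tuple] = Counter(h.key() for h in ds.complete_haplotypes())
    distinct = len(counter)
    singletons = sum(1 for c in counter.values() if c == 1)
    return dict(counter), distinct, singletons


def match_probability(counts: HaplotypeCounts) -> float:
    """MP = sum over haplotypes of (count/n)^2."""
    n = sum(counts.values())
    if n < 1:
        raise ValueError("empty haplotype counts")
    return sum((c / n) ** 2 for c in sorted(counts.values()))


def haplotype_diversity(counts: HaplotypeCounts) -> float:
    """HD = n(1 - sum p_i^2)/(n - 1) over haplotype frequencies."""
    return _nei_diversity(list(counts.values()))


def discrimination_capacity(counts: HaplotypeCounts) -> float:
    """DC = distinct haplotypes / sample size."""
    n = sum(counts.values())
    if n < 1:
        raise ValueError("empty haplotype counts")
    return len(counts) / n


def summarize_population(ds: PopulationDataset) -> ForensicSummary:
    """All forensic parameters for one dataset on its own panel."""
    complete = ds.complete_haplotypes()
    n = len(complete)
    if n < 2:
        raise ValueError(
            f"population {ds.population}: {n} complete profile(s); need >= 2"
        )
    counts, distinct, singletons = haplotype_counts(ds)
    mp = match_probability(counts)
    hd = haplotype_diversity(counts)
    dc = discrimination_capacity(counts)
    locus_divs = []
    for marker, _ in ds.panel.markers:
        freqs = count_allele_frequencies(ds, marker)
        locus_divs.append(gene_diversity(freqs))
    return ForensicSummary(
        population=ds.population,
        panel_name=ds.panel.name,
        n=n,
        n_excluded=ds.n - n,
        distinct_haplotypes=distinct,
        singleton_haplotypes=singletons,
        hd=hd,
        mp=mp,
        dc=dc,
        locus_diversities=tuple(locus_divs),
    )


def summarize_across_panels(
    ds: PopulationDataset, panels: Sequence[LocusPanel]
) -> list[ForensicSummary]:
    """One summary per panel, via subsetting; shrinking a panel can only
    merge haplotype classes, so the distinct count is non-increasing."""
    return [summarize_population(subset_to_panel(ds, panel)) for panel in panels]
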