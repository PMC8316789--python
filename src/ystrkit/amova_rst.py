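"""Pairwise Rst genetic distances via AMOVA on squared repeat-count differences.

The molecular distance between two haplotypes is the sum over usable markers
of squared differences in repeat count; multi-copy markers contribute one
term per rank-matched copy of their sorted allele lists. An Excoffier-style
analysis of molecular variance partitions the total sum of squared
deviations into among- and within-population components:

    SS_total  = (1/(2N)) * sum_ij d2_ij           over all N samples
    SS_within = sum_pop (1/(2 n_p)) * sum_ij d2_ij   within each population
    SS_among  = SS_total - SS_within

    MS_among = SS_among/(P-1),  MS_within = SS_within/(N-P)
    sigma2_w = MS_within
    sigma2_a = (MS_among - MS_within)/n_bar,  n_bar = (N - sum n_p^2/N)/(P-1)

    Rst = sigma2_a / (sigma2_a + sigma2_w)

which is Slatkin's microsatellite analogue of Fst: the among-population
fraction of variance in allele repeat size. Negative sigma2_a (sampling
noise around zero differentiation) is clamped so Rst >= 0 by default.

Significance is assessed by permuting samples across the two populations
(sizes preserved) and counting permuted Rst values at least as large as the
observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .haplotype_io import Haplotype, LocusPanel, PopulationDataset

__all__ = [
    "RepeatDistanceConfig",
    "AmovaResult",
    "DistanceMatrix",
    "haplotype_to_repeat_vector",
    "haplotype_squared_distance",
    "repeat_matrix",
    "amova_pair",
    "amova_from_matrix",
    "pairwise_rst",
    "permutation_pvalue",
]


@dataclass(frozen=True)
class RepeatDistanceConfig:
    """Options for the repeat-count distance underlying AMOVA.

    multi_copy_mode
        ``rank_matched`` pairs the sorted allele lists of a multi-copy marker
        copy-by-copy; ``exclude`` drops multi-copy markers entirely.
    missing_mode
        ``exclude_pairwise`` skips a marker only for pairs where either
        sample lacks it; ``exclude_sample`` drops incomplete samples.
    negative_rst
        ``clamp_to_zero`` floors Rst at 0; ``report_raw`` keeps the
        (slightly negative) raw estimate.
    microvariant_mode
        ``numeric`` uses allele values as printed (17.2 - 17 = 0.2);
        ``truncate`` drops the fractional part before differencing.
    """

    multi_copy_mode: Literal["rank_matched", "exclude"] = "rank_matched"
    missing_mode: Literal["exclude_pairwise", "exclude_sample"] = "exclude_pairwise"
    negative_rst: Literal["clamp_to_zero", "report_raw"] = "clamp_to_zero"
    microvariant_mode: Literal["numeric", "truncate"] = "numeric"


@dataclass(frozen=True)
class AmovaResult:
    populations: tuple[str, ...]
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    rst: float
    n_per_population: tuple[int, ...]
    permutation_p: float | None = None

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labelled populations."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal not zero")
        object.__setattr__(self, "values", (v + v.T) / 2)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(p) for p in pair)
        return float(self.values[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="")

    def write_phylip(self, path) -> None:
        """PHYLIP square distance format (label width 10+)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                safe = label.replace(" ", "_")
                fh.write(safe.ljust(10) + "  ")
                fh.write("  ".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(labels=tuple(str(c) for c in df.columns), values=df.to_numpy(float))

    @classmethod
    def read_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(labels) != n:
            raise ValueError(f"expected {n} rows, found {len(labels)}")
        return cls(labels=tuple(labels), values=np.array(rows, dtype=float))


def haplotype_to_repeat_vector(
    h: Haplotype, panel: LocusPanel, cfg: RepeatDistanceConfig
) -> np.ndarray:
    """Numeric repeat counts, one slot per locus copy; NaN where unusable.

    Multi-copy markers occupy consecutive slots holding the sorted allele
    list (rank matching); a sample whose copy number differs from the
    panel's expectation gets NaN at that marker, which pairwise deletion
    then skips.
    """
    out: list[float] = []
    for (marker, copies), g in zip(panel.markers, h.genotypes):
        if copies > 1 and cfg.multi_copy_mode == "exclude":
            continue
        if g is None or g.copy_number != copies:
            out.extend([math.nan] * copies)
            continue
        for a in g.alleles:
            r = a.repeats
            out.append(float(int(r)) if cfg.microvariant_mode == "truncate" else r)
    return np.array(out, dtype=float)


def repeat_matrix(
    datasets: Sequence[PopulationDataset], cfg: RepeatDistanceConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Stack all samples into an (N, L) repeat matrix plus population index.

    Under ``exclude_sample`` missing-data handling, samples with any NaN
    slot are dropped.
    """
    panel = datasets[0].panel
    for ds in datasets[1:]:
        if ds.panel.markers != panel.markers:
            raise ValueError("datasets must share one panel")
    rows, pops = [], []
    for p, ds in enumerate(datasets):
        for h in ds:
            v = haplotype_to_repeat_vector(h, panel, cfg)
            if cfg.missing_mode == "exclude_sample" and np.isnan(v).any():
                continue
            rows.append(v)
            pops.append(p)
    X = np.vstack(rows)
    return X, np.array(pops, dtype=int)


def _squared_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise sum of squared per-locus differences with NaN-pairwise deletion."""
    if not np.isnan(X).any():
        return squareform(pdist(X, metric="sqeuclidean"))
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = X[i] - X[i + 1 :]
        d2 = np.nansum(diff * diff, axis=1)
        usable = (~np.isnan(diff)).any(axis=1)
        if not usable.all():
            bad = np.where(~usable)[0]
            raise ValueError(
                f"sample pair ({i}, {i + 1 + bad[0]}) shares no usable marker"
            )
        D[i, i + 1 :] = d2
        D[i + 1 :, i] = d2
    return D


def haplotype_squared_distance(
    a: Haplotype,
    b: Haplotype,
    panel: LocusPanel,
    cfg: RepeatDistanceConfig | None = None,
) -> float:
    """delta^2(a, b): summed squared repeat differences over usable markers."""
    cfg = cfg or RepeatDistanceConfig()
    va = haplotype_to_repeat_vector(a, panel, cfg)
    vb = haplotype_to_repeat_vector(b, panel, cfg)
    diff = va - vb
    usable = ~np.isnan(diff)
    if not usable.any():
        raise ValueError(
            f"samples {a.sample_id} and {b.sample_id} share no usable marker"
        )
    return float(np.sum(diff[usable] ** 2))


def _amova_components(
    D2: np.ndarray, pops: np.ndarray
) -> tuple[float, float, int, int, float, float, float]:
    """Variance components from a squared-distance matrix and group index.

    Returns (ss_among, ss_within, df_among, df_within, sigma2_a, sigma2_w,
    raw rst). All-zero total variance yields rst = 0 by convention.
    """
    N = len(pops)
    groups = np.unique(pops)
    P = len(groups)
    if P < 2:
        raise ValueError("AMOVA needs at least two populations")
    sizes = np.array([(pops == g).sum() for g in groups])
    if (sizes < 2).any():
        raise ValueError(f"every population needs n >= 2, got sizes {sizes.tolist()}")

    ss_total = D2.sum() / (2 * N)
    ss_within = 0.0
    for g in groups:
        mask = pops == g
        ss_within += D2[np.ix_(mask, mask)].sum() / (2 * mask.sum())
    ss_among = ss_total - ss_within

    df_among = P - 1
    df_within = N - P
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n_bar = (N - (sizes**2).sum() / N) / (P - 1)
    sigma2_w = ms_within
    sigma2_a = (ms_among - ms_within) / n_bar
    denom = sigma2_a + sigma2_w
    rst = 0.0 if denom <= 0 else sigma2_a / denom
    return ss_among, ss_within, df_among, df_within, sigma2_a, sigma2_w, rst


def amova_from_matrix(
    D2: np.ndarray,
    pops: np.ndarray,
    labels: Sequence[str],
    cfg: RepeatDistanceConfig | None = None,
) -> AmovaResult:
    cfg = cfg or RepeatDistanceConfig()
    ss_a, ss_w, df_a, df_w, s2a, s2w, rst = _amova_components(D2, pops)
    if cfg.negative_rst == "clamp_to_zero":
        rst = max(rst, 0.0)
    sizes = tuple(int((pops == g).sum()) for g in np.unique(pops))
    return AmovaResult(
        populations=tuple(labels),
        ss_among=ss_a,
        ss_within=ss_w,
        df_among=df_a,
        df_within=df_w,
        sigma2_among=s2a,
        sigma2_within=s2w,
        rst=rst,
        n_per_population=sizes,
    )


def amova_pair(
    ds1: PopulationDataset,
    ds2: PopulationDataset,
    cfg: RepeatDistanceConfig | None = None,
) -> AmovaResult:
    """Two-population AMOVA on repeat-count distances; Rst and components."""
    cfg = cfg or RepeatDistanceConfig()
    X, pops = repeat_matrix([ds1, ds2], cfg)
    D2 = _squared_distance_matrix(X)
    return amova_from_matrix(D2, pops, (ds1.population, ds2.population), cfg)


def pairwise_rst(
    datasets: Sequence[PopulationDataset],
    cfg: RepeatDistanceConfig | None = None,
) -> DistanceMatrix:
    """Matrix of pairwise Rst values over a set of populations."""
    if len(datasets) < 2:
        raise ValueError("need at least two populations")
    cfg = cfg or RepeatDistanceConfig()
    k = len(datasets)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = amova_pair(datasets[i], datasets[j], cfg).rst
            values[i, j] = values[j, i] = r
    return DistanceMatrix(
        labels=tuple(ds.population for ds in datasets), values=values
    )


def permutation_pvalue(
    ds1: PopulationDataset,
    ds2: PopulationDataset,
    cfg: RepeatDistanceConfig | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for Rst > 0.

    Samples are randomly reassigned to the two populations (sizes
    preserved); p = (1 + #{Rst* >= Rst_obs}) / (1 + n_perm). The squared-
    distance matrix is computed once and only the group index is permuted.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    cfg = cfg or RepeatDistanceConfig()
    X, pops = repeat_matrix([ds1, ds2], cfg)
    D2 = _squared_distance_matrix(X)
    observed = _amova_components(D2, pops)[-1]
    if cfg.negative_rst == "clamp_to_zero":
        observed = max(observed, 0.0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pops)
        r = _amova_components(D2, perm)[-1]
        if cfg.negative_rst == "clamp_to_zero":
            r = max(r, 0.0)
        if r >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)
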