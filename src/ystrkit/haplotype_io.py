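"""Reading, validating, writing and panel-subsetting of Y-STR haplotype tables.

The central objects are:

* :class:`AlleleValue` — a single STR allele designation, an integer repeat
  count or a microvariant such as ``17.2`` (17 full repeats plus 2 bases).
* :class:`LocusGenotype` — the allele multiset one male carries at one marker
  (one allele at single-copy markers, normally two at multi-copy markers such
  as DYS385a/b). Alleles are stored sorted, so ``{13,17}`` and ``{17,13}``
  are the same genotype.
* :class:`Haplotype` — a sample's genotypes across an ordered marker panel;
  multi-copy markers are treated as unordered allelic combinations, never as
  pseudo-loci.
* :class:`LocusPanel` — an ordered marker list with expected copy counts;
  the built-in panels are AGCU37 (34 markers / 37 locus copies), YFILER17
  and YFILERPLUS27.
* :class:`PopulationDataset` — the haplotypes of one population.

Tables are delimited text (TSV by default, CSV accepted) with a header row
``SampleID``, ``Population``, then one column per marker. Multi-copy cells
hold alleles joined by ``,`` (``-`` accepted on input). Missing data is an
empty cell or ``NA``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "AlleleValue",
    "LocusGenotype",
    "Haplotype",
    "LocusPanel",
    "PopulationDataset",
    "ValidationIssue",
    "ValidationReport",
    "builtin_panel",
    "read_haplotype_table",
    "write_haplotype_table",
    "subset_to_panel",
    "validate_dataset",
]

_MISSING_TOKENS = {"", "NA", "na", "N/A", "-", "."}
# "-" doubles as the alternate multi-copy separator; a bare "-" cell is missing.

_BUILTIN_PANEL_FILES = {
    "AGCU37": "agcu37.yaml",
    "YFILER17": "yfiler17.yaml",
    "YFILERPLUS27": "yfilerplus27.yaml",
}


@dataclass(frozen=True, order=True)
class AlleleValue:
    """An STR allele in repeat units, stored exactly as tenths of a repeat.

    Integer alleles (``14``) and microvariants (``17.2``, meaning 17 repeats
    plus 2 bases) are both representable; the fractional part must be one of
    .0/.1/.2/.3 per the STR nomenclature convention. Storing tenths as an
    integer makes equality, ordering and hashing exact.
    """

    tenths: int

    def __post_init__(self) -> None:
        if self.tenths <= 0:
            raise ValueError(f"allele must be positive, got {self.repeats}")
        if self.tenths % 10 not in (0, 1, 2, 3):
            raise ValueError(
                f"allele fractional part must be .0/.1/.2/.3, got {self.repeats}"
            )

    @property
    def repeats(self) -> float:
        """Numeric repeat count (e.g. ``17.2``)."""
        return self.tenths / 10

    @classmethod
    def from_string(cls, token: str) -> "AlleleValue":
        token = token.strip()
        try:
            if "." in token:
                whole, frac = token.split(".")
                if len(frac) != 1:
                    raise ValueError
                return cls(int(whole) * 10 + int(frac))
            return cls(int(token) * 10)
        except ValueError as exc:
            raise ValueError(f"unparseable allele token {token!r}") from exc

    @classmethod
    def from_number(cls, value: float) -> "AlleleValue":
        tenths = round(value * 10)
        if abs(tenths - value * 10) > 1e-6:
            raise ValueError(f"allele {value} is not a tenth-resolution repeat count")
        return cls(int(tenths))

    def __str__(self) -> str:
        whole, frac = divmod(self.tenths, 10)
        return str(whole) if frac == 0 else f"{whole}.{frac}"


@dataclass(frozen=True, order=True)
class LocusGenotype:
    """The allele combination one sample carries at one marker.

    ``alleles`` is canonically sorted ascending, so genotype equality is
    invariant to the order alleles were typed in.
    """

    marker: str
    alleles: tuple[AlleleValue, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"{self.marker}: genotype needs at least one allele")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def copy_number(self) -> int:
        return len(self.alleles)

    def __str__(self) -> str:
        return ",".join(str(a) for a in self.alleles)


@dataclass(frozen=True)
class LocusPanel:
    """An ordered Y-STR marker list with expected copy counts.

    A "locus count" in kit names (17/27/37) counts each copy of a multi-copy
    marker, so AGCU37 has 34 markers but 37 locus copies.
    """

    name: str
    markers: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [m for m, _ in self.markers]
        if len(set(names)) != len(names):
            raise ValueError(f"panel {self.name}: duplicate marker names")
        for marker, copies in self.markers:
            if copies not in (1, 2):
                raise ValueError(f"panel {self.name}: {marker} copy count {copies}")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.markers)

    @property
    def locus_count(self) -> int:
        """Total locus copies (each multi-copy marker counted per copy)."""
        return sum(c for _, c in self.markers)

    def copy_count(self, marker: str) -> int:
        for m, c in self.markers:
            if m == marker:
                return c
        raise KeyError(f"marker {marker!r} not in panel {self.name}")

    def __contains__(self, marker: str) -> bool:
        return marker in self.marker_names

    def __len__(self) -> int:
        return len(self.markers)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LocusPanel":
        with open(path) as fh:
            return cls._from_mapping(yaml.safe_load(fh), str(path))

    @classmethod
    def _from_mapping(cls, doc: Mapping, source: str) -> "LocusPanel":
        try:
            name = doc["name"]
            markers = tuple((str(m), int(c)) for m, c in doc["markers"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed panel definition in {source}") from exc
        return cls(name=name, markers=markers)

    def to_yaml(self, path: str | Path) -> None:
        doc = {"name": self.name, "markers": [[m, c] for m, c in self.markers]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def builtin_panel(name: str) -> LocusPanel:
    """Load one of the shipped panels: AGCU37, YFILER17, YFILERPLUS27."""
    key = name.upper()
    if key not in _BUILTIN_PANEL_FILES:
        raise KeyError(
            f"unknown built-in panel {name!r}; choose from {sorted(_BUILTIN_PANEL_FILES)}"
        )
    ref = resources.files("ystrkit.panels") / _BUILTIN_PANEL_FILES[key]
    with ref.open() as fh:
        return LocusPanel._from_mapping(yaml.safe_load(fh), str(ref))


@dataclass(frozen=True)
class Haplotype:
    """One sample's marker-to-genotype mapping over a panel.

    Markers the sample lacks data for map to ``None``. Two haplotypes are
    equal iff their canonicalized genotypes agree at every panel marker.
    """

    sample_id: str
    genotypes: tuple[LocusGenotype | None, ...]  # aligned with panel.markers

    def genotype(self, panel: LocusPanel, marker: str) -> LocusGenotype | None:
        return self.genotypes[panel.marker_names.index(marker)]

    @property
    def is_complete(self) -> bool:
        return all(g is not None for g in self.genotypes)

    def key(self) -> tuple:
        """Hashable identity over panel markers; the unit of haplotype counting."""
        return tuple(
            None if g is None else g.alleles for g in self.genotypes
        )


@dataclass
class PopulationDataset:
    """Haplotypes of one population typed on one panel."""

    population: str
    haplotypes: list[Haplotype]
    panel: LocusPanel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [h.sample_id for h in self.haplotypes]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(
                f"population {self.population}: duplicate sample IDs {sorted(dupes)}"
            )
        for h in self.haplotypes:
            if len(h.genotypes) != len(self.panel):
                raise ValueError(
                    f"sample {h.sample_id}: {len(h.genotypes)} genotype slots "
                    f"for a {len(self.panel)}-marker panel"
                )

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    def complete_haplotypes(self) -> list[Haplotype]:
        """Samples with no missing panel markers (the unit of direct counting)."""
        return [h for h in self.haplotypes if h.is_complete]

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self.haplotypes)


@dataclass(frozen=True)
class ValidationIssue:
    sample_id: str
    marker: str | None
    message: str


@dataclass
class ValidationReport:
    population: str
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return f"{self.population}: OK"
        lines = [f"{self.population}: {len(self.issues)} issue(s)"]
        for i in self.issues:
            where = f" at {i.marker}" if i.marker else ""
            lines.append(f"  {i.sample_id}{where}: {i.message}")
        return "\n".join(lines)


def _parse_cell(cell: str, marker: str, row: int) -> LocusGenotype | None:
    cell = cell.strip()
    if cell in _MISSING_TOKENS:
        return None
    # "-" is accepted as an alternate multi-copy separator on input.
    tokens = cell.replace("-", ",").split(",")
    try:
        alleles = tuple(AlleleValue.from_string(t) for t in tokens if t.strip())
    except ValueError as exc:
        raise ValueError(f"row {row}, column {marker}: {exc}") from exc
    if not alleles:
        return None
    return LocusGenotype(marker=marker, alleles=alleles)


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_haplotype_table(
    path: str | Path,
    panel: LocusPanel,
    delimiter: str | None = None,
) -> list[PopulationDataset]:
    """Read a delimited haplotype table into one dataset per population.

    The header must contain ``SampleID``, ``Population`` and every panel
    marker. Populations are returned in first-appearance order; sample order
    within each population is preserved.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        required = ["SampleID", "Population", *panel.marker_names]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in required}

        by_pop: dict[str, list[Haplotype]] = {}
        seen_ids: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            sample_id = row[idx["SampleID"]].strip()
            pop = row[idx["Population"]].strip()
            if sample_id in seen_ids:
                raise ValueError(f"{path}: duplicate sample ID {sample_id!r}")
            seen_ids.add(sample_id)
            genotypes = tuple(
                _parse_cell(row[idx[marker]], marker, rownum)
                for marker in panel.marker_names
            )
            by_pop.setdefault(pop, []).append(
                Haplotype(sample_id=sample_id, genotypes=genotypes)
            )
    return [
        PopulationDataset(population=pop, haplotypes=haps, panel=panel)
        for pop, haps in by_pop.items()
    ]


def write_haplotype_table(
    datasets: Sequence[PopulationDataset],
    path: str | Path,
    delimiter: str | None = None,
) -> None:
    """Write datasets to one delimited table; inverse of read on canonical data."""
    if not datasets:
        raise ValueError("no datasets to write")
    panel = datasets[0].panel
    for ds in datasets[1:]:
        if ds.panel != panel:
            raise ValueError(
                f"mixed panels: {ds.panel.name} vs {panel.name}; subset first"
            )
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["SampleID", "Population", *panel.marker_names])
        for ds in datasets:
            for h in ds:
                writer.writerow(
                    [h.sample_id, ds.population]
                    + ["" if g is None else str(g) for g in h.genotypes]
                )


def subset_to_panel(ds: PopulationDataset, target: LocusPanel) -> PopulationDataset:
    """Restrict a dataset to a sub-panel, preserving sample order and n."""
    absent = [m for m in target.marker_names if m not in ds.panel]
    if absent:
        raise ValueError(
            f"panel {target.name} markers absent from {ds.panel.name}: {absent}"
        )
    positions = [ds.panel.marker_names.index(m) for m in target.marker_names]
    haplotypes = [
        Haplotype(
            sample_id=h.sample_id,
            genotypes=tuple(h.genotypes[p] for p in positions),
        )
        for h in ds.haplotypes
    ]
    return PopulationDataset(
        population=ds.population,
        haplotypes=haplotypes,
        panel=target,
        metadata=dict(ds.metadata),
    )


def validate_dataset(ds: PopulationDataset) -> ValidationReport:
    """Report per-sample issues without modifying the dataset.

    Checks: missing markers, copy numbers other than the panel's expected
    count (e.g. two alleles at a single-copy marker), and implausible repeat
    counts (outside 1–99).
    """
    issues: list[ValidationIssue] = []
    for h in ds.haplotypes:
        for (marker, expected), g in zip(ds.panel.markers, h.genotypes):
            if g is None:
                issues.append(ValidationIssue(h.sample_id, marker, "missing genotype"))
                continue
            if g.copy_number != expected:
                kind = "single-copy" if expected == 1 else f"{expected}-copy"
                issues.append(
                    ValidationIssue(
                        h.sample_id,
                        marker,
                        f"unexpected copy count {g.copy_number} at {kind} marker",
                    )
                )
            for a in g.alleles:
                if not 1 <= a.repeats < 100:
                    issues.append(
                        ValidationIssue(
                            h.sample_id, marker, f"allele {a} out of plausible range"
                        )
                    )
    return ValidationReport(population=ds.population, issues=issues)
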