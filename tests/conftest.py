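import numpy as np
import pytest

from ystrkit.haplotype_io import (
    AlleleValue,
    Haplotype,
    LocusGenotype,
    LocusPanel,
    PopulationDataset,
    builtin_panel,
)


@pytest.fixture(scope="session")
def agcu37():
    return builtin_panel("AGCU37")


@pytest.fixture(scope="session")
def yfiler17():
    return builtin_panel("YFILER17")


@pytest.fixture(scope="session")
def yfilerplus27():
    return builtin_panel("YFILERPLUS27")


@pytest.fixture(scope="session")
def one_marker_panel():
    return LocusPanel(name="one", markers=(("DYS999", 1),))


def single_locus_dataset(population, alleles, panel, prefix="s"):
    """Dataset over a 1-marker panel from a plain list of integer alleles."""
    haps = [
        Haplotype(
            sample_id=f"{population}_{prefix}{i}",
            genotypes=(
                LocusGenotype(panel.markers[0][0], (AlleleValue(int(a) * 10),)),
            ),
        )
        for i, a in enumerate(alleles)
    ]
    return PopulationDataset(population=population, haplotypes=haps, panel=panel)


@pytest.fixture
def toy_table(tmp_path, agcu37):
    """4-sample, 2-population TSV on the full 34-marker panel."""
    rng = np.random.default_rng(42)
    header = ["SampleID", "Population", *agcu37.marker_names]
    rows = []
    for pop, sid in [("Miao", "M1"), ("Miao", "M2"), ("Tujia", "T1"), ("Tujia", "T2")]:
        cells = []
        for marker, copies in agcu37.markers:
            alleles = sorted(rng.integers(10, 20, size=copies).tolist())
            cells.append(",".join(str(a) for a in alleles))
        rows.append([sid, pop, *cells])
    path = tmp_path / "toy.tsv"
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return path
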