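import numpy as np
import pytest

from ystrkit.data import Allele, Haplotype, LocusCall, PopulationDataset, get_panel


@pytest.fixture(scope="session")
def panels():
    return {name: get_panel(name) for name in
            ("Minimal", "PowerPlexY12", "Yfiler", "PowerPlexY23",
             "Microreader24Y")}


def random_dataset(rng: np.random.Generator, n: int, name: str = "rand",
                   allele_range=(10, 14)) -> PopulationDataset:
    """Random complete 24-locus dataset (narrow allele range forces repeats)."""
    panel = get_panel("Microreader24Y")
    lo, hi = allele_range
    haplotypes = []
    for i in range(n):
        calls = {}
        for locus in panel.loci:
            if locus == "DYS385a/b":
                pair = sorted(rng.integers(lo, hi + 1, size=2))
                calls[locus] = LocusCall(locus, tuple(Allele(int(v)) for v in pair))
            else:
                calls[locus] = LocusCall(locus, (Allele(int(rng.integers(lo, hi + 1))),))
        haplotypes.append(Haplotype(f"{name}{i:04d}", calls, population=name))
    return PopulationDataset(name, haplotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(20230914)
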