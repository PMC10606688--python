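"""Synthetic Y-STR data: exact-spectrum dataset construction and a stepwise
mutation model simulator of structured populations.

``dataset_from_spectrum`` inverts haplotype counting: given a multiplicity
spectrum it builds a dataset whose spectrum is *exactly* the request.  The
nested variant accepts one spectrum per panel of a nested chain and solves
the implied refinement problem (finer-panel haplotype classes must partition
coarser-panel classes) exactly, erroring when no consistent dataset exists.

``simulate_populations`` evolves haplotypes under a strictly single-step
symmetric mutation model: each locus mutates with probability mu per
generation, moving one repeat unit up or down with equal probability.
Populations share ancestral lineages and accumulate independent drift for a
configurable number of generations after the split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .data import (
    Allele,
    Haplotype,
    LocusCall,
    PanelDef,
    PopulationDataset,
    expected_copies,
    get_panel,
    multiplicity_spectrum,
)
from .errors import ConfigError, InfeasibleSpectrumError

#: bundled five-panel multiplicity-spectrum profile of a 910-male,
#: 24-locus Han reference cohort (count of distinct haplotypes per
#: observation multiplicity, one column per nested panel)
REFERENCE_SPECTRA: dict[str, dict[int, int]] = {
    "Minimal": {1: 590, 2: 74, 3: 16, 4: 9, 5: 3, 6: 5, 9: 2, 10: 1, 15: 1},
    "PowerPlexY12": {1: 674, 2: 70, 3: 12, 4: 6, 5: 3, 6: 1, 7: 1, 8: 1},
    "Yfiler": {1: 813, 2: 40, 3: 2, 4: 1, 7: 1},
    "PowerPlexY23": {1: 867, 2: 20, 3: 1},
    "Microreader24Y": {1: 877, 2: 15, 3: 1},
}

#: default integer allele range used for generated haplotypes
DEFAULT_ALLELE_RANGE = (7, 25)


# ---------------------------------------------------------------------------
# exact-spectrum construction
# ---------------------------------------------------------------------------

def _locus_value_pool(locus: str, lo: int, hi: int) -> list[tuple[Allele, ...]]:
    """All candidate allele tuples for one locus column."""
    singles = [Allele(r) for r in range(lo, hi + 1)]
    copies = expected_copies(locus)
    if copies == 1:
        return [(a,) for a in singles]
    return [
        tuple(combo)
        for combo in itertools.combinations_with_replacement(singles, copies)
    ]


def _spectrum_sizes(spectrum: Mapping[int, int]) -> list[int]:
    if not spectrum:
        raise InfeasibleSpectrumError("empty spectrum")
    sizes: list[int] = []
    for k, c in sorted(spectrum.items(), reverse=True):
        if k < 1 or c < 1:
            raise InfeasibleSpectrumError(f"invalid spectrum entry {k}:{c}")
        sizes.extend([k] * c)
    return sizes  # descending class sizes


def _refine_sizes(parent_sizes: list[int], child_sizes: list[int]) -> list[list[int]]:
    """Partition the multiset of child class sizes into groups summing exactly
    to each parent class size (exact bin-filling with backtracking).

    Returns, aligned with ``parent_sizes``, the child sizes assigned to each
    parent.  Raises :class:`InfeasibleSpectrumError` when no assignment
    exists.
    """
    if sum(parent_sizes) != sum(child_sizes):
        raise InfeasibleSpectrumError(
            "nested spectra disagree on the number of individuals"
        )
    if len(child_sizes) < len(parent_sizes):
        raise InfeasibleSpectrumError(
            "a finer panel cannot have fewer haplotype classes"
        )
    order = sorted(range(len(parent_sizes)), key=lambda i: -parent_sizes[i])
    remaining = [parent_sizes[i] for i in order]
    bins: list[list[int]] = [[] for _ in remaining]
    children = sorted((c for c in child_sizes if c > 1), reverse=True)
    n_ones = sum(1 for c in child_sizes if c == 1)

    def place(idx: int) -> bool:
        if idx == len(children):
            # only unit-size children left: they exactly fill what remains
            return sum(remaining) == n_ones
        child = children[idx]
        tried: set[int] = set()
        for b, cap in enumerate(remaining):
            if cap >= child and cap not in tried:
                tried.add(cap)
                remaining[b] -= child
                bins[b].append(child)
                if place(idx + 1):
                    return True
                remaining[b] += child
                bins[b].pop()
        return False

    if not place(0):
        raise InfeasibleSpectrumError(
            "no refinement of the coarser spectrum realises the finer one"
        )
    for b, cap in enumerate(remaining):
        bins[b].extend([1] * cap)
    out: list[list[int]] = [[] for _ in parent_sizes]
    for pos, i in enumerate(order):
        out[i] = bins[pos]
    return out


def _draw_distinct(rng: np.ndarray, pools: list[list], count: int) -> list[tuple]:
    """``count`` distinct combinations over the per-locus value pools."""
    capacity = 1
    for p in pools:
        capacity *= len(p)
        if capacity >= 10**9:
            break
    if capacity < count:
        raise InfeasibleSpectrumError(
            f"allele space of size {capacity} cannot host {count} distinct "
            "haplotype classes"
        )
    if capacity <= 4 * count:  # small space: enumerate and subsample
        combos = list(itertools.product(*pools))
        idx = rng.choice(len(combos), size=count, replace=False)
        return [combos[i] for i in sorted(idx)]
    seen: set[tuple] = set()
    out: list[tuple] = []
    while len(out) < count:
        combo = tuple(p[rng.integers(len(p))] for p in pools)
        if combo not in seen:
            seen.add(combo)
            out.append(combo)
    return out


def dataset_from_nested_spectra(
    spectra: Sequence[tuple[PanelDef, Mapping[int, int]]],
    seed: int,
    *,
    name: str = "synthetic",
    allele_range: tuple[int, int] = DEFAULT_ALLELE_RANGE,
) -> PopulationDataset:
    """Build a dataset realising a multiplicity spectrum under every panel of
    a nested chain simultaneously.

    ``spectra`` pairs panels (ordered or not) with their target spectra; the
    panels must form a subset chain.  The construction solves the refinement
    problem level by level, then assigns distinct allele combinations to the
    coarsest classes and distinct values at each level's added loci to the
    classes it splits into.
    """
    if not spectra:
        raise InfeasibleSpectrumError("no spectra supplied")
    levels = sorted(spectra, key=lambda ps: len(ps[0].loci))
    for coarse, fine in zip(levels, levels[1:]):
        if not coarse[0].is_subset_of(fine[0]):
            raise ConfigError(
                f"panels {coarse[0].name!r} and {fine[0].name!r} are not nested"
            )
    rng = np.random.default_rng(seed)
    lo, hi = allele_range

    # class sizes per level, plus child->parent structure
    parent_sizes = _spectrum_sizes(levels[0][1])
    # profiles: per coarsest class, the allele assignment over its loci
    base_panel = levels[0][0]
    base_pools = [_locus_value_pool(l, lo, hi) for l in base_panel.loci]
    base_combos = _draw_distinct(rng, base_pools, len(parent_sizes))
    classes = [
        {"sizes": s, "calls": dict(zip(base_panel.loci, combo))}
        for s, combo in zip(parent_sizes, base_combos)
    ]

    for (coarse_panel, _), (fine_panel, fine_spec) in zip(levels, levels[1:]):
        added = [l for l in fine_panel.loci if l not in coarse_panel.loci]
        child_sizes = _spectrum_sizes(fine_spec)
        groups = _refine_sizes([c["sizes"] for c in classes], child_sizes)
        added_pools = [_locus_value_pool(l, lo, hi) for l in added]
        new_classes = []
        for cls, group in zip(classes, groups):
            combos = _draw_distinct(rng, added_pools, len(group))
            for size, combo in zip(group, combos):
                calls = dict(cls["calls"])
                calls.update(zip(added, combo))
                new_classes.append({"sizes": size, "calls": calls})
        classes = new_classes

    haplotypes = []
    counter = itertools.count(1)
    for cls in classes:
        calls = {
            locus: LocusCall(locus, alleles)
            for locus, alleles in cls["calls"].items()
        }
        for _ in range(cls["sizes"]):
            haplotypes.append(
                Haplotype(f"S{next(counter):04d}", calls, population=name)
            )
    rng.shuffle(haplotypes)
    haplotypes = [
        Haplotype(f"S{i + 1:04d}", h.calls, population=name)
        for i, h in enumerate(haplotypes)
    ]
    dataset = PopulationDataset(name, haplotypes)
    for panel, spec in levels:  # construction is exact by design; verify
        assert multiplicity_spectrum(dataset, panel) == dict(sorted(spec.items()))
    return dataset


def dataset_from_spectrum(
    spectrum: Mapping[int, int],
    panel: PanelDef,
    seed: int,
    *,
    name: str = "synthetic",
    allele_range: tuple[int, int] = DEFAULT_ALLELE_RANGE,
) -> PopulationDataset:
    """Dataset whose multiplicity spectrum under ``panel`` equals ``spectrum``."""
    return dataset_from_nested_spectra(
        [(panel, spectrum)], seed, name=name, allele_range=allele_range
    )


REFERENCE_SEED = 910


def reference_dataset(seed: int = REFERENCE_SEED) -> PopulationDataset:
    """A 910-male, 24-locus dataset reproducing the bundled five-panel
    multiplicity-spectrum profile, with microvariant alleles at DYS458 and
    copy-number-variant calls at DYS385a/b injected into singleton lineages.

    Regeneration with the same seed is byte-identical.
    """
    panels = [(get_panel(p), s) for p, s in REFERENCE_SPECTRA.items()]
    dataset = dataset_from_nested_spectra(panels, seed, name="reference")

    # individuals unique already at the coarsest panel stay unique at every
    # panel whatever we do to the finer loci, so edits below keep all spectra
    minimal = get_panel("Minimal")
    from collections import Counter

    key_counts = Counter(h.key(minimal.loci) for h in dataset.haplotypes)
    singles = [
        h for h in dataset.haplotypes if key_counts[h.key(minimal.loci)] == 1
    ]
    singles.sort(key=lambda h: h.sample_id)
    micro_partials = [Allele(13, 1), Allele(14, 1), Allele(15, 1)]
    cnv_extra_sizes = [3, 4, 4, 4, 5]
    edited: dict[str, Haplotype] = {}
    for h, allele in zip(singles[:3], micro_partials):
        calls = dict(h.calls)
        calls["DYS458"] = LocusCall("DYS458", (allele,))
        edited[h.sample_id] = Haplotype(h.sample_id, calls, h.population)
    for h, n_alleles in zip(singles[3:8], cnv_extra_sizes):
        calls = dict(h.calls)
        base = calls["DYS385a/b"].alleles
        extra = tuple(
            Allele(base[-1].repeats + k + 1) for k in range(n_alleles - len(base))
        )
        calls["DYS385a/b"] = LocusCall("DYS385a/b", base + extra)
        edited[h.sample_id] = Haplotype(h.sample_id, calls, h.population)
    haplotypes = [edited.get(h.sample_id, h) for h in dataset.haplotypes]
    out = PopulationDataset(dataset.name, haplotypes)
    for panel, spec in panels:
        assert multiplicity_spectrum(out, panel) == dict(sorted(spec.items()))
    return out


# ---------------------------------------------------------------------------
# stepwise mutation model simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusModel:
    """Founder allele range and per-generation mutation rate for one locus."""

    name: str
    low: int = DEFAULT_ALLELE_RANGE[0]
    high: int = DEFAULT_ALLELE_RANGE[1]
    mu: float = 0.002

    def __post_init__(self) -> None:
        if self.low > self.high or self.low < 0:
            raise ConfigError(f"bad allele range for {self.name}: "
                              f"[{self.low}, {self.high}]")
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigError(f"mutation rate for {self.name} not in [0,1]")


@dataclass
class SimulationConfig:
    """Parameters of the structured-population simulator."""

    n_populations: int
    n_individuals: int
    loci: list[LocusModel]
    seed: int
    n_founders: int = 10
    generations: int = 100
    divergence_generations: int = 0
    microvariant_rate: float = 0.0
    cnv_rate: float = 0.0
    microvariant_locus: str = "DYS458"
    cnv_locus: str = "DYS385a/b"

    def validate(self) -> None:
        if self.n_populations < 1 or self.n_individuals < 1:
            raise ConfigError("need >= 1 population and >= 1 individual")
        if not self.loci:
            raise ConfigError("need at least one locus model")
        if self.n_founders < 1:
            raise ConfigError("need >= 1 founder lineage")
        if self.generations < 0 or self.divergence_generations < 0:
            raise ConfigError("generation counts must be >= 0")
        for rate in (self.microvariant_rate, self.cnv_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("injection rates must lie in [0,1]")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        loci = [LocusModel(**entry) for entry in doc.pop("loci")]
        cfg = cls(loci=loci, **doc)
        cfg.validate()
        return cfg


def _smm_steps(rng, base: np.ndarray, generations: int, mu: np.ndarray) -> np.ndarray:
    """Apply ``generations`` rounds of symmetric single-step mutation.

    Equivalent to the per-generation walk: the number of mutation events is
    Binomial(t, mu) and each event moves +-1 with equal probability.
    """
    if generations == 0:
        return base.copy()
    events = rng.binomial(generations, np.broadcast_to(mu, base.shape))
    ups = rng.binomial(events, 0.5)
    return base + 2 * ups - events


def simulate_populations(cfg: SimulationConfig) -> list[PopulationDataset]:
    """Simulate structured populations under the stepwise mutation model.

    Founder haplotypes are drawn uniformly from each locus's allele range
    and shared by all populations.  After the split each population's copy
    of every founder drifts independently for ``divergence_generations``;
    each sampled individual then accumulates ``generations`` of private
    mutations on top of a uniformly chosen (population-local) founder.
    With ``divergence_generations=0`` the populations are panmictic
    replicates; with ``mu=0`` every individual equals its founder.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_loci = len(cfg.loci)
    mu = np.array([l.mu for l in cfg.loci])
    founders = np.column_stack(
        [rng.integers(l.low, l.high + 1, size=cfg.n_founders) for l in cfg.loci]
    ).astype(np.int64)

    datasets = []
    for p in range(cfg.n_populations):
        pop_founders = _smm_steps(rng, founders, cfg.divergence_generations, mu)
        picks = rng.integers(cfg.n_founders, size=cfg.n_individuals)
        base = pop_founders[picks]
        alleles = _smm_steps(rng, base, cfg.generations, mu)
        alleles = np.maximum(alleles, 1)  # repeat counts stay positive
        name = f"pop{p + 1}"
        haplotypes = []
        micro_hits = rng.random(cfg.n_individuals) < cfg.microvariant_rate
        cnv_hits = rng.random(cfg.n_individuals) < cfg.cnv_rate
        for i in range(cfg.n_individuals):
            calls = {}
            for j, locus in enumerate(cfg.loci):
                copies = expected_copies(locus.name)
                vals = [int(alleles[i, j])] * copies
                if copies > 1:  # duplicated marker: jitter the second copy
                    vals[1:] = [v + 1 for v in vals[1:]]
                parts = [0] * copies
                if locus.name == cfg.microvariant_locus and micro_hits[i]:
                    parts[0] = 1
                allele_objs = tuple(
                    Allele(v, q) for v, q in zip(vals, parts)
                )
                if locus.name == cfg.cnv_locus and cnv_hits[i]:
                    allele_objs += (Allele(vals[-1] + 2),)
                calls[locus.name] = LocusCall(locus.name, allele_objs)
            haplotypes.append(
                Haplotype(f"{name}_{i + 1:04d}", calls, population=name)
            )
        datasets.append(PopulationDataset(name, haplotypes))
    return datasets


def default_locus_models(
    n_loci: int = 20, mu: float = 0.002, prefix: str = "L"
) -> list[LocusModel]:
    """Generic single-copy locus models for simulation studies."""
    return [LocusModel(f"{prefix}{i + 1:02d}", mu=mu) for i in range(n_loci)]
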