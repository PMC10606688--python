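"""Synthetic data: exact-spectrum construction, SMM simulator properties."""

import numpy as np
import pytest

from ystrkit.data import (
    PANEL_CHAIN,
    get_panel,
    multiplicity_spectrum,
    read_haplotype_table,
    write_haplotype_table,
)
from ystrkit.errors import ConfigError, InfeasibleSpectrumError
from ystrkit.simulate import (
    REFERENCE_SPECTRA,
    LocusModel,
    SimulationConfig,
    _refine_sizes,
    dataset_from_nested_spectra,
    dataset_from_spectrum,
    default_locus_models,
    reference_dataset,
    simulate_populations,
)
from ystrkit.structure import pairwise_rst


class TestRefineSizes:
    def test_simple_split(self):
        groups = _refine_sizes([3, 2], [2, 1, 1, 1])
        assert sorted(sum(g) for g in groups) == [2, 3]
        assert sorted(c for g in groups for c in g) == [1, 1, 1, 2]

    def test_exact_preservation(self):
        groups = _refine_sizes([5], [5])
        assert groups == [[5]]

    def test_infeasible(self):
        # a child class larger than every parent cannot be placed
        with pytest.raises(InfeasibleSpectrumError):
            _refine_sizes([3, 3], [4, 1, 1])

    def test_count_mismatch(self):
        with pytest.raises(InfeasibleSpectrumError):
            _refine_sizes([3], [2, 2])

    def test_fewer_children_than_parents(self):
        with pytest.raises(InfeasibleSpectrumError):
            _refine_sizes([2, 2], [4])

    def test_backtracking_case(self):
        # greedy largest-fit fails here; backtracking must find {4,2},{3,3}
        groups = _refine_sizes([6, 6], [4, 3, 3, 2])
        assert sorted(sorted(g) for g in groups) == [[2, 4], [3, 3]]


class TestDatasetFromSpectrum:
    def test_three_singletons(self):
        ds = dataset_from_spectrum({1: 3}, get_panel("Minimal"), seed=1)
        assert ds.N == 3
        assert multiplicity_spectrum(ds, get_panel("Minimal")) == {1: 3}

    def test_one_doubleton_hd_zero(self):
        from ystrkit.forensic import haplotype_diversity

        ds = dataset_from_spectrum({2: 1}, get_panel("Minimal"), seed=1)
        spectrum = multiplicity_spectrum(ds, get_panel("Minimal"))
        assert spectrum == {2: 1}
        assert haplotype_diversity(spectrum) == pytest.approx(0.0)

    def test_reference_24y_spectrum(self):
        ds = dataset_from_spectrum(
            {1: 877, 2: 15, 3: 1}, get_panel("Microreader24Y"), seed=4
        )
        assert ds.N == 910
        assert multiplicity_spectrum(ds, get_panel("Microreader24Y")) == \
            {1: 877, 2: 15, 3: 1}

    def test_exactness_random_spectra(self, rng):
        panel = get_panel("Minimal")
        for _ in range(10):
            ks = rng.choice(np.arange(1, 7), size=3, replace=False)
            spectrum = {int(k): int(rng.integers(1, 20)) for k in ks}
            ds = dataset_from_spectrum(spectrum, panel, seed=int(rng.integers(1e6)))
            assert multiplicity_spectrum(ds, panel) == dict(sorted(spectrum.items()))

    def test_infeasible_allele_space(self):
        tiny = get_panel("Minimal")
        with pytest.raises(InfeasibleSpectrumError):
            dataset_from_spectrum({1: 10}, tiny, seed=1, allele_range=(10, 10))

    def test_deterministic_by_seed(self):
        panel = get_panel("Minimal")
        a = dataset_from_spectrum({1: 5, 2: 2}, panel, seed=9)
        b = dataset_from_spectrum({1: 5, 2: 2}, panel, seed=9)
        assert [h.key() for h in a.haplotypes] == [h.key() for h in b.haplotypes]


class TestNestedSpectra:
    def test_all_five_reference_panels(self, panels):
        ds = dataset_from_nested_spectra(
            [(panels[p], REFERENCE_SPECTRA[p]) for p in PANEL_CHAIN], seed=2
        )
        for p in PANEL_CHAIN:
            assert multiplicity_spectrum(ds, panels[p]) == \
                dict(sorted(REFERENCE_SPECTRA[p].items()))

    def test_non_nested_panels_rejected(self, panels):
        from ystrkit.data import PanelDef

        other = PanelDef("other", ("DYS19", "DYS999"))
        with pytest.raises(ConfigError, match="not nested"):
            dataset_from_nested_spectra(
                [(panels["Minimal"], {1: 2}), (other, {1: 2})], seed=1
            )

    def test_inconsistent_totals_rejected(self, panels):
        with pytest.raises(InfeasibleSpectrumError):
            dataset_from_nested_spectra(
                [(panels["Minimal"], {1: 3}),
                 (panels["Yfiler"], {1: 4})], seed=1
            )


class TestReferenceDataset:
    def test_shape_and_spectra(self, panels):
        ds = reference_dataset()
        assert ds.N == 910
        assert len(ds.loci) == 23
        assert multiplicity_spectrum(ds, panels["Microreader24Y"]) == \
            {1: 877, 2: 15, 3: 1}

    def test_contains_microvariants(self):
        ds = reference_dataset()
        labels = {h.calls["DYS458"].label for h in ds.haplotypes}
        assert {"13.1", "14.1", "15.1"} <= labels

    def test_contains_cnv_patterns(self):
        ds = reference_dataset()
        sizes = sorted(
            h.calls["DYS385a/b"].size for h in ds.haplotypes
            if h.calls["DYS385a/b"].size > 2
        )
        assert sizes == [3, 4, 4, 4, 5]

    def test_regeneration_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_haplotype_table(reference_dataset(), p1)
        write_haplotype_table(reference_dataset(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_matches_committed_fixture(self, tmp_path):
        import pathlib

        fixture = pathlib.Path(__file__).parent / "data" / "reference_dataset.tsv"
        regenerated = tmp_path / "regen.tsv"
        write_haplotype_table(reference_dataset(), regenerated)
        assert regenerated.read_bytes() == fixture.read_bytes()


class TestSimulator:
    base = dict(n_populations=2, n_individuals=15, n_founders=2)

    def test_no_mutation_equals_founders(self):
        cfg = SimulationConfig(
            loci=default_locus_models(4, mu=0.0), seed=3,
            generations=50, divergence_generations=50, n_founders=1,
            n_populations=2, n_individuals=10,
        )
        pops = simulate_populations(cfg)
        keys = {h.key() for pop in pops for h in pop.haplotypes}
        assert len(keys) == 1  # single founder, no mutation anywhere

    def test_deterministic_by_seed(self):
        cfg = SimulationConfig(
            loci=default_locus_models(3, mu=0.01), seed=11, generations=20,
            **self.base,
        )
        a = simulate_populations(cfg)
        b = simulate_populations(cfg)
        assert [h.key() for h in a[0].haplotypes] == \
            [h.key() for h in b[0].haplotypes]

    def test_variance_growth_rate(self):
        # E[(x_i - x_j)^2] for two independent lineages after t generations
        # is 2 mu t under the symmetric single-step model
        mu, t = 0.02, 100
        cfg = SimulationConfig(
            n_populations=1, n_individuals=4000, n_founders=1,
            loci=[LocusModel("L01", low=50, high=50, mu=mu)],
            generations=t, divergence_generations=0, seed=5,
        )
        pop = simulate_populations(cfg)[0]
        x = np.array([h.calls["L01"].alleles[0].value for h in pop.haplotypes])
        diffs = (x[: len(x) // 2] - x[len(x) // 2:]) ** 2
        assert diffs.mean() == pytest.approx(2 * mu * t, rel=0.15)

    def test_panmixia_gives_near_zero_rst(self):
        rsts = []
        for rep in range(20):
            cfg = SimulationConfig(
                loci=default_locus_models(5, mu=0.01), seed=100 + rep,
                generations=30, divergence_generations=0,
                n_populations=2, n_individuals=30, n_founders=3,
            )
            a, b = simulate_populations(cfg)
            rsts.append(
                pairwise_rst(a, b, [l.name for l in cfg.loci]).rst
            )
        assert abs(float(np.median(rsts))) < 0.05

    def test_divergence_monotonicity(self):
        medians = []
        for divergence in (0, 50, 500):
            rsts = []
            for rep in range(10):
                cfg = SimulationConfig(
                    loci=default_locus_models(10, mu=0.002), seed=300 + rep,
                    generations=50, divergence_generations=divergence,
                    n_populations=2, n_individuals=40, n_founders=1,
                )
                a, b = simulate_populations(cfg)
                rsts.append(pairwise_rst(a, b, [l.name for l in cfg.loci]).rst)
            medians.append(float(np.median(rsts)))
        assert medians[0] < medians[1] < medians[2]

    def test_microvariant_and_cnv_injection(self):
        cfg = SimulationConfig(
            n_populations=1, n_individuals=200, n_founders=2,
            loci=default_locus_models(2) + [
                LocusModel("DYS458"), LocusModel("DYS385a/b")],
            generations=10, seed=8,
            microvariant_rate=0.1, cnv_rate=0.1,
        )
        pop = simulate_populations(cfg)[0]
        micro = sum(
            any(a.partial for a in h.calls["DYS458"].alleles)
            for h in pop.haplotypes
        )
        cnv = sum(h.calls["DYS385a/b"].size > 2 for h in pop.haplotypes)
        assert micro > 0
        assert cnv > 0
        # DYS385a/b normally carries two alleles in simulated data
        assert all(h.calls["DYS385a/b"].size >= 2 for h in pop.haplotypes)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                n_populations=0, n_individuals=5,
                loci=default_locus_models(2), seed=1,
            ).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(
                n_populations=1, n_individuals=5,
                loci=default_locus_models(2), seed=1,
                microvariant_rate=1.5,
            ).validate()
        with pytest.raises(ConfigError):
            LocusModel("bad", low=10, high=5)

    def test_yaml_round_trip(self, tmp_path):
        cfg_path = tmp_path / "sim.yaml"
        cfg_path.write_text(
            "n_populations: 2\nn_individuals: 8\nseed: 4\n"
            "generations: 10\nn_founders: 2\n"
            "loci:\n  - name: L01\n    mu: 0.01\n  - name: L02\n",
            encoding="utf-8",
        )
        cfg = SimulationConfig.from_yaml(cfg_path)
        assert cfg.n_individuals == 8
        assert cfg.loci[0].mu == 0.01
        pops = simulate_populations(cfg)
        assert len(pops) == 2

    def test_emits_standard_tsv(self, tmp_path):
        cfg = SimulationConfig(
            loci=[LocusModel("DYS19"), LocusModel("DYS390")], seed=2,
            generations=5, **self.base,
        )
        pop = simulate_populations(cfg)[0]
        path = tmp_path / "pop.tsv"
        write_haplotype_table(pop, path)
        back = read_haplotype_table(path)
        assert [h.key() for h in back.haplotypes] == \
            [h.key() for h in pop.haplotypes]
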