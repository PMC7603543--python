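"""Circuit composition, validation, and sparse connectivity realisation."""

import dataclasses

import numpy as np
import pytest

from izhcortex.network import (
    ConnectionSpec,
    GroupSpec,
    InvalidConfigError,
    NetworkConfig,
    build_adjacency,
    default_cortex_config,
    scaled_config,
    validate,
)
from izhcortex.neuron import SpikingType


@pytest.fixture(scope="module")
def cortex():
    return default_cortex_config()


class TestDefaultComposition:
    def test_totals(self, cortex):
        assert cortex.n_neurons == 10_000
        n_exc = sum(g.count for g in cortex.groups if g.polarity == "excitatory")
        n_inh = sum(g.count for g in cortex.groups if g.polarity == "inhibitory")
        assert n_exc == 8000
        assert n_inh == 2000
        assert cortex.excitatory_fraction == 0.80

    @pytest.mark.parametrize(
        "cell_class, layer, spiking, count",
        [
            ("pyramidal", "L2/3", "RS", 2500),
            ("pyramidal", "L4", "RS", 1000),
            ("pyramidal", "L2/3", "CH", 500),
            ("pyramidal", "L4", "CH", 1400),
            ("pyramidal", "L5/6", "IB", 100 + 500),
            ("spiny", "L4", "RS", 1000),
            ("spiny", "L2/3", "RS", 1000),
            ("GABA_nb", "L1", "LTS", 200),
            ("GABA_nb", "L2", "LTS", 400),
            ("GABA_nb", "L4", "LTS", 200),
            ("GABA_nb", "L5", "LTS", 100),
            ("GABA_nb", "L6", "LTS", 200),
            ("GABA_b", "L2", "FS", 200),
            ("GABA_b", "L4", "FS", 400),
            ("GABA_b", "L5", "FS", 100),
            ("GABA_b", "L6", "FS", 200),
        ],
    )
    def test_per_row_counts(self, cortex, cell_class, layer, spiking, count):
        total = sum(
            g.count
            for g in cortex.groups
            if g.cell_class == cell_class
            and g.layer == layer
            and g.spiking_type == SpikingType(spiking)
        )
        assert total == count

    def test_receptor_assignment(self, cortex):
        for g in cortex.groups:
            if g.polarity == "inhibitory":
                assert g.receptor == "GABA"
            elif g.cell_class == "spiny":
                assert g.receptor == "AMPA"
            elif g.layer in ("L2/3", "L4"):
                assert g.receptor == "AMPA"
            else:
                assert g.receptor == "NMDA"

    def test_all_pairs_connected(self, cortex):
        assert len(cortex.connections) == 17 * 17
        for c in cortex.connections:
            assert c.sparseness == 0.1
            assert c.weight == 10.0

    def test_validates_cleanly(self, cortex):
        assert validate(cortex, expected_excitatory_fraction=0.8) == []


class TestValidate:
    def test_absent_group_reference(self, cortex):
        bad = dataclasses.replace(
            cortex,
            connections=cortex.connections + (ConnectionSpec("ghost", "RS_p23"),),
        )
        violations = validate(bad)
        assert len(violations) == 1
        assert "ghost" in violations[0]

    def test_bad_sparseness_and_weight(self, cortex):
        bad = dataclasses.replace(
            cortex,
            connections=(ConnectionSpec("RS_p23", "RS_p4", sparseness=1.5, weight=-1.0),),
        )
        violations = validate(bad)
        assert any("sparseness" in v for v in violations)
        assert any("weight" in v for v in violations)

    def test_duplicate_names_and_bad_polarity(self):
        g = GroupSpec("X", "GABA_b", "L4", 10, SpikingType.FS, "AMPA")
        cfg = NetworkConfig(groups=(g, g), connections=())
        violations = validate(cfg)
        assert any("not unique" in v for v in violations)
        assert any("GABA" in v for v in violations)

    def test_wrong_excitatory_fraction_reported(self, cortex):
        shrunk = dataclasses.replace(
            cortex,
            groups=tuple(
                dataclasses.replace(g, count=g.count // 2)
                if g.polarity == "inhibitory"
                else g
                for g in cortex.groups
            ),
        )
        assert validate(shrunk) == []
        assert validate(shrunk, expected_excitatory_fraction=0.8) != []


class TestScaledConfig:
    def test_tenth_scale_preserves_composition(self, cortex):
        small = scaled_config(cortex, 0.1)
        assert small.n_neurons == 1000
        assert small.excitatory_fraction == 0.80
        for g, s in zip(cortex.groups, small.groups):
            assert s.count == g.count // 10
            assert s.spiking_type == g.spiking_type


def two_group_config(n_a, n_b, sparseness, weight=10.0):
    groups = (
        GroupSpec("A", "pyramidal", "L2/3", n_a, SpikingType.RS, "AMPA"),
        GroupSpec("B", "GABA_b", "L4", n_b, SpikingType.FS, "GABA"),
    )
    return NetworkConfig(
        groups=groups,
        connections=(ConnectionSpec("A", "B", sparseness=sparseness, weight=weight),),
    )


class TestBuildAdjacency:
    def test_zero_sparseness_gives_no_edges(self):
        adj = build_adjacency(two_group_config(10, 20, 0.0), seed=0)
        assert adj.n_edges == 0

    def test_full_sparseness_complete_bipartite(self):
        adj = build_adjacency(two_group_config(10, 20, 1.0), seed=0)
        assert adj.n_edges == 200

    def test_recurrent_excludes_self_edges(self):
        g = GroupSpec("A", "pyramidal", "L2/3", 10, SpikingType.RS, "AMPA")
        cfg = NetworkConfig(groups=(g,), connections=(ConnectionSpec("A", "A", 1.0),))
        adj = build_adjacency(cfg, seed=0)
        assert adj.n_edges == 10 * 9
        assert not np.any(adj.edge_sets[0].src == adj.edge_sets[0].tgt)

    def test_edge_count_matches_binomial_mean(self):
        """Mean edge count over many seeds sits within 3 standard errors of
        n_source * n_target * sparseness."""
        cfg = two_group_config(100, 100, 0.1)
        n_seeds = 400
        counts = np.array(
            [build_adjacency(cfg, seed=s).n_edges for s in range(n_seeds)]
        )
        expected = 100 * 100 * 0.1
        se = np.sqrt(10_000 * 0.1 * 0.9 / n_seeds)
        assert abs(counts.mean() - expected) < 3 * se

    def test_deterministic_given_seed(self):
        cfg = two_group_config(50, 50, 0.2)
        a1 = build_adjacency(cfg, seed=11)
        a2 = build_adjacency(cfg, seed=11)
        a3 = build_adjacency(cfg, seed=12)
        np.testing.assert_array_equal(a1.edge_sets[0].src, a2.edge_sets[0].src)
        np.testing.assert_array_equal(a1.edge_sets[0].tgt, a2.edge_sets[0].tgt)
        assert not np.array_equal(a1.edge_sets[0].src, a3.edge_sets[0].src)

    def test_polarity_routing(self):
        """Inhibitory sources drive GABA; excitatory sources drive their
        group's AMPA/NMDA receptor."""
        cfg = default_cortex_config()
        small = scaled_config(cfg, 0.01)
        adj = build_adjacency(small, seed=0)
        receptor_of = {g.name: g.receptor for g in small.groups}
        polarity_of = {g.name: g.polarity for g in small.groups}
        for es in adj.edge_sets:
            assert es.receptor == receptor_of[es.source]
            if polarity_of[es.source] == "inhibitory":
                assert es.receptor == "GABA"
            else:
                assert es.receptor in ("AMPA", "NMDA")

    def test_invalid_config_rejected(self):
        cfg = two_group_config(10, 20, 1.5)
        with pytest.raises(InvalidConfigError):
            build_adjacency(cfg, seed=0)

    def test_csv_export_schema(self, tmp_path):
        import pandas as pd

        adj = build_adjacency(two_group_config(10, 20, 1.0), seed=0)
        path = tmp_path / "adjacency.csv"
        adj.write_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["source_id", "target_id", "weight_mV", "receptor"]
        assert len(df) == 200
        assert set(df["receptor"]) == {"AMPA"}
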