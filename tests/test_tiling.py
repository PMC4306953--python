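import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pksline.errors import TilingError, ValidationError
from pksline.labeling import calls_from_tables
from pksline.simulate import SimulationConfig, simulate_pipeline_inputs
from pksline.tiling import (
    CarbonGraph,
    PrecursorRule,
    Unit,
    brute_force_tile,
    default_precursor_rules,
    extender_sequence,
    predicted_label_positions,
    read_graph,
    tile,
    write_graph,
)


def chain_graph(n, hint=None):
    return CarbonGraph(
        nodes=tuple(range(1, n + 1)),
        bonds=tuple((i, i + 1) for i in range(1, n)),
        terminal_hint=hint,
    )


def canonical(tiling):
    return (
        round(tiling.concordance, 9),
        tiling.n_anomalous,
        tuple((u.c2, u.c1, u.side) for u in tiling.units),
        tuple(sorted(tiling.bond_classes.items())),
    )


class TestCarbonGraph:
    def test_disconnected_rejected(self):
        with pytest.raises(ValidationError, match="connected"):
            CarbonGraph(nodes=(1, 2, 3, 4), bonds=((1, 2),))

    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError, match="self-loop"):
            CarbonGraph(nodes=(1, 2), bonds=((1, 1), (1, 2)))

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValidationError, match="unknown node"):
            CarbonGraph(nodes=(1, 2), bonds=((1, 9),))

    def test_hint_must_be_a_node(self):
        with pytest.raises(ValidationError, match="terminal_hint"):
            chain_graph(4, hint=99)

    def test_round_trip(self, akaeolide_graph, tmp_path):
        path = tmp_path / "g.yaml"
        write_graph(akaeolide_graph, path)
        assert read_graph(path) == akaeolide_graph

    def test_fixture_shapes(self, akaeolide_graph, lorneic_graph):
        assert len(akaeolide_graph.nodes) == 22
        assert len(akaeolide_graph.bonds) == 22  # one ring closure
        assert len(lorneic_graph.nodes) == 17
        assert len(lorneic_graph.bonds) == 16  # a tree


class TestPredictedLabels:
    def test_alkyl_unit_label_sites(self, precursor_rules):
        # Propyl side chain: the elongated acyl chain is C1-C2-s0-s1-s2,
        # with the terminal three carbons propionate-derived.
        unit = Unit(index=1, c2=4, c1=5, side=(6, 7, 8))
        pred = predicted_label_positions([unit], precursor_rules)
        assert pred["acetate_1_13C"] == {5}
        assert pred["acetate_2_13C"] == {4}
        assert pred["propionate_1_13C"] == {6}

    def test_even_alkyl_side_is_all_acetate(self, precursor_rules):
        unit = Unit(index=1, c2=4, c1=5, side=(6, 7))
        pred = predicted_label_positions([unit], precursor_rules)
        assert pred["acetate_1_13C"] == {5, 6}
        assert pred["acetate_2_13C"] == {4, 7}
        assert pred["propionate_1_13C"] == set()

    def test_methylmalonyl_is_propionate_c1(self, precursor_rules):
        unit = Unit(index=1, c2=2, c1=3, side=(9,))
        pred = predicted_label_positions([unit], precursor_rules)
        assert pred["propionate_1_13C"] == {3}
        assert pred["acetate_1_13C"] == set()

    def test_rule_validation(self):
        with pytest.raises(ValidationError):
            PrecursorRule("acetate_1_13C", "C1", frozenset())
        with pytest.raises(ValidationError):
            PrecursorRule("acetate_1_13C", "C3", frozenset({"malonyl"}))


class TestTileWorkedExamples:
    def test_four_carbon_chain(self, precursor_rules):
        graph = chain_graph(4)
        calls = {"acetate_1_13C": {1, 3}}
        best = tile(graph, calls, precursor_rules)[0]
        assert extender_sequence(best) == ["acetyl_starter", "malonyl"]
        assert best.concordance == 1.0
        assert best.n_anomalous == 0

    def test_lorneic_unique_top_tiling(
        self, lorneic_graph, lorneic_calls, precursor_rules
    ):
        tilings = tile(lorneic_graph, lorneic_calls, precursor_rules)
        best = tilings[0]
        assert len(best.units) == 8
        assert extender_sequence(best) == [
            "acetyl_starter", "malonyl", "malonyl", "malonyl",
            "methylmalonyl", "malonyl", "malonyl", "malonyl",
        ]
        unit5 = best.units[4]
        assert (unit5.c2, unit5.c1, unit5.side) == (8, 7, (17,))
        assert best.concordance == 1.0
        assert best.n_anomalous == 0
        # uniqueness of the top tiling
        if len(tilings) > 1:
            assert tilings[1].concordance < 1.0

    def test_akaeolide_flags_post_assembly_bond(
        self, akaeolide_graph, akaeolide_calls, precursor_rules
    ):
        best = tile(akaeolide_graph, akaeolide_calls, precursor_rules)[0]
        assert len(best.units) == 8
        assert best.anomalous_bonds == ((16, 17),)
        sides = [len(u.side) for u in best.units[1:]]
        assert sides == [1, 1, 0, 1, 0, 3, 0]
        assert extender_sequence(best) == [
            "acetyl_starter", "methylmalonyl", "methylmalonyl", "malonyl",
            "methylmalonyl", "malonyl", "alkylmalonyl(C5)", "malonyl",
        ]

    def test_akaeolide_bond_classes(
        self, akaeolide_graph, akaeolide_calls, precursor_rules
    ):
        best = tile(akaeolide_graph, akaeolide_calls, precursor_rules)[0]
        classes = best.bond_classes
        assert classes[(16, 17)] == "anomalous"
        assert classes[(15, 16)] == "intra_unit"
        assert classes[(14, 15)] == "inter_unit"
        assert classes[(3, 4)] == "side_attachment"
        assert classes[(2, 3)] == "side_attachment"

    def test_units_partition_nodes(
        self, akaeolide_graph, akaeolide_calls, precursor_rules
    ):
        for tiling in tile(akaeolide_graph, akaeolide_calls, precursor_rules):
            covered = [n for u in tiling.units for n in u.nodes]
            assert sorted(covered) == list(akaeolide_graph.nodes)

    def test_enriched_position_must_be_node(
        self, lorneic_graph, precursor_rules
    ):
        with pytest.raises(ValidationError, match="not nodes"):
            tile(lorneic_graph, {"acetate_1_13C": {99}}, precursor_rules)

    def test_no_cover_raises(self, precursor_rules):
        # Odd node count: no sequence of 2-carbon-backbone units covers it
        # once the single side position cannot absorb the remainder.
        graph = CarbonGraph(nodes=(1, 2, 3), bonds=((1, 2), (2, 3)))
        with pytest.raises(TilingError):
            tile(graph, {}, precursor_rules)


class TestBruteForceOracle:
    def test_refuses_large_graphs(self, akaeolide_graph, precursor_rules):
        with pytest.raises(TilingError, match="refused"):
            brute_force_tile(akaeolide_graph, {}, precursor_rules)

    def test_empty_calls_vacuous_concordance(self, precursor_rules):
        tilings = brute_force_tile(chain_graph(6), {}, precursor_rules)
        assert {t.concordance for t in tilings} == {1.0}
        assert [canonical(t) for t in tilings] == [
            canonical(t) for t in tile(chain_graph(6), {}, precursor_rules)
        ]

    def test_truncated_lorneic_matches(self, precursor_rules):
        # First ten chain carbons from the methyl terminus: C-16 .. C-7.
        graph = CarbonGraph(
            nodes=tuple(range(7, 17)),
            bonds=tuple((i, i + 1) for i in range(7, 16)),
            terminal_hint=16,
        )
        calls = {
            "acetate_1_13C": {9, 11, 13, 15},
            "propionate_1_13C": {7},
        }
        a = tile(graph, calls, precursor_rules)
        b = brute_force_tile(graph, calls, precursor_rules)
        assert [canonical(t) for t in a] == [canonical(t) for t in b]


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 5_000))
def test_oracle_equivalence_on_generated_graphs(seed):
    """tile == brute_force_tile on every generated graph <= 12 nodes."""
    import numpy as np

    rng = np.random.default_rng(seed)
    config = SimulationConfig(
        seed=seed,
        n_extension_modules=int(rng.integers(2, 5)),
        inject_post_pks_bond=bool(rng.integers(2)),
    )
    try:
        _, _, _, result = simulate_pipeline_inputs(config)
    except Exception:
        return  # injection occasionally impossible; not the property here
    if len(result.graph.nodes) > 12:
        return
    calls = calls_from_tables(result.tables, 3.0)
    rules = default_precursor_rules()
    a = tile(result.graph, calls, rules)
    b = brute_force_tile(result.graph, calls, rules)
    assert [canonical(t) for t in a] == [canonical(t) for t in b]
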