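import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pksline.assembly import (
    assemble,
    count_double_bonds,
    hill_formula,
    molecular_formula,
    to_smiles,
)
from pksline.cluster import ClusterSpec, DomainSpec, ModuleSpec
from pksline.datasets import lorneic_cluster
from pksline.errors import ClassificationError
from pksline.rules import default_rules
from pksline.simulate import SimulationConfig, generate_cluster

rdkit_chem = pytest.importorskip("rdkit.Chem")


def parse_with_rdkit(smiles):
    mol = rdkit_chem.MolFromSmiles(smiles)
    assert mol is not None, f"rdkit rejected {smiles!r}"
    return mol


def rdkit_formula(smiles):
    from rdkit.Chem.rdMolDescriptors import CalcMolFormula

    return CalcMolFormula(parse_with_rdkit(smiles))


def loading_only_cluster():
    return ClusterSpec(
        id="loading-only",
        modules=[
            ModuleSpec(0, True, [DomainSpec("AT", signature="HAFH"),
                                 DomainSpec("ACP")])
        ],
    )


class TestAssemble:
    def test_akaeolide_has_22_carbons(self, akaeolide_product):
        assert akaeolide_product.total_carbons == 22
        assert akaeolide_product.backbone_length == 16

    def test_lorneic_has_17_carbons(self, lorneic_product):
        assert lorneic_product.total_carbons == 17
        assert lorneic_product.backbone_length == 16

    def test_loading_only_is_acetate(self, rules):
        product = assemble(loading_only_cluster(), rules)
        assert product.total_carbons == 2
        assert [c.oxidation for c in product.carbons] == ["methyl", "carboxyl"]

    def test_backbone_order_and_roles(self, lorneic_product):
        roles = [c.unit_role for c in lorneic_product.carbons]
        assert roles == ["C2", "C1"] * 8
        assert lorneic_product.carbons[0].oxidation == "methyl"
        assert lorneic_product.carbons[-1].oxidation == "carboxyl"

    def test_exactly_one_carboxyl(self, akaeolide_product):
        n = sum(1 for c in akaeolide_product.carbons
                if c.oxidation == "carboxyl")
        assert n == 1

    def test_akaeolide_stereo_verdicts(self, akaeolide_product):
        # Backbone chain positions (methyl terminus = 1) carrying the
        # carbon-level verdicts: hydroxyls at positions 6 and 12 are S,
        # the alkyl-bearing alpha carbon at 13 is R, the methyl-bearing
        # alpha at 5 is S (from the ER class).
        by_pos = {c.chain_index: c for c in akaeolide_product.carbons}
        assert (by_pos[6].oxidation, by_pos[6].stereo) == ("hydroxyl", "S")
        assert (by_pos[12].oxidation, by_pos[12].stereo) == ("hydroxyl", "S")
        assert by_pos[13].stereo == "R"
        assert by_pos[5].stereo == "S"

    def test_lorneic_all_trans(self, lorneic_product):
        geoms = {
            c.geometry for c in lorneic_product.carbons
            if c.oxidation == "enoyl"
        }
        assert geoms == {"E"}

    def test_enoyl_carbons_pair_up(self, lorneic_product):
        carbons = lorneic_product.carbons
        i = 0
        while i < len(carbons):
            if carbons[i].oxidation == "enoyl":
                assert carbons[i + 1].oxidation == "enoyl"
                assert carbons[i].geometry == carbons[i + 1].geometry
                i += 2
            else:
                i += 1

    def test_unresolvable_at_propagates(self, rules):
        cluster = ClusterSpec(
            id="bad",
            modules=[
                ModuleSpec(0, True, [DomainSpec("AT", signature="HAFH"),
                                     DomainSpec("ACP")]),
                ModuleSpec(1, False, [DomainSpec("KS"),
                                      DomainSpec("AT", signature="ZZZZ"),
                                      DomainSpec("ACP")]),
            ],
        )
        with pytest.raises(ClassificationError, match="ZZZZ"):
            assemble(cluster, rules)

    def test_deterministic(self, akaeolide_cluster, rules):
        assert assemble(akaeolide_cluster, rules) == assemble(
            akaeolide_cluster, rules
        )


class TestDoubleBonds:
    def test_akaeolide_fixture_has_two(self, akaeolide_product):
        assert count_double_bonds(akaeolide_product) == 2

    def test_akaeolide_all_active_has_four(self, akaeolide_cluster, rules):
        from dataclasses import replace

        modules = [
            ModuleSpec(m.index, m.loading,
                       [replace(d, active=True) for d in m.domains])
            for m in akaeolide_cluster.modules
        ]
        product = assemble(ClusterSpec(id="x", modules=modules), rules)
        assert count_double_bonds(product) == 4

    def test_lorneic_has_four(self, lorneic_product):
        assert count_double_bonds(lorneic_product) == 4


class TestMolecularFormula:
    def test_lorneic_intermediate_scenario(self, rules):
        product = assemble(lorneic_cluster(m4_er_active=False), rules)
        assert hill_formula(molecular_formula(product)) == "C17H24O2"

    def test_loading_only_is_acetic_acid(self, rules):
        product = assemble(loading_only_cluster(), rules)
        assert molecular_formula(product) == {"C": 2, "H": 4, "O": 2}

    def test_oxygen_at_least_two(self, akaeolide_product, lorneic_product):
        for product in (akaeolide_product, lorneic_product):
            assert molecular_formula(product)["O"] >= 2

    def test_hill_rendering(self):
        assert hill_formula({"C": 17, "H": 24, "O": 2}) == "C17H24O2"
        assert hill_formula({"C": 1, "H": 4}) == "CH4"


class TestToSmiles:
    def test_loading_only(self, rules):
        product = assemble(loading_only_cluster(), rules)
        mol = parse_with_rdkit(product.smiles)
        assert rdkit_chem.MolToSmiles(mol) == rdkit_chem.CanonSmiles("CC(=O)O")

    def test_lorneic_carbon_count_and_formula(self, lorneic_product):
        mol = parse_with_rdkit(lorneic_product.smiles)
        n_c = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
        assert n_c == 17
        assert rdkit_formula(lorneic_product.smiles) == hill_formula(
            molecular_formula(lorneic_product)
        )

    def test_akaeolide_reparse_carbon_count(self, akaeolide_product):
        mol = parse_with_rdkit(akaeolide_product.smiles)
        n_c = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
        assert n_c == 22

    def test_stereo_flag_adds_markers_and_parses(self, akaeolide_product):
        plain = to_smiles(akaeolide_product)
        stereo = to_smiles(akaeolide_product, include_stereo=True)
        assert "@" in stereo and "/" in stereo
        assert "@" not in plain and "/" not in plain
        parse_with_rdkit(stereo)

    def test_stereo_flag_skips_unspecified(self, rules):
        product = assemble(loading_only_cluster(), rules)
        assert to_smiles(product, include_stereo=True) == to_smiles(product)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 7))
def test_generated_product_invariants(seed, n):
    """Carbon conservation, profile/feature equivalence and SMILES
    re-parse formula agreement on generated clusters."""
    config = SimulationConfig(seed=seed, n_extension_modules=n,
                              p_inactive_dh=0.25)
    cluster, _ = generate_cluster(config)
    rules = default_rules()
    product = assemble(cluster, rules)

    assert product.total_carbons == sum(
        t.carbon_count for t in product.unit_types
    )

    profiles = [m.reductive_profile() for m in cluster.extension_modules]
    assert count_double_bonds(product) == profiles.count("DH+KR")
    n_hydroxyl = sum(
        1 for c in product.carbons if c.oxidation == "hydroxyl"
    )
    # KR with no active DH leaves a hydroxyl (a lone ER is vacuous)
    assert n_hydroxyl == profiles.count("KR") + profiles.count("ER+KR")

    formula = hill_formula(molecular_formula(product))
    assert rdkit_formula(product.smiles) == formula
    assert rdkit_formula(to_smiles(product, include_stereo=True)) == formula
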