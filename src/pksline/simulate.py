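"""Seeded generators for clusters, products, graphs and enrichment tables.

The noise model mirrors the statistical shape of published feeding tables:
enriched carbons carry a large ratio (``base_enrichment`` with lognormal
noise) while unenriched carbons scatter around 1.  All randomness flows
through a single explicitly-passed generator; nothing touches global RNG
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import LinearProduct, assemble
from .cluster import ClusterSpec, DomainSpec, ModuleSpec
from .errors import GenerationError, ValidationError
from .labeling import EnrichmentRecord, EnrichmentTable
from .rules import RuleConfig, default_rules
from .tiling import CarbonGraph, Unit, predicted_label_positions

REDUCTIVE_PROFILES = ("none", "KR", "DH+KR", "DH+ER+KR")
_EPS = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_extension_modules: int = 5
    substrate_weights: dict = field(
        default_factory=lambda: {
            "malonyl": 0.6, "methylmalonyl": 0.3, "alkylmalonyl": 0.1,
        }
    )
    reductive_profile_weights: dict = field(
        default_factory=lambda: {
            "none": 0.25, "KR": 0.25, "DH+KR": 0.25, "DH+ER+KR": 0.25,
        }
    )
    p_inactive_dh: float = 0.0
    base_enrichment: float = 5.0
    noise_sd_unlabeled: float = 0.0
    noise_sd_enriched_log: float = 0.0
    inject_post_pks_bond: bool = False

    def __post_init__(self) -> None:
        if self.n_extension_modules < 1:
            raise ValidationError("n_extension_modules must be >= 1")
        for name, table in (
            ("substrate_weights", self.substrate_weights),
            ("reductive_profile_weights", self.reductive_profile_weights),
        ):
            if not table or all(w <= 0 for w in table.values()):
                raise ValidationError(f"{name}: need at least one positive weight")
            if any(w < 0 for w in table.values()):
                raise ValidationError(f"{name}: weights must be non-negative")
        if not 0 <= self.p_inactive_dh <= 1:
            raise ValidationError("p_inactive_dh must be in [0, 1]")
        if not self.base_enrichment > 1:
            raise ValidationError("base_enrichment must be > 1")
        if self.noise_sd_unlabeled < 0 or self.noise_sd_enriched_log < 0:
            raise ValidationError("noise SDs must be >= 0")


def _weighted_choice(rng, table: dict) -> str:
    names = sorted(table)
    weights = np.array([table[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=weights / weights.sum())]


def _signature_for(substrate: str, config: RuleConfig) -> str:
    for token, ext in sorted(config.at_signature_table.items()):
        if ext.name == substrate:
            return token
    raise GenerationError(f"no signature token for substrate {substrate!r}")


def generate_cluster(config: SimulationConfig, rng=None):
    """Draw a random cluster; returns (ClusterSpec, ground-truth labels).

    AT signatures are drawn from the default rule table's tokens, so
    substrate prediction inverts the draw exactly; the ground-truth labels
    are therefore the generator's own record of what it sampled, starter
    first.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rules = default_rules()
    kr_tokens = sorted(rules.kr_fingerprint_table)
    modules = [
        ModuleSpec(
            index=0,
            loading=True,
            domains=[
                DomainSpec("AT", signature=_signature_for("malonyl", rules)),
                DomainSpec("ACP"),
            ],
        )
    ]
    truth = ["acetyl_starter"]
    for i in range(1, config.n_extension_modules + 1):
        substrate = _weighted_choice(rng, config.substrate_weights)
        signature = _signature_for(substrate, rules)
        ext = rules.at_signature_table[signature]
        truth.append(ext.label)
        profile = _weighted_choice(rng, config.reductive_profile_weights)
        domains = [DomainSpec("KS"), DomainSpec("AT", signature=signature)]
        if "DH" in profile:
            dh_active = bool(rng.random() >= config.p_inactive_dh)
            domains.append(DomainSpec("DH", active=dh_active))
        if "ER" in profile:
            domains.append(DomainSpec("ER", signature="Y"))
        if "KR" in profile:
            domains.append(
                DomainSpec(
                    "KR",
                    kr_fingerprint=kr_tokens[rng.integers(len(kr_tokens))],
                )
            )
        domains.append(DomainSpec("ACP"))
        if i == config.n_extension_modules:
            domains.append(DomainSpec("TE"))
        modules.append(ModuleSpec(index=i, loading=False, domains=domains))
    cluster = ClusterSpec(
        id=f"synthetic-{config.seed}-{config.n_extension_modules}",
        modules=modules,
        compound_hint="synthetic",
    )
    return cluster, truth


def true_units(product: LinearProduct) -> tuple:
    """Ground-truth tiling units of a product, in graph node ids."""
    units = []
    for j, ext in enumerate(product.unit_types):
        c2, c1 = 2 * j + 1, 2 * j + 2
        side = tuple(c.chain_index for c in product.side_chains.get(c2, ()))
        units.append(Unit(index=j, c2=c2, c1=c1, side=side, starter=(j == 0)))
    return tuple(units)


def product_graph(product: LinearProduct) -> CarbonGraph:
    """Carbon graph of the linear product (node ids = chain indices)."""
    nodes = [c.chain_index for c in product.carbons]
    bonds = [
        (product.carbons[i].chain_index, product.carbons[i + 1].chain_index)
        for i in range(len(product.carbons) - 1)
    ]
    for at, sides in product.side_chains.items():
        prev = at
        for c in sides:
            nodes.append(c.chain_index)
            bonds.append((prev, c.chain_index))
            prev = c.chain_index
    return CarbonGraph(
        nodes=tuple(nodes), bonds=tuple(bonds), terminal_hint=1
    )


@dataclass(frozen=True)
class SimulationResult:
    tables: dict  # experiment -> EnrichmentTable
    graph: CarbonGraph
    units: tuple  # ground-truth Units
    true_labels: dict  # experiment -> set of truly labeled nodes
    references: dict  # experiment -> reference carbon used
    injected_bond: tuple | None


def simulate_labeling(
    product: LinearProduct,
    rules,
    config: SimulationConfig,
    rng=None,
    mode: str = "ratios",
) -> SimulationResult:
    """Simulate per-experiment enrichment tables and the compound graph.

    ``mode='ratios'`` emits tables in the published pass-through form;
    ``mode='intensities'`` emits raw labeled/unlabeled intensities (with a
    random overall scale) to exercise the two-spectrum computation.  With
    ``inject_post_pks_bond`` one extra bond is added between the C2 carbons
    of two acetate-derived units, recorded as ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if mode not in ("ratios", "intensities"):
        raise GenerationError(f"unknown simulation mode {mode!r}")
    units = true_units(product)
    graph = product_graph(product)

    injected = None
    if config.inject_post_pks_bond:
        eligible = sorted(
            u.c2 for u in units if u.type_name in ("acetyl_starter", "malonyl")
        )
        existing = set(graph.bonds)
        pairs = [
            (a, b)
            for i, a in enumerate(eligible)
            for b in eligible[i + 1:]
            if (a, b) not in existing
        ]
        if not pairs:
            raise GenerationError(
                "no eligible C2-C2 pair for post-assembly bond injection"
            )
        injected = pairs[rng.integers(len(pairs))]
        graph = CarbonGraph(
            nodes=graph.nodes,
            bonds=graph.bonds + (injected,),
            terminal_hint=graph.terminal_hint,
        )

    true_labels = predicted_label_positions(units, rules)
    ever_labeled = set().union(*true_labels.values()) if true_labels else set()
    never_labeled = sorted(set(graph.nodes) - ever_labeled)

    tables = {}
    references = {}
    for experiment in sorted(true_labels):
        labeled = true_labels[experiment]
        # Prefer one carbon unlabeled in every experiment (the published
        # convention); fall back to a carbon unlabeled in this experiment.
        candidates = never_labeled or sorted(set(graph.nodes) - labeled)
        if not candidates:
            raise GenerationError(
                f"{experiment}: no never-labeled carbon available as a "
                "reference"
            )
        reference = candidates[0]
        references[experiment] = reference
        scale = float(rng.uniform(0.5, 2.0))
        records = []
        for node in graph.nodes:
            if node in labeled:
                ratio = config.base_enrichment * float(
                    np.exp(rng.normal(0.0, config.noise_sd_enriched_log))
                )
            else:
                ratio = max(
                    _EPS, 1.0 + float(rng.normal(0.0, config.noise_sd_unlabeled))
                )
            shift = 10.0 + float(node)  # placeholder shift, not physical
            if mode == "ratios":
                records.append(
                    EnrichmentRecord(
                        position=node, shift_ppm=shift, ratio=ratio
                    )
                )
            else:
                unlabeled_i = max(
                    _EPS, 1.0 + float(rng.normal(0.0, config.noise_sd_unlabeled))
                )
                records.append(
                    EnrichmentRecord(
                        position=node,
                        shift_ppm=shift,
                        labeled_intensity=ratio * unlabeled_i * scale,
                        unlabeled_intensity=unlabeled_i,
                    )
                )
        tables[experiment] = EnrichmentTable(
            compound="synthetic",
            experiment=experiment,
            records=records,
            reference_position=reference,
        )
    return SimulationResult(
        tables=tables,
        graph=graph,
        units=units,
        true_labels=true_labels,
        references=references,
        injected_bond=injected,
    )


def simulate_pipeline_inputs(config: SimulationConfig, rules=None):
    """Cluster -> product -> labeling, all from one seeded generator."""
    from .tiling import default_precursor_rules

    rng = np.random.default_rng(config.seed)
    cluster, truth = generate_cluster(config, rng)
    product = assemble(cluster, default_rules())
    result = simulate_labeling(
        product, rules or default_precursor_rules(), config, rng
    )
    return cluster, truth, product, result
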