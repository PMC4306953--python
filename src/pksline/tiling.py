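"""Precursor-unit tiling of a compound's carbon skeleton.

A tiling partitions the carbon graph into one starter unit (two carbons,
anchored at a terminal methyl or at the ``terminal_hint``) followed by
extender units walking the graph head to tail: each new unit's C2 bonds the
previous unit's C1.  Carbons hanging off a C2 form the unit's side chain
and type it by size (0 -> malonyl, 1 -> methylmalonyl, n >= 2 ->
alkylmalonyl).  Bonds not used by the chain or the side assignments are
classified anomalous: they cannot arise from chain extension and imply
carbon-carbon bond formation after assembly.

Label calls from feeding experiments are consistency evidence, not the
typing signal: concordance is the fraction of (experiment, node)
observations whose enriched status matches the label positions the tiling
predicts.  Only carbon-carbon connectivity is tiled; oxygens are not part
of the graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import yaml

from .errors import TilingError, ValidationError
from .labeling import EXPERIMENTS

BRUTE_FORCE_MAX_NODES = 14


@dataclass(frozen=True)
class CarbonGraph:
    nodes: tuple
    bonds: tuple  # canonical sorted pairs
    terminal_hint: int | None = None

    def __post_init__(self) -> None:
        nodes = tuple(sorted(set(self.nodes)))
        bonds = tuple(sorted(tuple(sorted(b)) for b in self.bonds))
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "bonds", bonds)
        node_set = set(nodes)
        for a, b in bonds:
            if a == b:
                raise ValidationError(f"self-loop on node {a}")
            if a not in node_set or b not in node_set:
                raise ValidationError(f"bond ({a}, {b}) references unknown node")
        if len(set(bonds)) != len(bonds):
            raise ValidationError("duplicate bonds")
        if self.terminal_hint is not None and self.terminal_hint not in node_set:
            raise ValidationError(
                f"terminal_hint {self.terminal_hint} is not a node"
            )
        g = self.to_networkx()
        if len(nodes) and not nx.is_connected(g):
            raise ValidationError("carbon graph must be connected")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.bonds)
        return g


def read_graph(path) -> CarbonGraph:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "nodes" not in raw or "bonds" not in raw:
        raise ValidationError(f"{path}: graph file needs 'nodes' and 'bonds'")
    return CarbonGraph(
        nodes=tuple(int(n) for n in raw["nodes"]),
        bonds=tuple((int(a), int(b)) for a, b in raw["bonds"]),
        terminal_hint=(
            int(raw["terminal_hint"]) if raw.get("terminal_hint") is not None
            else None
        ),
    )


def write_graph(graph: CarbonGraph, path) -> None:
    out = {
        "nodes": list(graph.nodes),
        "bonds": [list(b) for b in graph.bonds],
    }
    if graph.terminal_hint is not None:
        out["terminal_hint"] = graph.terminal_hint
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


@dataclass(frozen=True)
class PrecursorRule:
    """Which unit carbon a labeled precursor marks, and in which unit types."""

    experiment: str
    labels_role: str  # "C1" or "C2"
    applies_to: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "applies_to", frozenset(self.applies_to))
        if self.experiment not in EXPERIMENTS:
            raise ValidationError(f"unknown experiment {self.experiment!r}")
        if self.labels_role not in ("C1", "C2"):
            raise ValidationError("labels_role must be 'C1' or 'C2'")
        if not self.applies_to:
            raise ValidationError("applies_to must be non-empty")


def default_precursor_rules() -> list:
    """Default incorporation rules for the three backbone precursors.

    Acetate enters acetate-derived positions of alkylmalonyl units too
    (their acyl chains are built from acetate extensions), and
    [1-13C]propionate marks the methylmalonyl C1 but, in an alkylmalonyl
    unit, the propionate-derived triad at the end of the elongated acyl
    chain - i.e. the first side-chain carbon.
    """
    return [
        PrecursorRule(
            "acetate_1_13C", "C1",
            frozenset({"acetyl_starter", "malonyl", "alkylmalonyl"}),
        ),
        PrecursorRule(
            "acetate_2_13C", "C2",
            frozenset({"acetyl_starter", "malonyl", "alkylmalonyl"}),
        ),
        PrecursorRule(
            "propionate_1_13C", "C1",
            frozenset({"methylmalonyl", "alkylmalonyl"}),
        ),
    ]


@dataclass(frozen=True)
class Unit:
    index: int
    c2: int
    c1: int
    side: tuple = ()
    side_linear: bool = True
    starter: bool = False

    @property
    def nodes(self) -> tuple:
        return (self.c2, self.c1) + tuple(self.side)

    @property
    def type_name(self) -> str:
        if self.starter:
            return "acetyl_starter"
        n = len(self.side)
        if n == 0:
            return "malonyl"
        if n == 1:
            return "methylmalonyl"
        return "alkylmalonyl"

    @property
    def label(self) -> str:
        if self.type_name == "alkylmalonyl":
            return f"alkylmalonyl(C{2 + len(self.side)})"
        return self.type_name


@dataclass(frozen=True)
class UnitTiling:
    units: tuple
    bond_classes: dict  # canonical bond -> class string
    concordance: float

    @property
    def anomalous_bonds(self) -> tuple:
        return tuple(
            sorted(b for b, c in self.bond_classes.items() if c == "anomalous")
        )

    @property
    def n_anomalous(self) -> int:
        return len(self.anomalous_bonds)


def _bond(a: int, b: int) -> tuple:
    return (a, b) if a < b else (b, a)


def predicted_label_positions(units, rules) -> dict:
    """Predicted labeled nodes per experiment for a sequence of units."""
    out = {rule.experiment: set() for rule in rules}
    for rule in rules:
        role_offset = 0 if rule.labels_role == "C1" else 1
        for unit in units:
            if unit.type_name not in rule.applies_to:
                continue
            if unit.type_name != "alkylmalonyl":
                out[rule.experiment].add(
                    unit.c1 if rule.labels_role == "C1" else unit.c2
                )
                continue
            if not unit.side_linear:
                continue  # no elongated-chain model for branched sides
            # Elongated acyl chain: position 1 = C1, 2 = C2, 3.. = side.
            chain = (unit.c1, unit.c2) + tuple(unit.side)
            length = len(chain)
            odd_side = len(unit.side) % 2 == 1
            # Odd side: a propionate triad caps the chain; even side: the
            # whole acyl chain is acetate pairs.
            acetate_top = length - 3 if odd_side else length
            if rule.experiment in ("acetate_1_13C", "acetate_2_13C"):
                for pos in range(1 + role_offset, acetate_top + 1, 2):
                    out[rule.experiment].add(chain[pos - 1])
            elif rule.experiment == "propionate_1_13C" and odd_side:
                out[rule.experiment].add(chain[length - 3 + role_offset])
    return out


def concordance_score(graph: CarbonGraph, calls: dict, units, rules) -> float:
    """Fraction of (experiment, node) observations matching predictions."""
    if not calls:
        return 1.0
    predicted = predicted_label_positions(units, rules)
    total = 0
    matched = 0
    for experiment, enriched in calls.items():
        enriched = set(enriched)
        pred = predicted.get(experiment, set())
        for node in graph.nodes:
            total += 1
            matched += (node in enriched) == (node in pred)
    return matched / total if total else 1.0


def _validate_inputs(graph: CarbonGraph, calls: dict) -> None:
    node_set = set(graph.nodes)
    for experiment, enriched in calls.items():
        if experiment not in EXPERIMENTS:
            raise ValidationError(f"unknown experiment {experiment!r}")
        bad = set(enriched) - node_set
        if bad:
            raise ValidationError(
                f"{experiment}: enriched positions {sorted(bad)} are not nodes"
            )


def _candidate_starters(graph: CarbonGraph, g: nx.Graph) -> list:
    if graph.terminal_hint is not None:
        return [graph.terminal_hint]
    starters = sorted(n for n in g.nodes if g.degree[n] == 1)
    if not starters:
        raise TilingError(
            "no degree-1 carbon to anchor the starter; provide a terminal hint"
        )
    return starters


def _linearize_side(g: nx.Graph, comp: set, anchor: int):
    """Order a side component as a chain rooted at the anchor C2.

    Returns (ordered nodes, is_linear).  Non-linear components are returned
    in sorted order with the flag down.
    """
    roots = sorted(n for n in comp if g.has_edge(anchor, n))
    if len(roots) != 1:
        return tuple(sorted(comp)), False
    order = [roots[0]]
    seen = {roots[0]}
    while True:
        nxt = [n for n in g.neighbors(order[-1]) if n in comp and n not in seen]
        if not nxt:
            break
        if len(nxt) > 1:
            return tuple(sorted(comp)), False
        order.append(nxt[0])
        seen.add(nxt[0])
    if len(order) != len(comp):
        return tuple(sorted(comp)), False
    return tuple(order), True


def _build_tiling(
    graph: CarbonGraph, g: nx.Graph, path, assignment, calls, rules
) -> UnitTiling:
    """Assemble units and bond classes from a backbone path and a mapping
    of side components to extension-unit C2 anchors."""
    sides = {}  # c2 -> merged node set
    for comp, anchor in assignment:
        sides.setdefault(anchor, set()).update(comp)
    units = []
    for j in range(len(path) // 2):
        c2, c1 = path[2 * j], path[2 * j + 1]
        comp = sides.get(c2, set())
        side, linear = (
            _linearize_side(g, comp, c2) if comp else ((), True)
        )
        units.append(
            Unit(
                index=j, c2=c2, c1=c1, side=side, side_linear=linear,
                starter=(j == 0),
            )
        )
    classes = {b: "anomalous" for b in graph.bonds}
    for j, unit in enumerate(units):
        classes[_bond(unit.c2, unit.c1)] = "intra_unit"
        if j:
            classes[_bond(units[j - 1].c1, unit.c2)] = "inter_unit"
        scope = set(unit.side) | {unit.c2}
        for node in unit.side:
            for nbr in g.neighbors(node):
                if nbr in scope:
                    classes[_bond(node, nbr)] = "side_attachment"
    score = concordance_score(graph, calls, units, rules)
    return UnitTiling(units=tuple(units), bond_classes=classes, concordance=score)


def _complete_assignments(g: nx.Graph, path):
    """Yield all assignments of leftover components to extension C2 anchors.

    Each connected component of the graph minus the backbone must hang off
    an adjacent extension-unit C2 (the starter unit takes no side chain).
    """
    rest = set(g.nodes) - set(path)
    extension_c2s = [path[i] for i in range(2, len(path), 2)]
    if not rest:
        yield ()
        return
    comps = [frozenset(c) for c in nx.connected_components(g.subgraph(rest))]
    anchor_lists = []
    for comp in comps:
        anchors = [
            c2 for c2 in extension_c2s
            if any(g.has_edge(c2, n) for n in comp)
        ]
        if not anchors:
            return  # this backbone cannot cover the graph
        anchor_lists.append(anchors)
    for choice in itertools.product(*anchor_lists):
        yield tuple(zip(comps, choice))


def _rank_key(tiling: UnitTiling):
    return (
        -tiling.concordance,
        tiling.n_anomalous,
        tuple(u.label for u in tiling.units),
        tuple((u.c2, u.c1, u.side) for u in tiling.units),
    )


def _finalize(tilings) -> list:
    seen = set()
    unique = []
    for t in tilings:
        key = tuple((u.c2, u.c1, u.side) for u in t.units)
        if key not in seen:
            seen.add(key)
            unique.append(t)
    unique.sort(key=_rank_key)
    return unique


def tile(graph: CarbonGraph, calls: dict, rules) -> list:
    """Enumerate unit tilings by backtracking, ranked best first.

    Ranking is (concordance desc, anomalous-bond count asc, lexicographic
    unit-type sequence); all complete tilings are returned, ties included.
    """
    _validate_inputs(graph, calls)
    g = graph.to_networkx()
    if len(graph.nodes) < 2:
        raise TilingError("graph too small to contain a starter unit")
    results = []
    for starter in _candidate_starters(graph, g):
        for path in _even_paths_dfs(g, starter):
            for assignment in _complete_assignments(g, path):
                results.append(
                    _build_tiling(graph, g, path, assignment, calls, rules)
                )
    results = _finalize(results)
    if not results:
        raise TilingError("no unit decomposition covers the graph")
    return results


def _even_paths_dfs(g: nx.Graph, start: int):
    """All simple paths of even node count >= 2 starting at ``start``."""
    path = [start]
    on_path = {start}

    def extend():
        tail = path[-1]
        for nbr in sorted(g.neighbors(tail)):
            if nbr in on_path:
                continue
            path.append(nbr)
            on_path.add(nbr)
            if len(path) % 2 == 0:
                yield tuple(path)
            yield from extend()
            on_path.discard(nbr)
            path.pop()

    yield from extend()


def brute_force_tile(graph: CarbonGraph, calls: dict, rules) -> list:
    """Oracle twin of :func:`tile` by exhaustive subset enumeration.

    Enumerates every even-sized node subset containing the starter, every
    Hamiltonian ordering of that subset as a backbone, and every side
    assignment.  Only intended for tests; refuses graphs above
    ``BRUTE_FORCE_MAX_NODES`` nodes.
    """
    _validate_inputs(graph, calls)
    if len(graph.nodes) > BRUTE_FORCE_MAX_NODES:
        raise TilingError(
            f"brute force refused: {len(graph.nodes)} nodes exceeds "
            f"{BRUTE_FORCE_MAX_NODES}"
        )
    g = graph.to_networkx()
    if len(graph.nodes) < 2:
        raise TilingError("graph too small to contain a starter unit")
    results = []
    for starter in _candidate_starters(graph, g):
        others = sorted(set(graph.nodes) - {starter})
        for size in range(1, len(others) + 1, 2):  # subset sizes 2, 4, ...
            for combo in itertools.combinations(others, size):
                subset = {starter, *combo}
                for path in _hamiltonian_paths(g, subset, starter):
                    for assignment in _complete_assignments(g, path):
                        results.append(
                            _build_tiling(
                                graph, g, path, assignment, calls, rules
                            )
                        )
    results = _finalize(results)
    if not results:
        raise TilingError("no unit decomposition covers the graph")
    return results


def _hamiltonian_paths(g: nx.Graph, subset: set, start: int):
    """All orderings of ``subset`` forming a path in ``g`` from ``start``."""
    path = [start]
    used = {start}

    def extend():
        if len(path) == len(subset):
            yield tuple(path)
            return
        for nbr in sorted(g.neighbors(path[-1])):
            if nbr in subset and nbr not in used:
                path.append(nbr)
                used.add(nbr)
                yield from extend()
                used.discard(nbr)
                path.pop()

    yield from extend()


def extender_sequence(tiling: UnitTiling) -> list:
    """Unit type labels, starter first."""
    return [u.label for u in tiling.units]


def tiling_to_dict(tiling: UnitTiling) -> dict:
    return {
        "units": [
            {
                "index": u.index,
                "type": u.label,
                "C2": u.c2,
                "C1": u.c1,
                "side": list(u.side),
            }
            for u in tiling.units
        ],
        "concordance": round(tiling.concordance, 6),
        "bond_classes": {
            f"{a}-{b}": cls for (a, b), cls in sorted(tiling.bond_classes.items())
        },
        "anomalous_bonds": [list(b) for b in tiling.anomalous_bonds],
    }
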