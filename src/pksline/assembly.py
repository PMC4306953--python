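"""Deterministic assembly of the predicted linear polyketide product.

The backbone is laid out starter-methyl first:

    [starter C2, starter C1, unit1 C2, unit1 C1, ..., unitN C1]

so chain index 1 is the starter methyl terminus and the final backbone
carbon is the carboxyl released on hydrolysis of the thioester.  The
reductive domains of extension module *i* (active ones only) set the final
oxidation state of the beta carbon present at module *i*'s condensation,
which is C1 of unit *i - 1*:

    no reductive domains      -> ketone
    KR                        -> hydroxyl (beta descriptor from the KR type)
    KR + DH                   -> enoyl pair with C2 of unit i (geometry from
                                 the KR family)
    KR + DH + ER              -> fully reduced methylene (alpha-substituent
                                 descriptor from the ER class)

Cyclisations, lactonisations and all other tailoring chemistry are outside
this model; hydrogen counts assume standard valences and no rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .cluster import ClusterSpec
from .errors import AssemblyError
from .rules import (
    ExtenderType,
    RuleConfig,
    classify_er,
    classify_kr,
    predict_substrate,
)

OXIDATIONS = (
    "methyl", "methylene", "methine", "hydroxyl", "ketone", "enoyl", "carboxyl"
)


@dataclass(frozen=True)
class ChainCarbon:
    chain_index: int
    unit_index: int
    unit_role: str  # "C1", "C2" or "side"
    oxidation: str
    stereo: str = "unspecified"  # raw R/S label, not a validated CIP call
    geometry: str = "none"  # E/Z for enoyl pairs

    def __post_init__(self) -> None:
        if self.oxidation not in OXIDATIONS:
            raise AssemblyError(f"unknown oxidation state {self.oxidation!r}")


@dataclass(frozen=True)
class LinearProduct:
    """Predicted linear chain: backbone carbons plus side chains."""

    carbons: tuple  # backbone ChainCarbons in chain order
    side_chains: dict  # backbone chain_index -> tuple of side ChainCarbons
    unit_types: tuple  # ExtenderType per unit, starter first
    smiles: str | None = None

    @property
    def total_carbons(self) -> int:
        return len(self.carbons) + sum(len(v) for v in self.side_chains.values())

    @property
    def backbone_length(self) -> int:
        return len(self.carbons)


def assemble(cluster: ClusterSpec, config: RuleConfig) -> LinearProduct:
    """Assemble the linear product predicted from a cluster's domains."""
    units = []
    for module in cluster.modules:
        at = module.domain("AT")
        if at is None:
            raise AssemblyError(f"module {module.index} has no AT domain")
        ext = predict_substrate(at.signature, config)
        if module.loading:
            # Loading ATs with malonyl signatures load the decarboxylated
            # substrate, i.e. an acetyl starter.
            if ext.name in ("malonyl", "acetyl_starter"):
                ext = ExtenderType("acetyl_starter")
            else:
                raise AssemblyError(
                    f"unsupported loading-module substrate {ext.label}"
                )
        units.append(ext)

    n_units = len(units)
    backbone: list[dict] = []
    side_chains: dict[int, tuple] = {}
    for ui, ext in enumerate(units):
        c2_index = 2 * ui + 1
        backbone.append(
            {
                "chain_index": c2_index,
                "unit_index": ui,
                "unit_role": "C2",
                "oxidation": "methine" if ext.side_chain_carbons else "methylene",
                "stereo": "unspecified",
                "geometry": "none",
                "n_side": ext.side_chain_carbons,
            }
        )
        backbone.append(
            {
                "chain_index": c2_index + 1,
                "unit_index": ui,
                "unit_role": "C1",
                "oxidation": "ketone",
                "stereo": "unspecified",
                "geometry": "none",
                "n_side": 0,
            }
        )
    backbone[0]["oxidation"] = "methyl"  # starter methyl terminus
    backbone[-1]["oxidation"] = "carboxyl"  # chain release by hydrolysis

    # Beta processing: extension module i acts on backbone position 2i
    # (list offset 2i - 1); its own C2 sits at position 2i + 1 (offset 2i).
    for i, module in enumerate(cluster.extension_modules, start=1):
        beta = backbone[2 * i - 1]
        alpha = backbone[2 * i]
        kr = module.domain("KR", active_only=True)
        dh = module.domain("DH", active_only=True)
        er = module.domain("ER", active_only=True)
        if beta["oxidation"] == "carboxyl":
            continue  # the released carboxyl is never beta-processed
        if kr is None:
            # DH/ER without a KR have no beta-hydroxyl/enoyl substrate and
            # act vacuously; the beta carbon stays a ketone.
            continue
        if kr.kr_fingerprint:
            kr_class = classify_kr(kr.kr_fingerprint, config)
            beta_desc = kr_class.beta_hydroxyl
            alpha_desc = kr_class.alpha_substituent
            geometry = kr_class.geometry
        else:  # untyped KR: stereo unknown, geometry defaults to trans
            beta_desc = alpha_desc = "unspecified"
            geometry = "E"
        if dh is None:
            # An ER without an active DH never sees an enoyl and is vacuous.
            beta["oxidation"] = "hydroxyl"
            beta["stereo"] = beta_desc
            if alpha["n_side"]:
                alpha["stereo"] = alpha_desc
        elif er is None:
            beta["oxidation"] = "enoyl"
            alpha["oxidation"] = "enoyl"
            beta["geometry"] = geometry
            alpha["geometry"] = geometry
        else:
            beta["oxidation"] = "methylene"
            if alpha["n_side"]:
                alpha["stereo"] = classify_er(er.signature, config)

    carbons = []
    next_side = 2 * n_units + 1
    for entry in backbone:
        n_side = entry.pop("n_side")
        carbons.append(ChainCarbon(**entry))
        if n_side:
            sides = []
            for k in range(n_side):
                sides.append(
                    ChainCarbon(
                        chain_index=next_side,
                        unit_index=entry["unit_index"],
                        unit_role="side",
                        oxidation="methyl" if k == n_side - 1 else "methylene",
                    )
                )
                next_side += 1
            side_chains[entry["chain_index"]] = tuple(sides)

    product = LinearProduct(
        carbons=tuple(carbons),
        side_chains=side_chains,
        unit_types=tuple(units),
    )
    return replace(product, smiles=to_smiles(product))


def count_double_bonds(product: LinearProduct) -> int:
    """Number of enoyl pairs in the backbone."""
    return sum(1 for c in product.carbons if c.oxidation == "enoyl") // 2


def molecular_formula(product: LinearProduct) -> dict:
    """Element counts from valence completion of the chain model.

    Kept independent of the SMILES route so the two can cross-check:
    hydrogens are derived per carbon from 4 minus its explicit bond orders,
    oxygens from the oxidation states (carboxyl 2, hydroxyl/ketone 1 each).
    """
    n_backbone = len(product.carbons)
    h = 0
    o = 0
    for pos, c in enumerate(product.carbons, start=1):
        bonds = (pos > 1) + (pos < n_backbone)  # backbone neighbours
        # side chains are linear and attach through their first carbon
        bonds += 1 if product.side_chains.get(pos) else 0
        if c.oxidation == "carboxyl":
            bonds += 3  # =O plus O-H
            o += 2
            h += 1  # acid proton
        elif c.oxidation == "ketone":
            bonds += 2
            o += 1
        elif c.oxidation == "hydroxyl":
            bonds += 1
            o += 1
            h += 1  # hydroxyl proton
        elif c.oxidation == "enoyl":
            bonds += 1  # pi bond to the partner
        if bonds > 4:
            raise AssemblyError(
                f"carbon {c.chain_index}: valence exceeded ({bonds} bonds)"
            )
        h += 4 - bonds
    for sides in product.side_chains.values():
        for k, _ in enumerate(sides):
            nbrs = 2 if k < len(sides) - 1 else 1
            h += 4 - nbrs
    return {"C": product.total_carbons, "H": h, "O": o}


def hill_formula(counts: dict) -> str:
    """Render an element-count mapping in Hill order (C, H, then others)."""
    parts = []
    for el in ("C", "H"):
        n = counts.get(el, 0)
        if n:
            parts.append(f"{el}{n if n > 1 else ''}")
    for el in sorted(k for k in counts if k not in ("C", "H")):
        n = counts[el]
        if n:
            parts.append(f"{el}{n if n > 1 else ''}")
    return "".join(parts)


_STEREO_ATOM = {"R": "[C@@H]", "S": "[C@H]"}


def to_smiles(product: LinearProduct, include_stereo: bool = False) -> str:
    """Serialize the product as SMILES.

    Without ``include_stereo`` no stereocentres are emitted.  With it,
    enoyl pairs get E/Z directional bonds and carbons with R/S descriptors
    get tetrahedral marks under a fixed local convention (R -> @@, S -> @);
    these are positional stereo labels, not validated CIP assignments.
    'unspecified' centres are silently skipped.
    """
    n = len(product.carbons)
    tokens = []
    for pos, c in enumerate(product.carbons, start=1):
        if pos > 1:
            prev = product.carbons[pos - 2]
            if c.oxidation == "enoyl" and prev.oxidation == "enoyl" \
                    and prev.unit_role == "C1" and c.unit_role == "C2" \
                    and c.unit_index == prev.unit_index + 1:
                tokens.append("=")
            elif include_stereo and _needs_direction(product, pos):
                tokens.append(_direction(product, pos))
            else:
                tokens.append("")
        atom = "C"
        if include_stereo and c.stereo in _STEREO_ATOM \
                and c.oxidation in ("methine", "hydroxyl"):
            atom = _STEREO_ATOM[c.stereo]
        branch = ""
        sides = product.side_chains.get(pos, ())
        if sides:
            branch = "(" + "C" * len(sides) + ")"
        if c.oxidation == "carboxyl":
            tokens.append(atom + branch + "(=O)O")
        elif c.oxidation == "ketone":
            tokens.append(atom + branch + "(=O)")
        elif c.oxidation == "hydroxyl":
            tokens.append(atom + "(O)" + branch)
        else:
            tokens.append(atom + branch)
    return "".join(tokens)


def _enoyl_pair_at(product: LinearProduct, pos: int) -> bool:
    """True when the backbone bond pos-1 -> pos is the C=C of an enoyl pair."""
    if pos < 2 or pos > len(product.carbons):
        return False
    c, prev = product.carbons[pos - 1], product.carbons[pos - 2]
    return (
        c.oxidation == "enoyl" and prev.oxidation == "enoyl"
        and prev.unit_role == "C1" and c.unit_role == "C2"
        and c.unit_index == prev.unit_index + 1
    )


def _needs_direction(product: LinearProduct, pos: int) -> bool:
    """Single bond adjacent to a C=C whose geometry is set."""
    return _enoyl_pair_at(product, pos + 1) or _enoyl_pair_at(product, pos - 1)


def _direction(product: LinearProduct, pos: int) -> str:
    # Bond between backbone positions pos-1 and pos.  For the bond entering
    # a double bond we always write "/"; for the bond leaving it, "/" keeps
    # E (trans) and "\" gives Z.
    if _enoyl_pair_at(product, pos + 1):  # entering: next bond is the C=C
        return "/"
    beta = product.carbons[pos - 2]  # leaving: previous bond was the C=C
    return "/" if beta.geometry == "E" else "\\"


def product_to_dict(product: LinearProduct) -> dict:
    """Structured-text form of a product (per-carbon records)."""
    def carbon(c: ChainCarbon) -> dict:
        return {
            "chain_index": c.chain_index,
            "unit_index": c.unit_index,
            "unit_role": c.unit_role,
            "oxidation": c.oxidation,
            "stereo": c.stereo,
            "geometry": c.geometry,
        }

    return {
        "units": [t.label for t in product.unit_types],
        "formula": hill_formula(molecular_formula(product)),
        "smiles": product.smiles or to_smiles(product),
        "backbone": [carbon(c) for c in product.carbons],
        "side_chains": {
            at: [carbon(c) for c in sides]
            for at, sides in sorted(product.side_chains.items())
        },
    }


def write_product(product: LinearProduct, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(product_to_dict(product), fh, sort_keys=False)
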