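"""Config-driven rule engine for PKS domain annotations.

Maps acyltransferase (AT) signature tokens to extender substrates,
ketoreductase (KR) fingerprint tokens to stereochemical descriptors and
double-bond geometry, and enoylreductase (ER) class tokens to the
configuration of the alpha substituent.  All rule content is data: the
package ships a documented default :class:`RuleConfig`, and every table can
be replaced from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ClassificationError, ValidationError

EXTENDER_NAMES = ("acetyl_starter", "malonyl", "methylmalonyl", "alkylmalonyl")
DESCRIPTORS = ("R", "S", "unspecified")
GEOMETRIES = ("E", "Z")


@dataclass(frozen=True)
class ExtenderType:
    """A starter/extender building block.

    ``carbon_count`` is always ``2 + side_chain_carbons``: two backbone
    carbons (C1, the carboxyl-derived carbon, and C2, the alpha carbon)
    plus any alkyl side chain attached at C2.
    """

    name: str
    side_chain_carbons: int = 0

    def __post_init__(self) -> None:
        if self.name not in EXTENDER_NAMES:
            raise ValidationError(f"unknown extender name {self.name!r}")
        expected = {"acetyl_starter": 0, "malonyl": 0, "methylmalonyl": 1}
        if self.name in expected and self.side_chain_carbons != expected[self.name]:
            raise ValidationError(
                f"{self.name} must have {expected[self.name]} side-chain "
                f"carbons, got {self.side_chain_carbons}"
            )
        if self.name == "alkylmalonyl" and self.side_chain_carbons < 2:
            raise ValidationError(
                "alkylmalonyl requires side_chain_carbons >= 2, got "
                f"{self.side_chain_carbons}"
            )

    @property
    def carbon_count(self) -> int:
        return 2 + self.side_chain_carbons

    @property
    def label(self) -> str:
        """Canonical name; alkyl units carry their size (C5 != C3)."""
        if self.name == "alkylmalonyl":
            return f"alkylmalonyl(C{self.carbon_count})"
        return self.name


@dataclass(frozen=True)
class KrClassification:
    """Outcome of a KR fingerprint lookup."""

    type_token: str
    beta_hydroxyl: str  # configuration of the beta-hydroxyl it installs
    alpha_substituent: str  # configuration of the alpha substituent
    geometry: str  # double-bond geometry if a downstream DH acts


@dataclass(frozen=True)
class RuleConfig:
    """All lookup tables used to interpret domain annotations."""

    at_signature_table: dict  # signature token -> ExtenderType
    kr_fingerprint_table: dict  # token -> {"beta": .., "alpha": ..}
    er_table: dict  # class token -> alpha-methyl descriptor
    kr_geometry_table: dict  # KR family letter ("A"/"B") -> "E"/"Z"
    enrichment_threshold: float = 3.0
    allow_unknown_at_fallback: bool = False

    def __post_init__(self) -> None:
        for name in ("at_signature_table", "kr_fingerprint_table", "er_table",
                     "kr_geometry_table"):
            if not getattr(self, name):
                raise ValidationError(f"{name} must be non-empty")
        for token, entry in self.kr_fingerprint_table.items():
            for key in ("beta", "alpha"):
                if entry.get(key) not in DESCRIPTORS:
                    raise ValidationError(
                        f"KR fingerprint {token!r}: {key} descriptor must be "
                        f"one of {DESCRIPTORS}"
                    )
        for token, desc in self.er_table.items():
            if desc not in DESCRIPTORS:
                raise ValidationError(
                    f"ER class {token!r}: descriptor must be one of {DESCRIPTORS}"
                )
        for fam, geom in self.kr_geometry_table.items():
            if geom not in GEOMETRIES:
                raise ValidationError(
                    f"KR family {fam!r}: geometry must be one of {GEOMETRIES}"
                )
        if not self.enrichment_threshold > 1:
            raise ValidationError("enrichment_threshold must be > 1")


def default_rules() -> RuleConfig:
    """The default rule tables shipped with the package.

    Signature tokens are short canonical stand-ins for the active-site
    motifs used in the literature (HAFH-like for malonyl-CoA, YASH-like for
    methylmalonyl-CoA, HASH-like for longer alkylmalonyl-CoA); fixtures
    carry these pre-extracted tokens rather than full domain sequences.
    The lone alkylmalonyl token defaults to propylmalonyl-CoA (C5).
    """
    return RuleConfig(
        at_signature_table={
            "HAFH": ExtenderType("malonyl"),
            "YASH": ExtenderType("methylmalonyl", side_chain_carbons=1),
            "HASH": ExtenderType("alkylmalonyl", side_chain_carbons=3),
            "ACET": ExtenderType("acetyl_starter"),
        },
        kr_fingerprint_table={
            "A1": {"beta": "R", "alpha": "S"},
            "A2": {"beta": "R", "alpha": "R"},
            "B1": {"beta": "S", "alpha": "R"},
            "B2": {"beta": "S", "alpha": "S"},
        },
        er_table={"Y": "S", "V": "R", "unknown": "unspecified"},
        kr_geometry_table={"A": "Z", "B": "E"},
        enrichment_threshold=3.0,
    )


def load_rules(path) -> RuleConfig:
    """Read a :class:`RuleConfig` from a YAML file.

    Any table omitted from the file falls back to the default table.
    AT entries are written as ``token: {name: ..., side_chain_carbons: ...}``
    or the shorthand ``token: name``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_rules()
    at_table = dict(base.at_signature_table)
    if "at_signature_table" in raw:
        at_table = {}
        for token, entry in raw["at_signature_table"].items():
            if isinstance(entry, str):
                at_table[token] = ExtenderType(
                    entry, 1 if entry == "methylmalonyl" else 0
                )
            else:
                at_table[token] = ExtenderType(
                    entry["name"], entry.get("side_chain_carbons", 0)
                )
    return RuleConfig(
        at_signature_table=at_table,
        kr_fingerprint_table=raw.get(
            "kr_fingerprint_table", base.kr_fingerprint_table
        ),
        er_table=raw.get("er_table", base.er_table),
        kr_geometry_table=raw.get("kr_geometry_table", base.kr_geometry_table),
        enrichment_threshold=float(
            raw.get("enrichment_threshold", base.enrichment_threshold)
        ),
        allow_unknown_at_fallback=bool(
            raw.get("allow_unknown_at_fallback", base.allow_unknown_at_fallback)
        ),
    )


def predict_substrate(signature: str, config: RuleConfig) -> ExtenderType:
    """Resolve an AT signature token to its extender substrate.

    Unknown signatures raise unless ``config.allow_unknown_at_fallback`` is
    set, in which case the substrate is reported as the smallest
    alkylmalonyl (side-chain size unresolved beyond the minimum of 2).
    """
    if not signature:
        raise ClassificationError("AT signature must be non-empty")
    try:
        return config.at_signature_table[signature]
    except KeyError:
        if config.allow_unknown_at_fallback:
            return ExtenderType("alkylmalonyl", side_chain_carbons=2)
        raise ClassificationError(
            f"unknown AT signature {signature!r}"
        ) from None


def classify_kr(fingerprint: str, config: RuleConfig) -> KrClassification:
    """Resolve a KR fingerprint token to stereo descriptors and geometry."""
    if not fingerprint:
        raise ClassificationError("KR fingerprint must be non-empty")
    try:
        entry = config.kr_fingerprint_table[fingerprint]
    except KeyError:
        raise ClassificationError(
            f"unknown KR fingerprint {fingerprint!r}"
        ) from None
    family = fingerprint[0]
    try:
        geometry = config.kr_geometry_table[family]
    except KeyError:
        raise ClassificationError(
            f"no geometry rule for KR family {family!r}"
        ) from None
    return KrClassification(
        type_token=fingerprint,
        beta_hydroxyl=entry["beta"],
        alpha_substituent=entry["alpha"],
        geometry=geometry,
    )


def classify_er(er_class: str, config: RuleConfig) -> str:
    """Resolve an ER class token to the alpha-methyl descriptor."""
    try:
        return config.er_table[er_class]
    except KeyError:
        raise ClassificationError(f"unknown ER class {er_class!r}") from None
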