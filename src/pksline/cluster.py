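"""Declarative descriptions of modular type I PKS clusters.

A cluster is an ordered list of modules; a module is an ordered list of
typed domains.  Files are YAML with one mapping per module (see the README
for the schema).  Domain *annotation* (finding domains in protein sequence)
is out of scope: fixtures carry pre-extracted signature tokens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import yaml

from .errors import ValidationError

DOMAIN_KINDS = ("KS", "AT", "KR", "DH", "ER", "ACP", "TE")
REDUCTIVE_KINDS = ("DH", "ER", "KR")


@dataclass(frozen=True)
class DomainSpec:
    kind: str
    signature: str = ""
    active: bool = True
    kr_fingerprint: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValidationError(f"unknown domain kind {self.kind!r}")
        if self.kr_fingerprint is not None and self.kind != "KR":
            raise ValidationError(
                f"kr_fingerprint only allowed on KR domains, not {self.kind}"
            )
        if self.kind == "AT" and not self.signature:
            raise ValidationError("AT domain requires a non-empty signature")


@dataclass(frozen=True)
class ModuleSpec:
    index: int
    loading: bool
    domains: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        if self.index < 0:
            raise ValidationError(f"module index must be >= 0, got {self.index}")
        if self.loading and self.index != 0:
            raise ValidationError(
                f"module {self.index}: loading=true only allowed at index 0"
            )
        kinds = Counter(d.kind for d in self.domains)
        where = f"module {self.index}"
        if not self.loading:
            if kinds["KS"] != 1:
                raise ValidationError(f"{where}: needs exactly one KS domain")
            if kinds["AT"] != 1:
                raise ValidationError(f"{where}: needs exactly one AT domain")
        for kind in REDUCTIVE_KINDS:
            if kinds[kind] > 1:
                raise ValidationError(f"{where}: at most one {kind} domain")

    def domain(self, kind: str, active_only: bool = False) -> DomainSpec | None:
        """First domain of the given kind, optionally skipping inactive ones."""
        for d in self.domains:
            if d.kind == kind and (d.active or not active_only):
                return d
        return None

    def reductive_profile(self) -> str:
        """Active-domain profile: 'none', 'KR', 'DH+KR', 'DH+ER+KR', ..."""
        parts = [
            k for k in REDUCTIVE_KINDS
            if self.domain(k, active_only=True) is not None
        ]
        return "+".join(parts) if parts else "none"


@dataclass(frozen=True)
class ClusterSpec:
    id: str
    modules: tuple = ()
    compound_hint: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        if not self.modules:
            raise ValidationError(f"cluster {self.id!r}: empty module list")
        indices = [m.index for m in self.modules]
        if len(set(indices)) != len(indices):
            dup = [i for i, n in Counter(indices).items() if n > 1]
            raise ValidationError(
                f"cluster {self.id!r}: duplicate module index {dup[0]}"
            )
        if indices != list(range(len(indices))):
            raise ValidationError(
                f"cluster {self.id!r}: module indices must increase from 0, "
                f"got {indices}"
            )
        n_loading = sum(m.loading for m in self.modules)
        if n_loading != 1:
            raise ValidationError(
                f"cluster {self.id!r}: exactly one loading module required, "
                f"found {n_loading}"
            )

    @property
    def loading_module(self) -> ModuleSpec:
        return self.modules[0]

    @property
    def extension_modules(self) -> tuple:
        return tuple(m for m in self.modules if not m.loading)


def _domain_to_dict(d: DomainSpec) -> dict:
    out = {"kind": d.kind}
    if d.signature:
        out["signature"] = d.signature
    if not d.active:
        out["active"] = False
    if d.kr_fingerprint is not None:
        out["kr_fingerprint"] = d.kr_fingerprint
    return out


def _domain_from_dict(raw: dict, where: str) -> DomainSpec:
    if not isinstance(raw, dict) or "kind" not in raw:
        raise ValidationError(f"{where}: each domain needs a 'kind' field")
    unknown = set(raw) - {"kind", "signature", "active", "kr_fingerprint"}
    if unknown:
        raise ValidationError(f"{where}: unknown domain fields {sorted(unknown)}")
    return DomainSpec(
        kind=raw["kind"],
        signature=raw.get("signature", ""),
        active=bool(raw.get("active", True)),
        kr_fingerprint=raw.get("kr_fingerprint"),
    )


def cluster_to_dict(cluster: ClusterSpec) -> dict:
    out = {"id": cluster.id, "modules": []}
    if cluster.compound_hint is not None:
        out["compound_hint"] = cluster.compound_hint
    for m in cluster.modules:
        out["modules"].append(
            {
                "index": m.index,
                "loading": m.loading,
                "domains": [_domain_to_dict(d) for d in m.domains],
            }
        )
    return out


def cluster_from_dict(raw: dict) -> ClusterSpec:
    if not isinstance(raw, dict) or "id" not in raw:
        raise ValidationError("cluster file needs a top-level 'id' field")
    modules = []
    for mraw in raw.get("modules") or []:
        where = f"module {mraw.get('index', '?')}"
        domains = [
            _domain_from_dict(d, where) for d in (mraw.get("domains") or [])
        ]
        modules.append(
            ModuleSpec(
                index=int(mraw["index"]),
                loading=bool(mraw.get("loading", False)),
                domains=domains,
            )
        )
    return ClusterSpec(
        id=str(raw["id"]),
        modules=modules,
        compound_hint=raw.get("compound_hint"),
    )


def read_cluster(path) -> ClusterSpec:
    """Read and validate a cluster description from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return cluster_from_dict(raw)


def write_cluster(cluster: ClusterSpec, path) -> None:
    """Write a cluster description; round-trips through :func:`read_cluster`."""
    with open(path, "w") as fh:
        yaml.safe_dump(cluster_to_dict(cluster), fh, sort_keys=False)


def count_reductive_profiles(cluster: ClusterSpec) -> dict:
    """Count extension modules per active reductive-domain profile.

    Inactive domains are treated as absent, so a module whose DH is
    annotated ``active: false`` counts under 'KR', not 'DH+KR'.  Counts sum
    to the number of extension modules.
    """
    counts = Counter(m.reductive_profile() for m in cluster.extension_modules)
    return dict(counts)
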