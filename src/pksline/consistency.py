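"""Reconciliation of cluster-predicted and labeling-inferred unit sequences.

The two inference routes — domain annotation of the PKS cluster and
precursor-unit tiling of the isotope-labeled product — must agree on the
unit sequence for a cluster/compound assignment to stand.  Anomalous bonds
in the tiling do not break the assignment; they mark carbon-carbon bonds
formed after chain assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .assembly import LinearProduct
from .tiling import UnitTiling, extender_sequence

VERDICTS = ("consistent", "consistent_with_post_pks_bonds", "inconsistent")


@dataclass(frozen=True)
class ConsistencyReport:
    cluster_id: str
    compound: str
    predicted_sequence: tuple
    inferred_sequence: tuple
    per_position_match: tuple
    module_count_match: bool
    anomalous_bonds: tuple
    verdict: str


def compare(
    product: LinearProduct,
    tiling: UnitTiling,
    cluster_id: str = "",
    compound: str = "",
) -> ConsistencyReport:
    """Positionally compare predicted and inferred unit-type sequences.

    Alkylmalonyl side sizes are matched strictly (a C5 unit is not a C3
    unit).  Extra positions on either side count as mismatches.
    """
    predicted = tuple(t.label for t in product.unit_types)
    inferred = tuple(extender_sequence(tiling))
    length = max(len(predicted), len(inferred))
    matches = tuple(
        i < len(predicted) and i < len(inferred)
        and predicted[i] == inferred[i]
        for i in range(length)
    )
    anomalous = tiling.anomalous_bonds
    if all(matches) and len(predicted) == len(inferred):
        verdict = "consistent" if not anomalous else (
            "consistent_with_post_pks_bonds"
        )
    else:
        verdict = "inconsistent"
    return ConsistencyReport(
        cluster_id=cluster_id,
        compound=compound,
        predicted_sequence=predicted,
        inferred_sequence=inferred,
        per_position_match=matches,
        module_count_match=len(predicted) == len(inferred),
        anomalous_bonds=anomalous,
        verdict=verdict,
    )


def screen_clusters(clusters, target_unit_count: int) -> list:
    """Ids of clusters whose total module count equals the target."""
    return [c.id for c in clusters if len(c.modules) == target_unit_count]


def report_to_dict(report: ConsistencyReport) -> dict:
    return {
        "cluster_id": report.cluster_id,
        "compound": report.compound,
        "predicted_sequence": list(report.predicted_sequence),
        "inferred_sequence": list(report.inferred_sequence),
        "per_position_match": [bool(m) for m in report.per_position_match],
        "module_count_match": bool(report.module_count_match),
        "anomalous_bonds": [list(b) for b in report.anomalous_bonds],
        "verdict": report.verdict,
    }


def write_report(report: ConsistencyReport, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(report_to_dict(report), fh, sort_keys=False)


def render_report(report: ConsistencyReport) -> str:
    """Human-readable summary."""
    lines = [
        f"cluster:  {report.cluster_id or '-'}",
        f"compound: {report.compound or '-'}",
        f"verdict:  {report.verdict}",
        "",
        f"{'pos':>3}  {'predicted':<20} {'inferred':<20} match",
    ]
    length = len(report.per_position_match)
    for i in range(length):
        pred = (
            report.predicted_sequence[i]
            if i < len(report.predicted_sequence) else "-"
        )
        inf = (
            report.inferred_sequence[i]
            if i < len(report.inferred_sequence) else "-"
        )
        ok = "yes" if report.per_position_match[i] else "NO"
        lines.append(f"{i:>3}  {pred:<20} {inf:<20} {ok}")
    if report.anomalous_bonds:
        lines.append("")
        lines.append(
            "post-assembly bonds: "
            + ", ".join(f"{a}-{b}" for a, b in report.anomalous_bonds)
        )
    return "\n".join(lines) + "\n"
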