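"""Relative 13C enrichment ratios from NMR intensity tables.

Each table holds one feeding experiment for one compound.  Two input modes
are supported:

* intensity mode — every record carries labeled and unlabeled intensities;
  the enrichment ratio of carbon c is (L_c / U_c) / (L_ref / U_ref), which
  is scale invariant and exactly 1 at the reference carbon;
* pass-through mode — records carry precomputed ratios (the published form);
  they are renormalized so the reference carbon reads exactly 1.

A carbon is called enriched when its ratio reaches the configured
threshold (default 3.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DataError

EXPERIMENTS = (
    "acetate_1_13C",
    "acetate_2_13C",
    "propionate_1_13C",
    "succinate_1_4_13C2",
)

CSV_COLUMNS = (
    "position", "shift_ppm", "experiment",
    "labeled_intensity", "unlabeled_intensity", "ratio",
)


@dataclass(frozen=True)
class EnrichmentRecord:
    position: int
    shift_ppm: float
    labeled_intensity: float | None = None
    unlabeled_intensity: float | None = None
    ratio: float | None = None

    def __post_init__(self) -> None:
        for name in ("labeled_intensity", "unlabeled_intensity"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DataError(f"position {self.position}: {name} must be >= 0")
        if self.ratio is not None and self.ratio <= 0:
            raise DataError(f"position {self.position}: ratio must be positive")


@dataclass(frozen=True)
class EnrichmentTable:
    compound: str
    experiment: str
    records: tuple
    reference_position: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.experiment not in EXPERIMENTS:
            raise DataError(f"unknown experiment {self.experiment!r}")
        positions = [r.position for r in self.records]
        if len(set(positions)) != len(positions):
            raise DataError(f"{self.compound}: duplicate positions in table")
        if self.reference_position not in positions:
            raise DataError(
                f"{self.compound}: reference position "
                f"{self.reference_position} missing from records"
            )

    def record(self, position: int) -> EnrichmentRecord:
        for r in self.records:
            if r.position == position:
                return r
        raise DataError(f"position {position} not in table")


@dataclass(frozen=True)
class LabelCall:
    position: int
    ratio: float
    enriched: bool


def compute_enrichment(
    table: EnrichmentTable,
    threshold: float = 3.0,
    mode: str = "auto",
) -> list:
    """Fill per-carbon enrichment ratios and call enriched positions.

    ``mode`` is 'auto' (detect from the table), 'two_spectrum' (from
    intensities, double normalization) or 'single_spectrum' (labeled
    intensities against the stored natural-abundance baseline).
    """
    if not threshold > 1:
        raise DataError("threshold must be > 1")
    has_int = all(
        r.labeled_intensity is not None and r.unlabeled_intensity is not None
        for r in table.records
    )
    has_ratio = all(r.ratio is not None for r in table.records)
    if mode == "auto":
        mode = "two_spectrum" if has_int else "pass_through"
    if mode == "pass_through":
        if not has_ratio:
            raise DataError("pass-through mode requires a ratio on every record")
        ref = table.record(table.reference_position).ratio
        ratios = {r.position: r.ratio / ref for r in table.records}
    elif mode in ("two_spectrum", "single_spectrum"):
        if not has_int:
            raise DataError(f"{mode} mode requires intensities on every record")
        ref = table.record(table.reference_position)
        for r in table.records:
            if r.unlabeled_intensity <= 0:
                raise DataError(
                    f"position {r.position}: unlabeled intensity must be > 0"
                )
        if ref.labeled_intensity <= 0:
            raise DataError("reference labeled intensity must be > 0")
        if mode == "two_spectrum":
            norm = ref.labeled_intensity / ref.unlabeled_intensity
            ratios = {
                r.position:
                    (r.labeled_intensity / r.unlabeled_intensity) / norm
                for r in table.records
            }
        else:
            # Single labeled spectrum, divided by the stored
            # natural-abundance baseline profile.
            baseline_ref = ref.unlabeled_intensity
            ratios = {
                r.position:
                    (r.labeled_intensity / ref.labeled_intensity)
                    / (r.unlabeled_intensity / baseline_ref)
                for r in table.records
            }
    else:
        raise DataError(f"unknown mode {mode!r}")
    ratios[table.reference_position] = 1.0  # exact by construction
    return [
        LabelCall(r.position, ratios[r.position], ratios[r.position] >= threshold)
        for r in table.records
    ]


def classify_enriched(calls, threshold: float) -> set:
    """Positions whose ratio reaches the threshold."""
    if not threshold > 1:
        raise DataError("threshold must be > 1")
    return {c.position for c in calls if c.ratio >= threshold}


def calls_from_tables(tables: dict, threshold: float, mode: str = "auto") -> dict:
    """Per-experiment enriched-position sets from a dict of tables."""
    return {
        experiment: classify_enriched(
            compute_enrichment(table, threshold, mode), threshold
        )
        for experiment, table in tables.items()
    }


def _opt(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_enrichment_tables(
    path, reference: int, compound: str | None = None
) -> dict:
    """Read a CSV holding one or more experiments for one compound.

    Returns a mapping experiment name -> :class:`EnrichmentTable`.  The CSV
    header is ``position,shift_ppm,experiment,labeled_intensity,
    unlabeled_intensity,ratio``.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot parse {path}: {exc}") from exc
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if compound is None:
        compound = str(path)
    tables = {}
    for experiment, group in df.groupby("experiment", sort=False):
        records = []
        for i, row in group.iterrows():
            try:
                records.append(
                    EnrichmentRecord(
                        position=int(row["position"]),
                        shift_ppm=float(row["shift_ppm"]),
                        labeled_intensity=_opt(row["labeled_intensity"]),
                        unlabeled_intensity=_opt(row["unlabeled_intensity"]),
                        ratio=_opt(row["ratio"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise DataError(f"{path}: malformed row {i + 2}: {exc}") from exc
        tables[str(experiment)] = EnrichmentTable(
            compound=compound,
            experiment=str(experiment),
            records=records,
            reference_position=reference,
        )
    return tables


def read_enrichment_csv(
    path, reference: int, experiment: str | None = None,
    compound: str | None = None,
) -> EnrichmentTable:
    """Read a single-experiment table from a CSV file."""
    tables = read_enrichment_tables(path, reference, compound)
    if experiment is None:
        if len(tables) != 1:
            raise DataError(
                f"{path} holds experiments {sorted(tables)}; pass one explicitly"
            )
        return next(iter(tables.values()))
    try:
        return tables[experiment]
    except KeyError:
        raise DataError(f"{path}: no experiment {experiment!r}") from None


def write_enrichment_csv(tables, path) -> None:
    """Write one or several tables back to the documented CSV dialect."""
    if isinstance(tables, EnrichmentTable):
        tables = [tables]
    elif isinstance(tables, dict):
        tables = list(tables.values())
    rows = []
    for table in tables:
        for r in table.records:
            rows.append(
                {
                    "position": r.position,
                    "shift_ppm": r.shift_ppm,
                    "experiment": table.experiment,
                    "labeled_intensity": r.labeled_intensity,
                    "unlabeled_intensity": r.unlabeled_intensity,
                    "ratio": r.ratio,
                }
            )
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)
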