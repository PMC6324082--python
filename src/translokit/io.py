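"""Result serialization and run configuration.

Score tables are written with 4-decimal rendering (the display precision of
the published score listings); the optional full-precision columns preserve
the exact values.  CSV output follows RFC 4180 quoting with UTF-8 and LF
line endings; the TSV variant differs only in its delimiter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import yaml

from .scoring import (
    F1_OPTIMAL_THRESHOLD,
    HIGH_CONFIDENCE_THRESHOLD,
    TESResult,
    TranslocationClass,
)

RESULT_COLUMNS = ["protein_id", "raw_tes", "tes", "class"]


def write_results(
    results: Iterable[TESResult],
    sink: TextIO,
    format: str = "csv",
    dcs: Mapping[str, float] | None = None,
    full_precision: bool = False,
) -> None:
    """Write scored proteins with fixed column order and 4-decimal scores.

    ``dcs`` optionally maps protein_id -> Data Complexity Score, appended as
    a ``dcs`` column.  ``full_precision=True`` appends ``raw_tes_full`` and
    ``tes_full`` columns carrying full float precision.  Row order follows
    the input.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"format must be 'csv' or 'tsv', got {format!r}")
    delimiter = "," if format == "csv" else "\t"
    writer = csv.writer(sink, delimiter=delimiter, lineterminator="\n")
    header = list(RESULT_COLUMNS)
    if dcs is not None:
        header.append("dcs")
    if full_precision:
        header += ["raw_tes_full", "tes_full"]
    writer.writerow(header)
    for r in results:
        row = [
            r.protein_id,
            f"{r.raw_score:.4f}",
            f"{r.normalized_score:.4f}",
            r.label.value,
        ]
        if dcs is not None:
            value = dcs.get(r.protein_id)
            row.append("" if value is None else f"{value:.4f}")
        if full_precision:
            row += [repr(r.raw_score), repr(r.normalized_score)]
        writer.writerow(row)


def read_results(stream: TextIO, format: str = "csv") -> list[TESResult]:
    """Read a result table written by :func:`write_results` (4-decimal values)."""
    delimiter = "," if format == "csv" else "\t"
    reader = csv.DictReader(stream, delimiter=delimiter)
    out: list[TESResult] = []
    for row in reader:
        out.append(
            TESResult(
                protein_id=row["protein_id"],
                raw_score=float(row.get("raw_tes_full") or row["raw_tes"]),
                normalized_score=float(row.get("tes_full") or row["tes"]),
                label=TranslocationClass(row["class"]),
            )
        )
    return out


@dataclass
class RunConfig:
    """File paths and knobs for a scoring run; loadable from YAML."""

    ontology: str | None = None
    annotations: str | None = None
    edges: str | None = None
    registry: str | None = None
    features: str | None = None
    lower_threshold: float = F1_OPTIMAL_THRESHOLD
    upper_threshold: float = HIGH_CONFIDENCE_THRESHOLD
    normalization_reference: tuple[float, float] | None = None
    seed: int = 0
    output_format: str = "csv"
    model_precision: str = "high"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lower_threshold < self.upper_threshold:
            raise ValueError("thresholds must satisfy lower < upper")
        if self.output_format not in ("csv", "tsv"):
            raise ValueError("output_format must be 'csv' or 'tsv'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        if kwargs.get("normalization_reference") is not None:
            kwargs["normalization_reference"] = tuple(kwargs["normalization_reference"])
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)
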