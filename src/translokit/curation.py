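"""Curated-entry schema, training-set assembly, and the Data Complexity Score.

A curated entry records one experimentally validated translocating (or
deliberately non-translocating) human protein: its identifiers, literature
evidence, the initial and target subcellular localizations, interaction
partners and functions in both compartments, the translocation mechanism and
how it was detected, disease involvement and affected pathways.

Training-set assembly follows two rules: entries translocating exclusively
under pathological conditions are excluded from the positive set (the
interactome used for the network features contains no pathological
interactions), and the negative set consists of entries assigned one of five
non-translocation categories (diffuse multi-compartmental, single
compartment, nucleic-acid docked, membrane embedded, cytoskeleton attached).

The Data Complexity Score (DCS) summarizes how much curated information an
entry carries: a weighted fraction of populated fields, normalized to [0, 1],
with translocation-mechanism fields weighted above descriptive ones.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Iterable, Mapping, TextIO

MAJOR_LOCALIZATIONS = frozenset(
    {
        "cytoplasm",
        "extracellular",
        "mitochondrion",
        "nucleus",
        "membrane",
        "secretory-pathway",
    }
)

NEGATIVE_CATEGORIES = frozenset(
    {
        "diffuse_multicompartmental",
        "single_compartment",
        "nucleic_acid_docked",
        "membrane_embedded",
        "cytoskeleton_attached",
    }
)

# UniProt accession: 6 or 10 characters, e.g. P60484, Q9H3D4, A0A024R161.
UNIPROT_AC_PATTERN = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


class CurationError(ValueError):
    """Inconsistent curated data or configuration."""


@dataclass(frozen=True)
class Localization:
    major: str
    minor: str | None = None


@dataclass
class CuratedEntry:
    """One manually curated protein record."""

    uniprot_ac: str
    gene_name: str = ""
    protein_names: str = ""
    pubmed_ids: list[str] = field(default_factory=list)
    initial_localization: Localization | None = None
    target_localization: Localization | None = None
    partners_initial: list[str] = field(default_factory=list)
    partners_target: list[str] = field(default_factory=list)
    functions_initial: str = ""
    functions_target: str = ""
    mechanism: str = ""
    detection_method: str = ""
    structural_info: str = ""
    disease_group: str = ""
    disease: str = ""
    pathological_role: str = ""
    pathways: list[str] = field(default_factory=list)
    pathology_only: bool = False
    negative_category: str | None = None

    @property
    def is_translocating(self) -> bool:
        """True iff both localizations are set and actually differ."""
        if self.initial_localization is None or self.target_localization is None:
            return False
        return self.initial_localization != self.target_localization


def validate_entry(entry: CuratedEntry) -> list[str]:
    """Return schema violations (empty list = valid); never raises."""
    violations: list[str] = []
    if not UNIPROT_AC_PATTERN.match(entry.uniprot_ac):
        violations.append(
            f"uniprot_ac: {entry.uniprot_ac!r} does not match the UniProt "
            "accession pattern"
        )
    for name in ("initial_localization", "target_localization"):
        loc = getattr(entry, name)
        if loc is not None and loc.major not in MAJOR_LOCALIZATIONS:
            violations.append(
                f"{name}: major localization {loc.major!r} not in the "
                f"six-value vocabulary {sorted(MAJOR_LOCALIZATIONS)}"
            )
    if (
        entry.initial_localization is not None
        and entry.target_localization is not None
        and entry.initial_localization == entry.target_localization
        and entry.negative_category is None
    ):
        violations.append(
            "target_localization: a translocating entry must differ from its "
            "initial localization in major or minor term"
        )
    if entry.negative_category is not None:
        if entry.negative_category not in NEGATIVE_CATEGORIES:
            violations.append(
                f"negative_category: {entry.negative_category!r} not in "
                f"{sorted(NEGATIVE_CATEGORIES)}"
            )
    return violations


@dataclass(frozen=True)
class TrainingSets:
    positives: tuple[CuratedEntry, ...]
    negatives: tuple[CuratedEntry, ...]


def build_training_sets(entries: Iterable[CuratedEntry]) -> TrainingSets:
    """Assemble positive and negative training sets from curated entries.

    Positives: translocating entries not flagged pathology-only.  Negatives:
    entries carrying a negative category.  An entry that is both
    translocating and negative-flagged is contradictory and raises.
    """
    positives: list[CuratedEntry] = []
    negatives: list[CuratedEntry] = []
    for entry in entries:
        if entry.is_translocating and entry.negative_category is not None:
            raise CurationError(
                f"{entry.uniprot_ac}: entry is both translocating and assigned "
                f"negative category {entry.negative_category!r}"
            )
        if entry.negative_category is not None:
            negatives.append(entry)
        elif entry.is_translocating and not entry.pathology_only:
            positives.append(entry)
    return TrainingSets(positives=tuple(positives), negatives=tuple(negatives))


#: Default DCS weights: fields describing the translocation event itself
#: (mechanism, detection, structure) weigh 2; descriptive fields weigh 1.
#: Editable — pass your own mapping to :func:`data_complexity_score`.
DEFAULT_DCS_WEIGHTS: dict[str, float] = {
    "mechanism": 2.0,
    "detection_method": 2.0,
    "structural_info": 2.0,
    "pubmed_ids": 1.0,
    "partners_initial": 1.0,
    "partners_target": 1.0,
    "functions_initial": 1.0,
    "functions_target": 1.0,
    "disease_group": 1.0,
    "disease": 1.0,
    "pathological_role": 1.0,
    "pathways": 1.0,
}


def _is_present(value) -> bool:
    if value is None:
        return False
    if isinstance(value, (list, tuple, set)):
        return len(value) > 0
    return str(value).strip() != ""


def data_complexity_score(
    entry: CuratedEntry,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Normalized weighted presence of curated fields, in [0, 1].

    ``sum(weight_f * present_f) / sum(weight_f)`` over the weighted fields;
    a list-valued field counts as present iff non-empty.  All-zero or
    negative weights are a configuration error.
    """
    weights = dict(weights) if weights is not None else dict(DEFAULT_DCS_WEIGHTS)
    if any(w < 0 for w in weights.values()):
        raise CurationError("DCS weights must be non-negative")
    total = sum(weights.values())
    if total == 0:
        raise CurationError("DCS weights must include at least one positive weight")
    known = {f.name for f in dataclass_fields(CuratedEntry)}
    unknown = set(weights) - known
    if unknown:
        raise CurationError(f"DCS weights reference unknown field(s): {sorted(unknown)}")
    got = sum(w for f, w in weights.items() if _is_present(getattr(entry, f)))
    return got / total


# -- registry I/O -----------------------------------------------------------

_LIST_FIELDS = ("pubmed_ids", "partners_initial", "partners_target", "pathways")

REGISTRY_COLUMNS = [
    "uniprot_ac",
    "gene_name",
    "protein_names",
    "pubmed_ids",
    "initial_localization_major",
    "initial_localization_minor",
    "target_localization_major",
    "target_localization_minor",
    "partners_initial",
    "partners_target",
    "functions_initial",
    "functions_target",
    "mechanism",
    "detection_method",
    "structural_info",
    "disease_group",
    "disease",
    "pathological_role",
    "pathways",
    "pathology_only",
    "negative_category",
]


def _loc_from_row(row: Mapping[str, str], prefix: str) -> Localization | None:
    major = (row.get(f"{prefix}_major") or "").strip()
    if not major:
        return None
    minor = (row.get(f"{prefix}_minor") or "").strip() or None
    return Localization(major=major, minor=minor)


def read_registry(stream: TextIO, delimiter: str = ",") -> list[CuratedEntry]:
    """Read a curated registry CSV/TSV (semicolon-joined list cells)."""
    reader = csv.DictReader(stream, delimiter=delimiter)
    entries: list[CuratedEntry] = []
    for row in reader:
        kwargs = {
            "uniprot_ac": (row.get("uniprot_ac") or "").strip(),
            "gene_name": row.get("gene_name") or "",
            "protein_names": row.get("protein_names") or "",
            "functions_initial": row.get("functions_initial") or "",
            "functions_target": row.get("functions_target") or "",
            "mechanism": row.get("mechanism") or "",
            "detection_method": row.get("detection_method") or "",
            "structural_info": row.get("structural_info") or "",
            "disease_group": row.get("disease_group") or "",
            "disease": row.get("disease") or "",
            "pathological_role": row.get("pathological_role") or "",
            "pathology_only": (row.get("pathology_only") or "").strip().lower()
            in ("true", "1", "yes"),
            "negative_category": (row.get("negative_category") or "").strip() or None,
            "initial_localization": _loc_from_row(row, "initial_localization"),
            "target_localization": _loc_from_row(row, "target_localization"),
        }
        for name in _LIST_FIELDS:
            cell = row.get(name) or ""
            kwargs[name] = [v for v in cell.split(";") if v]
        entries.append(CuratedEntry(**kwargs))
    return entries


def write_registry(
    entries: Iterable[CuratedEntry],
    sink: TextIO,
    delimiter: str = ",",
    include_dcs: bool = True,
    weights: Mapping[str, float] | None = None,
) -> None:
    """Write a curated registry, optionally appending the DCS column."""
    columns = REGISTRY_COLUMNS + (["dcs"] if include_dcs else [])
    writer = csv.writer(sink, delimiter=delimiter, lineterminator="\n")
    writer.writerow(columns)
    for entry in entries:
        row: list[str] = []
        for col in REGISTRY_COLUMNS:
            if col in _LIST_FIELDS:
                row.append(";".join(getattr(entry, col)))
            elif col.startswith(("initial_localization", "target_localization")):
                prefix, part = col.rsplit("_", 1)
                loc = getattr(entry, prefix)
                row.append("" if loc is None else (getattr(loc, part) or ""))
            elif col == "pathology_only":
                row.append("true" if entry.pathology_only else "false")
            elif col == "negative_category":
                row.append(entry.negative_category or "")
            else:
                row.append(str(getattr(entry, col)))
        if include_dcs:
            row.append(f"{data_complexity_score(entry, weights):.4f}")
        writer.writerow(row)
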