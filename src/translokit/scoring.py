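"""Translocation Evidence Score (TES): featurization, scoring, classification.

The model is a table of binary features, each with an importance weight w_i
learned by gradient-boosted decision stumps.  For a protein with indicator
vector x (x_i = 1 if feature i is true for that protein, else 0) the raw
score is

    TES_raw = sum_i w_i * x_i                                        (n = 19)

Raw scores are min–max rescaled over the scored cohort,

    TES = (x - x_min) / (x_max - x_min),

so TES lies in [0, 1] and is proportional to the probability that the
protein translocates between subcellular compartments.  Two calibrated
cutoffs on the normalized scale partition proteins into three classes:

    TES >  0.6167        high-confidence translocating
    0.4487 <= TES <= 0.6167  low-confidence translocating
    TES <  0.4487        non-translocating

The lower cutoff maximizes the F1 score on the training cohort; the upper
cutoff is the largest normalized score attained by any negative-set protein,
so no curated non-translocating protein scores above it.  Both boundary
points fall in the low-confidence class.

Feature kinds
-------------
``go_term``          true iff the term is in the protein's ancestor-closed
                     GO annotation set.
``degree_below``     true iff the protein's interactome degree is defined
                     and strictly below the threshold.  The two cuts (14.5,
                     62.5) are cumulative: degree 10 activates both.
``bridgeness_below`` true iff bridgeness is defined and strictly below the
                     threshold.  Undefined values (protein outside the giant
                     component, or topology unknown) make the indicator
                     false.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

#: Default classification cutoffs on the normalized TES scale.
F1_OPTIMAL_THRESHOLD = 0.4487
HIGH_CONFIDENCE_THRESHOLD = 0.6167


class ScoringError(ValueError):
    """Contract violation in scoring inputs (mismatched or degenerate data)."""


class TranslocationClass(str, Enum):
    HIGH_CONFIDENCE = "high_confidence"
    LOW_CONFIDENCE = "low_confidence"
    NON_TRANSLOCATING = "non_translocating"


@dataclass(frozen=True)
class FeatureSpec:
    """One binary feature of the model with its importance weight."""

    feature_id: str
    kind: str  # "go_term" | "degree_below" | "bridgeness_below"
    weight: float
    term_id: str | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "go_term":
            if not self.term_id:
                raise ScoringError(f"{self.feature_id}: go_term feature needs term_id")
        elif self.kind in ("degree_below", "bridgeness_below"):
            if self.threshold is None:
                raise ScoringError(f"{self.feature_id}: {self.kind} needs threshold")
        else:
            raise ScoringError(f"{self.feature_id}: unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureWeightTable:
    """Ordered feature specs; the w of the scoring sum."""

    features: tuple[FeatureSpec, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ScoringError("duplicate feature_ids in weight table")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.features], dtype=float)


@dataclass(frozen=True)
class ProteinFeatures:
    """Raw per-protein inputs to featurization.

    ``go_terms`` must already be ancestor-closed (the ontology module does
    this).  ``degree``/``bridgeness`` are ``None`` when unknown, e.g. for a
    protein outside the interactome giant component.
    """

    protein_id: str
    go_terms: frozenset[str] = frozenset()
    degree: float | None = None
    bridgeness: float | None = None


@dataclass(frozen=True)
class TESResult:
    protein_id: str
    raw_score: float
    normalized_score: float
    label: TranslocationClass


def _go_weights() -> list[tuple[str, float, float]]:
    # (term_id, published 2-decimal weight, higher-precision weight where printed)
    return [
        ("GO:0009887", 2.68, 2.675),  # animal organ morphogenesis
        ("GO:0006109", 1.53, 1.53),   # regulation of carbohydrate metabolic process
        ("GO:0005737", 1.35, 1.353),  # cytoplasm
        ("GO:0044428", 1.12, 1.12),   # nuclear part
        ("GO:0048523", 1.12, 1.12),   # negative regulation of cellular process
        ("GO:0044459", 0.70, 0.70),   # plasma membrane part
        ("GO:0005576", 0.65, 0.65),   # extracellular region
        ("GO:0005829", 0.57, 0.57),   # cytosol
        ("GO:0005681", 0.23, 0.23),   # spliceosomal complex
        ("GO:1902532", -0.61, -0.61),  # neg. regulation of intracellular signal transduction
        ("GO:0030099", -0.74, -0.74),  # myeloid cell differentiation
        ("GO:0031224", -0.82, -0.82),  # intrinsic component of membrane
        ("GO:0003008", -0.91, -0.91),  # system process
        ("GO:0016337", -1.06, -1.06),  # single organismal cell-cell adhesion
        ("GO:0043234", -1.24, -1.24),  # protein complex
    ]


def published_model(precision: str = "high") -> FeatureWeightTable:
    """The packaged 19-feature model: 15 GO terms, 2 degree cuts, 2 bridgeness cuts.

    ``precision="high"`` (default) uses the three coefficients that were
    published at 3-decimal precision (2.675 for GO:0009887, 1.353 for
    GO:0005737, -0.497 for degree<62.5) and the 2-decimal values elsewhere;
    ``precision="table"`` uses the uniformly 2-decimal published table.
    """
    if precision not in ("high", "table"):
        raise ScoringError(f"precision must be 'high' or 'table', got {precision!r}")
    high = precision == "high"
    features: list[FeatureSpec] = []
    for term_id, w2, w3 in _go_weights():
        features.append(
            FeatureSpec(
                feature_id=term_id,
                kind="go_term",
                weight=w3 if high else w2,
                term_id=term_id,
            )
        )
    features.append(
        FeatureSpec("degree<14.5", "degree_below", -0.54, threshold=14.5)
    )
    features.append(
        FeatureSpec(
            "degree<62.5", "degree_below", -0.497 if high else -0.50, threshold=62.5
        )
    )
    features.append(
        FeatureSpec("bridgeness<2.5e-06", "bridgeness_below", -1.10, threshold=2.5e-06)
    )
    features.append(
        FeatureSpec("bridgeness<0.000292", "bridgeness_below", -0.36, threshold=0.000292)
    )
    return FeatureWeightTable(
        features=tuple(features),
        provenance=f"packaged 19-feature translocation model ({precision} precision)",
    )


def binarize(features: ProteinFeatures, table: FeatureWeightTable) -> np.ndarray:
    """Indicator vector x aligned to ``table`` (dtype int, values 0/1).

    Any undefined underlying value (degree or bridgeness ``None``) makes the
    corresponding indicator false.
    """
    x = np.zeros(len(table), dtype=int)
    for i, spec in enumerate(table):
        if spec.kind == "go_term":
            x[i] = int(spec.term_id in features.go_terms)
        elif spec.kind == "degree_below":
            x[i] = int(features.degree is not None and features.degree < spec.threshold)
        else:  # bridgeness_below
            x[i] = int(
                features.bridgeness is not None
                and features.bridgeness < spec.threshold
            )
    return x


def raw_tes(x: Sequence[int] | np.ndarray, table: FeatureWeightTable) -> float:
    """Raw score: sum of w_i over active features."""
    x = np.asarray(x)
    if x.shape != (len(table),):
        raise ScoringError(
            f"indicator length {x.shape} does not match table length {len(table)}"
        )
    return float(x @ table.weights)


def normalize(
    scores: Sequence[float] | np.ndarray,
    reference: tuple[float, float] | None = None,
) -> np.ndarray:
    """Min–max rescale raw scores to [0, 1].

    With ``reference=(min, max)`` new proteins can be scored against a frozen
    cohort's range; otherwise the cohort's own extremes are used.  A constant
    cohort (max == min) is degenerate and raises.
    """
    scores = np.asarray(scores, dtype=float)
    if reference is not None:
        lo, hi = reference
    else:
        lo, hi = float(scores.min()), float(scores.max())
    if not hi > lo:
        raise ScoringError(
            "degenerate cohort: min–max normalization is undefined when all "
            "raw scores are equal"
        )
    return (scores - lo) / (hi - lo)


def classify(
    normalized: float,
    lower: float = F1_OPTIMAL_THRESHOLD,
    upper: float = HIGH_CONFIDENCE_THRESHOLD,
) -> TranslocationClass:
    """Three-class partition of the normalized score.

    Strictly below ``lower`` is non-translocating, strictly above ``upper``
    is high-confidence; both boundary points belong to low-confidence.
    """
    if not lower < upper:
        raise ScoringError(f"thresholds must satisfy lower < upper, got {lower} >= {upper}")
    if math.isnan(normalized):
        raise ScoringError("cannot classify NaN score")
    if normalized < lower:
        return TranslocationClass.NON_TRANSLOCATING
    if normalized > upper:
        return TranslocationClass.HIGH_CONFIDENCE
    return TranslocationClass.LOW_CONFIDENCE


def score_cohort(
    features: Sequence[ProteinFeatures],
    table: FeatureWeightTable | None = None,
    lower: float = F1_OPTIMAL_THRESHOLD,
    upper: float = HIGH_CONFIDENCE_THRESHOLD,
    reference: tuple[float, float] | None = None,
) -> list[TESResult]:
    """Full pipeline binarize -> raw -> normalize -> classify, input order kept."""
    if table is None:
        table = published_model()
    raw = np.array([raw_tes(binarize(f, table), table) for f in features])
    norm = normalize(raw, reference=reference)
    return [
        TESResult(
            protein_id=f.protein_id,
            raw_score=float(r),
            normalized_score=float(s),
            label=classify(float(s), lower, upper),
        )
        for f, r, s in zip(features, raw, norm)
    ]


# -- merged feature table I/O -----------------------------------------------

def read_feature_table(stream: TextIO) -> list[ProteinFeatures]:
    """Read a merged feature TSV: protein_id, degree, bridgeness, go_terms.

    ``go_terms`` is a semicolon-joined list; empty degree/bridgeness cells
    mean undefined.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str)
    required = {"protein_id", "degree", "bridgeness", "go_terms"}
    missing = required - set(df.columns)
    if missing:
        raise ScoringError(f"feature table missing column(s): {sorted(missing)}")
    out: list[ProteinFeatures] = []
    for row in df.itertuples(index=False):
        terms = (
            frozenset(t for t in str(row.go_terms).split(";") if t)
            if isinstance(row.go_terms, str)
            else frozenset()
        )
        degree = None if pd.isna(row.degree) or row.degree == "" else float(row.degree)
        bridge = (
            None
            if pd.isna(row.bridgeness) or row.bridgeness == ""
            else float(row.bridgeness)
        )
        out.append(
            ProteinFeatures(
                protein_id=str(row.protein_id),
                go_terms=terms,
                degree=degree,
                bridgeness=bridge,
            )
        )
    return out


def write_feature_table(features: Iterable[ProteinFeatures], sink: TextIO) -> None:
    sink.write("protein_id\tdegree\tbridgeness\tgo_terms\n")
    for f in features:
        degree = "" if f.degree is None else repr(f.degree)
        bridge = "" if f.bridgeness is None else repr(f.bridgeness)
        terms = ";".join(sorted(f.go_terms))
        sink.write(f"{f.protein_id}\t{degree}\t{bridge}\t{terms}\n")


def build_protein_features(
    annotations: dict[str, frozenset[str]],
    topology: pd.DataFrame | None = None,
    protein_ids: Sequence[str] | None = None,
) -> list[ProteinFeatures]:
    """Merge ancestor-closed annotations with a topology table.

    ``topology`` is the interactome module's frame (protein_id, degree,
    bridgeness, in_giant_component).  Proteins absent from it get undefined
    degree/bridgeness; proteins absent from the annotations get empty GO sets.
    """
    topo: dict[str, tuple[float | None, float | None]] = {}
    if topology is not None:
        for row in topology.itertuples(index=False):
            bridge = None if pd.isna(row.bridgeness) else float(row.bridgeness)
            topo[str(row.protein_id)] = (float(row.degree), bridge)
    if protein_ids is None:
        protein_ids = sorted(set(annotations) | set(topo))
    out = []
    for pid in protein_ids:
        degree, bridge = topo.get(pid, (None, None))
        out.append(
            ProteinFeatures(
                protein_id=pid,
                go_terms=frozenset(annotations.get(pid, frozenset())),
                degree=degree,
                bridgeness=bridge,
            )
        )
    return out
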