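"""Seeded generators for every input the package consumes.

These generators produce toy versions of the real inputs — an OBO ontology,
protein→GO annotation tables, an interactome edge list, and a curated
registry — with planted structure mirroring the contrasts the method relies
on: translocating proteins have elevated interactome degree, designated
bridge proteins join network modules, and a handful of informative GO terms
are annotated at a higher rate in the positive class.  All randomness flows
from a single integer seed through ``numpy`` Generator streams, so every
artifact is byte-identical across runs and platforms.

The defaults mirror the curated study cohort: 160 positive (physiologically
translocating) and 139 negative (non-translocating) proteins, a registry of
213 translocating entries of which 53 are pathology-only, and a positives/
negatives mean-degree ratio of 2.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .curation import (
    MAJOR_LOCALIZATIONS,
    NEGATIVE_CATEGORIES,
    CuratedEntry,
    Localization,
)
from .ontology import OntologyDAG, ancestor_closure, annotate_proteins, load_ontology


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    degree_effect is the mean-degree ratio of positives over negatives;
    informative_effect is the difference in Bernoulli annotation rates
    between classes for the planted informative GO terms.
    """

    seed: int = 0
    n_terms: int = 90
    n_proteins: int = 400
    n_positive: int = 160
    n_negative: int = 139
    degree_effect: float = 2.0
    n_informative_go: int = 5
    informative_effect: float = 0.6
    noise_go: int = 50
    background_rate: float = 0.15
    base_degree: float = 8.0
    n_blocks: int = 2
    n_bridges: int = 3
    n_registry_translocating: int = 213
    n_registry_pathology_only: int = 53
    n_registry_negative: int = 139
    registry_population_rate: float = 0.9

    def __post_init__(self) -> None:
        if self.n_positive <= 0 or self.n_negative <= 0 or self.n_terms < 3:
            raise ValueError("counts must be positive and n_terms >= 3")
        if not 0 < self.background_rate < 1:
            raise ValueError("background annotation rate must be in (0, 1)")
        if not 0 <= self.background_rate + self.informative_effect <= 1:
            raise ValueError("informative annotation rate must stay within [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic RNG stream per generator."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(hash_stream(stream),))
        )


def hash_stream(name: str) -> int:
    """Stable small integer id for a named RNG stream (no PYTHONHASHSEED)."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def protein_ids(n: int) -> list[str]:
    """Synthetic UniProt-style accessions P00001, P00002, ..."""
    return [f"P{i:05d}" for i in range(1, n + 1)]


def go_id(i: int) -> str:
    """Synthetic GO-style term ids in a private 9xxxxxx range."""
    return f"GO:{9000000 + i:07d}"


# -- ontology ---------------------------------------------------------------

def _n_backbone(spec: SyntheticSpec) -> int:
    need = spec.n_informative_go + spec.noise_go
    return max(3, spec.n_terms - need)


def make_ontology_obo(spec: SyntheticSpec) -> str:
    """OBO text for a random rooted DAG (per namespace when size allows).

    The first terms form a backbone: each namespace starts as a 3-term chain
    (root <- child <- grandchild) and further backbone terms attach to 1–2
    existing parents of the same namespace via ``is_a`` (occasionally
    ``part_of``).  The remaining terms are dedicated annotation leaves —
    nothing ever attaches below them — reserved for the planted informative
    and noise annotations of :func:`make_cohort`.  Informative leaves hang
    directly beneath their namespace root, so their ancestor closure adds
    only the (near-constant) root column and no correlated proxy of the
    planted signal; noise leaves attach to random backbone terms.  Acyclic
    by construction.
    """
    rng = spec.rng("ontology")
    n_namespaces = 3 if spec.n_terms >= 9 else 1
    namespaces = [
        "cellular_component",
        "biological_process",
        "molecular_function",
    ][:n_namespaces]
    n_backbone = _n_backbone(spec)
    ns_of: list[str] = []
    parents: list[list[tuple[str, str]]] = []  # per-term (relation, parent id)
    members: dict[str, list[int]] = {ns: [] for ns in namespaces}
    for i in range(spec.n_terms):
        ns = namespaces[i % n_namespaces]
        own = members[ns]
        leaf_rank = i - n_backbone
        if i >= n_backbone and leaf_rank < spec.n_informative_go:
            parent_list = [("is_a", go_id(own[0]))]  # informative leaf: root child
        elif i >= n_backbone:
            k = 1 + int(rng.random() < 0.3)
            chosen = rng.choice(own, size=min(k, len(own)), replace=False)
            parent_list = [
                ("part_of" if rng.random() < 0.15 else "is_a", go_id(int(p)))
                for p in sorted(int(c) for c in chosen)
            ]
        elif len(own) == 0:
            parent_list = []
        elif len(own) <= 2:
            parent_list = [("is_a", go_id(own[-1]))]  # chain start
        else:
            k = 1 + int(rng.random() < 0.3)
            chosen = rng.choice(own, size=min(k, len(own)), replace=False)
            parent_list = [
                ("part_of" if rng.random() < 0.15 else "is_a", go_id(int(p)))
                for p in sorted(int(c) for c in chosen)
            ]
        ns_of.append(ns)
        parents.append(parent_list)
        if i < n_backbone:  # leaves never become parents
            members[ns].append(i)

    out = io.StringIO()
    out.write("format-version: 1.2\nontology: synthetic\n")
    for i in range(spec.n_terms):
        out.write("\n[Term]\n")
        out.write(f"id: {go_id(i)}\n")
        out.write(f"name: synthetic term {i}\n")
        out.write(f"namespace: {ns_of[i]}\n")
        for relation, parent in parents[i]:
            if relation == "is_a":
                out.write(f"is_a: {parent}\n")
            else:
                out.write(f"relationship: part_of {parent}\n")
    return out.getvalue()


def make_ontology(spec: SyntheticSpec) -> OntologyDAG:
    """Generate and parse a synthetic ontology (round-trips its own OBO)."""
    return load_ontology(make_ontology_obo(spec))


# -- interactome ------------------------------------------------------------

def make_interactome(spec: SyntheticSpec) -> nx.Graph:
    """Modular graph with planted hubs and bridges.

    Nodes alternate between ``n_blocks`` dense blocks; partners are sampled
    within-block with probability 0.9 (Chung–Lu style, proportional to a
    node's target degree) so blocks are dense with sparse inter-block edges.
    The first ``n_positive`` proteins get target degree ``base_degree *
    degree_effect``; the last ``n_bridges`` proteins are bridge nodes that
    sample partners uniformly across blocks at double rate.  Node attributes
    ``block``, ``role`` and ``is_bridge`` record the planted structure.
    """
    if spec.n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    rng = spec.rng("interactome")
    ids = protein_ids(spec.n_proteins)
    blocks = np.arange(spec.n_proteins) % spec.n_blocks
    target = np.full(spec.n_proteins, spec.base_degree, dtype=float)
    target[: spec.n_positive] *= spec.degree_effect
    is_bridge = np.zeros(spec.n_proteins, dtype=bool)
    bridge_idx = np.arange(spec.n_proteins - spec.n_bridges, spec.n_proteins)
    is_bridge[bridge_idx] = True
    target[bridge_idx] = 2.0 * spec.base_degree

    graph = nx.Graph()
    for i, pid in enumerate(ids):
        role = (
            "positive"
            if i < spec.n_positive
            else "negative"
            if i < spec.n_positive + spec.n_negative
            else "background"
        )
        graph.add_node(
            pid, block=int(blocks[i]), role=role, is_bridge=bool(is_bridge[i])
        )

    block_members = [np.flatnonzero(blocks == b) for b in range(spec.n_blocks)]
    block_weights = [target[m] / target[m].sum() for m in block_members]
    all_weights = target / target.sum()
    for i in range(spec.n_proteins):
        k = rng.poisson(target[i] / 2.0)
        for _ in range(k):
            if is_bridge[i]:
                j = int(rng.choice(spec.n_proteins, p=all_weights))
            elif rng.random() < 0.9:
                m = block_members[blocks[i]]
                j = int(rng.choice(m, p=block_weights[blocks[i]]))
            else:
                other = (blocks[i] + 1 + int(rng.integers(spec.n_blocks - 1))) % spec.n_blocks
                m = block_members[other]
                j = int(rng.choice(m, p=block_weights[other]))
            if j != i:
                graph.add_edge(ids[i], ids[j])
    return graph


def write_edges_tsv(graph: nx.Graph, sink) -> None:
    sink.write("interactor_a\tinteractor_b\n")
    for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
        sink.write(f"{a}\t{b}\n")


# -- labelled cohort --------------------------------------------------------

def planted_terms(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    """(informative, noise) GO term ids used by :func:`make_cohort`.

    These are the dedicated annotation leaves of :func:`make_ontology_obo`.
    """
    need = spec.n_informative_go + spec.noise_go
    n_backbone = _n_backbone(spec)
    if n_backbone + need > spec.n_terms:
        raise ValueError(
            f"ontology too small: need {need} annotation leaves plus a "
            f"{n_backbone}-term backbone, have n_terms={spec.n_terms}"
        )
    informative = [go_id(n_backbone + i) for i in range(spec.n_informative_go)]
    noise = [go_id(n_backbone + spec.n_informative_go + i) for i in range(spec.noise_go)]
    return informative, noise


def make_cohort(
    spec: SyntheticSpec,
    dag: OntologyDAG,
    graph: nx.Graph,
) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """Labelled training cohort plus its ancestor-closed annotation set.

    The first ``n_positive`` proteins are labelled 1, the next ``n_negative``
    0.  Informative terms are annotated at rate ``background_rate +
    informative_effect`` in positives vs ``background_rate`` in negatives;
    noise terms at the background rate in both classes.  Feature columns are
    the closed GO indicators plus ``degree`` and ``bridgeness`` from the
    graph's giant component (undefined bridgeness becomes 0).
    """
    from .interactome import giant_component, bridgeness as bridgeness_scores

    rng = spec.rng("cohort")
    informative, noise = planted_terms(spec)
    n = spec.n_positive + spec.n_negative
    ids = protein_ids(spec.n_proteins)[:n]
    labels = np.array([1] * spec.n_positive + [0] * spec.n_negative)

    raw: dict[str, set[str]] = {pid: set() for pid in ids}
    p_pos = spec.background_rate + spec.informative_effect
    for term in informative:
        draws = rng.random(n)
        rates = np.where(labels == 1, p_pos, spec.background_rate)
        for pid, hit in zip(ids, draws < rates):
            if hit:
                raw[pid].add(term)
    for term in noise:
        draws = rng.random(n)
        for pid, hit in zip(ids, draws < spec.background_rate):
            if hit:
                raw[pid].add(term)
    annotations = annotate_proteins(raw, dag)

    term_domain = sorted(set().union(*annotations.values()) | set(informative) | set(noise))
    giant = giant_component(graph)
    bridge = bridgeness_scores(giant)
    data: dict[str, list] = {t: [] for t in term_domain}
    data["degree"] = []
    data["bridgeness"] = []
    data["label"] = list(labels)
    for pid in ids:
        closed = annotations[pid]
        for t in term_domain:
            data[t].append(int(t in closed))
        data["degree"].append(graph.degree[pid] if pid in graph else 0)
        data["bridgeness"].append(bridge.get(pid, 0.0))
    cohort = pd.DataFrame(data, index=pd.Index(ids, name="protein_id"))
    return cohort, annotations


def write_annotations_tsv(annotations: dict[str, frozenset[str]], sink) -> None:
    for pid in sorted(annotations):
        for term in sorted(annotations[pid]):
            sink.write(f"{pid}\t{term}\n")


def write_cohort_tsv(cohort: pd.DataFrame, sink) -> None:
    cohort.to_csv(sink, sep="\t", lineterminator="\n")


# -- curated registry -------------------------------------------------------

def make_curated_registry(spec: SyntheticSpec) -> list[CuratedEntry]:
    """Schema-valid synthetic registry mirroring the curated cohort counts.

    Defaults: 213 translocating entries (53 pathology-only) and 139
    negative-category entries, with optional fields populated at
    ``registry_population_rate``.
    """
    rng = spec.rng("registry")
    majors = sorted(MAJOR_LOCALIZATIONS)
    categories = sorted(NEGATIVE_CATEGORIES)
    entries: list[CuratedEntry] = []
    total = spec.n_registry_translocating + spec.n_registry_negative
    ids = [f"Q{i:05d}" for i in range(10000, 10000 + total)]

    def maybe(value, default=""):
        return value if rng.random() < spec.registry_population_rate else default

    for i in range(total):
        translocating = i < spec.n_registry_translocating
        if translocating:
            a, b = rng.choice(len(majors), size=2, replace=False)
            initial = Localization(majors[int(a)])
            target = Localization(majors[int(b)])
            pathology_only = i < spec.n_registry_pathology_only
            category = None
        else:
            loc = majors[int(rng.integers(len(majors)))]
            initial = Localization(loc)
            target = None
            pathology_only = False
            category = categories[(i - spec.n_registry_translocating) % len(categories)]
        entries.append(
            CuratedEntry(
                uniprot_ac=ids[i],
                gene_name=f"GENE{i + 1}",
                protein_names=f"Synthetic protein {i + 1}",
                pubmed_ids=maybe([str(10_000_000 + int(rng.integers(1_000_000)))], []),
                initial_localization=initial,
                target_localization=target,
                partners_initial=maybe([f"GENE{int(rng.integers(1, total + 1))}"], []),
                partners_target=maybe([f"GENE{int(rng.integers(1, total + 1))}"], [])
                if translocating
                else [],
                functions_initial=maybe("synthetic initial function"),
                functions_target=maybe("synthetic target function") if translocating else "",
                mechanism=maybe("synthetic translocation mechanism") if translocating else "",
                detection_method=maybe("immunofluorescence microscopy"),
                structural_info=maybe("synthetic structural note"),
                disease_group=maybe("cancer"),
                disease=maybe("synthetic carcinoma"),
                pathological_role=maybe("driver") if translocating else "",
                pathways=maybe([f"hsa{4000 + int(rng.integers(1000)):05d}"], []),
                pathology_only=pathology_only,
                negative_category=category,
            )
        )
    return entries


# -- presets / bundle -------------------------------------------------------

PRESETS: dict[str, dict] = {
    "full": {},
    "tiny": {
        "n_terms": 24,
        "n_proteins": 60,
        "n_positive": 20,
        "n_negative": 18,
        "noise_go": 8,
        "n_informative_go": 3,
        "n_registry_translocating": 21,
        "n_registry_pathology_only": 5,
        "n_registry_negative": 14,
    },
}


def simulate_to_dir(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input file into ``outdir``; returns the paths."""
    from .curation import write_registry

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "edges": outdir / "edges.tsv",
        "registry": outdir / "registry.csv",
        "cohort": outdir / "cohort.tsv",
    }
    obo_text = make_ontology_obo(spec)
    paths["obo"].write_text(obo_text)
    dag = load_ontology(obo_text)
    graph = make_interactome(spec)
    with paths["edges"].open("w") as fh:
        write_edges_tsv(graph, fh)
    cohort, annotations = make_cohort(spec, dag, graph)
    with paths["annotations"].open("w") as fh:
        write_annotations_tsv(annotations, fh)
    with paths["cohort"].open("w") as fh:
        write_cohort_tsv(cohort, fh)
    registry = make_curated_registry(spec)
    with paths["registry"].open("w", newline="") as fh:
        write_registry(registry, fh)
    return paths
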