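"""Seeded generators emulating every input the study consumed.

No accession, interaction catalogue, or patient table is publicly
deposited for this workflow, so validation runs against synthetic inputs
with ground-truth sidecars:

* abstract corpora with planted gene–disease document co-occurrence rates;
* sparse undirected interaction catalogues with planted receptor→anchor
  cascades guaranteed shorter than any decoy route;
* four-group qPCR Ct tables (n = 30 per group by default, matching the
  study arms) with planted per-gene fold changes and a reference gene;
* ELISA plates generated from a known standard curve.

Every generator is a pure function of its spec including the seed: the
same spec reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .corpus import AbstractRecord
from .expression import CtMeasurement, STUDY_GROUPS
from .network import InteractionEdge

__all__ = [
    "CorpusSpec",
    "NetworkSpec",
    "ExpressionSpec",
    "ElisaSpec",
    "simulate_corpus",
    "simulate_network",
    "simulate_expression",
    "simulate_elisa",
]


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusSpec:
    """Planted document co-occurrence model for an abstract corpus.

    ``association_table`` maps each symbol to (P(mention | non-disease
    doc), P(mention | disease doc)); disease membership is Bernoulli with
    probability ``p_disease``.  Mentions are embedded into templated
    sentences with proper word boundaries; ``hard_mode`` additionally
    plants confusable substrings like "xBDNFx" that a boundary-aware
    matcher must ignore.
    """

    seed: int
    n_abstracts: int = 200
    disease_terms: tuple[str, ...] = ("T2DM", "type 2 diabetes")
    association_table: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    p_disease: float = 0.5
    year_range: tuple[int, int] = (1990, 2023)
    hard_mode: bool = False

    def __post_init__(self):
        for sym, (p0, p1) in self.association_table.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"probabilities for {sym} outside [0,1]")
        if not 0 <= self.p_disease <= 1:
            raise ValueError("p_disease outside [0,1]")


# every template carries the broad retrieval keyword "glucose" so that a
# keyword-curated corpus still mixes disease and non-disease documents —
# the contrast PMI needs
_FILLER = (
    "In a cohort study the authors measured circulating glucose markers",
    "Expression profiling in a glucose clamp revealed altered regulation",
    "A randomized trial evaluated the glucose response",
    "Mechanistic work on glucose handling implicated signalling changes",
)


def simulate_corpus(spec: CorpusSpec):
    """Generate (records, ground_truth).

    ``ground_truth`` holds the exact per-document memberships the mining
    stage must recover: ``n_docs``, ``disease_docs`` (ids), ``symbol_docs``
    (symbol -> id set), and the derived ``n_x``/``n_xd`` counts.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[AbstractRecord] = []
    disease_docs: set[str] = set()
    symbol_docs: dict[str, set[str]] = {s: set() for s in spec.association_table}
    symbols = sorted(spec.association_table)
    y0, y1 = spec.year_range
    for i in range(spec.n_abstracts):
        rid = f"SIM{i:06d}"
        is_disease = rng.random() < spec.p_disease
        mentioned = []
        for s in symbols:
            p0, p1 = spec.association_table[s]
            if rng.random() < (p1 if is_disease else p0):
                mentioned.append(s)
                symbol_docs[s].add(rid)
        parts = [str(_FILLER[int(rng.integers(len(_FILLER)))]) + "."]
        if is_disease:
            term = spec.disease_terms[int(rng.integers(len(spec.disease_terms)))]
            parts.append(f"The study enrolled participants with {term}.")
            disease_docs.add(rid)
        for s in mentioned:
            # repeat some mentions: per-document counting must be invariant
            reps = 1 + int(rng.integers(3))
            for _ in range(reps):
                parts.append(f"Levels of {s} were altered in cases.")
        if spec.hard_mode and symbols:
            decoy = symbols[int(rng.integers(len(symbols)))]
            parts.append(f"An unrelated token x{decoy}x appeared in methods.")
        year = int(rng.integers(y0, y1 + 1))
        records.append(AbstractRecord(rid, f"Simulated abstract {i}", " ".join(parts), year))
    n_d = len(disease_docs)
    ground_truth = {
        "n_docs": spec.n_abstracts,
        "disease_docs": sorted(disease_docs),
        "n_d": n_d,
        "symbol_docs": {s: sorted(d) for s, d in symbol_docs.items()},
        "n_x": {s: len(d) for s, d in symbol_docs.items()},
        "n_xd": {s: len(d & disease_docs) for s, d in symbol_docs.items()},
    }
    return records, ground_truth


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Random interaction catalogue with planted receptor→anchor cascades.

    Background edges follow G(n, p) over generic nodes; each planted path
    (receptor, intermediaries, anchor) is added verbatim.  A rejection
    step prunes background edges that would create a receptor→anchor route
    shorter than or equal in length to the planted path (other than the
    planted path itself), so planted-path recovery is deterministic.
    """

    seed: int
    n_nodes: int = 60
    edge_probability: float = 0.05
    planted_paths: tuple[tuple[str, tuple[str, ...], str], ...] = ()
    min_decoy_length: int | None = None

    def __post_init__(self):
        for receptor, mids, anchor in self.planted_paths:
            nodes = [receptor, *mids, anchor]
            if len(set(nodes)) != len(nodes):
                raise ValueError("planted path nodes must be distinct")
            if self.min_decoy_length is not None and self.min_decoy_length <= len(nodes) - 1:
                raise ValueError("min_decoy_length must exceed planted path length")
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be non-negative")
        if not 0 <= self.edge_probability <= 1:
            raise ValueError("edge_probability outside [0,1]")


def _planted_edges(spec: NetworkSpec) -> set[tuple[str, str]]:
    edges = set()
    for receptor, mids, anchor in spec.planted_paths:
        chain = [receptor, *mids, anchor]
        edges.update(tuple(sorted(e)) for e in zip(chain, chain[1:]))
    return edges


def simulate_network(spec: NetworkSpec):
    """Generate (edge catalogue, ground_truth sidecar).

    The sidecar records the planted cascades and the generator settings so
    fixtures are regenerable.
    """
    rng = np.random.default_rng(spec.seed)
    background = [f"N{i:04d}" for i in range(spec.n_nodes)]
    planted_nodes = sorted(
        {n for r, m, a in spec.planted_paths for n in (r, *m, a)}
    )
    nodes = planted_nodes + background
    g = nx.Graph()
    g.add_nodes_from(nodes)
    planted = _planted_edges(spec)
    g.add_edges_from(planted)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < spec.edge_probability:
                e = tuple(sorted((nodes[i], nodes[j])))
                if e not in planted:
                    g.add_edge(*e)
    # rejection: no accidental receptor→anchor route as short as planted
    for receptor, mids, anchor in spec.planted_paths:
        plen = len(mids) + 1
        floor = (spec.min_decoy_length or plen + 1) - 1
        chain = [receptor, *mids, anchor]
        while True:
            offenders = [
                p
                for p in nx.all_simple_paths(g, receptor, anchor, cutoff=floor)
                if p != chain
            ]
            if not offenders:
                break
            path = offenders[0]
            removable = [
                e for e in (tuple(sorted(x)) for x in zip(path, path[1:]))
                if e not in planted
            ]
            if not removable:  # decoy made only of planted edges: unresolvable
                raise ValueError("planted paths interfere with each other")
            g.remove_edge(*removable[0])
    edges = [InteractionEdge.make(a, b, source="sim") for a, b in sorted(g.edges)]
    ground_truth = {
        "planted_cascades": [
            {"nodes": [r, *m, a], "length": len(m) + 1}
            for r, m, a in spec.planted_paths
        ],
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "generator": {"family": "numpy.random.default_rng(PCG64)", "seed": spec.seed},
    }
    return edges, ground_truth


def paper_shaped_network_spec(seed: int = 0) -> NetworkSpec:
    """Default study-shaped spec: two planted cascades with one and two
    intermediaries (metformin receptor PRKAB1 → APP → BDNF; glimepiride
    receptor KCNJ11 → AP2M1 → ESR1 → BDNF) among random decoys."""
    return NetworkSpec(
        seed=seed,
        n_nodes=60,
        edge_probability=0.05,
        planted_paths=(
            ("PRKAB1", ("APP",), "BDNF"),
            ("KCNJ11", ("AP2M1", "ESR1"), "BDNF"),
        ),
    )


# ---------------------------------------------------------------------------
# Expression (qPCR) and ELISA
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSpec:
    """Planted per-(gene, group) mean dCt with Gaussian measurement noise.

    Defaults mirror the study arms: four groups of n = 30, reactions in
    triplicate.  Each sample gets a baseline shift (RNA input variation)
    that moves every gene's Ct equally and therefore cancels in dCt; on
    top of that, each replicate reading carries independent noise —
    ``sd_ct`` cycles for target genes, ``reference_sd`` for the reference
    gene.  Planted fold versus the calibrator group is
    2^-(dCt_mean[gene, group] - dCt_mean[gene, calibrator]).
    """

    seed: int
    genes: tuple[str, ...] = ("BDNF", "APP", "AP2M1", "ESR1")
    groups: Mapping[str, int] = field(
        default_factory=lambda: {g: 30 for g in STUDY_GROUPS}
    )
    delta_ct_mean: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sd_ct: float = 0.3
    reference_gene: str = "GAPDH"
    reference_mean: float = 20.0
    reference_sd: float = 0.3
    sample_shift_sd: float = 0.5
    n_replicates: int = 3
    calibrator_group: str = "healthy_control"

    def __post_init__(self):
        if self.sd_ct <= 0 or self.reference_sd <= 0:
            raise ValueError("SDs must be > 0")
        for g, n in self.groups.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2")

    def planted_fold(self, gene: str, group: str) -> float:
        d = self.delta_ct_mean.get((gene, group), 0.0)
        d0 = self.delta_ct_mean.get((gene, self.calibrator_group), 0.0)
        return 2.0 ** -(d - d0)


def simulate_expression(spec: ExpressionSpec):
    """Generate (Ct measurements, ground_truth of planted folds)."""
    rng = np.random.default_rng(spec.seed)
    rows: list[CtMeasurement] = []
    for group, n in spec.groups.items():
        for i in range(n):
            sid = f"{group}_{i:03d}"
            baseline = spec.reference_mean + rng.normal(0.0, spec.sample_shift_sd)
            for rep in range(1, spec.n_replicates + 1):
                rows.append(
                    CtMeasurement(
                        sid, group, spec.reference_gene, rep,
                        float(baseline + rng.normal(0.0, spec.reference_sd)),
                    )
                )
            for gene in spec.genes:
                d = spec.delta_ct_mean.get((gene, group), 0.0)
                for rep in range(1, spec.n_replicates + 1):
                    rows.append(
                        CtMeasurement(
                            sid, group, gene, rep,
                            float(baseline + d + rng.normal(0.0, spec.sd_ct)),
                        )
                    )
    ground_truth = {
        "planted_fold": {
            f"{gene}:{group}": spec.planted_fold(gene, group)
            for gene in spec.genes
            for group in spec.groups
        },
        "reference_gene": spec.reference_gene,
        "calibrator_group": spec.calibrator_group,
        "generator": {"family": "numpy.random.default_rng(PCG64)", "seed": spec.seed},
    }
    return rows, ground_truth


@dataclass
class ElisaSpec:
    """ELISA plate from a known linear standard curve.

    ``group_concentration_mean`` holds the true serum concentration
    (ng/mL) per group; absorbances are curve(conc) plus Gaussian noise.
    """

    seed: int
    intercept: float = 0.02
    slope: float = 0.05
    standards: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    group_concentration_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "untreated_T2DM": 6.0,
            "metformin": 9.0,
            "glimepiride": 12.0,
            "healthy_control": 10.0,
        }
    )
    concentration_sd: float = 1.0
    absorbance_sd: float = 0.005
    n_per_group: int = 30


def simulate_elisa(spec: ElisaSpec):
    """Generate (standards, samples, ground_truth).

    ``standards`` is a list of (concentration, absorbance); ``samples`` a
    list of (id, group, absorbance) rows; ground truth records each
    sample's true concentration and the curve parameters.
    """
    rng = np.random.default_rng(spec.seed)
    curve = lambda c: spec.intercept + spec.slope * c
    standards = [
        (float(c), float(curve(c) + rng.normal(0.0, spec.absorbance_sd)))
        for c in spec.standards
    ]
    samples = []
    true_conc = {}
    for group, mean in spec.group_concentration_mean.items():
        for i in range(spec.n_per_group):
            sid = f"{group}_{i:03d}"
            conc = max(0.0, mean + rng.normal(0.0, spec.concentration_sd))
            absorb = curve(conc) + rng.normal(0.0, spec.absorbance_sd)
            samples.append((sid, group, float(absorb)))
            true_conc[sid] = conc
    ground_truth = {
        "curve": {"model": "linear", "intercept": spec.intercept, "slope": spec.slope},
        "true_concentration": true_conc,
        "group_means": dict(spec.group_concentration_mean),
        "generator": {"family": "numpy.random.default_rng(PCG64)", "seed": spec.seed},
    }
    return standards, samples, ground_truth
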