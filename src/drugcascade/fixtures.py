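"""Study-shaped synthetic fixture bundle.

Writes, to one directory, every input file the pipeline consumes —
abstract corpus, gene lexicon, interaction catalogue, drug→receptor map,
GMT annotation collection, qPCR Ct table and ELISA plate — generated by
the :mod:`drugcascade.synthetic` module so that the bundle carries the
study's stated structure: the metformin receptor PRKAB1 reaches BDNF
through APP, the glimepiride receptor KCNJ11 through AP2M1 and ESR1, and
decoy routes are strictly longer.  All files are plain text and the
bundle is a pure function of the seed.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .corpus import write_structured
from .synthetic import (
    CorpusSpec,
    ElisaSpec,
    ExpressionSpec,
    NetworkSpec,
    paper_shaped_network_spec,
    simulate_corpus,
    simulate_elisa,
    simulate_expression,
    simulate_network,
)

__all__ = ["CASCADE_GENES", "write_fixture_bundle"]

# genes of the two reported cascades, assayed in the validation arm
CASCADE_GENES = ("BDNF", "APP", "AP2M1", "ESR1", "PRKAB1", "KCNJ11")

_LEXICON_ROWS = [
    ("BDNF", "brain-derived neurotrophic factor"),
    ("APP", "amyloid beta precursor protein"),
    ("AP2M1", ""),
    ("ESR1", "estrogen receptor 1"),
    ("PRKAB1", ""),
    ("KCNJ11", ""),
    ("GAPDH", ""),
    ("INS", "insulin gene"),
    ("IRS1", "insulin receptor substrate 1"),
    ("TCF7L2", ""),
    ("PPARG", ""),
    ("SLC2A4", "GLUT4"),
]

# Planted document co-occurrence rates: cascade genes strongly associated
# with disease documents, two null genes mentioned independently.
_ASSOCIATION = {
    "BDNF": (0.05, 0.60),
    "APP": (0.05, 0.45),
    "AP2M1": (0.04, 0.40),
    "ESR1": (0.05, 0.40),
    "PRKAB1": (0.03, 0.35),
    "KCNJ11": (0.03, 0.35),
    "INS": (0.10, 0.50),
    "IRS1": (0.08, 0.45),
    "TCF7L2": (0.06, 0.40),
    "PPARG": (0.06, 0.40),
    "SLC2A4": (0.20, 0.20),  # planted null: disease-independent
    "GAPDH": (0.15, 0.15),   # planted null: housekeeping chatter
}

# dCt shifts versus healthy controls, shaped like the reported direction:
# cascade genes down in untreated disease, restored/raised under treatment,
# with glimepiride lifting BDNF/AP2M1/ESR1 the most.
_DELTA_CT = {
    ("BDNF", "untreated_T2DM"): 1.0,
    ("BDNF", "metformin"): -0.5,
    ("BDNF", "glimepiride"): -1.0,
    ("APP", "untreated_T2DM"): 0.8,
    ("APP", "metformin"): -0.8,
    ("APP", "glimepiride"): -0.3,
    ("AP2M1", "untreated_T2DM"): 0.7,
    ("AP2M1", "metformin"): -0.2,
    ("AP2M1", "glimepiride"): -0.9,
    ("ESR1", "untreated_T2DM"): 0.7,
    ("ESR1", "metformin"): -0.2,
    ("ESR1", "glimepiride"): -0.8,
}

_GMT_TERMS = [
    ("PATH:NEUROTROPHIN", "neurotrophin signalling",
     ["BDNF", "APP", "ESR1", "AP2M1", "NTRK2", "NGFR"]),
    ("PATH:INSULIN", "insulin signalling",
     ["INS", "IRS1", "SLC2A4", "PRKAB1", "PPARG", "TCF7L2"]),
    ("PATH:ENDOCYTOSIS", "clathrin-mediated endocytosis",
     ["AP2M1", "APP", "KCNJ11"]),
    ("PATH:HOUSEKEEPING", "core metabolism",
     ["GAPDH", "INS", "PPARG"]),
]


def write_fixture_bundle(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the full input bundle; returns a name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("corpus", "corpus.tsv"),
        ("lexicon", "lexicon.tsv"),
        ("catalogue", "catalogue.sif"),
        ("drug_targets", "drug_targets.tsv"),
        ("gmt", "pathways.gmt"),
        ("ct", "ct_values.csv"),
        ("elisa", "elisa.csv"),
        ("ground_truth", "ground_truth.json"),
    ]}

    corpus_spec = CorpusSpec(
        seed=seed, n_abstracts=300, association_table=_ASSOCIATION, p_disease=0.5
    )
    records, corpus_gt = simulate_corpus(corpus_spec)
    write_structured(records, paths["corpus"])

    with open(paths["lexicon"], "w", encoding="utf-8") as fh:
        fh.write("symbol\tsynonyms\n")
        for symbol, syn in _LEXICON_ROWS:
            fh.write(f"{symbol}\t{syn}\n")

    net_spec = paper_shaped_network_spec(seed=seed)
    edges, net_gt = simulate_network(net_spec)
    with open(paths["catalogue"], "w", encoding="utf-8") as fh:
        for e in edges:
            fh.write(f"{e.a}\tpp\t{e.b}\n")

    with open(paths["drug_targets"], "w", encoding="utf-8") as fh:
        fh.write("drug\treceptor\nmetformin\tPRKAB1\nglimepiride\tKCNJ11\n")

    with open(paths["gmt"], "w", encoding="utf-8") as fh:
        for term, desc, genes in _GMT_TERMS:
            fh.write("\t".join([term, desc, *genes]) + "\n")

    expr_spec = ExpressionSpec(seed=seed + 1, delta_ct_mean=_DELTA_CT)
    measurements, expr_gt = simulate_expression(expr_spec)
    with open(paths["ct"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "group", "gene", "replicate", "ct"])
        for m in measurements:
            w.writerow([m.sample_id, m.group, m.gene, m.replicate, f"{m.ct:.4f}"])

    elisa_spec = ElisaSpec(seed=seed + 2)
    standards, samples, elisa_gt = simulate_elisa(elisa_spec)
    with open(paths["elisa"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "id", "group", "concentration", "absorbance"])
        for conc, absorb in standards:
            w.writerow(["standard", "", "", f"{conc:.4f}", f"{absorb:.5f}"])
        for sid, group, absorb in samples:
            w.writerow(["sample", sid, group, "", f"{absorb:.5f}"])

    paths["ground_truth"].write_text(
        json.dumps(
            {"corpus": corpus_gt, "network": net_gt,
             "expression": expr_gt, "elisa": elisa_gt},
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    return paths
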