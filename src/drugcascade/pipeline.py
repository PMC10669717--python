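"""End-to-end orchestration: mine → network → interactome → cascade →
enrichment → expression/ELISA statistics.

The pipeline mirrors the study workflow: curate a disease abstract
corpus, tag gene mentions and rank proteins by PMI, induce the disease
PPI network on the mined list from a reference catalogue, extract each
drug's receptor-anchored interactome and its shortest signal cascade,
run over-representation analysis of the interactome genes, and compute
the 2^-ddCt / ANOVA–Tukey / ELISA validation statistics.  Every stage
writes its outputs to the run directory; a single JSON report collects
the headline results.  Runs are deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from scipy import stats as _scipy_stats

from . import corpus as cm
from . import enrichment as en
from . import expression as ex
from . import interactome as di
from . import network as nb

__all__ = ["PipelineConfig", "PipelineError", "STAGES", "run_pipeline"]

STAGES = ("curate", "mine", "network", "cascade", "enrich", "expr", "elisa")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and per-stage parameters for one pipeline run."""

    corpus: str
    lexicon: str
    catalogue: str
    drug_targets: str
    gmt: str | None = None
    ct: str | None = None
    elisa: str | None = None
    anchor: str = "BDNF"
    keywords: list[str] = field(default_factory=lambda: ["glucose"])
    disease_terms: list[str] = field(
        default_factory=lambda: ["T2DM", "type 2 diabetes", "hyperglycemia"]
    )
    exclusion_terms: list[str] = field(default_factory=list)
    year_min: int = 1990
    year_max: int = 2023
    min_pmi: float = 0.25
    min_docs: int = 5
    path_budget: int | None = None  # None => shortest + 2
    enrichment_alpha: float = 0.01
    anova_alpha: float = 0.05
    reference_gene: str = "GAPDH"
    calibrator_group: str = "healthy_control"
    elisa_model: str = "linear"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.enrichment_alpha < 1 and 0 < self.anova_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if not self.anchor:
            raise ValueError("anchor symbol must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _read_corpus(path: str) -> list[cm.AbstractRecord]:
    if Path(path).suffix.lower() in (".medline", ".txt"):
        return cm.read_medline(path)
    return cm.read_structured(path)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, from_stage: str | None = None
) -> dict:
    """Execute the pipeline, writing per-stage outputs and report.json.

    ``from_stage`` resumes from a named stage, loading earlier stages'
    outputs from ``outdir`` instead of recomputing them; downstream
    outputs are reproduced byte-identically.  Any stage error aborts with
    the stage name and cause; completed-stage outputs are retained and
    recorded in MANIFEST.json.
    """
    if from_stage is not None and from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {s: "pending" for s in STAGES}
    manifest_path = outdir / "MANIFEST.json"

    def mark(stage: str, status: str):
        manifest[stage] = status
        _json_dump(manifest, manifest_path)

    def fresh(stage: str) -> bool:
        return from_stage is None or STAGES.index(stage) >= STAGES.index(from_stage)

    prev_report: dict = {}
    if from_stage is not None and (outdir / "report.json").exists():
        prev_report = json.loads((outdir / "report.json").read_text())

    report: dict = {"config": dataclasses.asdict(config), "seed": config.seed}

    # ---- curate -----------------------------------------------------------
    stage = "curate"
    curated_path = outdir / "curated_corpus.tsv"
    try:
        if fresh(stage) or "curation" not in prev_report:
            records = _read_corpus(config.corpus)
            curation = cm.curate_corpus(
                records, config.keywords, config.year_min, config.year_max,
                config.exclusion_terms,
            )
            if not curation.records:
                raise ValueError("no abstracts retained after curation")
            cm.write_structured(curation.records, curated_path)
            report["curation"] = {
                "n_input": curation.n_input,
                "n_retained": len(curation.records),
                "n_skipped_malformed": curation.n_skipped_malformed,
                "n_duplicates": curation.n_duplicates,
            }
        else:
            curated_records = cm.read_structured(curated_path)
            curation = cm.CurationReport(curated_records, len(curated_records), 0, 0)
            report["curation"] = prev_report["curation"]
        mark(stage, "done")
    except Exception as err:
        mark(stage, "failed")
        raise PipelineError(stage, str(err)) from err

    # ---- mine -------------------------------------------------------------
    stage = "mine"
    pmi_path = outdir / "pmi_scores.tsv"
    try:
        if fresh(stage) or "mining" not in prev_report:
            lexicon = cm.read_lexicon(config.lexicon)
            hits_by_record = {
                r.record_id: cm.match_mentions(r, lexicon) for r in curation.records
            }
            disease_terms = [t.lower() for t in config.disease_terms]
            disease_ids = [
                r.record_id
                for r in curation.records
                if any(t in (r.title + "\n" + r.body).lower() for t in disease_terms)
            ]
            counts = cm.count_cooccurrence(
                hits_by_record, disease_ids, len(curation.records)
            )
            scores = [cm.compute_pmi(counts, s) for s in sorted(counts.doc_count)]
            ranked = cm.rank_proteins(scores, config.min_pmi, config.min_docs)
            cm.write_pmi_table(ranked, counts.n_docs, pmi_path)
            proteins = [s.symbol for s in ranked]
            report["mining"] = {
                "n_symbols_mentioned": len(counts.doc_count),
                "n_disease_docs": counts.disease_doc_count,
                "n_proteins": len(proteins),
                "proteins": proteins,
            }
        else:
            report["mining"] = prev_report["mining"]
            proteins = list(report["mining"]["proteins"])
        mark(stage, "done")
    except Exception as err:
        mark(stage, "failed")
        raise PipelineError(stage, str(err)) from err

    # ---- network ----------------------------------------------------------
    stage = "network"
    net_path = outdir / "disease_network.sif"
    try:
        if fresh(stage) or "network" not in prev_report:
            catalogue = nb.load_edge_catalogue(config.catalogue)
            net = nb.induce_disease_network(proteins, catalogue.edges)
            nb.write_sif(net, net_path)
            report["network"] = nb.network_summary(net)
            report["network"]["catalogue_edges"] = len(catalogue.edges)
        else:
            net = nb.read_sif_network(net_path)
            report["network"] = prev_report["network"]
        mark(stage, "done")
    except Exception as err:
        mark(stage, "failed")
        raise PipelineError(stage, str(err)) from err

    # ---- cascade ----------------------------------------------------------
    stage = "cascade"
    try:
        drugs = di.read_drug_targets(config.drug_targets)
        report["drugs"] = {}
        interactome_nodes: dict[str, set[str]] = {}
        for dt in sorted(drugs, key=lambda d: d.drug):
            entry: dict = {"receptors": list(dt.receptors)}
            try:
                cascades = di.shortest_cascade(net, dt, config.anchor)
                inter = di.extract_interactome(
                    net, dt, config.anchor, config.path_budget
                )
                di.write_interactome_json(
                    inter, cascades, outdir / f"interactome_{dt.drug}.json"
                )
                entry.update(
                    connected=inter.connected,
                    n_nodes=len(inter.nodes),
                    n_edges=len(inter.edges),
                    max_path_len=inter.max_path_len,
                    cascades=[list(p.nodes) for p in cascades],
                )
                if cascades:
                    canonical = cascades[0]
                    entry["canonical_cascade"] = list(canonical.nodes)
                    entry["cascade_length"] = canonical.length
                    entry["intermediaries"] = di.intermediaries(canonical)
                interactome_nodes[dt.drug] = inter.nodes
            except ValueError as verr:
                entry.update(connected=False, warning=str(verr))
                interactome_nodes[dt.drug] = set()
            report["drugs"][dt.drug] = entry
        mark(stage, "done")
    except Exception as err:
        mark(stage, "failed")
        raise PipelineError(stage, str(err)) from err

    # ---- enrich -----------------------------------------------------------
    stage = "enrich"
    try:
        if config.gmt:
            collection = en.read_gmt(config.gmt)
            universe = net.nodes
            report["enrichment"] = {}
            for drug, nodes in sorted(interactome_nodes.items()):
                if not nodes:
                    report["enrichment"][drug] = {"significant_terms": [], "n_tested": 0}
                    continue
                results = en.enrich(
                    nodes, collection, universe, alpha=config.enrichment_alpha
                )
                en.write_enrichment_table(results, outdir / f"enrichment_{drug}.tsv")
                report["enrichment"][drug] = {
                    "n_tested": len(results),
                    "significant_terms": [
                        {"term": r.term_id, "p": r.p_value}
                        for r in results
                        if r.significant
                    ],
                }
        mark(stage, "done" if config.gmt else "skipped")
    except Exception as err:
        mark(stage, "failed")
        raise PipelineError(stage, str(err)) from err

    # ---- expr -------------------------------------------------------------
    stage = "expr"
    try:
        if config.ct:
            data = ex.read_ct_table(config.ct)
            folds = ex.delta_delta_ct(
                data, config.reference_gene, config.calibrator_group
            )
            with open(outdir / "fold_changes.tsv", "w", encoding="utf-8") as fh:
                fh.write("sample_id\tgroup\tgene\tdelta_ct\tdelta_delta_ct\tfold\n")
                for f in folds:
                    fh.write(
                        f"{f.sample_id}\t{f.group}\t{f.gene}\t{f.delta_ct:.6g}\t"
                        f"{f.delta_delta_ct:.6g}\t{f.fold:.6g}\n"
                    )
            report["expression"] = {}
            genes = sorted({f.gene for f in folds})
            for gene in genes:
                by_group: dict[str, list[float]] = {}
                for f in folds:
                    if f.gene == gene:
                        by_group.setdefault(f.group, []).append(f.fold)
                comp = ex.group_comparison(gene, by_group)
                report["expression"][gene] = _comparison_dict(
                    comp, config.calibrator_group, config.anova_alpha, by_group
                )
            _json_dump(report["expression"], outdir / "expression_stats.json")
        mark(stage, "done" if config.ct else "skipped")
    except Exception as err:
        mark(stage, "failed")
        raise PipelineError(stage, str(err)) from err

    # ---- elisa ------------------------------------------------------------
    stage = "elisa"
    try:
        if config.elisa:
            standards, samples = ex.read_elisa_csv(config.elisa)
            curve = ex.fit_standard_curve(standards, model=config.elisa_model)
            by_group: dict[str, list[float]] = {}
            n_out_of_range = 0
            for row in samples.itertuples():
                conc, in_range = ex.interpolate(curve, float(row.absorbance))
                if conc is None:
                    n_out_of_range += 1
                    continue
                by_group.setdefault(str(row.group), []).append(conc)
            comp = ex.group_comparison("BDNF_serum", by_group)
            report["elisa"] = _comparison_dict(
                comp, config.calibrator_group, config.anova_alpha, by_group
            )
            report["elisa"]["model"] = curve.model
            report["elisa"]["curve_params"] = list(curve.params)
            report["elisa"]["n_out_of_range"] = n_out_of_range
        mark(stage, "done" if config.elisa else "skipped")
    except Exception as err:
        mark(stage, "failed")
        raise PipelineError(stage, str(err)) from err

    _json_dump(report, outdir / "report.json")
    return report


def _comparison_dict(
    comp: ex.GroupComparison,
    calibrator: str,
    alpha: float,
    by_group: dict[str, list[float]],
) -> dict:
    """Serialize a GroupComparison; emits both Tukey-adjusted and
    unadjusted-t p-values for comparisons against the calibrator group."""
    unadjusted = {}
    if calibrator in by_group:
        for g, vals in by_group.items():
            if g == calibrator:
                continue
            t, p = _scipy_stats.ttest_ind(vals, by_group[calibrator], equal_var=True)
            unadjusted[g] = {"t": float(t), "p": float(p)}
    return {
        "group_means": {g: round(v, 10) for g, v in comp.group_means.items()},
        "group_sds": {g: round(v, 10) for g, v in comp.group_sds.items()},
        "group_ns": comp.group_ns,
        "F": round(comp.F, 10) if math.isfinite(comp.F) else "inf",
        "p_anova": round(comp.p_anova, 12),
        "anova_significant": comp.p_anova < alpha,
        "tukey": [
            {
                "pair": [t.group_a, t.group_b],
                "mean_difference": round(t.mean_difference, 10),
                "q": round(t.q, 10) if math.isfinite(t.q) else "inf",
                "p_adjusted": round(t.p_adjusted, 12),
                "significant": t.p_adjusted < alpha,
            }
            for t in comp.tukey
        ],
        "vs_calibrator_unadjusted": {
            g: {"t": round(d["t"], 10), "p": round(d["p"], 12)}
            for g, d in unadjusted.items()
        },
    }
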