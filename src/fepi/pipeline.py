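"""End-to-end orchestration: overlap -> fold filter -> typing -> clustering
-> co-expression network/modules -> GO enrichment -> promoter motif scan.

A run is described by a flat key=value config (or a :class:`RunConfig` built
in code).  In synthetic mode every input is generated from the config's seed
with planted ground truth; in file mode the config points at abundance
tables, DEG lists, a compendium, an ontology + annotations and a promoter
FASTA.  Each stage writes its artifact under the output directory and the
run ends with a machine-readable ``report.json`` whose counts are mutually
consistent; re-running with the same config and seed reproduces every file
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import foldchange as fc
from . import network as net
from . import ontology as onto
from . import synth
from . import motif as mo

log = logging.getLogger("fepi")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the study's stated constants."""

    outdir: str = "fepi_out"
    seed: int = 0
    fold_cutoff: float = 2.0        # primary fold filter
    secondary_cutoff: float = 1.5   # motif-candidate filter within type 4
    corr_threshold: float = 0.7     # Pearson edge threshold
    go_cutoff: float = 0.01         # elim significance/reporting cutoff
    motif_pattern: str = mo.P1BS
    upstream_length: int = 3000
    within_distance: int = 1000

    # file-mode inputs (all None -> synthetic mode)
    fe_abundance: str | None = None
    pi_abundance: str | None = None
    fe_deg_list: str | None = None
    pi_deg_list: str | None = None
    compendium: str | None = None
    obo: str | None = None
    annotations: str | None = None
    promoters: str | None = None

    # synthetic-mode generation sizes
    n_genes: int = 400
    n_deg: int = 120
    n_reps: int = 3
    noise_cv: float = 0.1
    zero_control_fraction: float = 0.05
    n_arrays: int = 200
    module_sizes: tuple[int, ...] = (12, 8, 5)
    module_latent_weight: float = 3.0
    n_go_terms: int = 40
    go_universe_size: int = 400
    enrichment_odds: float = 10.0

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1 or self.secondary_cutoff <= 1:
            raise ValueError("fold cutoffs must exceed 1")
        if not (0 < self.corr_threshold <= 1):
            raise ValueError("correlation threshold must lie in (0, 1]")
        mo.compile_iupac(self.motif_pattern)  # validates the pattern

    @property
    def file_mode(self) -> bool:
        return self.fe_abundance is not None


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        key, _, val = ln.partition("=")
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        typ = fields[key].type
        if val.lower() == "none":
            kwargs[key] = None
        elif "int" in typ and "tuple" not in typ:
            kwargs[key] = int(val)
        elif "float" in typ:
            kwargs[key] = float(val)
        elif "tuple" in typ:
            kwargs[key] = tuple(int(v) for v in val.split(",") if v.strip())
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def _read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "mode": "file" if config.file_mode else "synthetic"}
    truth = synth.SyntheticTruth()

    # ---------------- inputs ----------------
    _stage("inputs")
    if config.file_mode:
        fe_trt, fe_ctrl = synth.read_abundance_tsv(config.fe_abundance)
        pi_trt, pi_ctrl = synth.read_abundance_tsv(config.pi_abundance)
        fe_degs = _read_gene_list(config.fe_deg_list) if config.fe_deg_list \
            else list(fe_trt.index)
        pi_degs = _read_gene_list(config.pi_deg_list) if config.pi_deg_list \
            else list(pi_trt.index)
        compendium = pd.read_csv(config.compendium, sep="\t", index_col=0) \
            if config.compendium else None
        dag = onto.parse_obo(config.obo) if config.obo else None
        direct = onto.read_annotations(config.annotations) if config.annotations else None
        promoters = mo.read_promoter_fasta(config.promoters) if config.promoters else None
    else:
        fe_trt, fe_ctrl, t_fe = synth.gen_contrast_experiment(
            config.n_genes, config.n_deg, n_reps=config.n_reps,
            noise_cv=config.noise_cv,
            zero_control_fraction=config.zero_control_fraction,
            seed=config.seed, contrast="fe")
        pi_trt, pi_ctrl, t_pi = synth.gen_contrast_experiment(
            config.n_genes, config.n_deg, n_reps=config.n_reps,
            noise_cv=config.noise_cv,
            zero_control_fraction=config.zero_control_fraction,
            seed=config.seed + 1, contrast="pi")
        truth.deg_genes_per_contrast.update(t_fe.deg_genes_per_contrast)
        truth.deg_genes_per_contrast.update(t_pi.deg_genes_per_contrast)
        fe_degs = sorted(truth.deg_genes_per_contrast["fe"])
        pi_degs = sorted(truth.deg_genes_per_contrast["pi"])
        synth.write_abundance_tsv(fe_trt, fe_ctrl, out / "fe_abundance.tsv")
        synth.write_abundance_tsv(pi_trt, pi_ctrl, out / "pi_abundance.tsv")

    # ---------------- fold changes and overlap ----------------
    _stage("overlap")
    fe_records = fc.fold_change_table(fe_trt, fe_ctrl)
    pi_records = fc.fold_change_table(pi_trt, pi_ctrl)
    overlap = fc.overlap_genes(fe_degs, pi_degs)
    table = fc.build_overlap_table(fe_records, pi_records, overlap)
    fc.write_overlap_table(table, out / "overlap_foldchanges.tsv")
    report["overlap_genes"] = len(overlap)

    _stage("fold filter")
    filtered = fc.filter_by_fold(table, config.fold_cutoff)
    fc.write_overlap_table(filtered, out / "overlap_filtered.tsv")
    report["fold_cutoff"] = config.fold_cutoff
    report["filtered_genes"] = len(filtered)

    _stage("classification")
    assignment, counts, subcounts = fc.classify_types(
        table, subcount_cutoffs=(config.fold_cutoff, config.secondary_cutoff))
    assignment.rename_axis("gene").to_csv(out / "type_assignment.tsv", sep="\t")
    report["type_counts"] = {str(k): v for k, v in sorted(counts.items())}
    report["type_subcounts"] = {
        str(c): {k: dict(sorted(v.items())) for k, v in sc.items()}
        for c, sc in subcounts.items()
    }

    # ---------------- clustering ----------------
    _stage("clustering")
    if len(filtered) >= 2:
        matrix = _cluster.log2_fold_matrix(filtered)
        res = _cluster.hierarchical_cluster(matrix)
        res.ordered_matrix(matrix).to_csv(out / "log2_matrix_ordered.tsv", sep="\t")
        (out / "dendrogram.nwk").write_text(_cluster.to_newick(res) + "\n")
        report["clustered_genes"] = len(res.leaf_order)
        report["cluster_excluded"] = res.excluded
    else:
        report["clustered_genes"] = 0
        report["cluster_excluded"] = []

    # ---------------- co-expression network ----------------
    _stage("network")
    if config.file_mode and compendium is None:
        report["network"] = None
    else:
        if not config.file_mode:
            module_sizes = [
                (s, config.module_latent_weight) for s in config.module_sizes
            ]
            # modules occupy leading ids: put overlap genes first so the
            # planted structure lies inside the analyzed gene set
            ordering = overlap + sorted(set(fe_trt.index) - set(overlap))
            compendium, t_mod = synth.gen_compendium(
                config.n_genes, config.n_arrays, module_sizes,
                noise_sd=1.0, seed=config.seed, gene_ids=ordering)
            truth.module_membership = t_mod.module_membership
            compendium.to_csv(out / "compendium.tsv", sep="\t")
        genes = [g for g in overlap if g in compendium.index] or \
            list(compendium.index)
        corr, excluded = net.pearson_matrix(compendium, genes)
        graph, unconnected = net.build_network(corr, config.corr_threshold)
        modules = net.find_modules(graph)
        stats = net.network_stats(graph, modules)
        net.export_network(graph, modules, "sif", out / "network.sif")
        net.export_network(graph, modules, "tsv", out / "network_edges.tsv")
        net.write_modules(modules, out / "modules.tsv")
        stats["zero_variance_genes"] = excluded
        stats["unconnected_input_genes"] = len(unconnected)
        report["network"] = stats

    # ---------------- GO enrichment ----------------
    _stage("go enrichment")
    if config.file_mode and (dag is None or direct is None):
        report["go"] = None
    else:
        if not config.file_mode:
            obo_text, direct, study, t_go = synth.gen_go_universe(
                config.n_go_terms, max_depth=5,
                universe_size=config.go_universe_size,
                study_size=max(10, config.go_universe_size // 10),
                enrichment_odds=config.enrichment_odds, seed=config.seed)
            (out / "ontology.obo").write_text(obo_text)
            truth.enriched_term = t_go.enriched_term
            with open(out / "annotations.tsv", "w") as fh:
                for g in sorted(direct):
                    for t in sorted(direct[g]):
                        fh.write(f"{g}\t{t}\n")
            dag = onto.parse_obo(str(out / "ontology.obo"))
            universe = sorted(direct)
        else:
            universe = sorted(direct)
            study = [g for g in overlap if g in direct]
        propagated = onto.propagate_annotations(dag, direct)
        results = onto.elim_enrich(dag, propagated, study, universe,
                                   cutoff=config.go_cutoff)
        onto.write_enrichment(results, out / "go_enrichment.tsv")
        sig = [r for r in results if r.p_elim < config.go_cutoff]
        report["go"] = {
            "terms_tested": len(results),
            "significant_terms": len(sig),
            "top_term": results[0].term if results else None,
        }

    # ---------------- promoter motif scan ----------------
    _stage("motif scan")
    if config.file_mode and promoters is None:
        report["motif"] = None
    else:
        if not config.file_mode:
            # scan candidates: type-4 genes passing the secondary cutoff
            type4 = [g for g in assignment.index if assignment[g] == 4]
            sub = table.loc[type4]
            candidates = list(fc.filter_by_fold(sub, config.secondary_cutoff).index)
            plant = {
                g: [(137 + 61 * (i % 40), "GTATATGC")]
                for i, g in enumerate(candidates[: max(1, len(candidates) // 2)])
                if g in candidates
            }
            promoters, t_pm = synth.gen_promoters(
                len(candidates) or 1,
                length=config.upstream_length,
                plant_spec=plant,
                gene_ids=candidates or None,
                forbid_background_hits=True,
                pattern=config.motif_pattern,
                seed=config.seed)
            truth.planted_motifs = t_pm.planted_motifs
            synth.write_promoter_fasta(promoters, out / "promoters.fasta")
            report["motif_candidates"] = len(candidates)
        hits = mo.scan_promoter_set(promoters, config.motif_pattern)
        summary = mo.summarize_hits(hits, within=config.within_distance)
        mo.hits_to_frame(hits).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        report["motif"] = {
            "total_hits": summary.total_hits,
            "unique_genes": summary.unique_genes,
            "genes_within": summary.genes_within,
            "within_distance": summary.within_distance,
            "distinct_patterns": summary.distinct_patterns,
        }

    if not config.file_mode:
        truth.to_json(out / "truth.json")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _stage("done")
    return report
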