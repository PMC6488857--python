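"""End-to-end orchestration: normalize → DE → enrichment → CNC → cis/trans → validation.

One config object holds every threshold the pipeline uses (fold change
2.0, DE p 0.05, CNC |r| >= 0.9, cis/trans |r| > 0.85 & p < 0.01, cis
window 300 kb, trans floor 100 kb); stage logic never hard-codes them.
A JSON manifest records every output file with row counts and checksums,
so identical inputs + config + seed reproduce byte-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import array_io, cis_trans, coexpression, diffexpr, enrichment, validation
from .array_io import ExpressionMatrix, ProbeAnnotation
from .enrichment import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for a full run."""

    matrix: str = ""
    groups: str = ""
    annotation: str = ""
    gmt: str = ""
    qpcr: str = ""
    outdir: str = "lncnet_out"
    fc: float = 2.0
    p_de: float = 0.05
    r_cnc: float = 0.9
    r_cistrans: float = 0.85
    p_cistrans: float = 0.01
    cis_window_bp: int = 300_000
    trans_floor_bp: int = 100_000
    normalization: str = "quantile"
    ttest_variant: str = "pooled"
    fc_mode: str = "mean_ratio"
    distance_mode: str = "gap"
    top_n: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("fc", "p_de", "r_cnc", "r_cistrans", "p_cistrans", "cis_window_bp", "trans_floor_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.cis_window_bp <= self.trans_floor_bp:
            raise ValueError("cis_window_bp must be greater than trans_floor_bp")
        if self.normalization not in array_io.NORMALIZERS:
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, status: str, outputs: list[dict], seconds: float, **info) -> None:
        self.stages.append(
            {"stage": stage, "status": status, "seconds": round(seconds, 3), "outputs": outputs, **info}
        )

    @property
    def output_files(self) -> list[str]:
        return [o["path"] for s in self.stages for o in s["outputs"]]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh, indent=2)


def _file_record(path: Path) -> dict:
    data = path.read_bytes()
    rows = max(0, data.count(b"\n") - 1) if path.suffix in (".tsv", ".txt") else data.count(b"\n")
    return {"path": path.name, "rows": rows, "sha256": hashlib.sha256(data).hexdigest()}


def default_universe(annotation: ProbeAnnotation, gene_sets: GeneSetCollection) -> list[str]:
    """Array gene symbols carrying at least one gene-set annotation."""
    annotated = gene_sets.all_genes()
    return [s for s in annotation.symbols_for(annotation.probe_ids) if s in annotated]


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    annotation: ProbeAnnotation | None = None,
    gene_sets: GeneSetCollection | None = None,
    qpcr: validation.QpcrTable | None = None,
) -> RunManifest:
    """Execute all stages in order; inputs may be paths (from config) or
    in-memory objects. Returns the manifest; aborts on stage failure with
    the stage name, leaving partial outputs marked FAILED."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    manifest_path = outdir / "manifest.json"

    if matrix is None:
        groups = array_io.read_group_map(config.groups)
        matrix = array_io.read_expression_matrix(config.matrix, groups)
    if annotation is None:
        annotation = array_io.read_probe_annotation(config.annotation)
    if gene_sets is None:
        gene_sets = GeneSetCollection.from_gmt(config.gmt)
    if qpcr is None and config.qpcr:
        qpcr = validation.read_qpcr_table(config.qpcr, matrix.groups)

    state: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            logger.info("stage %s ...", name)
            try:
                outputs = fn() or []
            except Exception as exc:
                manifest.add(name, "FAILED", [], time.perf_counter() - t0, error=str(exc))
                manifest.write(manifest_path)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            records = [_file_record(p) for p in outputs]
            manifest.add(name, "ok", records, time.perf_counter() - t0)
            return records

        return wrap

    @stage("normalize")
    def _normalize():
        log2 = array_io.as_log2(matrix)
        norm = array_io.normalize(log2, config.normalization)
        state["norm"] = norm
        path = outdir / "normalized_log2.tsv"
        norm.write_tsv(path, outdir / "groups.tsv")
        return [path, outdir / "groups.tsv"]

    @stage("differential_expression")
    def _de():
        de = diffexpr.differential_expression(
            state["norm"], variant=config.ttest_variant, fc_mode=config.fc_mode
        )
        state["de"] = de
        outputs = []
        for klass in ("lncRNA", "mRNA"):
            probes = [p for p in annotation.probes_of_class(klass) if p in de.index]
            sub = de.loc[probes]
            up, down = diffexpr.volcano_filter(sub, config.fc, config.p_de)
            state[f"up_{klass}"], state[f"down_{klass}"] = up, down
            state[f"summary_{klass}"] = diffexpr.summarize_de(up, down)
            tag = "lnc" if klass == "lncRNA" else "mrna"
            de_path = outdir / f"de_{tag}.tsv"
            diffexpr.write_de_table(sub, annotation, de_path)
            top = diffexpr.top_table(
                sub.loc[sorted(up | down)], annotation, config.top_n, config.top_n
            )
            top_path = outdir / f"top_{tag}.tsv"
            top.to_csv(top_path, sep="\t", index=False, float_format="%.10g")
            up_path, down_path = outdir / f"up_{tag}.txt", outdir / f"down_{tag}.txt"
            enrichment.write_gene_list(sorted(up), up_path)
            enrichment.write_gene_list(sorted(down), down_path)
            outputs += [de_path, top_path, up_path, down_path]
        return outputs

    @stage("clustering")
    def _cluster():
        de_probes = sorted(
            state["up_lncRNA"] | state["down_lncRNA"] | state["up_mRNA"] | state["down_mRNA"]
        )
        if len(de_probes) < 2:
            return []
        order = diffexpr.hierarchical_cluster(state["norm"].subset(de_probes))
        path = outdir / "cluster_order.tsv"
        with open(path, "w") as fh:
            fh.write("axis\tid\n")
            for rid in order.row_order:
                fh.write(f"row\t{rid}\n")
            for cid in order.col_order:
                fh.write(f"col\t{cid}\n")
        return [path]

    universe = default_universe(annotation, gene_sets)

    def _enrich(genes, tag):
        res = enrichment.fisher_enrichment(genes, gene_sets, universe)
        path = outdir / f"enrichment_{tag}.tsv"
        enrichment.write_enrichment(res, path)
        return path

    @stage("enrichment_de")
    def _enrich_de():
        outputs = []
        for direction in ("up", "down"):
            probes = state[f"{direction}_mRNA"]
            outputs.append(_enrich(annotation.symbols_for(sorted(probes)), direction))
        return outputs

    @stage("cnc_network")
    def _cnc():
        network = coexpression.build_cnc_network(
            state["norm"],
            state["up_lncRNA"],
            state["down_lncRNA"],
            state["up_mRNA"],
            state["down_mRNA"],
            r_threshold=config.r_cnc,
        )
        state["network"] = network
        paths = [outdir / "cnc_nodes.tsv", outdir / "cnc_edges.tsv", outdir / "cnc.sif"]
        coexpression.export_network(network, *paths)
        return paths

    @stage("cis_trans")
    def _cis_trans():
        pairs = cis_trans.coexpressed_pairs(
            state["norm"],
            state["up_lncRNA"] | state["down_lncRNA"],
            state["up_mRNA"] | state["down_mRNA"],
            r_threshold=config.r_cistrans,
            p_threshold=config.p_cistrans,
        )
        assignments = cis_trans.classify_targets(
            pairs,
            annotation,
            cis_window=config.cis_window_bp,
            trans_floor=config.trans_floor_bp,
            distance_mode=config.distance_mode,
        )
        state["assignments"] = assignments
        cis_genes, trans_genes = cis_trans.target_gene_lists(assignments)
        state["cis_genes"], state["trans_genes"] = cis_genes, trans_genes
        a_path = outdir / "cis_trans_assignments.tsv"
        cis_trans.write_assignments(assignments, a_path)
        c_path, t_path = outdir / "cis_genes.txt", outdir / "trans_genes.txt"
        enrichment.write_gene_list(cis_genes, c_path)
        enrichment.write_gene_list(trans_genes, t_path)
        return [a_path, c_path, t_path]

    @stage("enrichment_cis_trans")
    def _enrich_ct():
        return [_enrich(state["cis_genes"], "cis"), _enrich(state["trans_genes"], "trans")]

    if qpcr is not None:

        @stage("validation")
        def _validate():
            shared = [p for p in qpcr.probes if p in state["de"].index]
            result = validation.platform_concordance(state["de"].loc[shared], qpcr)
            state["validation"] = result
            paths = [outdir / "validation_probes.tsv", outdir / "validation_summary.tsv"]
            result.write_tsv(*paths)
            return paths

    # internal identities recorded for downstream consumers
    counts = {
        "lncRNA": state["summary_lncRNA"],
        "mRNA": state["summary_mRNA"],
        "cnc_edges": state["network"].n_edges,
        "cis_pairs": int((state["assignments"]["klass"] == cis_trans.CIS).sum()),
        "trans_pairs": int((state["assignments"]["klass"] == cis_trans.TRANS).sum()),
    }
    with open(outdir / "counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    manifest.add("summary", "ok", [_file_record(outdir / "counts.json")], 0.0)
    manifest.write(manifest_path)
    return manifest
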