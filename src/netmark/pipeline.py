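"""End-to-end orchestration of the two-cycle biomarker pipeline.

Cycle one scores the cancer-signature interaction network topologically
and selects central genes (hubs plus the top betweenness tier).  Cycle two
calls differential expression in the tumor and PBMC compartments,
intersects the two DEG sets, and intersects the result with the central
set to nominate consensus biomarkers.  Downstream stages characterise the
nominee: an MI co-expression module seeded at it, gene-set enrichment of
that module, median-stratified survival, and delta-delta-Ct qPCR folds.

``make_demo`` emits a complete, self-consistent synthetic dataset (with a
planted consensus gene aliased to CCNB2) plus a ready-to-run YAML config;
``run_pipeline`` executes every stage from such a config and writes all
intermediates, a structured log and a deterministic summary report.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import coexpr as coexpr_mod
from . import dge, enrich, qpcr, survival, synth, topology
from . import io_formats as io

__all__ = ["PipelineConfig", "PipelineError", "make_demo", "run_pipeline"]

DEMO_CONSENSUS_ALIAS = "CCNB2"
DEMO_SHARED_ALIAS = "PGK1"
# planted delta-Ct shifts (cycles) for the three-group qPCR demo;
# relative to the primary-stage calibrator these give folds of
# 2^4.63 ~ 24.8 (metastatic) and 2^1.38 ~ 2.6 (healthy)
DEMO_QPCR_SHIFTS = {"healthy": 0.0, "primary": 1.38, "metastatic": 1.38 - 4.63}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    tumor_expression: str
    tumor_groups: str
    pbmc_expression: str
    pbmc_groups: str
    edges: str
    coexpr_expression: str
    coexpr_groups: str
    gmt: str
    survival_table: str
    qpcr_table: str
    logfc_cut: float = 0.5
    alpha: float = 0.05
    betweenness_quantile: float = 0.20
    degree_top_k: int | None = 6
    degree_threshold: float | None = None
    mi_bins: int | None = None
    mi_permutations: int = 100
    mi_alpha: float = 0.05
    dpi_tolerance: float = 0.1
    enrich_alpha: float = 0.05
    horizon: float | None = 5.0
    qpcr_reference: str = "primary"
    force_seed_gene: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = Path(path).parent
        for f in dataclasses.fields(cls):
            if f.name in _PATH_FIELDS:
                p = base / getattr(cfg, f.name)
                if not p.exists():
                    raise PipelineError(f"input file not found: {p}")
                setattr(cfg, f.name, str(p))
        return cfg


_PATH_FIELDS = {
    "tumor_expression",
    "tumor_groups",
    "pbmc_expression",
    "pbmc_groups",
    "edges",
    "coexpr_expression",
    "coexpr_groups",
    "gmt",
    "survival_table",
    "qpcr_table",
}


def make_demo(
    seed: int,
    out_dir,
    cfg: synth.SynthConfig | None = None,
    coexpr_genes: int = 40,
    coexpr_samples: int = 120,
    survival_subjects: int = 160,
) -> dict:
    """Generate the bundled synthetic demo dataset.

    One gene is planted simultaneously as a same-direction DEG in both
    compartments and as the top network hub (aliased to CCNB2); a second
    shared DEG is planted on a peripheral, non-central node (aliased to
    PGK1), mirroring the shared-vs-consensus distinction of the two-cycle
    design.  Writes all input files, a truth sidecar and ``run.yaml``;
    returns the planted truth as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg = synth.SynthConfig(n_genes=200, n_case=15, n_ctrl=15, seed=seed)
    else:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng((seed % (2**31), 1001))

    net, net_truth = synth.make_network(cfg)
    central = topology.select_central(
        net, betweenness_quantile=0.20, degree_rule=topology.TopKDegree(cfg.hub_count)
    )
    ranked = sorted(net.nodes(), key=lambda n: (-net.degree(n), n))
    consensus_gene = ranked[0]
    non_central = [g for g in reversed(ranked) if g not in central.central]
    shared_extra = non_central[0]
    alias = {consensus_gene: DEMO_CONSENSUS_ALIAS, shared_extra: DEMO_SHARED_ALIAS}
    net = nx.relabel_nodes(net, alias)
    genes = [alias.get(g, g) for g in synth.gene_names(cfg.n_genes)]
    hub_genes = {alias.get(g, g) for g in net_truth.hub_genes}

    n_extra = max(3, int(round(cfg.deg_fraction * cfg.n_genes)) - 2)
    pool = [g for g in genes if g not in alias.values()]
    extras = rng.choice(pool, size=2 * n_extra, replace=False)
    t_deg = {DEMO_CONSENSUS_ALIAS: 1, DEMO_SHARED_ALIAS: 1}
    p_deg = dict(t_deg)
    for g in extras[:n_extra]:
        t_deg[g] = int(rng.choice([-1, 1]))
    for g in extras[n_extra:]:
        p_deg[g] = int(rng.choice([-1, 1]))

    tumor, _ = synth.make_expression(cfg, deg_genes=t_deg, genes=genes)
    pbmc, _ = synth.make_expression(
        cfg, deg_genes=p_deg, genes=genes, stream="expression2"
    )

    co_pool = [g for g in genes if g != DEMO_CONSENSUS_ALIAS]
    co_genes = [DEMO_CONSENSUS_ALIAS] + list(
        rng.choice(co_pool, size=coexpr_genes - 1, replace=False)
    )
    co_matrix, co_truth = synth.make_coexpr_data(
        cfg, DEMO_CONSENSUS_ALIAS, n_samples=coexpr_samples, genes=co_genes
    )

    surv = synth.make_survival(cfg, n_subjects=survival_subjects,
                               gene=DEMO_CONSENSUS_ALIAS)
    ct = synth.make_qpcr(cfg, DEMO_QPCR_SHIFTS)

    # synthetic gene-set library over the co-expression gene universe:
    # one term holding most of the planted module plus random terms
    lib = io.GeneSetLibrary()
    module = sorted(co_truth.module_genes)
    keep = max(2, int(round(0.9 * len(module))))
    planted_members = set(module[:keep]) | set(
        rng.choice([g for g in co_genes if g not in co_truth.module_genes], size=3,
                   replace=False)
    )
    lib.sets["PLANTED_MODULE_TERM"] = io.GeneSet(
        "synthetic term around the planted module", planted_members
    )
    for i in range(15):
        size = int(rng.integers(5, 15))
        members = set(rng.choice(co_genes, size=size, replace=False))
        lib.sets[f"RANDOM_TERM_{i + 1:02d}"] = io.GeneSet("synthetic null term",
                                                          members)

    io.write_expression(tumor, out / "tumor_expression.tsv", out / "tumor_groups.tsv")
    io.write_expression(pbmc, out / "pbmc_expression.tsv", out / "pbmc_groups.tsv")
    io.write_edgelist(net, out / "network_edges.tsv")
    io.write_expression(
        co_matrix, out / "coexpr_expression.tsv", out / "coexpr_groups.tsv"
    )
    io.write_survival(surv, out / "survival.tsv")
    io.write_qpcr(ct, out / "ct.tsv")
    io.write_gmt(lib, out / "genesets.gmt")

    truth = {
        "consensus_gene": DEMO_CONSENSUS_ALIAS,
        "shared_genes": sorted([DEMO_CONSENSUS_ALIAS, DEMO_SHARED_ALIAS]),
        "hub_genes": sorted(hub_genes),
        "module_genes": sorted(co_truth.module_genes),
        "hazard_gene": DEMO_CONSENSUS_ALIAS,
        "tumor_deg_genes": {g: int(s) for g, s in sorted(t_deg.items())},
        "pbmc_deg_genes": {g: int(s) for g, s in sorted(p_deg.items())},
    }
    with open(out / "truth.txt", "w", encoding="utf-8") as fh:
        for key, val in truth.items():
            if isinstance(val, dict):
                val = ",".join(f"{g}:{s:+d}" for g, s in val.items())
            elif isinstance(val, list):
                val = ",".join(val)
            fh.write(f"{key}={val}\n")

    config = {
        "tumor_expression": "tumor_expression.tsv",
        "tumor_groups": "tumor_groups.tsv",
        "pbmc_expression": "pbmc_expression.tsv",
        "pbmc_groups": "pbmc_groups.tsv",
        "edges": "network_edges.tsv",
        "coexpr_expression": "coexpr_expression.tsv",
        "coexpr_groups": "coexpr_groups.tsv",
        "gmt": "genesets.gmt",
        "survival_table": "survival.tsv",
        "qpcr_table": "ct.tsv",
        "degree_top_k": cfg.hub_count,
        "qpcr_reference": "primary",
        "horizon": 5.0,
        "seed": seed,
    }
    with open(out / "run.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return truth


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute every stage of the two-cycle pipeline and write results.

    Writes per-stage TSVs, ``pipeline.log`` (one structured line per stage
    with input hashes, parameters and output row counts) and a
    deterministic ``summary.txt`` naming the consensus biomarker(s).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: list[str] = []

    def log(stage: str, **kv) -> None:
        kvs = " ".join(f"{k}={v}" for k, v in kv.items())
        log_lines.append(f"stage={stage} {kvs}")

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- cycle 1: network topology -------------------------------------
    def stage_topology():
        net = io.read_edgelist(cfg.edges)
        if cfg.degree_threshold is not None:
            rule = topology.DegreeThreshold(cfg.degree_threshold)
        else:
            rule = topology.TopKDegree(cfg.degree_top_k or 6)
        central = topology.select_central(
            net, betweenness_quantile=cfg.betweenness_quantile, degree_rule=rule
        )
        deg = topology.degree_map(net)
        btw = topology.betweenness_map(net)
        df = pd.DataFrame(
            {
                "gene": sorted(net.nodes()),
                "degree": [deg[g] for g in sorted(net.nodes())],
                "betweenness": [btw[g] for g in sorted(net.nodes())],
                "is_hub": [g in central.hubs for g in sorted(net.nodes())],
                "is_high_betweenness": [
                    g in central.high_betweenness for g in sorted(net.nodes())
                ],
                "is_central": [g in central.central for g in sorted(net.nodes())],
            }
        )
        io.write_table(df, out / "central.tsv")
        log(
            "topology",
            edges_hash=_file_hash(cfg.edges),
            nodes=net.number_of_nodes(),
            edges=net.number_of_edges(),
            n_central=len(central.central),
        )
        return central

    central = run_stage("topology", stage_topology)

    # --- cycle 2: differential expression per compartment ---------------
    def stage_dge(which, expr_path, groups_path):
        matrix = io.read_expression(expr_path, io.read_groups(groups_path))
        table = dge.call_degs(matrix, logfc_cut=cfg.logfc_cut, alpha=cfg.alpha)
        io.write_table(table, out / f"degs_{which}.tsv")
        log(
            f"dge_{which}",
            matrix_hash=_file_hash(expr_path),
            genes=len(table),
            significant=int(table["significant"].sum()),
            logfc_cut=cfg.logfc_cut,
            alpha=cfg.alpha,
        )
        return table

    degs_tumor = run_stage(
        "dge_tumor", lambda: stage_dge("tumor", cfg.tumor_expression, cfg.tumor_groups)
    )
    degs_pbmc = run_stage(
        "dge_pbmc", lambda: stage_dge("pbmc", cfg.pbmc_expression, cfg.pbmc_groups)
    )

    # --- consensus -------------------------------------------------------
    def stage_consensus():
        shared, prov = consensus_mod.shared_degs(degs_tumor, degs_pbmc)
        result = consensus_mod.consensus_with_central(shared, central, prov)
        io.write_table(result.to_frame(), out / "consensus.tsv")
        log(
            "consensus",
            shared=len(result.shared_degs),
            consensus=len(result.consensus),
            genes=",".join(sorted(result.consensus)) or "-",
        )
        return result

    result = run_stage("consensus", stage_consensus)
    summary.append("consensus biomarkers: " + (", ".join(sorted(result.consensus)) or "none"))
    summary.append(f"shared DEGs (tumor & PBMC): {', '.join(sorted(result.shared_degs)) or 'none'}")

    seed_genes = sorted(result.consensus)
    if not seed_genes and cfg.force_seed_gene:
        seed_genes = [cfg.force_seed_gene]
    if not seed_genes:
        summary.append("co-expression/enrichment skipped: no consensus gene")
        log("coexpr", skipped="no_consensus_gene")

    # --- co-expression module + enrichment per consensus gene -----------
    co_cfg = coexpr_mod.CoexprConfig(
        n_bins=cfg.mi_bins,
        n_permutations=cfg.mi_permutations,
        mi_alpha=cfg.mi_alpha,
        dpi_tolerance=cfg.dpi_tolerance,
    )
    for gene in seed_genes:
        def stage_coexpr(gene=gene):
            matrix = io.read_expression(
                cfg.coexpr_expression, io.read_groups(cfg.coexpr_groups)
            )
            if gene not in matrix.genes:
                summary.append(
                    f"co-expression skipped for {gene}: absent from matrix"
                )
                log("coexpr", gene=gene, skipped="absent")
                return None, matrix
            net, audit = coexpr_mod.infer_network(matrix, co_cfg, seed=cfg.seed)
            module = coexpr_mod.seed_module(net, gene)
            io.write_table(
                pd.DataFrame({"gene": sorted(module)}), out / f"module_{gene}.tsv"
            )
            edges = pd.DataFrame(
                [
                    (a, b, net.edges[a, b]["mi"])
                    for a, b in sorted(tuple(sorted(e)) for e in net.edges())
                ],
                columns=["gene_a", "gene_b", "mi"],
            )
            io.write_table(edges, out / f"coexpr_edges_{gene}.tsv")
            log(
                "coexpr",
                gene=gene,
                matrix_hash=_file_hash(cfg.coexpr_expression),
                module_size=len(module),
                edges=net.number_of_edges(),
                perms=co_cfg.n_permutations,
                dpi_eps=co_cfg.dpi_tolerance,
            )
            return module, matrix

        module, _ = run_stage("coexpr", stage_coexpr)
        if module is None:
            continue
        summary.append(f"co-expression module of {gene}: {len(module)} genes")

        def stage_enrich(gene=gene, module=module):
            lib = io.read_gmt(cfg.gmt)
            rows = enrich.enrich_library(set(module), lib, alpha=cfg.enrich_alpha)
            io.write_table(
                enrich.enrichment_frame(rows), out / f"enrichment_{gene}.tsv"
            )
            log("enrich", gene=gene, gmt_hash=_file_hash(cfg.gmt), terms=len(rows))
            return rows

        rows = run_stage("enrich", stage_enrich)
        if rows:
            top = rows[0]
            summary.append(
                f"top enriched term for {gene} module: {top.term} "
                f"(overlap {top.overlap}, adjusted P {top.p_adj:.3g})"
            )
        else:
            summary.append(f"no term enriched below adjusted P {cfg.enrich_alpha}")

    # --- survival --------------------------------------------------------
    def stage_survival():
        table = io.read_survival(cfg.survival_table)
        cmp_, km_high, km_low = survival.compare_by_median(table, horizon=cfg.horizon)
        km = pd.concat(
            [
                km_high.to_frame().assign(stratum="high"),
                km_low.to_frame().assign(stratum="low"),
            ]
        )
        io.write_table(km, out / "km.tsv")
        io.write_table(
            pd.DataFrame(
                [
                    {
                        "chi2": cmp_.logrank_chi2,
                        "p": cmp_.p,
                        "hazard_ratio": cmp_.hazard_ratio,
                        "horizon": cmp_.horizon,
                    }
                ]
            ),
            out / "survival_comparison.tsv",
        )
        log(
            "survival",
            table_hash=_file_hash(cfg.survival_table),
            subjects=len(table),
            hr=f"{cmp_.hazard_ratio:.4f}",
            p=f"{cmp_.p:.4g}",
        )
        return cmp_

    cmp_ = run_stage("survival", stage_survival)
    summary.append(
        f"survival (high vs low expression, horizon {cfg.horizon}): "
        f"HR={cmp_.hazard_ratio:.2f}, log-rank P={cmp_.p:.3g}"
    )

    # --- qPCR ------------------------------------------------------------
    def stage_qpcr():
        table = io.read_qpcr(cfg.qpcr_table)
        res = qpcr.delta_delta_ct(table, cfg.qpcr_reference)
        io.write_table(res, out / "folds.tsv")
        folds = qpcr.group_fold_summary(res)
        io.write_table(folds, out / "fold_summary.tsv")
        groups = [
            res.loc[res["group"] == g, "delta_ct"].to_numpy()
            for g in folds["group"]
        ]
        h, p = qpcr.kruskal_wallis(groups)
        log(
            "qpcr",
            table_hash=_file_hash(cfg.qpcr_table),
            reference=cfg.qpcr_reference,
            kw_h=f"{h:.4f}",
            kw_p=f"{p:.4g}",
        )
        return folds, h, p

    folds, h, p = run_stage("qpcr", stage_qpcr)
    for _, row in folds.iterrows():
        summary.append(
            f"qPCR mean fold vs {cfg.qpcr_reference}: {row['group']} = "
            f"{row['mean_fold']:.2f}"
        )
    summary.append(f"Kruskal-Wallis on delta-Ct: H={h:.2f}, P={p:.3g}")

    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    (out / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")
    return out
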