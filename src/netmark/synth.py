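"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: case/control
expression matrices with planted log2 fold changes, a scale-free
(preferential-attachment) interaction network with planted hubs, a
latent-factor co-expression module around a seed gene, survival times with
an expression-linked hazard, and multi-group qPCR Ct tables with planted
shifts.  Each generator is a pure function of its configuration: the RNG
stream is derived from ``(cfg.seed, call name)``, so adding calls never
perturbs earlier outputs and the same seed reproduces data bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = ["SynthConfig", "PlantedTruth", "ConfigError", "make_expression",
           "make_network", "make_coexpr_data", "make_survival", "make_qpcr"]


class ConfigError(ValueError):
    """A configuration field is outside its documented domain."""


# stable per-call stream identifiers; never renumber
_CALL_IDS = {
    "expression": 1,
    "network": 2,
    "coexpr": 3,
    "survival": 4,
    "qpcr": 5,
    "expression2": 6,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for all generators.

    Expression values are on the log2 scale; ``noise_sd`` is the per-gene
    residual SD in log2 units and ``planted_logfc`` the case-vs-control
    shift planted into DEG genes.  ``hazard_beta`` is the log hazard ratio
    between high- and low-expression strata; ``baseline_hazard`` is the
    event rate (1/time) of the low stratum.
    """

    n_genes: int = 500
    n_case: int = 20
    n_ctrl: int = 20
    deg_fraction: float = 0.05
    planted_logfc: float = 2.0
    noise_sd: float = 0.5
    hub_count: int = 6
    module_size: int = 10
    module_loading: float = 0.9
    hazard_beta: float = float(np.log(2.0))
    baseline_hazard: float = 0.2
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_case", "n_ctrl", "hub_count", "module_size"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ConfigError(f"deg_fraction must be in [0,1], got {self.deg_fraction}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.planted_logfc <= 0:
            raise ConfigError(f"planted_logfc must be > 0, got {self.planted_logfc}")
        if not 0.0 < self.module_loading <= 1.0:
            raise ConfigError(
                f"module_loading must be in (0,1], got {self.module_loading}"
            )
        if self.baseline_hazard <= 0:
            raise ConfigError(
                f"baseline_hazard must be > 0, got {self.baseline_hazard}"
            )
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError(f"censor_rate must be in [0,1), got {self.censor_rate}")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``deg_genes`` maps each planted DEG to its sign (+1 up in cases, -1
    down); ``module_genes`` always contains ``seed_gene``.
    """

    deg_genes: dict[str, int] = field(default_factory=dict)
    hub_genes: set[str] = field(default_factory=set)
    module_genes: set[str] = field(default_factory=set)
    seed_gene: str | None = None
    hazard_gene: str | None = None


def _rng(cfg: SynthConfig, call: str) -> np.random.Generator:
    return np.random.default_rng((int(cfg.seed) % (2**31), _CALL_IDS[call]))


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def make_expression(
    cfg: SynthConfig,
    deg_genes: dict[str, int] | None = None,
    genes: list[str] | None = None,
    stream: str = "expression",
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Case/control expression with planted log2 fold changes.

    Each gene gets a baseline drawn uniformly on [4, 12] log2 units plus
    Normal(0, noise_sd) measurement noise; planted DEG genes are shifted by
    ``sign * planted_logfc`` in case samples only.  By default a random
    ``deg_fraction`` of genes is planted with random signs; an explicit
    ``deg_genes`` mapping (gene -> +/-1) overrides the random choice, which
    is how demo datasets plant a specific biomarker.
    """
    cfg.validate()
    rng = _rng(cfg, stream)
    names = list(genes) if genes is not None else gene_names(cfg.n_genes)
    n_genes = len(names)
    samples = [f"case{i + 1}" for i in range(cfg.n_case)] + [
        f"ctrl{i + 1}" for i in range(cfg.n_ctrl)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}

    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(n_genes, len(samples))
    )

    if deg_genes is None:
        k = int(round(cfg.deg_fraction * n_genes))
        idx = rng.choice(n_genes, size=k, replace=False) if k else np.array([], int)
        signs = rng.choice([-1, 1], size=len(idx))
        deg_genes = {names[i]: int(s) for i, s in zip(idx, signs)}
    else:
        missing = set(deg_genes) - set(names)
        if missing:
            raise ConfigError(f"deg_genes not in gene list: {sorted(missing)}")
    pos = {g: i for i, g in enumerate(names)}
    for g, sign in deg_genes.items():
        values[pos[g], : cfg.n_case] += sign * cfg.planted_logfc

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=names, columns=samples), groups=groups
    )
    return matrix, PlantedTruth(deg_genes=dict(deg_genes))


def make_network(
    cfg: SynthConfig, m: int = 2, genes: list[str] | None = None
) -> tuple[nx.Graph, PlantedTruth]:
    """Preferential-attachment (scale-free) interaction network.

    ``m`` is the number of edges each newly attached node brings.  The
    planted hubs are the ``hub_count`` highest-degree nodes, ties broken by
    symbol so the truth is deterministic.
    """
    cfg.validate()
    if cfg.hub_count > cfg.n_genes:
        raise ConfigError(
            f"hub_count ({cfg.hub_count}) exceeds n_genes ({cfg.n_genes})"
        )
    rng = _rng(cfg, "network")
    g0 = nx.barabasi_albert_graph(
        cfg.n_genes, m, seed=int(rng.integers(2**31))
    )
    names = list(genes) if genes is not None else gene_names(cfg.n_genes)
    graph = nx.relabel_nodes(g0, dict(zip(range(cfg.n_genes), names)))
    ranked = sorted(graph.nodes(), key=lambda n: (-graph.degree(n), n))
    hubs = set(ranked[: cfg.hub_count])
    return graph, PlantedTruth(hub_genes=hubs)


def make_coexpr_data(
    cfg: SynthConfig,
    seed_gene: str,
    n_samples: int | None = None,
    genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Latent-factor co-expression module around a driver seed gene.

    A per-sample latent factor z ~ N(0,1) drives the module: the seed gene
    measures z directly (loading 1, residual SD ``noise_sd/2``) and every
    other module gene is ``module_loading * z + Normal(0, noise_sd)``.
    The seed therefore carries more information about each member than the
    members carry about each other — the member-member dependencies are
    mediated by the driver, which is exactly the indirect-edge structure
    that data-processing-inequality pruning removes.  Non-module genes are
    independent unit-variance noise.
    """
    cfg.validate()
    if cfg.module_size < 2:
        raise ConfigError(f"module_size must be >= 2, got {cfg.module_size}")
    if cfg.module_size > cfg.n_genes:
        raise ConfigError(
            f"module_size ({cfg.module_size}) exceeds n_genes ({cfg.n_genes})"
        )
    rng = _rng(cfg, "coexpr")
    names = list(genes) if genes is not None else gene_names(cfg.n_genes)
    if seed_gene not in names:
        names = [seed_gene] + names[: len(names) - 1]
    n = int(n_samples) if n_samples is not None else cfg.n_case + cfg.n_ctrl
    samples = [f"s{i + 1}" for i in range(n)]

    others = [g for g in names if g != seed_gene]
    members = [seed_gene] + list(
        rng.choice(others, size=cfg.module_size - 1, replace=False)
    )
    z = rng.normal(0.0, 1.0, size=n)
    baseline = rng.uniform(4.0, 12.0, size=len(names))
    values = np.empty((len(names), n))
    member_set = set(members)
    for i, g in enumerate(names):
        if g == seed_gene:
            values[i] = baseline[i] + z + rng.normal(0, cfg.noise_sd / 2.0, size=n)
        elif g in member_set:
            values[i] = (
                baseline[i]
                + cfg.module_loading * z
                + rng.normal(0, cfg.noise_sd, size=n)
            )
        else:
            values[i] = baseline[i] + rng.normal(0, 1.0, size=n)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=names, columns=samples),
        groups={s: "all" for s in samples},
    )
    return matrix, PlantedTruth(module_genes=member_set, seed_gene=seed_gene)


def make_survival(
    cfg: SynthConfig, n_subjects: int | None = None, gene: str = "G0001"
) -> pd.DataFrame:
    """Survival table with an expression-linked exponential hazard.

    Expression of the stratifying gene is N(8, 1); subjects above the
    median carry hazard ``baseline_hazard * exp(hazard_beta)``, the rest
    ``baseline_hazard``.  Censoring is administrative-uniform on
    [0, 2/baseline_hazard], applied to a ``censor_rate`` fraction of
    subjects drawn independently of the event process.
    """
    cfg.validate()
    rng = _rng(cfg, "survival")
    n = int(n_subjects) if n_subjects is not None else cfg.n_case + cfg.n_ctrl
    expr = rng.normal(8.0, 1.0, size=n)
    high = expr > np.median(expr)
    hazard = cfg.baseline_hazard * np.exp(cfg.hazard_beta * high.astype(float))
    event_time = rng.exponential(1.0 / hazard)
    t_max = 2.0 / cfg.baseline_hazard
    censored = rng.random(n) < cfg.censor_rate
    censor_time = np.where(censored, rng.uniform(0.0, t_max, size=n), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-9)  # times must be strictly positive
    return pd.DataFrame(
        {
            "subject": [f"subj{i + 1}" for i in range(n)],
            "time": time,
            "event": event,
            "expression": expr,
        }
    )


def make_qpcr(
    cfg: SynthConfig,
    group_shifts: dict[str, float],
    n_per_group: int = 8,
    hk_mean: float = 20.0,
    ct_sd: float = 0.25,
) -> pd.DataFrame:
    """Three-group (or k-group) Ct table with planted delta-Ct shifts.

    Housekeeping Ct ~ N(hk_mean, ct_sd); target Ct = housekeeping Ct +
    group shift + N(0, ct_sd).  ``ct_sd`` defaults to 0.25 cycles, the
    usual order of technical Ct variability.  A shift of -1 cycle relative
    to the calibrator group yields a planted fold change of 2.
    """
    cfg.validate()
    if len(group_shifts) < 2:
        raise ConfigError("need at least 2 groups for a comparative Ct table")
    if n_per_group < 2:
        raise ConfigError("need at least 2 samples per group")
    if ct_sd <= 0:
        raise ConfigError(f"ct_sd must be > 0, got {ct_sd}")
    rng = _rng(cfg, "qpcr")
    rows = []
    for group, shift in group_shifts.items():
        hk = rng.normal(hk_mean, ct_sd, size=n_per_group)
        target = hk + shift + rng.normal(0.0, ct_sd, size=n_per_group)
        for i in range(n_per_group):
            rows.append((f"{group}{i + 1}", group, target[i], hk[i]))
    return pd.DataFrame(
        rows, columns=["sample", "group", "ct_target", "ct_housekeeping"]
    )
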