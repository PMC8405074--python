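"""Case-vs-control differential expression.

Per-gene Welch two-sample t-tests on log2 expression with
Benjamini-Hochberg FDR control.  A gene is called differentially expressed
when |log2 fold change| is strictly greater than the cut (default 0.5) AND
the adjusted P is below alpha (default 0.05) — both criteria jointly.
The Welch statistic is the single substitution point should a moderated
(empirical-Bayes) test be preferred.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = ["test_gene", "bh_adjust", "call_degs"]


def test_gene(case_values, ctrl_values) -> tuple[float, float]:
    """Welch t-test of one gene: returns (log2 fold change, two-sided P).

    logFC = mean(case) - mean(ctrl) on log2 data.  When both groups have
    zero variance the test is degenerate: P is 1 for equal means and 0
    otherwise (the means differ with certainty under the model).
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need at least 2 values per group")
    if not (np.isfinite(case).all() and np.isfinite(ctrl).all()):
        raise ValueError("non-finite expression values")
    logfc = float(case.mean() - ctrl.mean())
    if case.std(ddof=1) == 0.0 and ctrl.std(ddof=1) == 0.0:
        return logfc, 1.0 if logfc == 0.0 else 0.0
    p = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    return logfc, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    matrix: ExpressionMatrix,
    logfc_cut: float = 0.5,
    alpha: float = 0.05,
    case_group: str | None = None,
) -> pd.DataFrame:
    """Per-gene DEG table: gene, logfc, p, p_adj, significant, direction.

    The matrix must carry exactly two groups; ``case_group`` names the
    group treated as cases (default: the label 'case' if present, else the
    first group level).
    """
    levels = matrix.group_levels
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    if case_group is None:
        case_group = "case" if "case" in levels else levels[0]
    if case_group not in levels:
        raise ValueError(f"case group {case_group!r} not among {levels}")
    ctrl_group = next(g for g in levels if g != case_group)
    case_cols = matrix.samples_in_group(case_group)
    ctrl_cols = matrix.samples_in_group(ctrl_group)

    case = matrix.values[case_cols].to_numpy()
    ctrl = matrix.values[ctrl_cols].to_numpy()
    rows = [test_gene(case[i], ctrl[i]) for i in range(case.shape[0])]
    logfc = np.array([r[0] for r in rows])
    p = np.array([r[1] for r in rows])
    p_adj = bh_adjust(p)
    significant = (np.abs(logfc) > logfc_cut) & (p_adj < alpha)
    direction = np.where(logfc > 0, "up", np.where(logfc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "logfc": logfc,
            "p": p,
            "p_adj": p_adj,
            "significant": significant,
            "direction": direction,
        }
    )
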