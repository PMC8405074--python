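"""Comparative Ct (delta-delta-Ct) quantification and group comparison.

Relative expression from qPCR cycle-threshold values under the classic
assumption of amplification efficiency 2: per sample,
dCt = Ct(target) - Ct(housekeeping); ddCt = dCt minus the calibrator
group's mean dCt; fold change = 2^(-ddCt).  Groups are compared with the
nonparametric Kruskal-Wallis rank test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_delta_ct", "kruskal_wallis", "group_fold_summary"]


def delta_delta_ct(table: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Per-sample ddCt and fold change against the calibrator group.

    Returns columns sample, group, delta_ct, ddct, fold.  The calibrator
    (reference) group's mean ddCt is 0 by construction, hence its
    group-level fold is exactly 1.
    """
    groups = set(table["group"])
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in table")
    if (table["group"] == reference_group).sum() < 2:
        raise ValueError("reference group needs at least 2 samples")
    out = table[["sample", "group"]].copy()
    out["delta_ct"] = table["ct_target"].to_numpy() - table[
        "ct_housekeeping"
    ].to_numpy()
    ref_mean = out.loc[out["group"] == reference_group, "delta_ct"].mean()
    out["ddct"] = out["delta_ct"] - ref_mean
    out["fold"] = 2.0 ** (-out["ddct"])
    return out


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square P on k-1 df.

    All values globally identical is a defined degenerate case: H = 0,
    P = 1 (no evidence of any group difference).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 values per group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def group_fold_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-group geometric-mean fold change with log-scale dispersion.

    The geometric mean of the folds equals 2^(-mean ddCt) exactly; the
    dispersion column is the geometric SD factor 2^(SD of ddCt).
    """
    rows = []
    for group, sub in results.groupby("group", sort=False):
        mean_ddct = sub["ddct"].mean()
        sd_ddct = sub["ddct"].std(ddof=1) if len(sub) > 1 else 0.0
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "mean_fold": 2.0 ** (-mean_ddct),
                "gsd_factor": 2.0**sd_ddct,
            }
        )
    return pd.DataFrame(rows)
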