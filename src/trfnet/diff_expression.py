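"""Two-group differential expression with class-specific fold-change filters.

Matrices are normalized to counts-per-million, fold change is the ratio of
pseudocounted group means, and the p-value comes from a two-sided pooled
(equal-variance) t-test on log2(x+1); at the study's three replicates per
group the pooled test stays calibrated where the Welch approximation is
conservative. An mRNA is called differentially expressed at fold
change >= 2.0 or <= 0.5 with p < 0.05; small RNAs (miRNAs and tRF/tiRNAs)
use the more permissive 1.2-fold criterion at the same alpha. No multiple
testing correction is applied by default, matching the raw-p criterion;
Benjamini-Hochberg q-values are available via ``fdr="bh"``.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: fold-change thresholds per feature class
CLASS_THRESHOLDS: dict[str, float] = {"mRNA": 2.0, "miRNA": 1.2, "tRF": 1.2}
DEFAULT_ALPHA = 0.05
PSEUDOCOUNT = 1.0


def split_groups(matrix: pd.DataFrame,
                 samples: Optional[pd.DataFrame] = None
                 ) -> tuple[list[str], list[str]]:
    """Resolve control/treated columns from ``_ctrl``/``_trt`` suffixes or a
    two-column (sample, group) table."""
    if samples is not None:
        lookup = dict(zip(samples.iloc[:, 0], samples.iloc[:, 1]))
        ctrl = [c for c in matrix.columns if lookup.get(c) == "control"]
        trt = [c for c in matrix.columns if lookup.get(c) == "treated"]
    else:
        ctrl = [c for c in matrix.columns if c.endswith("_ctrl")]
        trt = [c for c in matrix.columns if c.endswith("_trt")]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 replicates in each group")
    return ctrl, trt


def normalize_cpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample column so it sums to exactly 1e6."""
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative")
    sums = matrix.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {', '.join(zero.index)}")
    return matrix * (1e6 / sums)


def de_test(
    matrix: pd.DataFrame,
    feature_class: str = "mRNA",
    alpha: float = DEFAULT_ALPHA,
    threshold: Optional[float] = None,
    samples: Optional[pd.DataFrame] = None,
    fdr: Optional[str] = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature fold change, t-test p-value and direction call.

    fold_change = (mean treated + eps) / (mean control + eps); the test is a
    two-sided pooled-variance t on log2(value + 1). ``direction`` is ``up``
    when
    fold_change >= threshold and p < alpha, ``down`` when
    fold_change <= 1/threshold and p < alpha, else ``ns``.
    """
    if threshold is None:
        threshold = CLASS_THRESHOLDS[feature_class]
    ctrl_cols, trt_cols = split_groups(matrix, samples)
    ctrl = matrix[ctrl_cols].to_numpy(float)
    trt = matrix[trt_cols].to_numpy(float)

    mean_ctrl = ctrl.mean(axis=1)
    mean_trt = trt.mean(axis=1)
    fc = (mean_trt + pseudocount) / (mean_ctrl + pseudocount)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(np.log2(trt + 1.0), np.log2(ctrl + 1.0),
                               axis=1, equal_var=True)
    # identical constant groups yield an indeterminate t; call them null
    p = np.where(np.isnan(p), 1.0, p)

    res = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p_value": p,
            "mean_control": mean_ctrl,
            "mean_treated": mean_trt,
        },
        index=matrix.index.rename("feature"),
    )
    if fdr == "bh":
        res["q_value"] = multipletests(p, method="fdr_bh")[1]
    sig = res["p_value"] < alpha
    direction = np.where(sig & (fc >= threshold), "up",
                         np.where(sig & (fc <= 1.0 / threshold), "down", "ns"))
    res["direction"] = direction
    res["feature_class"] = feature_class
    return res


def summarize_de(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-class up/down/total counts, rows Upregulated/Downregulated/Sum."""
    table = {}
    for cls, df in results.items():
        n_up = int((df["direction"] == "up").sum())
        n_down = int((df["direction"] == "down").sum())
        table[f"DE {cls}"] = [n_up, n_down, n_up + n_down]
    return pd.DataFrame(table, index=["Upregulated", "Downregulated", "Sum"])
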