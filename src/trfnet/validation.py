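"""Relative qPCR quantification by the Livak 2^-ddCt method and the group
comparison statistics used on the resulting RQ values.

Per sample: dCt = Ct_target - Ct_reference; ddCt = dCt minus the arithmetic
mean dCt of the calibrator group; RQ = 2^-ddCt, so the calibrator group's
geometric-mean RQ is 1 by construction. Amplification efficiency is fixed at
2 (the method's exponent base). Group comparisons use Student's t for two
groups and one-way ANOVA with Tukey's HSD post hoc for more.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    return df


def _validate_ct(df: pd.DataFrame) -> None:
    for col in ("ct_target", "ct_reference"):
        bad = df.loc[df[col].isna(), "sample"].tolist()
        if bad:
            raise ValueError(f"missing {col} for sample(s): {bad}")
        out = df.loc[~df[col].between(0, 45, inclusive="neither"), "sample"]
        if len(out):
            raise ValueError(f"{col} outside (0, 45) for sample(s): "
                             f"{out.tolist()}")
    counts = df.groupby("group")["sample"].count()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with < 2 samples: {small.index.tolist()}")


def ddct(table: pd.DataFrame, calibrator_group: str = "control"
         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample RQ values plus per-group mean ± SD.

    Returns ``(per_sample, per_group)`` where ``per_sample`` adds dct, ddct
    and rq columns and ``per_group`` holds mean, SD and geometric mean of RQ.
    """
    _validate_ct(table)
    if calibrator_group not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    out = table.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    calib_mean = out.loc[out["group"] == calibrator_group, "dct"].mean()
    out["ddct"] = out["dct"] - calib_mean
    out["rq"] = 2.0 ** (-out["ddct"])
    grp = out.groupby("group")["rq"].agg(
        mean="mean", sd="std",
        geo_mean=lambda v: float(np.exp(np.mean(np.log(v)))),
        n="count").reset_index()
    return out, grp


def group_compare(values: Mapping[str, Sequence[float]]) -> dict:
    """Two groups: two-sided Student t. More: one-way ANOVA + Tukey HSD.

    Returns a dict with ``test``, the statistic and p-value, and for ANOVA a
    ``pairwise`` table of Tukey-adjusted p-values.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 values")
    names = list(groups)
    arrays = [groups[g] for g in names]
    if len(groups) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return {"test": "student_t", "statistic": float(t),
                "p_value": float(p), "groups": names}
    f, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise.append({"group_a": names[i], "group_b": names[j],
                             "p_adj": float(tukey.pvalue[i, j])})
    return {"test": "anova_tukey", "statistic": float(f),
            "p_value": float(p), "groups": names,
            "pairwise": pd.DataFrame(pairwise)}
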