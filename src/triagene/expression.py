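"""Expression-level validation: differential expression and differential
co-expression between case and control samples.

Per-gene group differences use the classical pooled-variance Student t test
(two-sided; Welch available by flag). Co-expression of a focal gene panel is
the within-group Pearson correlation matrix, and the differential signal is
the case-minus-control correlation change per gene pair.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

CASE, CONTROL = "case", "control"


def _split_groups(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups, dtype=object)
    labels = set(groups)
    if labels != {CASE, CONTROL}:
        raise ValueError(f"need exactly the groups {{case, control}}, got {sorted(labels)}")
    case = groups == CASE
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    return case, ~case


def dge_ttest(expr: pd.DataFrame, groups: np.ndarray,
              genes: list[str] | None = None,
              welch: bool = False) -> pd.DataFrame:
    """Two-sample t test per gene (case vs control), two-sided.

    Returns columns GENE, MEAN_CASE, MEAN_CONTROL, T, P, FLAG sorted by P;
    genes with zero variance in both groups get NA with a 'constant' flag.
    The t statistic is signed case minus control.
    """
    case, ctrl = _split_groups(groups)
    if genes is not None:
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise ValueError(f"genes absent from expression matrix: {missing}")
        expr = expr.loc[genes]
    x = expr.to_numpy(dtype=float)
    xc, xk = x[:, ctrl], x[:, case]
    var0 = (xc.std(axis=1) == 0) & (xk.std(axis=1) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
        t, p = stats.ttest_ind(xk, xc, axis=1, equal_var=not welch)
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    t[var0], p[var0] = np.nan, np.nan
    out = pd.DataFrame({
        "GENE": expr.index, "MEAN_CASE": xk.mean(axis=1),
        "MEAN_CONTROL": xc.mean(axis=1), "T": t, "P": p,
        "FLAG": np.where(var0, "constant", ""),
    })
    return out.sort_values(["P", "GENE"], kind="mergesort", na_position="last"
                           ).reset_index(drop=True)


def coexpression_compare(expr: pd.DataFrame, groups: np.ndarray,
                         focal: list[str]) -> dict:
    """Within-group Pearson correlation of a focal panel and its change.

    Returns {'r_control', 'r_case': DataFrames (genes x genes),
    'pairs': DataFrame GENE_A, GENE_B, R_CONTROL, R_CASE, DELTA sorted by
    |DELTA| descending}. Requires >= 3 samples per group.
    """
    missing = [g for g in focal if g not in expr.index]
    if missing:
        raise ValueError(f"focal genes absent from expression matrix: {missing}")
    if len(focal) < 2:
        raise ValueError("need at least 2 focal genes")
    case, ctrl = _split_groups(groups)
    if case.sum() < 3 or ctrl.sum() < 3:
        raise ValueError("Pearson comparison needs >= 3 samples per group")
    sub = expr.loc[focal].to_numpy(dtype=float)
    r_ctrl = np.corrcoef(sub[:, ctrl])
    r_case = np.corrcoef(sub[:, case])
    rc = pd.DataFrame(r_ctrl, index=focal, columns=focal)
    rk = pd.DataFrame(r_case, index=focal, columns=focal)
    rows = []
    for i, j in itertools.combinations(range(len(focal)), 2):
        rows.append((focal[i], focal[j], r_ctrl[i, j], r_case[i, j],
                     r_case[i, j] - r_ctrl[i, j]))
    pairs = pd.DataFrame(rows, columns=["GENE_A", "GENE_B", "R_CONTROL",
                                        "R_CASE", "DELTA"])
    pairs = pairs.reindex(pairs["DELTA"].abs().sort_values(
        ascending=False, kind="mergesort").index).reset_index(drop=True)
    return {"r_control": rc, "r_case": rk, "pairs": pairs}
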