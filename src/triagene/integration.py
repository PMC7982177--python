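"""Cross-stage integration: gene-set intersection, overlap permutation test,
and the real-vs-null comparative analysis.

The overlap permutation asks whether two gene sets share more members than
chance: the observed overlap N_observation is compared with the overlap
N_random of ``n_trials`` random draws of |set_b| genes from the background
universe (N_total genes). Two empirical p-values are reported: direction
``ge`` — the standard enrichment tail (1 + #{N_random >= N_observation}) /
(1 + n_trials) — and direction ``le``, its complement-style counterpart.
Both are computed because published descriptions of this procedure sometimes
state the counting rule with the opposite inequality from the enrichment
question actually being asked; ``ge`` is the default interpretation.

The comparative analysis contrasts, at several p-value cut points, how often
Bayesian-stage genes replicate in the gene-based scan of the real trait
versus the null trait, and tests the paired rate differences with a paired
Student t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CUT_POINTS = (0.05, 0.01, 0.001)
DEFAULT_N_TRIALS = 100_000


@dataclass
class PermutationResult:
    n_observation: int
    n_total: int
    n_trials: int
    n_count_ge: int  # trials with N_random >= N_observation
    n_count_le: int  # trials with N_random <= N_observation
    empirical_p_ge: float
    empirical_p_le: float

    def to_dict(self) -> dict:
        return {
            "N_observation": self.n_observation, "N_total": self.n_total,
            "n_trials": self.n_trials,
            "empirical_p_ge": self.empirical_p_ge,
            "empirical_p_le": self.empirical_p_le,
        }


def intersect_genesets(sets: list[list[str]]) -> list[str]:
    """Exact intersection of two or more gene lists, sorted."""
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets to intersect")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    return sorted(common)


def overlap_permutation(set_a: list[str], set_b: list[str], universe: list[str],
                        n_trials: int = DEFAULT_N_TRIALS,
                        seed: int = 0) -> PermutationResult:
    """Permutation test of the overlap between two gene sets.

    Each trial draws |set_b| genes uniformly without replacement from the
    universe and counts the overlap with set_a. Genes of set_b outside the
    universe are dropped with a warning.
    """
    uni = list(dict.fromkeys(universe))  # order-stable dedup
    uni_set = set(uni)
    if len(set(set_b)) > len(uni):
        raise ValueError("set_b larger than the universe")
    b = [g for g in dict.fromkeys(set_b) if g in uni_set]
    dropped = len(set(set_b)) - len(b)
    if dropped:
        warnings.warn(f"dropped {dropped} set_b genes outside the universe")
    k = len(b)
    if k > len(uni):
        raise ValueError("set_b larger than the universe")
    a_set = set(set_a)
    n_obs = len(a_set & set(b))
    a_mask = np.fromiter((g in a_set for g in uni), dtype=bool, count=len(uni))
    n_a = int(a_mask.sum())
    rng = np.random.default_rng(seed)
    n_uni = len(uni)
    counts = np.empty(n_trials, dtype=np.int64)
    if k == 0:
        counts[:] = 0
    else:
        # overlap of a uniform without-replacement draw with set_a is a
        # draw of k items from n_a marked / n_uni total: count the marked.
        idx_of_a = np.flatnonzero(a_mask)
        marked = np.zeros(n_uni, dtype=bool)
        marked[idx_of_a] = True
        for t in range(n_trials):
            draw = rng.choice(n_uni, size=k, replace=False)
            counts[t] = int(marked[draw].sum())
    n_ge = int(np.count_nonzero(counts >= n_obs))
    n_le = int(np.count_nonzero(counts <= n_obs))
    return PermutationResult(
        n_observation=n_obs, n_total=len(uni), n_trials=n_trials,
        n_count_ge=n_ge, n_count_le=n_le,
        empirical_p_ge=(1 + n_ge) / (1 + n_trials),
        empirical_p_le=(1 + n_le) / (1 + n_trials),
    )


def comparative_overlap(sherlock_results: list[pd.DataFrame],
                        real_gba: pd.DataFrame, null_gba: pd.DataFrame,
                        cut_points: tuple[float, ...] = DEFAULT_CUT_POINTS,
                        gba_alpha: float = 0.05) -> dict:
    """Replication-rate comparison of Bayesian-stage genes against the real-
    and null-trait gene-based scans.

    For each Bayesian results table (columns GENE, SIM_P) and each cut point
    c, the subgroup is the genes with SIM_P <= c; its rate against a scan is
    the fraction of subgroup genes significant there (EMP_P <= gba_alpha).
    Paired Student t over the (real, null) rate pairs across tables x cut
    points. Empty subgroups yield NA rates and drop the pair with a warning.
    """
    sig_real = set(real_gba.loc[real_gba["EMP_P"] <= gba_alpha, "GENE"])
    sig_null = set(null_gba.loc[null_gba["EMP_P"] <= gba_alpha, "GENE"])
    rows, pairs = [], []
    for ti, tab in enumerate(sherlock_results):
        for c in cut_points:
            sub = set(tab.loc[tab["SIM_P"] <= c, "GENE"])
            if not sub:
                warnings.warn(f"empty subgroup at cut point {c}; pair dropped")
                rows.append((ti, c, len(sub), np.nan, np.nan))
                continue
            r_real = len(sub & sig_real) / len(sub)
            r_null = len(sub & sig_null) / len(sub)
            rows.append((ti, c, len(sub), r_real, r_null))
            pairs.append((r_real, r_null))
    table = pd.DataFrame(rows, columns=["TABLE", "CUT_POINT", "N_SUBGROUP",
                                        "RATE_REAL", "RATE_NULL"])
    if len(pairs) < 2:
        raise ValueError("paired t test needs at least 2 rate pairs")
    real = np.array([p[0] for p in pairs])
    null = np.array([p[1] for p in pairs])
    t, p = paired_t(real, null)
    return {"table": table, "t": t, "p": p, "n_pairs": len(pairs)}


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Paired Student t: t = mean(d) / (sd(d)/sqrt(m)), two-sided p.

    All-zero differences give t = 0, p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    m = d.size
    if m < 2:
        raise ValueError("paired t test undefined for a single pair")
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if np.allclose(d, 0) else (np.inf * np.sign(d.mean()), 0.0)
    t = d.mean() / (sd / np.sqrt(m))
    p = 2 * stats.t.sf(abs(t), df=m - 1)
    return float(t), float(p)
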