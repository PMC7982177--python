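"""Bayesian eSNP-to-gene scoring of GWAS signal (Sherlock-style inference).

A gene's expression "signature" is the set of SNPs significantly associated
with its expression (eSNPs, cis or trans). Each eSNP is scored by how strongly
the same SNP is associated with the trait in the GWAS: an approximate Bayes
factor computed from the GWAS z-score,

    log10 BF(z) = 0.5*log10(1/(1+W)) + (z^2/2) * (W/(1+W)) * log10(e),

where ``W`` is the prior variance of the standardized trait effect and
``z = Phi^-1(1 - p/2)``. Weak GWAS signal (small z) yields a negative score,
strong signal a positive one, and a SNP with trait association but no eQTL
evidence contributes nothing because it is never an eSNP. The per-gene
evidence is the sum of its eSNP scores plus the prior log-odds
``log10(alpha/(1-alpha))`` of a SNP being trait-associated, with separate
priors for cis and trans eSNPs.

This scoring is a reconstruction of the published Bayesian framework from its
qualitative contract (the exact published Bayes-factor algebra integrates over
genotype data not available from summary statistics); ``W`` and the priors
are configurable.

Significance is empirical: the gene's score is recomputed ``n_sim`` times with
its eSNPs' GWAS p-values replaced by draws (without replacement, matching the
gene's cis/trans composition) from the pool of all GWAS p-values, and the
simulated P is the add-one tail proportion of resampled scores reaching the
observed one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOG10_E = np.log10(np.e)
MIN_P = 1e-300


@dataclass
class SherlockPriors:
    """Prior configuration.

    alpha_* are the prior probabilities of a SNP being trait-associated
    (cis/trans eSNPs); beta is the prior probability of a SNP being an eQTL
    (carried for completeness; it cancels for fixed eSNP sets); W is the
    prior variance of the standardized effect.
    """

    alpha_cis: float = 1.0e-3
    alpha_trans: float = 5.0e-5
    beta: float = 1.0e-3
    W: float = 0.1
    esnp_threshold: float = 1.0e-5
    n_sim: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha_trans <= self.alpha_cis < 1):
            raise ValueError("require 0 < alpha_trans <= alpha_cis < 1")
        if not (0 < self.beta < 1):
            raise ValueError("beta must lie in (0, 1)")
        if self.W <= 0:
            raise ValueError("W must be positive")
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")


def detect_esnps(eqtl: pd.DataFrame, gwas: pd.DataFrame,
                 priors: SherlockPriors) -> pd.DataFrame:
    """eSNP records: eQTL rows passing the threshold, joined to GWAS by rsID.

    Returns columns SNP, GENE, EQTL_P, TYPE, GWAS_P sorted by gene. eSNPs
    absent from the GWAS (or with missing GWAS p) are dropped; the count is
    logged and exposed as ``result.attrs['n_unmatched']``. Duplicate
    (SNP, GENE) rows keep the smallest eQTL p with a warning.
    """
    if "TYPE" not in eqtl.columns or eqtl["TYPE"].isna().any():
        raise ValueError("eQTL table must label every row cis or trans")
    bad = set(eqtl["TYPE"].unique()) - {"cis", "trans"}
    if bad:
        raise ValueError(f"unknown eQTL TYPE labels: {sorted(bad)}")
    hits = eqtl[eqtl["P"] <= priors.esnp_threshold].copy()
    n_dup = hits.duplicated(subset=["SNP", "GENE"]).sum()
    if n_dup:
        warnings.warn(f"{n_dup} duplicate (SNP, GENE) eQTL rows; keeping smallest p")
        hits = (hits.sort_values("P", kind="mergesort")
                    .drop_duplicates(subset=["SNP", "GENE"], keep="first"))
    gw = gwas[["SNP", "P"]].dropna(subset=["P"]).rename(columns={"P": "GWAS_P"})
    merged = hits.rename(columns={"P": "EQTL_P"}).merge(gw, on="SNP", how="left")
    unmatched = merged["GWAS_P"].isna()
    n_unmatched = int(unmatched.sum())
    if n_unmatched:
        logger.info("dropped %d eSNPs absent from the GWAS table", n_unmatched)
    out = (merged[~unmatched]
           .sort_values(["GENE", "EQTL_P"], kind="mergesort")
           .reset_index(drop=True)[["SNP", "GENE", "EQTL_P", "TYPE", "GWAS_P"]])
    out.attrs["n_unmatched"] = n_unmatched
    return out


def snp_log10_bf(gwas_p, W: float = 0.1):
    """Approximate log10 Bayes factor of a SNP from its GWAS p-value.

    Strictly decreasing in p; negative at z = 0 and -> 0 as W -> 0.
    """
    p = np.asarray(gwas_p, dtype=float)
    if np.any(p > 1):
        raise ValueError("gwas_p > 1")
    if np.any(p <= 0):
        warnings.warn("gwas_p of 0 clamped to smallest representable value")
        p = np.clip(p, MIN_P, 1.0)
    z = stats.norm.isf(p / 2)
    shrink = W / (1.0 + W)
    out = 0.5 * np.log10(1.0 / (1.0 + W)) + (z * z / 2.0) * shrink * LOG10_E
    return out if out.ndim else float(out)


def _prior_logodds(kinds: np.ndarray, priors: SherlockPriors) -> np.ndarray:
    a = np.where(kinds == "cis", priors.alpha_cis, priors.alpha_trans)
    return np.log10(a / (1.0 - a))


def score_gene(esnps: pd.DataFrame, priors: SherlockPriors) -> float:
    """Gene log10 Bayes factor: sum over its eSNPs of BF plus prior log-odds.

    An empty eSNP list is an error — a gene without eSNPs has no score, no
    matter how significant nearby trait SNPs are.
    """
    if len(esnps) == 0:
        raise ValueError("gene has no eSNPs; no score is assigned")
    bf = snp_log10_bf(esnps["GWAS_P"].to_numpy(), priors.W)
    return float(np.sum(bf) + np.sum(_prior_logodds(esnps["TYPE"].to_numpy(), priors)))


def _sample_without_replacement(rng: np.random.Generator, pool_size: int,
                                k: int, n_sim: int) -> np.ndarray:
    """(n_sim, k) index matrix, each row k distinct draws from range(pool_size)."""
    if k > pool_size:
        raise ValueError("pool smaller than the number of eSNPs")
    idx = rng.integers(pool_size, size=(n_sim, k))
    if k > 1:
        for _ in range(64):
            srt = np.sort(idx, axis=1)
            dup = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
            if not dup.any():
                break
            idx[dup] = rng.integers(pool_size, size=(int(dup.sum()), k))
    return idx


def simulated_p(gene_lbf: float, n_cis: int, n_trans: int,
                gwas_p_pool: np.ndarray, priors: SherlockPriors,
                rng: np.random.Generator | None = None) -> float:
    """Empirical significance of a gene score under resampled GWAS p-values.

    Each of ``n_sim`` trials redraws the gene's eSNP count of p-values without
    replacement from the pool (cis/trans composition fixed) and recomputes the
    score; returns (1 + #{score_sim >= score_obs}) / (n_sim + 1).
    """
    if rng is None:
        rng = np.random.default_rng(priors.seed)
    pool = np.asarray(gwas_p_pool, dtype=float)
    pool = pool[~np.isnan(pool)]
    k = n_cis + n_trans
    if k < 1:
        raise ValueError("gene has no eSNPs")
    idx = _sample_without_replacement(rng, pool.size, k, priors.n_sim)
    bf = snp_log10_bf(pool[idx.ravel()], priors.W).reshape(priors.n_sim, k)
    const = (n_cis * np.log10(priors.alpha_cis / (1 - priors.alpha_cis))
             + n_trans * np.log10(priors.alpha_trans / (1 - priors.alpha_trans)))
    sim = bf.sum(axis=1) + const
    return float((1 + np.count_nonzero(sim >= gene_lbf)) / (priors.n_sim + 1))


def sherlock_analysis(eqtl: pd.DataFrame, gwas: pd.DataFrame,
                      priors: SherlockPriors) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full stage: eSNP detection, per-gene scoring, simulated significance.

    Returns ``(results, support)``: results has columns GENE, LBF, N_ESNPS,
    SIM_P sorted by SIM_P then gene; support lists each gene's eSNPs with
    their eQTL and GWAS p-values.
    """
    esnps = detect_esnps(eqtl, gwas, priors)
    pool = gwas["P"].dropna().to_numpy()
    rng = np.random.default_rng(priors.seed)
    rows = []
    for gene, grp in esnps.groupby("GENE", sort=True):
        lbf = score_gene(grp, priors)
        n_cis = int((grp["TYPE"] == "cis").sum())
        n_trans = len(grp) - n_cis
        sp = simulated_p(lbf, n_cis, n_trans, pool, priors, rng=rng)
        rows.append((gene, lbf, len(grp), sp))
    results = pd.DataFrame(rows, columns=["GENE", "LBF", "N_ESNPS", "SIM_P"])
    results = (results.sort_values(["SIM_P", "GENE"], kind="mergesort")
                      .reset_index(drop=True))
    support = esnps.rename(columns={"TYPE": "KIND"})[
        ["GENE", "SNP", "KIND", "EQTL_P", "GWAS_P"]]
    return results, support
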