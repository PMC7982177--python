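"""Negative-control GWAS: random phenotype labels and per-SNP logistic regression.

The null trait is built by assigning each sample an i.i.d. Bernoulli case
label, severing any genotype-phenotype link; the per-SNP association scan on
those labels is the pipeline's negative control. The same scan also produces
the "real" GWAS summary table for synthetic studies with planted effects.

``logistic_assoc`` fits the single-covariate model
``logit P(y=1) = a + b * g`` (additive dosage coding) independently for every
SNP, with all SNPs advanced in parallel by Newton-Raphson (the 2x2 observed
information has a closed-form inverse). P-values come from the Wald or
likelihood-ratio test. Monomorphic SNPs are reported with p = NA; SNPs whose
fit diverges (complete separation) fall back to Fisher's exact test on the
carrier-collapsed 2x2 table. Both conditions are flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAX_ITER = 40
TOL = 1e-10
SEPARATION_BETA = 15.0  # |log-OR| beyond this is numerically a separation


@dataclass
class NullGwasConfig:
    seed: int = 0
    case_label_prob: float = 0.5
    test: str = "wald"  # or "lrt"

    def __post_init__(self):
        if not (0 < self.case_label_prob < 1):
            raise ValueError("case_label_prob must lie in (0, 1)")
        if self.test not in ("wald", "lrt"):
            raise ValueError("test must be 'wald' or 'lrt'")


def randomize_phenotype(n_samples: int, config: NullGwasConfig) -> np.ndarray:
    """I.i.d. Bernoulli(case_label_prob) 0/1 labels, reproducible by seed."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples to randomize a phenotype")
    rng = np.random.default_rng(config.seed)
    return rng.binomial(1, config.case_label_prob, size=n_samples).astype(np.int8)


def _fisher_dominant(g: np.ndarray, y: np.ndarray) -> float:
    """Fisher's exact p on the carrier-collapsed (g>0) x case table."""
    carrier = g > 0
    table = [[int(((y == 1) & carrier).sum()), int(((y == 1) & ~carrier).sum())],
             [int(((y == 0) & carrier).sum()), int(((y == 0) & ~carrier).sum())]]
    return float(stats.fisher_exact(table)[1])


def logistic_assoc(genotypes: np.ndarray, labels: np.ndarray,
                   test: str = "wald",
                   snp_ids: list[str] | None = None,
                   chrom: list[str] | None = None,
                   positions: np.ndarray | None = None,
                   chunk: int = 1024) -> pd.DataFrame:
    """Per-SNP logistic regression scan.

    Returns a GWAS summary DataFrame with columns SNP, CHR, BP, P and a FLAG
    column ('' | 'monomorphic' | 'separation').
    """
    g_all = np.asarray(genotypes, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if g_all.ndim != 2 or g_all.shape[0] != y.shape[0]:
        raise ValueError("genotypes must be samples x SNPs aligned with labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; association is undefined")
    if not set(classes).issubset({0.0, 1.0}):
        raise ValueError("labels must be binary 0/1")

    n, m = g_all.shape
    pvals = np.full(m, np.nan)
    flags = np.array([""] * m, dtype=object)
    ybar = y.mean()
    ll0 = n * (ybar * np.log(ybar) + (1 - ybar) * np.log1p(-ybar))

    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        g = g_all[:, lo:hi]
        mono = g.std(axis=0) == 0
        a = np.full(hi - lo, np.log(ybar / (1 - ybar)))
        b = np.zeros(hi - lo)
        for _ in range(MAX_ITER):
            eta = a + b * g
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1 - p)
            r = y[:, None] - p
            ga, gb = r.sum(axis=0), (g * r).sum(axis=0)
            iaa, iab, ibb = w.sum(axis=0), (w * g).sum(axis=0), (w * g * g).sum(axis=0)
            det = iaa * ibb - iab * iab
            det = np.where(np.abs(det) < 1e-300, np.nan, det)
            da = (ibb * ga - iab * gb) / det
            db = (-iab * ga + iaa * gb) / det
            da, db = np.nan_to_num(da), np.nan_to_num(db)
            a, b = a + da, b + db
            if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < TOL:
                break
        eta = a + b * g
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        iaa, iab, ibb = w.sum(axis=0), (w * g).sum(axis=0), (w * g * g).sum(axis=0)
        det = iaa * ibb - iab * iab
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(iaa / det)
            if test == "wald":
                pv = 2 * stats.norm.sf(np.abs(b / se))
            elif test == "lrt":
                eps = 1e-300
                ll1 = (y[:, None] * np.log(p + eps)
                       + (1 - y[:, None]) * np.log(1 - p + eps)).sum(axis=0)
                pv = stats.chi2.sf(2 * (ll1 - ll0), df=1)
            else:
                raise ValueError("test must be 'wald' or 'lrt'")
        sep = (~mono) & (~np.isfinite(pv) | (np.abs(b) > SEPARATION_BETA))
        for j in np.flatnonzero(sep):
            pv[j] = _fisher_dominant(g_all[:, lo + j], y)
        pv[mono] = np.nan
        pvals[lo:hi] = pv
        flags[lo:hi][mono] = "monomorphic"
        flags[lo:hi][sep] = "separation"

    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(m)]
    if chrom is None:
        chrom = ["1"] * m
    if positions is None:
        positions = np.arange(m)
    return pd.DataFrame({
        "SNP": snp_ids, "CHR": chrom, "BP": np.asarray(positions),
        "P": pvals, "FLAG": flags,
    })


def null_gwas(genotypes: np.ndarray, config: NullGwasConfig,
              snp_ids: list[str] | None = None,
              chrom: list[str] | None = None,
              positions: np.ndarray | None = None) -> pd.DataFrame:
    """Randomize the phenotype and scan: the full negative-control construction."""
    labels = randomize_phenotype(genotypes.shape[0], config)
    return logistic_assoc(genotypes, labels, test=config.test,
                          snp_ids=snp_ids, chrom=chrom, positions=positions)
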