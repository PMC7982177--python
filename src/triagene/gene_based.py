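"""Gene-based association from GWAS summary statistics with an LD-aware null.

SNPs are assigned to a gene if they fall in the gene body or within a
symmetric flanking window (default 20 kb; coordinates 0-based half-open, so a
SNP at ``start - window`` is included and one at ``start - window - 1`` is
not). The gene statistic is the snp-wise mean chi-square: each SNP p-value is
converted to its 1-df chi-square quantile and averaged. Significance is
empirical: null z-vectors are drawn from MVN(0, R) with R the SNP-SNP LD
matrix estimated from a reference dosage panel, the statistic recomputed, and
the add-one tail proportion reported. This is the summary-statistic gene
model (mean-chi-square with an MVN null) rather than a raw-genotype
regression, so it needs only p-values, positions and a reference panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

DEFAULT_WINDOW_KB = 20.0


@dataclass
class GeneAssocResult:
    gene: str
    n_snps: int
    stat: float
    empirical_p: float


def map_snps_to_genes(gwas: pd.DataFrame, annotation: pd.DataFrame,
                      window_kb: float = DEFAULT_WINDOW_KB) -> dict[str, list[str]]:
    """Map each gene to the SNPs inside its windowed span.

    A SNP may map to several genes. Chromosome labels present in the GWAS but
    absent from the annotation (or vice versa) raise an error naming them.
    """
    window = int(round(window_kb * 1000))
    gwas_chroms = set(map(str, gwas["CHR"].unique()))
    ann_chroms = set(map(str, annotation["chrom"].unique()))
    if gwas_chroms != ann_chroms:
        raise ValueError(
            "chromosome label mismatch: GWAS-only "
            f"{sorted(gwas_chroms - ann_chroms)}, annotation-only "
            f"{sorted(ann_chroms - gwas_chroms)}")
    trees: dict[str, IntervalTree] = {}
    for _, row in annotation.iterrows():
        lo = int(row["start"]) - window
        hi = int(row["end"]) + window  # half-open: [start-w, end+w)
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(lo, hi, row["gene"])
    mapping: dict[str, list[str]] = {g: [] for g in annotation["gene"]}
    for snp, chrom, pos in zip(gwas["SNP"], gwas["CHR"].astype(str), gwas["BP"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree[int(pos)]:
            mapping[iv.data].append(snp)
    return mapping


def nearest_psd(mat: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues; keeps the diagonal close to 1."""
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    return (v * np.clip(w, eps, None)) @ v.T


def gene_empirical_p(snp_ps: np.ndarray, ld: np.ndarray, n_perm: int = 10_000,
                     seed: int = 0, gene: str = "") -> GeneAssocResult | None:
    """Mean-chi-square gene statistic with an MVN(0, LD) permutation null.

    Returns None (gene skipped) for an empty SNP list. A non-PSD LD matrix is
    projected to the nearest PSD matrix with a warning.
    """
    ps = np.asarray(snp_ps, dtype=float)
    ps = ps[~np.isnan(ps)]
    if ps.size == 0:
        return None
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (ps.size, ps.size):
        raise ValueError("LD matrix does not match the SNP list")
    stat = float(np.mean(stats.chi2.isf(ps, df=1)))
    wmin = np.linalg.eigvalsh((ld + ld.T) / 2).min()
    if wmin < -1e-8:
        warnings.warn("LD matrix not positive semi-definite; projecting")
        ld = nearest_psd(ld)
    try:
        chol = np.linalg.cholesky(ld + 1e-10 * np.eye(ps.size))
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(nearest_psd(ld) + 1e-8 * np.eye(ps.size))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_perm, ps.size)) @ chol.T
    stat_sim = np.mean(z * z, axis=1)
    emp_p = (1 + np.count_nonzero(stat_sim >= stat)) / (n_perm + 1)
    return GeneAssocResult(gene=gene, n_snps=int(ps.size), stat=stat,
                           empirical_p=float(emp_p))


def estimate_ld(ref_panel: np.ndarray) -> np.ndarray:
    """SNP-SNP Pearson correlation from a reference dosage panel.

    Monomorphic columns get zero off-diagonal correlation (unit diagonal).
    """
    ref = np.asarray(ref_panel, dtype=float)
    if ref.shape[1] == 1:
        return np.ones((1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ref, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return r


def gene_based_test(gwas: pd.DataFrame, annotation: pd.DataFrame,
                    ref_panel: np.ndarray, snp_ids: list[str],
                    window_kb: float = DEFAULT_WINDOW_KB,
                    n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Gene-based scan over all annotated genes.

    ``ref_panel`` (samples x SNPs, columns named by ``snp_ids``) supplies the
    LD. Returns a DataFrame GENE, NSNPS, STAT, EMP_P sorted by EMP_P. Genes
    with no mapped SNP are skipped.
    """
    mapping = map_snps_to_genes(gwas, annotation, window_kb)
    col = {s: j for j, s in enumerate(snp_ids)}
    pmap = dict(zip(gwas["SNP"], gwas["P"]))
    ss = np.random.SeedSequence(seed)
    rows = []
    for gene in annotation["gene"]:
        snps = [s for s in mapping.get(gene, []) if s in col]
        if not snps:
            continue
        ps = np.array([pmap[s] for s in snps], dtype=float)
        keep = ~np.isnan(ps)
        snps = [s for s, k in zip(snps, keep) if k]
        if not snps:
            continue
        ld = estimate_ld(ref_panel[:, [col[s] for s in snps]])
        res = gene_empirical_p(ps[keep], ld, n_perm=n_perm,
                               seed=ss.spawn(1)[0].generate_state(1)[0] % (2**31),
                               gene=gene)
        if res is not None:
            rows.append((res.gene, res.n_snps, res.stat, res.empirical_p))
    df = pd.DataFrame(rows, columns=["GENE", "NSNPS", "STAT", "EMP_P"])
    return df.sort_values(["EMP_P", "GENE"], kind="mergesort").reset_index(drop=True)
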