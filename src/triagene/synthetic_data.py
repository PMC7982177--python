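"""Synthetic study generator for the GWAS x eQTL prioritization pipeline.

Generates every input the pipeline consumes — genotypes, a case/control
phenotype, GWAS summary statistics, two independent eQTL association tables,
gene annotation, gene-set collections and a case/control expression matrix —
with a planted truth: a handful of "true" genes whose eSNPs both regulate
expression (small eQTL p-values) and carry genuine GWAS signal through a
per-allele log-odds effect on the phenotype. All other eQTL signal is
background noise uncoupled from the trait.

Geometry: genes are laid out on a single chromosome, 100 kb apart, each with
a 20 kb body holding an equal share of the SNPs, so that the +/-20 kb
gene-based windows are disjoint and every gene is testable.

The defaults are the study conditions the rest of the package is validated
under; see docs/methods.md for their rationale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as tio

GENE_SPACING = 100_000  # bp between gene starts; keeps +/-20kb windows disjoint
GENE_LENGTH = 20_000
N_EQTL_REF = 1_000  # nominal eQTL-study sample size behind eqtl_effect -> z


@dataclass
class SyntheticConfig:
    """Study conditions for :func:`simulate_study`.

    ``gwas_effect`` is the per-allele log-odds ratio on the binary trait for
    planted eSNPs; ``eqtl_effect`` is the per-allele expression shift in
    residual-SD units, converted to a z-score noncentrality at a nominal
    eQTL sample size of 1000.
    """

    n_samples: int = 2000
    n_snps: int = 5000
    n_genes: int = 500
    n_true_genes: int = 4
    maf_range: tuple[float, float] = (0.05, 0.5)
    esnp_per_gene: int = 3
    gwas_effect: float = 0.4
    eqtl_effect: float = 0.35
    background_esnp_rate: float = 0.3
    trans_esnp_prob: float = 0.2
    n_case_samples: int = 9
    n_control_samples: int = 10
    de_genes: dict[str, float] | None = None
    coexpr_delta: list[tuple[tuple[str, str], float, float]] | None = None
    n_gene_sets: int = 50
    ld_rho: float | None = None
    ld_block: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_snps < 1 or self.n_genes < 1:
            raise ValueError("n_samples, n_snps and n_genes must be >= 1")
        if self.n_true_genes > self.n_genes:
            raise ValueError("n_true_genes exceeds n_genes")
        if self.n_true_genes < 0 or self.esnp_per_gene < 1:
            raise ValueError("n_true_genes >= 0 and esnp_per_gene >= 1 required")
        if self.n_true_genes * self.esnp_per_gene > self.n_snps:
            raise ValueError("not enough SNPs to plant all eSNPs")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.esnp_per_gene > self.n_snps // self.n_genes:
            raise ValueError("esnp_per_gene exceeds SNPs available per gene")
        if self.coexpr_delta is not None:
            for _, rc, rk in self.coexpr_delta:
                if not (-1 <= rc <= 1 and -1 <= rk <= 1):
                    raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class SyntheticStudy:
    """All pipeline inputs plus the planted truth."""

    config: SyntheticConfig
    genotypes: np.ndarray  # samples x SNPs, dosages 0/1/2
    sample_ids: list[str]
    snp_ids: list[str]
    phenotype: np.ndarray  # 0/1 labels
    gwas: pd.DataFrame
    eqtl_discovery: pd.DataFrame
    eqtl_replication: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: dict[str, list[str]]
    expression: pd.DataFrame
    expression_groups: np.ndarray
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every input table to ``outdir``; return the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gwas": outdir / "gwas.tsv",
            "eqtl_discovery": outdir / "eqtl_discovery.tsv",
            "eqtl_replication": outdir / "eqtl_replication.tsv",
            "annotation": outdir / "annotation.bed",
            "gene_sets": outdir / "gene_sets.gmt",
            "expression": outdir / "expression.tsv",
            "dosage": outdir / "dosage.tsv",
            "phenotype": outdir / "phenotype.tsv",
        }
        tio.write_gwas(self.gwas, paths["gwas"])
        tio.write_eqtl(self.eqtl_discovery, paths["eqtl_discovery"])
        tio.write_eqtl(self.eqtl_replication, paths["eqtl_replication"])
        tio.write_annotation(self.annotation, paths["annotation"])
        tio.write_gmt(self.gene_sets, paths["gene_sets"])
        tio.write_expression(self.expression, self.expression_groups, paths["expression"])
        tio.write_dosage(self.genotypes, self.sample_ids, self.snp_ids, paths["dosage"])
        pd.DataFrame({"sample": self.sample_ids, "phenotype": self.phenotype}).to_csv(
            paths["phenotype"], sep="\t", index=False)
        return paths


def simulate_genotypes(n_samples: int, n_snps: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       seed: int = 0,
                       mafs: np.ndarray | None = None,
                       ld_rho: float | None = None,
                       ld_block: int = 1) -> np.ndarray:
    """Dosage matrix (samples x SNPs) of independent biallelic SNPs.

    Column j is Binomial(2, maf_j) per sample with maf_j uniform in
    ``maf_range``. With ``ld_rho`` set, SNPs within consecutive blocks of
    ``ld_block`` share a latent Gaussian factor of weight sqrt(rho) per
    haplotype, inducing positive within-block dosage correlation (a stylized
    LD block, used to exercise the gene-based test's LD handling).
    """
    if n_samples < 1 or n_snps < 1:
        raise ValueError("n_samples and n_snps must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(lo, hi, size=n_snps)
    if ld_rho is None or ld_block <= 1:
        return rng.binomial(2, mafs, size=(n_samples, n_snps)).astype(np.int8)
    # Gaussian-copula haplotypes with block-constant latent correlation.
    thresh = stats.norm.ppf(mafs)
    n_blocks = -(-n_snps // ld_block)
    dosage = np.zeros((n_samples, n_snps), dtype=np.int8)
    for hap in range(2):
        shared = rng.standard_normal((n_samples, n_blocks))
        shared = np.repeat(shared, ld_block, axis=1)[:, :n_snps]
        z = np.sqrt(ld_rho) * shared + np.sqrt(1 - ld_rho) * rng.standard_normal(
            (n_samples, n_snps))
        dosage += (z < thresh).astype(np.int8)
    return dosage


def _noncentral_p(rng: np.random.Generator, ncp: np.ndarray | float,
                  size: int) -> np.ndarray:
    """Two-sided p-values of z ~ N(+/-ncp, 1) with random sign."""
    sign = rng.choice([-1.0, 1.0], size=size)
    z = sign * ncp + rng.standard_normal(size)
    return np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


def nearest_psd_correlation(mat: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix with unit diagonal."""
    sym = (mat + mat.T) / 2
    w, v = np.linalg.eigh(sym)
    out = (v * np.clip(w, eps, None)) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _default_expression_planting(true_genes: list[str]) -> tuple[dict, list]:
    """Paper-scale defaults: shifts for the focal panel and four pairwise
    correlation contrasts between the control and case groups."""
    de: dict[str, float] = {}
    pairs: list[tuple[tuple[str, str], float, float]] = []
    effects = [1.5, 1.5, -1.5, 0.5]
    for g, eff in zip(true_genes, effects):
        de[g] = eff
    contrasts = [((0, 2), -0.39, -0.76), ((1, 3), -0.01, -0.35),
                 ((0, 1), 0.66, 0.46), ((0, 3), 0.17, -0.09)]
    for (i, j), rc, rk in contrasts:
        if i < len(true_genes) and j < len(true_genes):
            pairs.append(((true_genes[i], true_genes[j]), rc, rk))
    return de, pairs


def simulate_expression(genes: list[str], n_case: int, n_control: int,
                        de_genes: dict[str, float],
                        coexpr_delta: list[tuple[tuple[str, str], float, float]],
                        seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Genes x samples expression with planted group shifts and group-specific
    co-expression among the focal genes.

    The pairwise targets in ``coexpr_delta`` are assembled into one
    correlation matrix per group over the focal panel (unspecified entries 0,
    PSD-projected) and each group is drawn jointly from it, so genes shared
    between pairs stay mutually consistent.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    expr = rng.standard_normal((len(genes), n))
    gidx = {g: i for i, g in enumerate(genes)}
    focal = sorted({g for (pair, _, _) in coexpr_delta for g in pair}, key=gidx.get)
    for g in focal:
        if g not in gidx:
            raise ValueError(f"coexpr_delta gene {g!r} not in gene list")
    if focal:
        m = len(focal)
        fpos = {g: i for i, g in enumerate(focal)}
        r_ctrl, r_case = np.eye(m), np.eye(m)
        for (a, b), rc, rk in coexpr_delta:
            i, j = fpos[a], fpos[b]
            r_ctrl[i, j] = r_ctrl[j, i] = rc
            r_case[i, j] = r_case[j, i] = rk
        r_ctrl = nearest_psd_correlation(r_ctrl)
        r_case = nearest_psd_correlation(r_case)
        rows = [gidx[g] for g in focal]
        l_ctrl = np.linalg.cholesky(r_ctrl + 1e-12 * np.eye(m))
        l_case = np.linalg.cholesky(r_case + 1e-12 * np.eye(m))
        expr[rows, :n_control] = l_ctrl @ rng.standard_normal((m, n_control))
        expr[rows, n_control:] = l_case @ rng.standard_normal((m, n_case))
    for g, eff in de_genes.items():
        if g in gidx:
            expr[gidx[g], n_control:] += eff
    groups = np.array(["control"] * n_control + ["case"] * n_case, dtype=object)
    samples = [f"S{i}" for i in range(n)]
    return pd.DataFrame(expr, index=genes, columns=samples), groups


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full synthetic study per ``config`` (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_snps, n_genes = config.n_snps, config.n_genes
    snps_per_gene = n_snps // n_genes

    snp_ids = [f"rs{i}" for i in range(n_snps)]
    sample_ids = [f"ind{i}" for i in range(config.n_samples)]
    genes = [f"G{i:04d}" for i in range(n_genes)]

    # annotation: gene g spans [g*100kb, g*100kb + 20kb) on chromosome 1
    starts = np.arange(n_genes) * GENE_SPACING
    annotation = pd.DataFrame({
        "chrom": "1", "start": starts, "end": starts + GENE_LENGTH, "gene": genes,
    })

    # SNP positions: gene g holds SNPs [g*spg, (g+1)*spg); leftovers intergenic
    positions = np.empty(n_snps, dtype=np.int64)
    step = GENE_LENGTH // (snps_per_gene + 1)
    for g in range(n_genes):
        sl = slice(g * snps_per_gene, (g + 1) * snps_per_gene)
        positions[sl] = starts[g] + step * (1 + np.arange(snps_per_gene))
    n_rest = n_snps - n_genes * snps_per_gene
    if n_rest:
        positions[n_genes * snps_per_gene:] = (
            n_genes * GENE_SPACING + GENE_SPACING * (1 + np.arange(n_rest)))
    snp_gene = np.full(n_snps, -1)  # host gene index of each SNP
    snp_gene[: n_genes * snps_per_gene] = np.repeat(np.arange(n_genes), snps_per_gene)

    mafs = rng.uniform(*config.maf_range, size=n_snps)
    genotypes = simulate_genotypes(
        config.n_samples, n_snps, config.maf_range,
        seed=rng.integers(2**31), mafs=mafs,
        ld_rho=config.ld_rho, ld_block=config.ld_block)

    # planted truth: first esnp_per_gene SNPs of each true gene
    true_idx = list(range(config.n_true_genes))
    true_genes = [genes[i] for i in true_idx]
    planted: dict[str, list[int]] = {
        genes[g]: list(range(g * snps_per_gene, g * snps_per_gene + config.esnp_per_gene))
        for g in true_idx
    }
    planted_snps = sorted(s for lst in planted.values() for s in lst)

    # phenotype through a logistic model on the planted SNPs
    eta = np.zeros(config.n_samples)
    if planted_snps:
        g_centered = genotypes[:, planted_snps] - 2 * mafs[planted_snps]
        eta = config.gwas_effect * g_centered.sum(axis=1)
    phenotype = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)

    from .null_gwas import logistic_assoc  # deferred: avoids import cycle at module load

    gwas = logistic_assoc(genotypes, phenotype, snp_ids=snp_ids,
                          chrom=["1"] * n_snps, positions=positions)

    ncp = config.eqtl_effect * np.sqrt(2 * mafs * (1 - mafs) * N_EQTL_REF)
    eqtl_discovery = _make_eqtl_table(
        rng, config, genes, snp_ids, snp_gene, planted, planted_snps, ncp)
    eqtl_replication = _make_eqtl_table(
        rng, config, genes, snp_ids, snp_gene, planted, planted_snps, ncp)

    gene_sets = _make_gene_sets(rng, genes, true_genes, config.n_gene_sets)

    de = config.de_genes
    pairs = config.coexpr_delta
    if de is None and pairs is None and true_genes:
        de, pairs = _default_expression_planting(true_genes)
    expression, groups = simulate_expression(
        genes, config.n_case_samples, config.n_control_samples,
        de or {}, pairs or [], seed=rng.integers(2**31))

    truth = {
        "genes": true_genes,
        "esnps": {g: [snp_ids[i] for i in idx] for g, idx in planted.items()},
    }
    return SyntheticStudy(
        config=config, genotypes=genotypes, sample_ids=sample_ids, snp_ids=snp_ids,
        phenotype=phenotype, gwas=gwas, eqtl_discovery=eqtl_discovery,
        eqtl_replication=eqtl_replication, annotation=annotation,
        gene_sets=gene_sets, expression=expression, expression_groups=groups,
        truth=truth)


def _make_eqtl_table(rng, config, genes, snp_ids, snp_gene, planted,
                     planted_snps, ncp) -> pd.DataFrame:
    """One eQTL association table: planted cis eSNPs for true genes (strong,
    trait-coupled), background eSNPs for a fraction of other genes (strong,
    trait-null), and sub-threshold filler rows."""
    rows: list[tuple[str, str, float, str]] = []
    planted_set = set(planted_snps)
    for g, snps in planted.items():
        ps = _noncentral_p(rng, ncp[snps], len(snps))
        rows += [(snp_ids[s], g, p, "cis") for s, p in zip(snps, ps)]
    n_genes = len(genes)
    spg = config.n_snps // n_genes
    bg = rng.random(n_genes) < config.background_esnp_rate
    for gi in np.flatnonzero(bg):
        if genes[gi] in planted:
            continue
        k = int(rng.integers(1, config.esnp_per_gene + 1))
        own = [s for s in range(gi * spg, (gi + 1) * spg) if s not in planted_set]
        chosen = list(rng.choice(own, size=min(k, len(own)), replace=False))
        kinds = ["cis"] * len(chosen)
        if rng.random() < config.trans_esnp_prob:
            far = int(rng.integers(config.n_snps))
            if far not in planted_set and snp_gene[far] != gi:
                chosen.append(far)
                kinds.append("trans")
        ps = _noncentral_p(rng, ncp[chosen], len(chosen))
        rows += [(snp_ids[s], genes[gi], p, kd)
                 for s, p, kd in zip(chosen, ps, kinds)]
    # filler: clearly non-significant rows, exercise threshold filtering
    used = {(r[0], r[1]) for r in rows}
    n_filler = n_genes
    snp_pick = rng.integers(config.n_snps, size=2 * n_filler)
    gene_pick = rng.integers(n_genes, size=2 * n_filler)
    p_fill = rng.uniform(0.1, 1.0, size=2 * n_filler)
    added = 0
    for s, gi, p in zip(snp_pick, gene_pick, p_fill):
        if added >= n_filler:
            break
        key = (snp_ids[s], genes[gi])
        if key in used:
            continue
        used.add(key)
        rows.append((key[0], key[1], p, "cis"))
        added += 1
    df = pd.DataFrame(rows, columns=tio.EQTL_COLUMNS)
    return df.sort_values(["GENE", "P"], kind="mergesort").reset_index(drop=True)


def _make_gene_sets(rng, genes, true_genes, n_sets) -> dict[str, list[str]]:
    """Random GMT collection plus one set seeded with the true genes."""
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = min(int(rng.integers(10, 101)), len(genes))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET_{i:03d}"] = sorted(members)
    if true_genes:
        others = [g for g in genes if g not in true_genes]
        fill = rng.choice(others,
                          size=min(len(others), max(0, 20 - len(true_genes))),
                          replace=False)
        sets["SET_TRUE"] = sorted([*true_genes, *fill])
    return sets
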