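"""Three-stage orchestration of the integrative prioritization analysis.

Stage 1 (discovery): Bayesian eSNP-to-gene scoring of the trait GWAS against
the discovery eQTL table. Stage 2 (replication): the same scoring against an
independent eQTL table, plus an LD-aware gene-based scan of the GWAS — and,
as negative control, of a GWAS on a randomized phenotype. Stage 3
(prioritization): intersection of the significant gene sets, overlap
permutation and real-vs-null comparative validation, pathway enrichment with
MDS clustering, and expression-level validation of the final genes.

Every stochastic stage receives a child seed derived from the single global
seed, so a fixed config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .enrichment import (GeneSetCollection, enrichment_table, hypergeom_enrich,
                         jaccard_distance_matrix, mds_cluster)
from .expression import coexpression_compare, dge_ttest
from .gene_based import gene_based_test
from .integration import (DEFAULT_CUT_POINTS, DEFAULT_N_TRIALS,
                          comparative_overlap, intersect_genesets,
                          overlap_permutation)
from .null_gwas import NullGwasConfig, null_gwas
from .sherlock_score import SherlockPriors, sherlock_analysis

logger = logging.getLogger(__name__)


class PipelineInputError(ValueError):
    pass


@dataclass
class PipelineConfig:
    gwas: str
    eqtl_discovery: str
    eqtl_replication: str
    annotation: str
    dosage: str
    gene_sets: str
    expression: str
    outdir: str = "triagene_out"
    priors_discovery: SherlockPriors = field(default_factory=SherlockPriors)
    priors_replication: SherlockPriors = field(default_factory=SherlockPriors)
    sherlock_alpha: float = 0.05
    window_kb: float = 20.0
    gba_n_perm: int = 10_000
    gba_alpha: float = 0.05
    null_case_prob: float = 0.5
    enrich_alpha: float = 0.05
    enrich_min_size: int = 5
    enrich_max_size: int = 2000
    k_clusters: int = 5
    cut_points: tuple[float, ...] = DEFAULT_CUT_POINTS
    n_trials: int = DEFAULT_N_TRIALS
    focal_genes: list[str] | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key in ("priors_discovery", "priors_replication"):
            if isinstance(raw.get(key), dict):
                raw[key] = SherlockPriors(**raw[key])
        if "cut_points" in raw:
            raw["cut_points"] = tuple(raw["cut_points"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        # outdir and log level do not affect the analysis
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("outdir", "log_level")}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    geneset_sizes: dict
    intersection: list[str]
    permutation: dict
    comparative: dict
    enrichment: dict
    expression: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=_jsonable)

    def to_markdown(self) -> str:
        lines = ["# Prioritization run report", ""]
        lines.append("## Gene-set sizes")
        for k, v in self.geneset_sizes.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
        lines.append(f"## Final intersection ({len(self.intersection)} genes)")
        lines.append(", ".join(self.intersection) or "(empty)")
        lines.append("")
        lines.append("## Overlap permutation (discovery vs replication)")
        for k, v in self.permutation.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
        lines.append("## Comparative analysis (real vs null gene-based scan)")
        lines.append(f"- paired t = {self.comparative['t']:.4g}, "
                     f"p = {self.comparative['p']:.4g} "
                     f"over {self.comparative['n_pairs']} rate pairs")
        lines.append("")
        lines.append("## Enrichment")
        lines.append(f"- significant sets: {self.enrichment['n_significant']}")
        reps = self.enrichment.get("cluster_representatives", [])
        if reps:
            lines.append(f"- cluster representatives: {', '.join(reps)}")
        lines.append("")
        lines.append("## Expression validation")
        lines.append(f"- DGE genes at p<=0.05: {self.expression['n_dge_significant']}")
        lines.append(f"- largest |delta r|: {self.expression.get('max_abs_delta_r')}")
        lines.append("")
        prov = self.provenance
        lines.append(f"_config {prov['config_digest']}, seed {prov['seed']}, "
                     f"triagene {prov['version']}_")
        return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Check file dialects, p-value ranges and gene-namespace overlap.

    Raises :class:`PipelineInputError` on hard errors (unreadable file,
    missing column, out-of-range p-value, with path and line number); returns
    a list of warning strings. Never mutates inputs.
    """
    warnings_out: list[str] = []
    for name in ("gwas", "eqtl_discovery", "eqtl_replication", "annotation",
                 "dosage", "gene_sets", "expression"):
        path = Path(getattr(config, name))
        if not path.is_file():
            raise PipelineInputError(f"{name} file not found: {path}")
    try:
        gwas = tio.read_gwas(config.gwas)
    except Exception as exc:
        raise PipelineInputError(f"unreadable GWAS file {config.gwas}: {exc}") from exc
    pvals = gwas["P"]
    bad = pvals.notna() & ((pvals < 0) | (pvals > 1))
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise PipelineInputError(
            f"{config.gwas}:{line}: GWAS p-value {pvals[bad.idxmax()]} outside [0, 1]")
    ann = tio.read_annotation(config.annotation)
    ann_genes = set(ann["gene"])
    for name in ("eqtl_discovery", "eqtl_replication"):
        path = getattr(config, name)
        try:
            eqtl = tio.read_eqtl(path)
        except tio.InputFormatError as exc:
            raise PipelineInputError(str(exc)) from exc
        bad = eqtl["P"].notna() & ((eqtl["P"] < 0) | (eqtl["P"] > 1))
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise PipelineInputError(f"{path}:{line}: eQTL p-value outside [0, 1]")
        genes = set(eqtl["GENE"])
        overlap = len(genes & ann_genes) / max(1, len(genes))
        if overlap < 0.5:
            warnings_out.append(
                f"{name}: only {overlap:.0%} of eQTL genes found in the "
                f"annotation; check gene namespaces")
    return warnings_out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in dependency order and write every stage output
    plus ``report.json`` / ``report.md`` under ``config.outdir``."""
    logging.basicConfig(level=config.log_level)
    warnings_list = validate_inputs(config)
    for w in warnings_list:
        logger.warning(w)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(8)]

    gwas = tio.read_gwas(config.gwas)
    eqtl_d = tio.read_eqtl(config.eqtl_discovery)
    eqtl_r = tio.read_eqtl(config.eqtl_replication)
    annotation = tio.read_annotation(config.annotation)
    dosage, _, snp_ids = tio.read_dosage(config.dosage)
    gene_sets = tio.read_gmt(config.gene_sets)
    expr, groups = tio.read_expression(config.expression)

    # stage 1: discovery Bayesian scoring
    pri_d = dataclasses.replace(config.priors_discovery, seed=seeds[0])
    res_d, support_d = sherlock_analysis(eqtl_d, gwas, pri_d)
    res_d.to_csv(outdir / "sherlock_discovery.tsv", sep="\t", index=False)
    support_d.to_csv(outdir / "sherlock_discovery_esnps.tsv", sep="\t", index=False)
    geneset1 = res_d.loc[res_d["SIM_P"] <= config.sherlock_alpha, "GENE"].tolist()

    # stage 2: replication scoring + gene-based scans (real and null trait)
    pri_r = dataclasses.replace(config.priors_replication, seed=seeds[1])
    res_r, support_r = sherlock_analysis(eqtl_r, gwas, pri_r)
    res_r.to_csv(outdir / "sherlock_replication.tsv", sep="\t", index=False)
    support_r.to_csv(outdir / "sherlock_replication_esnps.tsv", sep="\t", index=False)
    geneset2 = res_r.loc[res_r["SIM_P"] <= config.sherlock_alpha, "GENE"].tolist()

    gba_real = gene_based_test(gwas, annotation, dosage, snp_ids,
                               window_kb=config.window_kb,
                               n_perm=config.gba_n_perm, seed=seeds[2])
    gba_real.to_csv(outdir / "gene_based_real.tsv", sep="\t", index=False)
    geneset3 = gba_real.loc[gba_real["EMP_P"] <= config.gba_alpha, "GENE"].tolist()

    snp_meta = gwas.set_index("SNP")
    chrom = [str(snp_meta["CHR"].get(s, "NA")) for s in snp_ids]
    positions = np.array([int(snp_meta["BP"].get(s, -1)) for s in snp_ids])
    null_summary = null_gwas(
        dosage, NullGwasConfig(seed=seeds[3], case_label_prob=config.null_case_prob),
        snp_ids=snp_ids, chrom=chrom, positions=positions)
    tio.write_gwas(null_summary, outdir / "null_gwas.tsv")
    gba_null = gene_based_test(null_summary, annotation, dosage, snp_ids,
                               window_kb=config.window_kb,
                               n_perm=config.gba_n_perm, seed=seeds[4])
    gba_null.to_csv(outdir / "gene_based_null.tsv", sep="\t", index=False)
    geneset4 = gba_null.loc[gba_null["EMP_P"] <= config.gba_alpha, "GENE"].tolist()

    # stage 3: intersection + validation
    intersection = intersect_genesets([geneset1, geneset2, geneset3])
    perm_universe = res_r["GENE"].tolist()  # replication-stage background
    perm = overlap_permutation(geneset1, geneset2, perm_universe,
                               n_trials=config.n_trials, seed=seeds[5])
    comp = comparative_overlap([res_d, res_r], gba_real, gba_null,
                               cut_points=config.cut_points,
                               gba_alpha=config.gba_alpha)
    comp["table"].to_csv(outdir / "comparative.tsv", sep="\t", index=False)

    universe = res_d["GENE"].tolist()  # discovery-stage background
    query = [g for g in geneset1 if g in set(universe)]
    collection = GeneSetCollection(gene_sets, config.enrich_min_size,
                                   config.enrich_max_size)
    enriched_all = hypergeom_enrich(query, collection, universe) if query else []
    etable = enrichment_table(enriched_all)
    etable.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    sig = [r for r in enriched_all if r.p <= config.enrich_alpha]
    enrich_summary = {"n_tested": len(enriched_all), "n_significant": len(sig),
                      "cluster_representatives": []}
    if len(sig) >= 2:
        dmat = jaccard_distance_matrix(
            sig, memberships={k: set(v) for k, v in gene_sets.items()},
            universe=universe)
        k = min(config.k_clusters, len(sig))
        emb = mds_cluster(dmat, np.array([r.p for r in sig]), k, seed=seeds[6],
                          names=[r.name for r in sig])
        emb.to_csv(outdir / "enrichment_mds.tsv", sep="\t", index=False)
        enrich_summary["cluster_representatives"] = (
            emb.loc[emb["REPRESENTATIVE"], "SET"].tolist())

    focal = config.focal_genes or intersection
    focal = [g for g in focal if g in expr.index]
    expr_summary: dict = {"n_dge_significant": 0, "max_abs_delta_r": None}
    if focal:
        dge = dge_ttest(expr, groups, genes=focal)
        dge.to_csv(outdir / "dge.tsv", sep="\t", index=False)
        expr_summary["n_dge_significant"] = int((dge["P"] <= 0.05).sum())
        expr_summary["dge"] = dge[["GENE", "T", "P"]].to_dict("records")
    if len(focal) >= 2 and min((groups == "case").sum(),
                               (groups == "control").sum()) >= 3:
        coex = coexpression_compare(expr, groups, focal)
        coex["pairs"].to_csv(outdir / "coexpression.tsv", sep="\t", index=False)
        expr_summary["max_abs_delta_r"] = float(coex["pairs"]["DELTA"].abs().max())
        expr_summary["coexpression"] = coex["pairs"].to_dict("records")

    from . import __version__

    report = RunReport(
        geneset_sizes={
            "geneset1_discovery": len(geneset1),
            "geneset2_replication": len(geneset2),
            "geneset3_gene_based_real": len(geneset3),
            "geneset4_gene_based_null": len(geneset4),
        },
        intersection=intersection,
        permutation=perm.to_dict(),
        comparative={"t": comp["t"], "p": comp["p"], "n_pairs": comp["n_pairs"]},
        enrichment=enrich_summary,
        expression=expr_summary,
        provenance={"config_digest": config.digest(), "seed": config.seed,
                    "version": __version__, "warnings": warnings_list},
    )
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.md").write_text(report.to_markdown())
    return report
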