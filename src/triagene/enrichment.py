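"""Over-representation analysis and pathway-redundancy clustering.

A query gene list is tested against each gene set in a collection with the
upper-tail hypergeometric test (P(X >= k) for k overlap genes, K set members
in the universe, n query genes, N universe genes), with Benjamini-Hochberg
FDR across the retained sets. Sets whose universe-intersected size falls
outside [min_size, max_size] are excluded before testing.

Redundancy among enriched sets is summarized by the Jaccard distance
d(A, B) = 1 - |A n B| / |A u B| on their gene memberships: classical
(Torgerson) MDS embeds the distance matrix in 2D for display, and k-medoids
(PAM) on the original distances groups the sets, each cluster represented by
its most significant member. Classical MDS is used deliberately: on a
distance matrix that is exactly 2-D Euclidean the embedding is exact (zero
stress), which SMACOF-style iterative MDS cannot guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    min_size: int = 5
    max_size: int = 2000


@dataclass
class EnrichmentResult:
    name: str
    overlap: list[str]
    k: int
    K: int
    n: int
    N: int
    p: float
    fdr: float = field(default=np.nan)


def hypergeom_enrich(query: list[str], collection: GeneSetCollection,
                     universe: list[str]) -> list[EnrichmentResult]:
    """Hypergeometric ORA of ``query`` against every retained set.

    Results are BH-adjusted across retained sets and sorted by p. Query genes
    outside the universe are dropped with a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        warnings.warn(f"dropped {len(outside)} query genes outside the universe")
        q &= uni
    if not q:
        raise ValueError("empty query after intersecting with the universe")
    N, n = len(uni), len(q)
    results = []
    for name, members in collection.sets.items():
        in_uni = set(members) & uni
        K = len(in_uni)
        if not (collection.min_size <= K <= collection.max_size):
            continue
        overlap = sorted(q & in_uni)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # upper tail P(X >= k)
        results.append(EnrichmentResult(name, overlap, k, K, n, N, p))
    if results:
        fdr = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, f in zip(results, fdr):
            r.fdr = float(f)
    return sorted(results, key=lambda r: (r.p, r.name))


def jaccard_distance_matrix(enriched: list[EnrichmentResult],
                            memberships: dict[str, set[str]] | None = None,
                            universe: list[str] | None = None) -> np.ndarray:
    """Pairwise Jaccard distances between enriched sets' gene memberships.

    By default membership is the set's universe-intersected genes, recovered
    from the collection via ``memberships`` (name -> gene set); if omitted,
    the overlap genes recorded in the results are used.
    """
    if len(enriched) < 2:
        raise ValueError("need at least 2 enriched sets")
    uni = set(universe) if universe is not None else None
    sets = []
    for r in enriched:
        s = set(memberships[r.name]) if memberships else set(r.overlap)
        if uni is not None:
            s &= uni
        sets.append(s)
    m = len(sets)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            union = len(sets[i] | sets[j])
            inter = len(sets[i] & sets[j])
            d[i, j] = d[j, i] = 1.0 - (inter / union if union else 1.0)
    return d


def classical_mds(distances: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson MDS: double-center the squared distances and eigendecompose."""
    d2 = np.asarray(distances, dtype=float) ** 2
    m = d2.shape[0]
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
    return coords


def mds_stress(distances: np.ndarray, coords: np.ndarray) -> float:
    """Normalized residual: sqrt(sum (d_hat - d)^2 / sum d^2)."""
    d = np.asarray(distances, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    d_hat = np.sqrt((diff ** 2).sum(axis=-1))
    denom = (d ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_hat - d) ** 2).sum() / denom))


def k_medoids(distances: np.ndarray, k: int, seed: int = 0,
              n_restarts: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """PAM on a precomputed distance matrix; returns (labels, medoid indices).

    Seeded random restarts with greedy swap descent; deterministic by seed.
    """
    d = np.asarray(distances, dtype=float)
    m = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError("k exceeds the number of points")
    rng = np.random.default_rng(seed)
    best_cost, best_medoids = np.inf, None
    for _ in range(n_restarts):
        medoids = rng.choice(m, size=k, replace=False)
        cost = d[:, medoids].min(axis=1).sum()
        improved = True
        while improved:
            improved = False
            for mi in range(k):
                for cand in range(m):
                    if cand in medoids:
                        continue
                    trial = medoids.copy()
                    trial[mi] = cand
                    c = d[:, trial].min(axis=1).sum()
                    if c < cost - 1e-12:
                        medoids, cost, improved = trial, c, True
        if cost < best_cost - 1e-12:
            best_cost, best_medoids = cost, np.sort(medoids)
    labels = np.argmin(d[:, best_medoids], axis=1)
    return labels, best_medoids


def mds_cluster(distances: np.ndarray, pvalues: np.ndarray, k: int,
                seed: int = 0, names: list[str] | None = None) -> pd.DataFrame:
    """2-D embedding plus k-medoids clustering of enriched sets.

    Clustering runs on the original Jaccard distances, not the embedding.
    Returns columns SET, MDS1, MDS2, CLUSTER, REPRESENTATIVE, P; the
    representative of each cluster is its lowest-p member.
    """
    d = np.asarray(distances, dtype=float)
    m = d.shape[0]
    if names is None:
        names = [f"set{i}" for i in range(m)]
    coords = classical_mds(d, 2) if m > 1 else np.zeros((m, 2))
    labels, _ = k_medoids(d, k, seed=seed)
    pv = np.asarray(pvalues, dtype=float)
    rep = np.zeros(m, dtype=bool)
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if idx.size:
            rep[idx[np.argmin(pv[idx])]] = True
    return pd.DataFrame({
        "SET": names, "MDS1": coords[:, 0], "MDS2": coords[:, 1],
        "CLUSTER": labels, "REPRESENTATIVE": rep, "P": pv,
    })


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "SET": r.name, "K": r.K, "N_QUERY": r.n, "K_OVERLAP": r.k,
        "N_UNIVERSE": r.N, "P": r.p, "FDR": r.fdr,
        "GENES": ",".join(r.overlap),
    } for r in results])
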