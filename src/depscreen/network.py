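"""Co-dependency networks and similarity network fusion.

Per modality, a gene x gene Pearson-correlation matrix over cell lines is
the raw co-dependency network.  Two such networks are fused with an
adaptation of Similarity Network Fusion: correlation magnitude |r| is the
affinity (SNF needs nonnegative weights), full kernels are row-normalised
affinities with diagonal set to 1/2 before normalisation, sparse kernels
keep each row's k nearest neighbours (k = 7 by default, or round(ln n)),
and the two kernels cross-diffuse for a fixed 20 iterations before being
averaged and symmetrised.  Network quality is scored by recovery of prior
known gene-gene relations (one-sided KS on |similarity|, best prior rank).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import ks_2samp

from .containers import SimilarityNetwork


def correlation_similarity(
    matrix: pd.DataFrame, gene_filter: list[str] | None = None
) -> SimilarityNetwork:
    """All-pairs Pearson correlation network over the filtered genes."""
    genes = list(gene_filter) if gene_filter is not None else list(matrix.columns)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes after filtering")
    if matrix.shape[0] < 10:
        raise ValueError("need at least 10 cell lines")
    sub = matrix[genes]
    sd = sub.std(ddof=0)
    dead = [g for g in genes if not np.isfinite(sd[g]) or sd[g] == 0]
    if dead:
        warnings.warn(f"{len(dead)} zero-variance genes excluded", stacklevel=2)
        sub = sub.drop(columns=dead)
    w = sub.corr()  # pairwise-complete
    return SimilarityNetwork(weights=w, kind="raw_correlation")


def knn_sparsify(network: SimilarityNetwork, k: int = 7) -> SimilarityNetwork:
    """Keep each row's k largest weights by |value|, renormalise to sum 1."""
    if k <= 0:
        raise ValueError("k must be positive")
    W = network.weights.to_numpy(dtype=float).copy()
    n = W.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of genes")
    out = np.zeros_like(W)
    order = np.argsort(-np.abs(W), axis=1, kind="stable")
    for i in range(n):
        keep = order[i, :k]
        total = W[i, keep].sum()
        if total != 0:
            out[i, keep] = W[i, keep] / total
        else:
            out[i, keep] = 1.0 / k
    return SimilarityNetwork(
        weights=pd.DataFrame(out, index=network.genes, columns=network.genes),
        kind="knn_sparse",
    )


def full_kernel(W: pd.DataFrame, diagonal: float = 0.5) -> np.ndarray:
    """Row-normalised |correlation| affinity kernel (diagonal set first)."""
    A = np.abs(W.to_numpy(dtype=float)).copy()
    np.fill_diagonal(A, diagonal)
    return A / A.sum(axis=1, keepdims=True)


def snf_diffuse(
    network_a: SimilarityNetwork,
    network_b: SimilarityNetwork,
    k: int | str = 7,
    iterations: int = 20,
    kernel_diagonal: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-diffuse the two kernels; returns the row-stochastic pair.

    Full kernels P_v are row-normalised |correlation| affinities; sparse
    kernels S_v keep each row's k nearest neighbours.  Each step updates
    P_A <- S_A P_B S_A^T and P_B <- S_B P_A_prev S_B^T with row
    renormalisation.  Exactly ``iterations`` steps are run — no
    convergence test.
    """
    if not network_a.genes.equals(network_b.genes):
        raise ValueError("networks must share the gene axis")
    if network_a.kind != "raw_correlation" or network_b.kind != "raw_correlation":
        raise ValueError("snf expects raw_correlation networks")
    n = len(network_a.genes)
    if k == "auto":
        k = max(1, int(round(np.log(n))))
    P = {m: full_kernel(net.weights, kernel_diagonal) for m, net in
         {"A": network_a, "B": network_b}.items()}
    S = {}
    for m, net in {"A": network_a, "B": network_b}.items():
        abs_net = SimilarityNetwork(
            weights=pd.DataFrame(
                np.abs(net.weights.to_numpy()), index=net.genes, columns=net.genes
            ),
            kind="raw_correlation",
        )
        S[m] = knn_sparsify(abs_net, k=k).weights.to_numpy()

    for it in range(iterations):
        prev_a = P["A"]
        P["A"] = S["A"] @ P["B"] @ S["A"].T
        P["B"] = S["B"] @ prev_a @ S["B"].T
        for m in ("A", "B"):
            if not np.isfinite(P[m]).all():
                raise FloatingPointError(f"non-finite kernel at iteration {it}")
            P[m] = P[m] / P[m].sum(axis=1, keepdims=True)
    return P["A"], P["B"]


def snf_fuse(
    network_a: SimilarityNetwork,
    network_b: SimilarityNetwork,
    k: int | str = 7,
    iterations: int = 20,
    kernel_diagonal: float = 0.5,
) -> SimilarityNetwork:
    """Fused similarity network: symmetrised average of the diffused pair."""
    pa, pb = snf_diffuse(network_a, network_b, k, iterations, kernel_diagonal)
    fused = (pa + pb) / 2.0
    fused = (fused + fused.T) / 2.0
    return SimilarityNetwork(
        weights=pd.DataFrame(fused, index=network_a.genes, columns=network_a.genes),
        kind="fused",
    )


@dataclass
class EnrichmentResult:
    per_gene: pd.DataFrame  # ks_stat, ks_pvalue, best_related_rank, n_related
    rank_counts: dict[int, int]  # queries with best rank <= {1, 5, 10, 100}


def related_enrichment(
    network: SimilarityNetwork,
    priors: dict[str, set[str]],
    rank_cutoffs: tuple[int, ...] = (1, 5, 10, 100),
) -> EnrichmentResult:
    """Prior-relation recovery per query gene.

    For each query with at least one prior in the network and >= 10
    non-prior genes: a one-sided two-sample KS test of whether the
    |similarity| scores of its known related genes are stochastically
    larger than those of the other genes, and the best rank of any prior
    when all other genes are sorted by |similarity| (self excluded).
    """
    W = network.weights
    genes = list(W.index)
    rows = {}
    for q in genes:
        if q not in priors:
            continue
        related = {g for g in priors[q] if g in W.columns and g != q}
        if not related:
            warnings.warn(f"query {q}: no priors resolve in network; skipped", stacklevel=2)
            continue
        others = [g for g in genes if g != q]
        if len(others) - len(related) < 10:
            continue
        scores = W.loc[q, others].abs()
        rel_scores = scores[list(related)].to_numpy()
        non_scores = scores[[g for g in others if g not in related]].to_numpy()
        # alternative="less": related-gene CDF lies below the others',
        # i.e. their scores are stochastically larger
        ks = ks_2samp(rel_scores, non_scores, alternative="less", method="auto")
        ranks = scores.rank(ascending=False, method="min")
        best = int(ranks[list(related)].min())
        rows[q] = {
            "ks_stat": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue),
            "best_related_rank": best,
            "n_related": len(related),
        }
    per_gene = pd.DataFrame.from_dict(rows, orient="index")
    counts = {
        c: int((per_gene["best_related_rank"] <= c).sum()) if len(per_gene) else 0
        for c in rank_cutoffs
    }
    return EnrichmentResult(per_gene=per_gene, rank_counts=counts)


def local_network_extract(
    network: SimilarityNetwork, query: str, top_n: int = 10
) -> nx.DiGraph:
    """Local neighbourhood digraph around a query gene.

    Vertices are the query plus its ``top_n`` co-dependencies by
    |similarity|; a directed edge u -> v exists iff v is in u's top_n.
    Edge weights are z-scores of the similarity over the full matrix.
    """
    W = network.weights
    if query not in W.index:
        raise KeyError(f"query gene {query} not in network")
    mu = float(W.to_numpy().mean())
    sd = float(W.to_numpy().std())

    def top_of(g: str) -> list[str]:
        s = W.loc[g].drop(labels=[g]).abs()
        return list(s.sort_values(ascending=False, kind="stable").head(top_n).index)

    vertices = [query] + top_of(query)
    graph = nx.DiGraph()
    graph.add_nodes_from(vertices)
    for u in vertices:
        tops = set(top_of(u))
        for v in vertices:
            if v != u and v in tops:
                graph.add_edge(u, v, weight=(float(W.loc[u, v]) - mu) / sd)
    return graph
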