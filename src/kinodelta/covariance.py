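"""Molecule-level covariance networks across the deletion-strain panel.

Proteins (or phosphosites) whose log2-ratio profiles co-vary across
~110 perturbations are likely to be functionally coupled: same complex,
pathway, compartment or a direct interaction. Every molecule pair with
shared measurements in at least 50% of strains is correlated (Pearson,
pairwise complete); edges require |r| ≥ 0.7 and Bonferroni-adjusted
p ≤ 0.001, the Bonferroni factor being the number of pairs actually
evaluated. A permutation test (independent within-row shuffles of the
strain order) estimates the false-positive rate of the reported edge
set, and edges are attributed to known relationship classes supplied as
annotation databases.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from ._stats import pairwise_complete_pearson, pearson_p_from_r
from .containers import EDGE_COLUMNS, AnnotationDB
from .errors import DataError
from .io_formats import parse_site_key

logger = logging.getLogger("kinodelta")


def _edge_scan(X: np.ndarray, min_shared: int, r_min: float,
               p_adj_max: float):
    """Shared pair scan; returns (i, j, r, n_shared, p, p_adj, n_eval)."""
    r, n = pairwise_complete_pearson(X)
    iu, ju = np.triu_indices(X.shape[0], k=1)
    eligible = (n[iu, ju] >= min_shared) & ~np.isnan(r[iu, ju])
    n_eval = int(eligible.sum())
    empty = np.empty(0)
    if n_eval == 0:
        return (np.empty(0, int), np.empty(0, int), empty,
                np.empty(0, int), empty, empty, 0)
    ii, jj = iu[eligible], ju[eligible]
    rr = r[ii, jj]
    cand = np.abs(rr) >= r_min
    ii, jj, rr = ii[cand], jj[cand], rr[cand]
    nn = n[ii, jj]
    p = pearson_p_from_r(rr, nn)
    p_adj = np.minimum(p * n_eval, 1.0)
    keep = p_adj <= p_adj_max
    return (ii[keep], jj[keep], rr[keep], nn[keep], p[keep], p_adj[keep],
            n_eval)


def molecule_pair_correlations(merged: pd.DataFrame,
                               min_shared_fraction: float = 0.5,
                               r_min: float = 0.7,
                               p_adj_max: float = 0.001
                               ) -> tuple[pd.DataFrame, int]:
    """Covariance edges over all molecule pairs.

    ``merged`` is a molecules × strains frame (replicates merged, the
    deleted gene's own product masked). Returns the edge table (node
    pairs in lexicographic order) and the number of evaluated pairs
    (the Bonferroni factor).
    """
    n_strains = merged.shape[1]
    min_shared = max(3, math.ceil(min_shared_fraction * n_strains))
    X = merged.to_numpy(dtype=float)
    ii, jj, rr, nn, p, p_adj, n_eval = _edge_scan(X, min_shared, r_min,
                                                  p_adj_max)
    mols = merged.index.to_numpy()
    a, b = mols[ii].copy(), mols[jj].copy()
    swap = a > b
    a[swap], b[swap] = mols[jj][swap], mols[ii][swap]
    edges = pd.DataFrame({
        "node_a": a, "node_b": b, "r": rr, "n": nn, "p": p, "p_adj": p_adj,
        "sign": np.where(rr >= 0, "pos", "neg"),
    })[EDGE_COLUMNS]
    edges = edges.sort_values(["node_a", "node_b"], ignore_index=True)
    logger.info("covariance scan: %d pairs evaluated, %d edges", n_eval,
                len(edges))
    return edges, n_eval


def permutation_false_positive_rate(merged: pd.DataFrame, n_perm: int = 1000,
                                    min_shared_fraction: float = 0.5,
                                    r_min: float = 0.7,
                                    p_adj_max: float = 0.001,
                                    seed: int = 0) -> dict:
    """Permutation estimate of the edge set's false-positive rate.

    Each permutation independently shuffles the strain order of every
    molecule's profile (missing entries travel with their values),
    preserving marginals while destroying cross-molecule structure.
    rate = 100 · mean(permuted edge count) / observed edge count.
    """
    n_strains = merged.shape[1]
    min_shared = max(3, math.ceil(min_shared_fraction * n_strains))
    X = merged.to_numpy(dtype=float)
    observed = int(_edge_scan(X, min_shared, r_min, p_adj_max)[0].size)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=np.int64)
    for k in range(n_perm):
        Xp = rng.permuted(X, axis=1)
        counts[k] = _edge_scan(Xp, min_shared, r_min, p_adj_max)[0].size
    mean_perm = float(counts.mean()) if n_perm else float("nan")
    result = {
        "observed_edges": int(observed),
        "mean_permuted_edges": mean_perm,
        "permuted_counts": counts,
        "rate_percent": None,
        "undefined": observed == 0,
    }
    if observed:
        result["rate_percent"] = 100.0 * mean_perm / observed
    else:
        logger.warning("permutation FPR undefined: no observed edges")
    return result


def _node_protein(node: str, site_to_protein: dict | None) -> str:
    if site_to_protein and node in site_to_protein:
        return site_to_protein[node]
    try:
        return parse_site_key(node).protein
    except Exception:
        return node


def attribute_edges(edges: pd.DataFrame, databases: list[AnnotationDB],
                    site_to_protein: dict | None = None) -> dict:
    """Fraction of edges explained by each known relationship class.

    Classes are non-exclusive: an edge counts toward every database it
    matches (shared term, or a known interaction pair). Also reports the
    union ("any") and unexplained fractions and, when endpoints are
    phosphosites, the fraction of edges between sites on one protein.
    """
    n_edges = len(edges)
    out: dict[str, float] = {}
    if n_edges == 0:
        return {"n_edges": 0}
    pa = edges["node_a"].map(lambda x: _node_protein(x, site_to_protein))
    pb = edges["node_b"].map(lambda x: _node_protein(x, site_to_protein))
    explained_any = np.zeros(n_edges, dtype=bool)
    for db in databases:
        if db.kind == "interaction":
            pairs = db.pairs
            hit = np.array([frozenset((x, y)) in pairs
                            for x, y in zip(pa, pb)])
        else:
            membership: dict[str, set] = {}
            for term, genes in db.term_to_genes.items():
                for g in genes:
                    membership.setdefault(g, set()).add(term)
            hit = np.array([
                bool(membership.get(x, set()) & membership.get(y, set()))
                for x, y in zip(pa, pb)])
        out[db.name] = float(hit.mean())
        explained_any |= hit
    out["any"] = float(explained_any.mean())
    out["unexplained"] = float(1.0 - explained_any.mean())
    same = (pa.to_numpy() == pb.to_numpy())
    if same.any() or (edges["node_a"] != pa).any():
        out["same_protein"] = float(same.mean())
    out["n_edges"] = n_edges
    return out


def neighbor_subnetwork(node: str, edges: pd.DataFrame,
                        sign_filter: str | None = None,
                        merged: pd.DataFrame | None = None) -> dict:
    """First-shell neighborhood of one node in the covariance network.

    ``sign_filter`` restricts to ``pos`` or ``neg`` edges. Returns the
    neighbor list, the induced edge table among {node} ∪ neighbors and,
    when ``merged`` profiles are supplied, the strain-pattern table for
    heatmap export.
    """
    in_network = set(edges["node_a"]) | set(edges["node_b"])
    if node not in in_network:
        raise DataError(f"node {node!r} is not in the network")
    sel = edges if sign_filter is None else edges[edges["sign"] == sign_filter]
    touching = sel[(sel["node_a"] == node) | (sel["node_b"] == node)]
    neighbors = sorted(
        (set(touching["node_a"]) | set(touching["node_b"])) - {node})
    members = set(neighbors) | {node}
    induced = sel[sel["node_a"].isin(members) &
                  sel["node_b"].isin(members)].reset_index(drop=True)
    profiles = None
    if merged is not None:
        present = [m for m in [node] + neighbors if m in merged.index]
        profiles = merged.loc[present]
    return {"node": node, "neighbors": neighbors, "edges": induced,
            "profiles": profiles}
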