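"""Δgene-Δgene functional correlation networks.

Two deletion strains with correlated perturbation profiles are likely to
act in the same pathway. For every strain pair the molecules responsive
in at least one of the two strains (|log2 ratio| above the level's floor)
and measured in both are correlated (Pearson). Pairs need at least 25
qualifying molecules; the deleted gene's own product is masked first so
the deletions themselves cannot create correlations. Edges keep
|r| ≥ 0.6; Benjamini-Hochberg adjusted p-values over all evaluated pairs
are recorded on every edge. Non-qualifying pairs enter the full
correlation matrix as 0.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from ._stats import bh_adjust, pearson_p_from_r, pearson_r_p
from .containers import EDGE_COLUMNS, RatioMatrix
from .io_formats import parse_site_key

logger = logging.getLogger("kinodelta")


def mask_deleted(matrix: RatioMatrix, deletion_map: dict,
                 site_to_protein: dict | None = None) -> RatioMatrix:
    """Blank the deleted gene's product in its cognate strain.

    At protein level the (deleted gene, strain) entries become missing;
    at phosphosite level every site on the deleted protein is masked in
    that strain.
    """
    out = matrix.copy()
    if matrix.level == "protein":
        for strain, gene in deletion_map.items():
            if gene in out.data.index and strain in {
                    s for s, _ in out.data.columns}:
                out.data.loc[gene, strain] = np.nan
    else:
        host = dict(site_to_protein or {})
        for site in out.data.index:
            if site not in host:
                try:
                    host[site] = parse_site_key(site).protein
                except Exception:
                    continue
        by_protein: dict[str, list] = {}
        for site, prot in host.items():
            by_protein.setdefault(prot, []).append(site)
        strains = {s for s, _ in out.data.columns}
        for strain, gene in deletion_map.items():
            sites = [s for s in by_protein.get(gene, [])
                     if s in out.data.index]
            if sites and strain in strains:
                out.data.loc[sites, strain] = np.nan
    return out


def select_pair_features(merged: pd.DataFrame, strain_a: str, strain_b: str,
                         fc_floor: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Paired profile values for one strain pair.

    Keeps molecules measured in both strains whose |log2 ratio| reaches
    ``fc_floor`` in at least one of the two.
    """
    a = merged[strain_a]
    b = merged[strain_b]
    keep = a.notna() & b.notna() & ((a.abs() >= fc_floor) |
                                    (b.abs() >= fc_floor))
    return a[keep].to_numpy(), b[keep].to_numpy(), int(keep.sum())


def gene_pair_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n−2 df) for one pair."""
    return pearson_r_p(x, y)


def build_gene_network(merged: pd.DataFrame, fc_floor: float,
                       r_min: float = 0.6, min_molecules: int = 25,
                       p_adj_max: float | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate all strain pairs; return (edge table, full r matrix).

    The symmetric matrix has unit diagonal; pairs that fail the edge
    criteria (insufficient molecules, |r| < ``r_min`` or, if given, BH
    adjusted p above ``p_adj_max``) are recorded as 0.
    """
    strains = list(merged.columns)
    values = merged.to_numpy(dtype=float)
    present = ~np.isnan(values)
    with np.errstate(invalid="ignore"):
        responsive = present & (np.abs(values) >= fc_floor)
    results = []
    for ia, ib in itertools.combinations(range(len(strains)), 2):
        keep = present[:, ia] & present[:, ib] & \
            (responsive[:, ia] | responsive[:, ib])
        n = int(keep.sum())
        if n < min_molecules:
            continue
        x, y = values[keep, ia], values[keep, ib]
        dx, dy = x - x.mean(), y - y.mean()
        den = float(np.sqrt((dx @ dx) * (dy @ dy)))
        if den == 0.0:
            r, p = 0.0, 1.0
        else:
            r = float(np.clip((dx @ dy) / den, -1.0, 1.0))
            p = float(pearson_p_from_r(r, n))
        results.append((strains[ia], strains[ib], r, n, p))
    edges = pd.DataFrame(results, columns=["node_a", "node_b", "r", "n", "p"])
    if len(edges):
        edges["p_adj"] = bh_adjust(edges["p"].to_numpy())
    else:
        edges["p_adj"] = pd.Series(dtype=float)
    edges["sign"] = np.where(edges["r"] >= 0, "pos", "neg")

    keep = edges["r"].abs() >= r_min
    if p_adj_max is not None:
        keep &= edges["p_adj"] <= p_adj_max
    kept = edges[keep].reset_index(drop=True)[EDGE_COLUMNS]

    matrix = pd.DataFrame(np.eye(len(strains)), index=strains,
                          columns=strains)
    for row in kept.itertuples(index=False):
        matrix.loc[row.node_a, row.node_b] = row.r
        matrix.loc[row.node_b, row.node_a] = row.r
    logger.info("gene network: %d/%d strain pairs evaluated, %d edges",
                len(edges), len(strains) * (len(strains) - 1) // 2, len(kept))
    return kept, matrix


def order_by_clustering(corr_matrix: pd.DataFrame) -> list[str]:
    """Average-linkage leaf order of a symmetric correlation matrix."""
    dist = 1.0 - corr_matrix.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    return [corr_matrix.index[i] for i in leaves_list(linkage)]
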