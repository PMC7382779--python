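"""Hypergeometric gene-set enrichment with Benjamini-Hochberg control.

Three modes share one engine:

* **regulator enrichment** — for each molecule, do the strains in which
  it is regulated over-represent a pathway's kinases/phosphatases (e.g.
  the HOG cascade) among all active regulators?
* **effector enrichment** — for each strain and direction, are its up-
  or down-regulated effector proteins enriched in an annotation term?
  Multiple phosphosites on one protein count once; the background is
  every perturbed protein in the regulation network.
* **neighbor enrichment** — for each node of a covariance network, are
  its positively correlated neighbors enriched in a term? The background
  is every positively connected protein except the node surveyed.

p is the upper hypergeometric tail P(X ≥ k); the BH family is all tests
within one database (all strains/nodes × all terms), filtered at
adjusted p ≤ 1%. Term universes are restricted to the background before
computing term sizes so annotation-only genes cannot inflate N.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import bh_adjust
from .containers import ENRICHMENT_COLUMNS, AnnotationDB
from .errors import DataError
from .io_formats import parse_site_key

logger = logging.getLogger("kinodelta")


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    N genes in the background, K of them annotated, n drawn; probability
    of at least k annotated among the draw. k = 0 gives 1.
    """
    if not (0 <= k <= min(K, n)):
        raise DataError(f"inconsistent counts: k={k}, K={K}, n={n}")
    if K > N or n > N or N < 0:
        raise DataError(f"inconsistent counts: K={K}, n={n}, N={N}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def _collapse_to_protein(molecule: str, site_to_protein: dict | None) -> str:
    if site_to_protein and molecule in site_to_protein:
        return site_to_protein[molecule]
    try:
        return parse_site_key(molecule).protein
    except Exception:
        return molecule


def _finish(rows: list[dict], alpha: float) -> pd.DataFrame:
    """BH-adjust a block of tests and filter at alpha."""
    frame = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if frame.empty:
        return frame
    frame = frame.sort_values(["context", "direction", "term"],
                              ignore_index=True)
    frame["p_adj"] = bh_adjust(frame["p"].to_numpy())
    out = frame[frame["p_adj"] <= alpha].reset_index(drop=True)
    return out.sort_values(["p_adj", "p", "term"], ignore_index=True)


def regulator_enrichment(calls: pd.DataFrame, pathway_regulators: set,
                         active_background: set, alpha: float = 0.01,
                         consistency: bool = True) -> pd.DataFrame:
    """Molecules whose regulating strains over-represent a pathway.

    For each molecule: N = active regulators, K = pathway regulators,
    n = strains regulating the molecule, k = their overlap with the
    pathway. With ``consistency`` set, molecules whose call directions
    differ across their pathway strains are removed after testing.
    """
    background = set(active_background)
    if not background:
        raise DataError("active_background is empty")
    pathway = set(pathway_regulators) & background
    if pathway != set(pathway_regulators):
        raise DataError("pathway regulators must be a subset of the "
                        "active background")
    sub = calls[calls["strain"].isin(background)]
    N, K = len(background), len(pathway)
    rows = []
    for molecule, grp in sub.groupby("molecule"):
        strains = set(grp["strain"])
        n = len(strains)
        k = len(strains & pathway)
        rows.append({"context": molecule, "term": "pathway",
                     "direction": "regulators", "k": k, "K": K, "n": n,
                     "N": N, "p": hypergeometric_tail(k, K, n, N),
                     "p_adj": np.nan})
    out = _finish(rows, alpha)
    if consistency and len(out):
        consistent = []
        for molecule in out["context"]:
            grp = sub[(sub["molecule"] == molecule) &
                      sub["strain"].isin(pathway)]
            consistent.append(grp["direction"].nunique() <= 1)
        removed = int(len(out) - sum(consistent))
        if removed:
            logger.info("consistency filter removed %d molecules", removed)
        out = out[np.array(consistent, dtype=bool)].reset_index(drop=True)
    return out


def effector_enrichment(calls: pd.DataFrame, databases: list[AnnotationDB],
                        alpha: float = 0.01,
                        site_to_protein: dict | None = None,
                        direction_split: bool = True) -> pd.DataFrame:
    """Per-strain enrichment of up-/down-regulated effector proteins.

    Phosphosite calls collapse to their host protein. The background is
    the union of perturbed proteins over all strains; the BH family is
    all strains × directions × terms within one database.
    """
    calls = calls.copy()
    calls["protein"] = [
        _collapse_to_protein(m, site_to_protein) for m in calls["molecule"]]
    background = set(calls["protein"])
    if not background:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    N = len(background)
    directions = ["up", "down"] if direction_split else ["any"]
    blocks = []
    for db in databases:
        if db.kind == "interaction":
            continue
        terms = {t: set(g) & background
                 for t, g in db.term_to_genes.items()}
        terms = {t: g for t, g in terms.items() if g}
        rows = []
        for strain, grp in calls.groupby("strain"):
            for direction in directions:
                if direction == "any":
                    query = set(grp["protein"])
                else:
                    query = set(grp.loc[grp["direction"] == direction,
                                        "protein"])
                n = len(query)
                for term, members in sorted(terms.items()):
                    k = len(query & members)
                    rows.append({
                        "context": strain, "term": f"{db.name}:{term}",
                        "direction": direction, "k": k, "K": len(members),
                        "n": n, "N": N,
                        "p": hypergeometric_tail(k, len(members), n, N),
                        "p_adj": np.nan})
        blocks.append(_finish(rows, alpha))
    if not blocks:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(blocks, ignore_index=True)


def neighbor_enrichment(edges: pd.DataFrame, databases: list[AnnotationDB],
                        nodes: list | None = None, alpha: float = 0.01,
                        site_to_protein: dict | None = None) -> pd.DataFrame:
    """Enrichment of each node's positively correlated neighbors.

    Query = positive neighbors (as proteins); background = all
    positively connected proteins minus the node surveyed; BH across all
    nodes and terms per database.
    """
    pos = edges[edges["sign"] == "pos"]
    neighbor_map: dict[str, set] = {}
    for row in pos.itertuples(index=False):
        pa = _collapse_to_protein(row.node_a, site_to_protein)
        pb = _collapse_to_protein(row.node_b, site_to_protein)
        neighbor_map.setdefault(row.node_a, set()).add(pb)
        neighbor_map.setdefault(row.node_b, set()).add(pa)
    connected = {_collapse_to_protein(n, site_to_protein)
                 for n in neighbor_map}
    surveyed = nodes if nodes is not None else sorted(neighbor_map)
    blocks = []
    for db in databases:
        if db.kind == "interaction":
            continue
        rows = []
        for node in surveyed:
            if node not in neighbor_map:
                continue
            me = _collapse_to_protein(node, site_to_protein)
            background = connected - {me}
            terms = {t: set(g) & background
                     for t, g in db.term_to_genes.items()}
            terms = {t: g for t, g in terms.items() if g}
            query = neighbor_map[node] & background
            n, N = len(query), len(background)
            if n == 0 or N == 0:
                continue
            for term, members in sorted(terms.items()):
                k = len(query & members)
                rows.append({
                    "context": node, "term": f"{db.name}:{term}",
                    "direction": "neighbors", "k": k, "K": len(members),
                    "n": n, "N": N,
                    "p": hypergeometric_tail(k, len(members), n, N),
                    "p_adj": np.nan})
        blocks.append(_finish(rows, alpha))
    if not blocks:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(blocks, ignore_index=True)
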