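"""Regulation-event calling per deletion strain.

For every molecule, variability across the strain panel is summarized by
a trimmed standard deviation (top and bottom 5% of merged changes
removed). A molecule is called regulated in a strain when

* both biological replicates are quantified, each replicate's |log2
  ratio| exceeds 3 × trimmed SD and the replicates agree in sign, or
* a single replicate is quantified and exceeds 6 × trimmed SD,

and the merged (mean) ratio clears a level-specific fold-change floor
(log2 0.38 for proteins ≈ 1.3-fold, 0.5 for phosphosites ≈ 1.4-fold).
The deleted gene's own product (and its phosphosites) is excluded from
its strain's effector calls — it is the perturbation, not a response.

Phosphorylation calls made on the raw and the protein-normalized site
matrices are compared to attribute each event to protein abundance
(``protein_driven``), phosphorylation stoichiometry (``phospho_driven``)
or to changes unmasked only after normalization (``newly_captured``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CALL_COLUMNS, RatioMatrix
from .io_formats import parse_site_key

logger = logging.getLogger("kinodelta")

#: default merged log2-ratio floors (minimum fold changes 1.3 and 1.4)
FC_FLOOR = {"protein": 0.38, "phosphosite": 0.5}


@dataclass(frozen=True)
class TrimmedStats:
    """Per-molecule trimmed SD and derived call thresholds."""

    molecule: str
    sd: float
    n_used: int

    @property
    def thresholds(self) -> tuple[float, float]:
        return 3 * self.sd, 6 * self.sd


def merge_replicates(matrix: RatioMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean of available replicates per strain, plus support labels.

    Returns (merged molecules × strains frame, support frame with
    values ``both`` / ``single`` / NaN).
    """
    merged = matrix.data.T.groupby(level=0).mean().T
    counts = matrix.data.notna().T.groupby(level=0).sum().T
    support = pd.DataFrame(np.where(counts >= 2, "both",
                                    np.where(counts == 1, "single", None)),
                           index=counts.index, columns=counts.columns)
    return merged, support


def trimmed_sd(values, trim: float = 0.05) -> TrimmedStats | None:
    """SD after discarding floor(trim·n) values from each tail.

    Returns None (caller logs the exclusion) when fewer than 3 values
    are available. SD uses the n−1 denominator; a constant profile has
    SD 0.
    """
    arr = np.sort(np.asarray(pd.Series(values).dropna(), dtype=float))
    n = arr.size
    if n < 3:
        return None
    k = math.floor(trim * n)
    kept = arr[k: n - k] if k else arr
    sd = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
    return TrimmedStats("", sd, int(kept.size))


def compute_trimmed_stats(merged: pd.DataFrame,
                          trim: float = 0.05) -> pd.DataFrame:
    """Trimmed SD per molecule over merged strain values.

    Molecules with fewer than 3 strain values are excluded (warning).
    Returns a frame indexed by molecule with columns ``sd``, ``n_used``.
    """
    records, dropped = {}, 0
    for mol, row in merged.iterrows():
        stats = trimmed_sd(row, trim)
        if stats is None:
            dropped += 1
            continue
        records[mol] = (stats.sd, stats.n_used)
    if dropped:
        logger.warning("%d molecules excluded from calling (<3 strain "
                       "values)", dropped)
    out = pd.DataFrame.from_dict(records, orient="index",
                                 columns=["sd", "n_used"])
    out.index.name = "molecule"
    return out


def _self_mask(index, strains, deletion_map, level, site_to_protein):
    """Boolean frame marking the deleted gene's own product per strain."""
    mask = pd.DataFrame(False, index=index, columns=strains)
    if not deletion_map:
        return mask
    if level == "protein":
        owner = {g: s for s, g in deletion_map.items()}
        for mol in index:
            s = owner.get(mol)
            if s is not None and s in mask.columns:
                mask.loc[mol, s] = True
    else:
        owner = {g: s for s, g in deletion_map.items()}
        host = site_to_protein or {}
        for mol in index:
            prot = host.get(mol)
            if prot is None:
                try:
                    prot = parse_site_key(mol).protein
                except Exception:
                    continue
            s = owner.get(prot)
            if s is not None and s in mask.columns:
                mask.loc[mol, s] = True
    return mask


def call_regulated_events(matrix: RatioMatrix, stats: pd.DataFrame,
                          fc_floor: float | None = None,
                          sd_mult_both: float = 3.0,
                          sd_mult_single: float = 6.0,
                          deletion_map: dict | None = None,
                          site_to_protein: dict | None = None,
                          level: str | None = None) -> pd.DataFrame:
    """Apply the replicate-aware SD and fold-change rules.

    Returns a call table with columns strain, molecule, level,
    direction, ratio (merged), support.
    """
    level = level or matrix.level
    if fc_floor is None:
        fc_floor = FC_FLOOR["protein" if level == "protein" else "phosphosite"]
    data = matrix.data
    if matrix.protein_normalized is not None:
        # a pass-through (unnormalized) entry confounds stoichiometry with
        # protein abundance; it cannot support a normalized-level call
        data = data.where(matrix.protein_normalized)
    data = data.loc[data.index.intersection(stats.index)]
    if data.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    sd = stats["sd"].reindex(data.index)

    present = data.notna()
    nrep = present.T.groupby(level=0).sum().T
    merged = data.T.groupby(level=0).mean().T

    thr_both = sd * sd_mult_both
    ok_mag = data.abs().ge(thr_both, axis=0) | ~present
    all_mag = ok_mag.T.groupby(level=0).all().T
    all_pos = (data.gt(0) | ~present).T.groupby(level=0).all().T
    all_neg = (data.lt(0) | ~present).T.groupby(level=0).all().T

    both_call = (nrep >= 2) & all_mag & (all_pos | all_neg)
    single_call = (nrep == 1) & merged.abs().ge(sd * sd_mult_single, axis=0)
    called = (both_call | single_call) & merged.abs().ge(fc_floor)

    self_mask = _self_mask(data.index, called.columns, deletion_map or {},
                           "protein" if level == "protein" else "phosphosite",
                           site_to_protein)
    called &= ~self_mask

    stacked = called.stack()
    hits = stacked[stacked].index
    records = pd.DataFrame({
        "strain": hits.get_level_values(1),
        "molecule": hits.get_level_values(0),
        "level": level,
        "direction": np.where(
            merged.stack().reindex(hits) > 0, "up", "down"),
        "ratio": merged.stack().reindex(hits).to_numpy(),
        "support": np.where(nrep.stack().reindex(hits) >= 2,
                            "both", "single"),
    })
    return records.sort_values(["strain", "molecule"],
                               ignore_index=True)


def attribute_phospho_events(raw_calls: pd.DataFrame,
                             normalized_calls: pd.DataFrame
                             ) -> tuple[pd.DataFrame, dict]:
    """Classify phosphorylation events by comparing raw vs normalized calls.

    * ``protein_driven`` — called on the raw site matrix only: the site
      moved because its protein did.
    * ``phospho_driven`` — called on both: a genuine stoichiometry change.
    * ``newly_captured`` — called only after protein normalization.

    Returns the merged event table with an ``attribution`` column and a
    summary dict with class counts and fractions (overall and per strain).
    """
    raw_keys = set(zip(raw_calls["strain"], raw_calls["molecule"]))
    norm_keys = set(zip(normalized_calls["strain"],
                        normalized_calls["molecule"]))

    def classify(key):
        if key in raw_keys and key in norm_keys:
            return "phospho_driven"
        if key in raw_keys:
            return "protein_driven"
        return "newly_captured"

    norm_only = normalized_calls[
        ~normalized_calls.set_index(["strain", "molecule"]).index.isin(
            raw_keys)]
    events = pd.concat([raw_calls, norm_only], ignore_index=True)
    events["attribution"] = [
        classify((s, m)) for s, m in zip(events["strain"], events["molecule"])]

    counts = events["attribution"].value_counts().to_dict()
    total = int(len(events))
    fractions = {cls: counts.get(cls, 0) / total if total else float("nan")
                 for cls in ("protein_driven", "phospho_driven",
                             "newly_captured")}
    per_strain = (events.groupby("strain")["attribution"]
                  .value_counts(normalize=True).unstack(fill_value=0.0))
    summary = {"counts": counts, "fractions": fractions,
               "per_strain": per_strain, "n_events": total}
    return events, summary


def impact_factor(calls: pd.DataFrame, merged: pd.DataFrame) -> pd.Series:
    """Percent of quantified molecules called regulated, per strain."""
    quantified = merged.notna().sum(axis=0)
    n_calls = calls.groupby("strain").size().reindex(quantified.index,
                                                     fill_value=0)
    with np.errstate(invalid="ignore"):
        return 100.0 * n_calls / quantified


def build_regulation_network(calls: pd.DataFrame
                             ) -> tuple[nx.DiGraph, dict]:
    """Bipartite regulator → effector network plus summary counts."""
    g = nx.DiGraph()
    for row in calls.itertuples(index=False):
        g.add_node(row.strain, role="regulator")
        g.add_node(row.molecule, role="effector")
        g.add_edge(row.strain, row.molecule, direction=row.direction,
                   level=row.level, ratio=row.ratio)
    regulators = {n for n, d in g.nodes(data=True)
                  if d.get("role") == "regulator"}
    summary = {
        "n_regulators": len(regulators),
        "n_effectors": g.number_of_nodes() - len(regulators),
        "n_up": int((calls["direction"] == "up").sum()),
        "n_down": int((calls["direction"] == "down").sum()),
        "n_edges": g.number_of_edges(),
    }
    return g, summary
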