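"""From per-plex reporter intensities to joined log2 ratio matrices.

The chain mirrors standard bridge-channel TMT processing:

1. isotopic impurity correction (solve the reagent mixing system),
2. peptide filtering on summed signal-to-noise and isolation specificity,
3. roll-up of unique peptides to proteins,
4. loading equalization (equal summed protein signal per channel), with
   the protein-derived factors reused for the phosphosite table,
5. log2 ratio to the wild-type bridge channel,
6. per-column trimmed-mean centering (absorbs bridge measurement error),
7. joining plexes by molecule identification,
8. protein normalization of phosphosite ratios (subtract the cognate
   protein ratio so the remainder reflects phosphorylation stoichiometry),
9. coverage filtering (molecules quantified in ≥ 50% of strains).

All operations accept and return :class:`PlexIntensityTable` /
:class:`RatioMatrix` containers and leave their inputs untouched.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from ._stats import pairwise_complete_pearson
from .containers import PlexIntensityTable, RatioMatrix
from .errors import DataError, DesignError, NumericError

logger = logging.getLogger("kinodelta")


def correct_isotopic_impurities(table: PlexIntensityTable,
                                impurity_matrix: np.ndarray) -> PlexIntensityTable:
    """Invert the reagent isotopic-impurity mixing per molecule.

    ``impurity_matrix[i, j]`` is the fraction of channel ``j``'s true
    signal observed in channel ``i``; observed = M · true. Negative
    solutions are clamped to 0 (count logged). Rows with missing
    channels pass through uncorrected.
    """
    M = np.asarray(impurity_matrix, dtype=float)
    k = table.data.shape[1]
    if M.shape != (k, k):
        raise DataError(f"impurity matrix must be {k}×{k}, got {M.shape}")
    if (M.sum(axis=0) > 1 + 1e-9).any():
        raise DataError("impurity matrix columns must sum to <= 1")
    if abs(np.linalg.det(M)) < 1e-12:
        raise NumericError("impurity matrix is singular")
    out = table.copy()
    values = out.data.to_numpy()
    complete = ~np.isnan(values).any(axis=1)
    if complete.any():
        solved = np.linalg.solve(M, values[complete].T).T
        n_neg = int((solved < 0).sum())
        if n_neg:
            logger.info("impurity correction clamped %d negative values "
                        "in plex %s", n_neg, table.plex_id)
        values[complete] = np.clip(solved, 0.0, None)
    out.data = pd.DataFrame(values, index=out.data.index,
                            columns=out.data.columns)
    return out


def filter_peptides(table: PlexIntensityTable, noise: pd.Series,
                    specificity: pd.Series, snr_sum_min: float = 200.0,
                    isolation_min: float = 0.5) -> PlexIntensityTable:
    """Keep peptides with Σ(S/N) ≥ ``snr_sum_min`` across channels and
    isolation specificity ≥ ``isolation_min`` (both inclusive)."""
    if table.level != "peptide":
        raise DataError("filter_peptides expects a peptide-level table")
    missing = [c for c in table.data.columns if c not in noise.index]
    if missing:
        raise DataError(f"noise estimates missing for channels {missing}")
    absent = table.data.index.difference(specificity.index)
    if len(absent):
        raise DataError(f"isolation specificity missing for peptides "
                        f"{list(absent[:5])}")
    snr = (table.data / noise[table.data.columns]).sum(axis=1, min_count=1)
    keep = (snr >= snr_sum_min) & \
           (specificity.reindex(table.data.index) >= isolation_min)
    out = table.copy()
    out.data = out.data.loc[keep.fillna(False)]
    return out


def rollup_peptides_to_protein(table: PlexIntensityTable,
                               peptide_to_protein: dict) -> PlexIntensityTable:
    """Sum unique peptides per protein and channel.

    Peptides mapping to more than one protein (value is a set/list with
    several members) or to none are discarded; a protein-channel cell is
    missing when no contributing peptide was measured.
    """
    if table.level != "peptide":
        raise DataError("rollup expects a peptide-level table")
    assign = {}
    for pep, prot in peptide_to_protein.items():
        if isinstance(prot, (set, frozenset, list, tuple)):
            if len(prot) != 1:
                continue        # shared peptide: excluded from all proteins
            prot = next(iter(prot))
        assign[pep] = prot
    usable = [p for p in table.data.index if p in assign]
    grouped = table.data.loc[usable].groupby(
        [assign[p] for p in usable]).sum(min_count=1)
    return PlexIntensityTable(table.plex_id, "protein", grouped,
                              table.channels.copy())


def equalize_loading(table: PlexIntensityTable
                     ) -> tuple[PlexIntensityTable, pd.Series]:
    """Scale channels so summed protein signal is equal within the plex.

    Column sums are computed over molecules observed in every channel so
    missingness cannot bias the factors; each channel is multiplied by
    mean(sums)/sum(channel). Returns the corrected table and the factors
    for reuse on the plex's phosphosite table.
    """
    if table.level != "protein":
        raise DataError("equalize_loading expects a protein-level table")
    complete = table.data.dropna()
    if complete.empty:
        raise DataError(f"plex {table.plex_id}: no molecule observed in all "
                        "channels; cannot estimate loading")
    sums = complete.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise DataError(f"plex {table.plex_id}: channels with zero total "
                        f"signal: {bad}")
    factors = sums.mean() / sums
    out = table.copy()
    out.data = out.data * factors
    return out, factors


def apply_loading_to_phospho(phospho_table: PlexIntensityTable,
                             factors: pd.Series) -> PlexIntensityTable:
    """Apply protein-derived loading factors to the phosphosite table."""
    if list(phospho_table.data.columns) != list(factors.index):
        raise DesignError("loading factors do not match phospho channels")
    out = phospho_table.copy()
    out.data = out.data * factors
    return out


def bridge_log2_ratios(table: PlexIntensityTable) -> pd.DataFrame:
    """log2(sample) − log2(bridge) per molecule; bridge column consumed.

    Zeros are treated as missing (logged); a molecule missing in the
    bridge loses all its ratios in the plex. Returns a frame with
    (strain, replicate) MultiIndex columns.
    """
    data = table.data.where(table.data > 0)
    n_zero = int((table.data == 0).sum().sum())
    if n_zero:
        logger.info("plex %s: %d zero intensities treated as missing",
                    table.plex_id, n_zero)
    bridge = data[table.bridge_channel]
    samples = data[table.sample_channels]
    ratios = np.log2(samples).sub(np.log2(bridge), axis=0)
    meta = table.channels.loc[table.sample_channels]
    ratios.columns = pd.MultiIndex.from_arrays(
        [meta["strain"], meta["replicate"]], names=["strain", "replicate"])
    return ratios


def center_trimmed_mean(ratios: pd.DataFrame,
                        trim_fraction: float = 0.05) -> pd.DataFrame:
    """Subtract each column's trimmed mean (``trim_fraction`` per tail).

    Absorbs the bridge channel's own measurement error: after centering
    the trimmed mean of every column is 0.
    """
    out = ratios.copy()
    for col in out.columns:
        vals = out[col].dropna().to_numpy()
        if vals.size == 0:
            continue
        out[col] = out[col] - sps.trim_mean(vals, trim_fraction)
    return out


def join_plexes(per_plex_ratios: list[pd.DataFrame],
                level: str = "protein") -> RatioMatrix:
    """Join per-plex ratio columns by molecule identification.

    The joined matrix holds the union of molecules; entries are missing
    where a molecule was absent from a plex. Duplicate (strain,
    replicate) columns are a design error.
    """
    joined = pd.concat(per_plex_ratios, axis=1)
    dup = joined.columns[joined.columns.duplicated()]
    if len(dup):
        raise DesignError(f"duplicate (strain, replicate) columns: "
                          f"{sorted(set(dup))}")
    joined = joined.sort_index(axis=1)
    return RatioMatrix(level, joined)


def normalize_phospho_by_protein(phospho: RatioMatrix, protein: RatioMatrix,
                                 site_to_protein: dict
                                 ) -> tuple[RatioMatrix, float]:
    """Subtract the cognate protein's log2 ratio from each phosphosite.

    Entries lacking a cognate protein ratio (protein not quantified in
    that strain/replicate, or site not mapping to a known protein) keep
    the unnormalized value and are flagged False in
    ``protein_normalized``. Returns the matrix and the fraction of
    non-missing entries that could be normalized.
    """
    if phospho.level != "phosphosite":
        raise DataError("expected a phosphosite-level matrix")
    grid = phospho.data.columns
    if not grid.equals(protein.data.columns):
        raise DataError("phospho and protein matrices must share the "
                        "strain × replicate grid")
    hosts = [site_to_protein.get(site) for site in phospho.data.index]
    unknown = sum(h is None or h not in protein.data.index for h in hosts)
    if unknown:
        logger.warning("%d phosphosites lack a quantified cognate protein "
                       "row", unknown)
    rows = []
    for h in hosts:
        if h is not None and h in protein.data.index:
            rows.append(protein.data.loc[h].to_numpy())
        else:
            rows.append(np.full(len(grid), np.nan))
    host_rows = pd.DataFrame(rows, index=phospho.data.index, columns=grid)
    normalizable = phospho.data.notna() & host_rows.notna()
    normalized = phospho.data.where(~normalizable,
                                    phospho.data - host_rows)
    present = int(phospho.data.notna().sum().sum())
    fraction = float(normalizable.sum().sum() / present) if present else 0.0
    logger.info("protein-normalized %.1f%% of phosphosite measurements",
                100 * fraction)
    return RatioMatrix("phosphosite", normalized, normalizable), fraction


def filter_min_coverage(matrix: RatioMatrix,
                        min_fraction: float = 0.5) -> RatioMatrix:
    """Keep molecules quantified (any replicate) in ≥ ceil(f·n) strains."""
    by_strain = matrix.data.notna().T.groupby(level=0).any().T
    n_strains = by_strain.shape[1]
    need = math.ceil(min_fraction * n_strains)
    keep = by_strain.sum(axis=1) >= need
    pn = matrix.protein_normalized
    return RatioMatrix(matrix.level, matrix.data.loc[keep],
                       None if pn is None else pn.loc[keep])


def cluster_samples(matrix: RatioMatrix):
    """Average-linkage clustering of samples on correlation distance.

    Distance is 1 − pairwise-complete Pearson r between sample columns.
    Columns sharing fewer than 3 observations with every other column
    are excluded with a warning.

    Returns (linkage, leaf order, labels) where labels are
    ``strain|replicate`` strings in input order.
    """
    if matrix.data.shape[1] < 2:
        raise DataError("clustering needs at least 2 sample columns")
    labels = [f"{s}|{r}" for s, r in matrix.data.columns]
    r, n = pairwise_complete_pearson(matrix.data.to_numpy().T)
    usable = np.array([bool((n[i] >= 3).sum() > 1) for i in range(len(labels))])
    if not usable.all():
        dropped = [lab for lab, u in zip(labels, usable) if not u]
        logger.warning("excluding samples with <3 shared values: %s", dropped)
    idx = np.where(usable)[0]
    r = r[np.ix_(idx, idx)]
    labels = [labels[i] for i in idx]
    dist = 1.0 - np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    order = list(leaves_list(linkage))
    return linkage, order, labels


def normalize_plexes(tables: list[PlexIntensityTable],
                     phospho_tables: list[PlexIntensityTable] | None = None,
                     trim_fraction: float = 0.05
                     ) -> tuple[RatioMatrix, RatioMatrix | None]:
    """Equalize → bridge ratio → center → join, for one study.

    ``phospho_tables`` (matched by plex ID) are scaled with the protein
    loading factors before their own ratio/centering/join chain.
    """
    phospho_by_plex = {t.plex_id: t for t in (phospho_tables or [])}
    prot_cols, phos_cols = [], []
    for table in tables:
        equalized, factors = equalize_loading(table)
        prot_cols.append(center_trimmed_mean(bridge_log2_ratios(equalized),
                                             trim_fraction))
        if table.plex_id in phospho_by_plex:
            scaled = apply_loading_to_phospho(phospho_by_plex[table.plex_id],
                                              factors)
            phos_cols.append(center_trimmed_mean(bridge_log2_ratios(scaled),
                                                 trim_fraction))
    protein = join_plexes(prot_cols, "protein")
    phospho = join_plexes(phos_cols, "phosphosite") if phos_cols else None
    return protein, phospho


def process_study(protein_tables: list[PlexIntensityTable],
                  phospho_tables: list[PlexIntensityTable],
                  site_to_protein: dict, min_fraction: float = 0.5,
                  trim_fraction: float = 0.05) -> dict:
    """Full normalization chain for one study.

    Returns a dict with the coverage-filtered protein matrix, the raw
    and protein-normalized phosphosite matrices, and the fraction of
    normalizable phosphosite measurements.
    """
    protein, phospho_raw = normalize_plexes(protein_tables, phospho_tables,
                                            trim_fraction)
    phospho_norm, fraction = normalize_phospho_by_protein(
        phospho_raw, protein, site_to_protein)
    return {
        "protein": filter_min_coverage(protein, min_fraction),
        "phospho_raw": filter_min_coverage(phospho_raw, min_fraction),
        "phospho_norm": filter_min_coverage(phospho_norm, min_fraction),
        "normalizable_fraction": fraction,
    }
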