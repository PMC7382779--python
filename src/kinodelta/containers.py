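"""Core in-memory containers shared across pipeline stages.

The quantitative containers wrap :class:`pandas.DataFrame` objects:

``PlexIntensityTable``
    one multiplexed run — molecules × reporter channels, non-negative
    intensities, NaN encodes "not quantified in this plex".
``RatioMatrix``
    the joined, replicate-resolved log2 ratio matrix — molecules ×
    (strain, replicate) MultiIndex columns.
``PlexDesign``
    the channel layout of every plex (strain, replicate, bridge flag,
    growth batch).

Tabular results (regulation calls, correlation edges, enrichment results)
are plain DataFrames with documented column contracts; see
:data:`CALL_COLUMNS`, :data:`EDGE_COLUMNS` and :data:`ENRICHMENT_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DesignError

LEVELS = ("peptide", "protein", "phosphosite")

#: columns of a regulation-call table
CALL_COLUMNS = ["strain", "molecule", "level", "direction", "ratio", "support"]

#: columns of a correlation-edge table
EDGE_COLUMNS = ["node_a", "node_b", "r", "n", "p", "p_adj", "sign"]

#: columns of an enrichment-result table
ENRICHMENT_COLUMNS = [
    "context", "term", "direction", "k", "K", "n", "N", "p", "p_adj",
]


@dataclass
class PlexIntensityTable:
    """Reporter intensities for one isobaric plex.

    Parameters
    ----------
    plex_id
        Unique identifier of the plex.
    level
        One of ``peptide``, ``protein``, ``phosphosite``.
    data
        molecules × channels intensities; NaN = missing. Row index are
        molecule IDs, columns are channel IDs.
    channels
        Channel metadata indexed by channel ID with columns ``strain``,
        ``replicate`` (int), ``bridge`` (bool) and optionally ``batch``.
    """

    plex_id: str
    level: str
    data: pd.DataFrame
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise DataError(f"unknown level {self.level!r}")
        if list(self.data.columns) != list(self.channels.index):
            raise DataError(
                f"plex {self.plex_id}: data columns do not match channel table"
            )
        if int(self.channels["bridge"].sum()) != 1:
            raise DesignError(
                f"plex {self.plex_id}: expected exactly one bridge channel, "
                f"found {int(self.channels['bridge'].sum())}"
            )
        if (self.data.to_numpy() < 0).any():
            raise DataError(f"plex {self.plex_id}: negative intensities")

    @property
    def bridge_channel(self) -> str:
        return self.channels.index[self.channels["bridge"]][0]

    @property
    def sample_channels(self) -> list[str]:
        return list(self.channels.index[~self.channels["bridge"]])

    def copy(self) -> "PlexIntensityTable":
        return PlexIntensityTable(
            self.plex_id, self.level, self.data.copy(), self.channels.copy()
        )


@dataclass
class RatioMatrix:
    """Joined log2-ratio matrix, molecules × (strain, replicate).

    ``protein_normalized`` is a same-shaped boolean frame (phosphosite
    level only) flagging entries from which the cognate protein ratio has
    been subtracted.
    """

    level: str
    data: pd.DataFrame
    protein_normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise DataError(f"unknown level {self.level!r}")
        if self.data.columns.nlevels != 2:
            raise DataError("RatioMatrix columns must be (strain, replicate)")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise DataError("RatioMatrix contains non-finite ratios")

    @property
    def strains(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def copy(self) -> "RatioMatrix":
        pn = None if self.protein_normalized is None else self.protein_normalized.copy()
        return RatioMatrix(self.level, self.data.copy(), pn)


@dataclass
class PlexDesign:
    """Channel layout of a multi-plex experiment.

    ``table`` has one row per channel with columns ``plex``, ``channel``,
    ``strain``, ``replicate``, ``bridge``, ``batch``.
    """

    table: pd.DataFrame

    REQUIRED = ("plex", "channel", "strain", "replicate", "bridge", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        per_plex = self.table.groupby("plex")["bridge"].sum()
        bad = per_plex[per_plex != 1]
        if len(bad):
            raise DesignError(
                f"plexes without exactly one bridge channel: {list(bad.index)}"
            )
        samp = self.table[~self.table["bridge"]]
        dup = samp.duplicated(subset=["strain", "replicate"])
        if dup.any():
            pairs = samp.loc[dup, ["strain", "replicate"]].itertuples(index=False)
            raise DesignError(
                f"duplicate (strain, replicate) assignments: {list(pairs)}"
            )

    @property
    def plex_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["plex"]))

    @property
    def n_plexes(self) -> int:
        return len(self.plex_ids)

    @property
    def strains(self) -> list[str]:
        samp = self.table[~self.table["bridge"]]
        return list(dict.fromkeys(samp["strain"]))

    def channels_of(self, plex_id: str) -> pd.DataFrame:
        sub = self.table[self.table["plex"] == plex_id]
        if sub.empty:
            raise DesignError(f"unknown plex {plex_id!r}")
        out = sub.set_index("channel")[["strain", "replicate", "bridge", "batch"]]
        return out


@dataclass
class AnnotationDB:
    """A named collection of gene sets or pairwise relationships.

    ``kind`` is one of ``pathway``, ``complex``, ``cellular_component``,
    ``molecular_function``, ``interaction``. For ``interaction`` the
    members of the single pseudo-term ``pairs`` are unordered gene pairs
    stored as frozensets.
    """

    name: str
    kind: str
    term_to_genes: dict[str, set] = field(default_factory=dict)

    KINDS = ("pathway", "complex", "cellular_component", "molecular_function",
             "interaction")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise DataError(f"unknown annotation kind {self.kind!r}")
        for term, members in self.term_to_genes.items():
            if not members:
                raise DataError(f"annotation term {term!r} is empty")

    @property
    def pairs(self) -> set[frozenset]:
        if self.kind != "interaction":
            raise DataError(f"{self.name}: not an interaction database")
        return self.term_to_genes.get("pairs", set())


@dataclass(frozen=True)
class PhosphoSiteKey:
    """A localized phosphosite (or site combination) on one protein.

    Sites are (residue, 1-based position) with residue in S/T/Y, strictly
    increasing positions. Serializes as ``PROT_pS123`` or
    ``PROT_pS123_pT130``.
    """

    protein: str
    sites: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise DataError("phosphosite key needs at least one site")
        positions = [p for _, p in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise DataError("site positions must be strictly increasing")
        for res, pos in self.sites:
            if res not in "STY":
                raise DataError(f"invalid phospho residue {res!r}")
            if pos < 1:
                raise DataError("site positions are 1-based")

    def __str__(self) -> str:
        return self.protein + "".join(f"_p{r}{p}" for r, p in self.sites)
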