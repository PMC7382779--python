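"""Readers and writers for every external artifact.

Formats:

* intensity / ratio matrices — TSV, first column molecule ID, empty cell
  encodes a missing value (never ``NA`` or 0, which would be ambiguous
  against true zeros),
* plex designs — TSV with columns plex/channel/strain/replicate/bridge/batch,
* gene sets — standard GMT (term, description, members),
* pairwise relationships — two-column TSV (one unordered pair per line),
* networks — SIF (``node  interaction  node``) or edge TSV carrying r, p
  and adjusted p.

Readers validate and raise :class:`~kinodelta.errors.FormatError` with a
row reference rather than silently coercing malformed input; every writer
produces files its paired reader round-trips.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (AnnotationDB, PhosphoSiteKey, PlexDesign,
                         PlexIntensityTable, RatioMatrix)
from .errors import FormatError

logger = logging.getLogger("kinodelta")


# ---------------------------------------------------------------- matrices

def _read_tsv_matrix(path) -> pd.DataFrame:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    index, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(f"{path}: ragged row at line {lineno} "
                              f"({len(row)} fields, expected {width})")
        index.append(row[0])
        vals = []
        for j, cell in enumerate(row[1:], start=1):
            if cell == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                    f"column {header[j]!r}") from exc
        data.append(vals)
    dup = pd.Index(index)[pd.Index(index).duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate molecule IDs: "
                          f"{sorted(set(dup))}")
    frame = pd.DataFrame(data, index=index, columns=header[1:], dtype=float)
    frame.index.name = header[0] or "molecule"
    return frame


def _write_tsv_matrix(frame: pd.DataFrame, path) -> None:
    frame = frame.copy()
    frame.index.name = frame.index.name or "molecule"
    frame.to_csv(path, sep="\t", na_rep="")


def read_intensity_table(path, channels: pd.DataFrame, plex_id: str,
                         level: str = "protein") -> PlexIntensityTable:
    """Read one plex intensity matrix; ``channels`` supplies metadata."""
    frame = _read_tsv_matrix(path)
    if (frame.to_numpy() < 0).any():
        bad = frame.index[(frame < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative intensity for molecule {bad!r}")
    return PlexIntensityTable(plex_id, level, frame, channels)


def write_intensity_table(table: PlexIntensityTable, path) -> None:
    _write_tsv_matrix(table.data, path)


def read_ratio_matrix(path, level: str = "protein") -> RatioMatrix:
    """Read a joined ratio matrix; columns are ``strain|replicate``."""
    frame = _read_tsv_matrix(path)
    cols = []
    for c in frame.columns:
        strain, _, rep = c.rpartition("|")
        if not strain or not rep.isdigit():
            raise FormatError(f"{path}: column {c!r} is not strain|replicate")
        cols.append((strain, int(rep)))
    frame.columns = pd.MultiIndex.from_tuples(cols,
                                              names=["strain", "replicate"])
    return RatioMatrix(level, frame)


def write_ratio_matrix(matrix: RatioMatrix, path) -> None:
    flat = matrix.data.copy()
    flat.columns = [f"{s}|{r}" for s, r in matrix.data.columns]
    _write_tsv_matrix(flat, path)


# ----------------------------------------------------------------- designs

def read_design(path) -> PlexDesign:
    table = pd.read_csv(path, sep="\t", dtype={"plex": str, "channel": str,
                                               "strain": str})
    for col in PlexDesign.REQUIRED:
        if col not in table.columns:
            raise FormatError(f"{path}: design lacks column {col!r}")
    table["bridge"] = table["bridge"].astype(bool)
    table["replicate"] = table["replicate"].astype(int)
    table["batch"] = table["batch"].astype(int)
    return PlexDesign(table)


def write_design(design: PlexDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- gene sets

def read_gmt(path, name: str | None = None, kind: str = "pathway") -> AnnotationDB:
    """Parse a GMT gene-set file (term, description, members...)."""
    path = Path(path)
    term_to_genes: dict[str, set] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno} has {len(fields)} "
                              "fields, GMT needs term, description, members")
        term, members = fields[0], {m for m in fields[2:] if m}
        if not members:
            raise FormatError(f"{path}: line {lineno}: term {term!r} has no "
                              "members")
        term_to_genes[term] = members
    if not term_to_genes:
        logger.warning("GMT file %s is empty", path)
    return AnnotationDB(name or path.stem, kind, term_to_genes)


def write_gmt(db: AnnotationDB, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(db.term_to_genes):
            members = "\t".join(sorted(db.term_to_genes[term]))
            fh.write(f"{term}\t{db.kind}\t{members}\n")


def read_pairs(path, name: str | None = None) -> AnnotationDB:
    """Two-column TSV of unordered gene pairs -> interaction database."""
    path = Path(path)
    pairs: set[frozenset] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 or not all(fields):
                raise FormatError(f"{path}: line {lineno} is not a gene pair")
            if fields[0] != fields[1]:
                pairs.add(frozenset(fields))
    return AnnotationDB(name or path.stem, "interaction", {"pairs": pairs})


def write_pairs(db: AnnotationDB, path) -> None:
    with open(path, "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in db.pairs):
            fh.write("\t".join(pair) + "\n")


# --------------------------------------------------------------- networks

def _is_call_table(edges: pd.DataFrame) -> bool:
    return "direction" in edges.columns


def write_network(edges: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Export a correlation-edge or regulation-call table.

    SIF interaction labels are ``pos``/``neg`` for correlation edges and
    ``up``/``down`` for regulation calls; output rows sort by node pair.
    """
    if dialect not in ("sif", "tsv"):
        raise FormatError(f"unknown network dialect {dialect!r}")
    edges = edges.copy()
    if _is_call_table(edges):
        a, b, label = "strain", "molecule", edges["direction"]
        cols = ["strain", "molecule", "level", "direction", "ratio"]
    else:
        a, b, label = "node_a", "node_b", edges["sign"]
        cols = ["node_a", "node_b", "r", "n", "p", "p_adj", "sign"]
    edges["_label"] = label
    edges = edges.sort_values([a, b], kind="mergesort")
    if dialect == "sif":
        with open(path, "w") as fh:
            for _, row in edges.iterrows():
                fh.write(f"{row[a]}\t{row['_label']}\t{row[b]}\n")
    else:
        edges[[c for c in cols if c in edges.columns]].to_csv(
            path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------ phosphosites

def parse_site_key(key: str) -> PhosphoSiteKey:
    """Parse ``PROT_pS123`` / ``PROT_pS123_pT130`` site identifiers."""
    parts = key.split("_p")
    if len(parts) < 2:
        raise FormatError(f"{key!r} is not a phosphosite identifier")
    protein = parts[0]
    sites = []
    for chunk in parts[1:]:
        if len(chunk) < 2 or chunk[0] not in "STY" or not chunk[1:].isdigit():
            raise FormatError(f"{key!r}: malformed site element {chunk!r}")
        sites.append((chunk[0], int(chunk[1:])))
    return PhosphoSiteKey(protein, tuple(sites))


def format_site_key(key: PhosphoSiteKey) -> str:
    return str(key)


def site_protein(key: str) -> str:
    """Protein part of a serialized phosphosite key."""
    return parse_site_key(key).protein


# ------------------------------------------------------------- truth & misc

def write_truth(truth, outdir) -> None:
    """Write the ground-truth tables of a synthetic study as TSVs."""
    from .simulate import truth_tables
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in truth_tables(truth).items():
        frame.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


def write_simulation(tables: dict, design: PlexDesign, truth, outdir) -> None:
    """Persist a full synthetic study (intensities, design, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_design(design, outdir / "design.tsv")
    for level, plexes in tables.items():
        for table in plexes:
            write_intensity_table(
                table, outdir / f"intensity_{level}_{table.plex_id}.tsv")
    write_truth(truth, outdir)
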