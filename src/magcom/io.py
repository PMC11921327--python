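"""Readers and writers for the tab-separated interchange tables.

All files are UTF-8 TSV with a header line; ``.`` denotes a missing value.
Quality and abundance values are percentages (0-100); module stepwise
completeness is on 0-1.  Every reader validates shape strictly: ragged rows
and malformed cells are rejected with the offending row number.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    MODULE_COMPLETION_THRESHOLD,
    AbundanceTable,
    AniMatrix,
    FormatError,
    MagCluster,
    ModuleCompletenessTable,
    RANK_PREFIXES,
    TaxonomyString,
)

MISSING = "."


# ---------------------------------------------------------------------------
# low-level strict TSV handling


def _read_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a TSV into (header, rows), rejecting ragged rows by number."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: row {lineno} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            rows.append(row)
    return header, rows


def _write_rows(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def _require_columns(path, header: list[str], required: Sequence[str]) -> None:
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")


def _parse_float(path, cell: str, lineno: int, column: str) -> float:
    if cell == MISSING:
        return float("nan")
    try:
        return float(cell)
    except ValueError:
        raise FormatError(
            f"{path}: row {lineno}, column {column!r}: non-numeric value {cell!r}"
        ) from None


def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isnan(x):
        return MISSING
    return format(float(x), ".10g")


# ---------------------------------------------------------------------------
# taxonomy


def parse_taxonomy(gtdb_string: str) -> TaxonomyString:
    """Parse ``d__...;p__...;...;s__...`` into a 7-rank taxonomy.

    Trailing ranks may be empty (``g__``); prefixes must appear in GTDB
    order, domain through species.
    """
    fields = gtdb_string.split(";")
    if len(fields) != len(RANK_PREFIXES):
        raise FormatError(
            f"taxonomy string has {len(fields)} fields, expected "
            f"{len(RANK_PREFIXES)}: {gtdb_string!r}"
        )
    ranks = []
    for field, prefix in zip(fields, RANK_PREFIXES):
        field = field.strip()
        if not field.startswith(prefix):
            raise FormatError(
                f"taxonomy field {field!r} does not start with {prefix!r}"
            )
        ranks.append(field[len(prefix):])
    return TaxonomyString(tuple(ranks))


def make_taxonomic_ids(
    mags: Mapping[str, TaxonomyString] | Iterable[tuple[str, TaxonomyString]],
) -> dict[str, str]:
    """Assign each MAG a display id: its lowest assigned rank, with a
    numeric suffix (" 1", " 2", ... in sorted-mag_id order) wherever two or
    more MAGs share the same label."""
    items = dict(mags)
    labels = {m: t.lowest_nonempty_rank() for m, t in items.items()}
    counts: dict[str, int] = {}
    for label in labels.values():
        counts[label] = counts.get(label, 0) + 1
    suffix_next = {label: 1 for label, n in counts.items() if n > 1}
    ids = {}
    for mag_id in sorted(labels):
        label = labels[mag_id]
        if label in suffix_next:
            ids[mag_id] = f"{label} {suffix_next[label]}"
            suffix_next[label] += 1
        else:
            ids[mag_id] = label
    return ids


def read_taxonomy_table(path: str | Path) -> dict[str, TaxonomyString]:
    """Read mag_id -> GTDB taxonomy string (columns: name, taxonomy)."""
    header, rows = _read_rows(path)
    _require_columns(path, header, ("name", "taxonomy"))
    i_name, i_tax = header.index("name"), header.index("taxonomy")
    out: dict[str, TaxonomyString] = {}
    for lineno, row in enumerate(rows, start=2):
        mag_id = row[i_name]
        if mag_id in out:
            raise FormatError(f"{path}: duplicate mag_id {mag_id!r} at row {lineno}")
        out[mag_id] = parse_taxonomy(row[i_tax])
    return out


def write_taxonomy_table(path: str | Path, taxa: Mapping[str, TaxonomyString]) -> None:
    _write_rows(path, ("name", "taxonomy"),
                ((m, t.to_gtdb()) for m, t in taxa.items()))


# ---------------------------------------------------------------------------
# quality table


def read_quality_table(path: str | Path) -> pd.DataFrame:
    """Read a genome quality table (columns: name, completeness,
    contamination; percent scale) into a frame indexed by MAG id."""
    header, rows = _read_rows(path)
    _require_columns(path, header, ("name", "completeness", "contamination"))
    idx = {c: header.index(c) for c in ("name", "completeness", "contamination")}
    names, comp, cont = [], [], []
    for lineno, row in enumerate(rows, start=2):
        name = row[idx["name"]]
        if name in names:
            raise FormatError(f"{path}: duplicate mag_id {name!r} at row {lineno}")
        names.append(name)
        comp.append(_parse_float(path, row[idx["completeness"]], lineno, "completeness"))
        cont.append(_parse_float(path, row[idx["contamination"]], lineno, "contamination"))
    return pd.DataFrame(
        {"completeness": comp, "contamination": cont},
        index=pd.Index(names, name="name"),
    )


def write_quality_table(path: str | Path, quality: pd.DataFrame) -> None:
    _write_rows(
        path,
        ("name", "completeness", "contamination"),
        (
            (name, _fmt(row.completeness), _fmt(row.contamination))
            for name, row in quality.iterrows()
        ),
    )


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, host, site_or_colony, origin)."""
    header, rows = _read_rows(path)
    cols = ("sample_id", "host", "site_or_colony", "origin")
    _require_columns(path, header, cols)
    idx = {c: header.index(c) for c in cols}
    records = []
    seen = set()
    for lineno, row in enumerate(rows, start=2):
        sid = row[idx["sample_id"]]
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample_id {sid!r} at row {lineno}")
        seen.add(sid)
        if not row[idx["host"]] or not row[idx["site_or_colony"]]:
            raise FormatError(
                f"{path}: row {lineno}: host and site_or_colony must be non-empty"
            )
        records.append([row[idx[c]] for c in cols])
    frame = pd.DataFrame(records, columns=list(cols))
    return frame.set_index("sample_id")


def write_metadata(path: str | Path, metadata: pd.DataFrame) -> None:
    _write_rows(
        path,
        ("sample_id", "host", "site_or_colony", "origin"),
        (
            (sid, row.host, row.site_or_colony, row.origin)
            for sid, row in metadata.iterrows()
        ),
    )


# ---------------------------------------------------------------------------
# ANI matrix


def read_ani_matrix(path: str | Path) -> AniMatrix:
    """Read a square symmetric ANI matrix; first column holds MAG ids."""
    header, rows = _read_rows(path)
    ids = header[1:]
    if len(rows) != len(ids):
        raise FormatError(
            f"{path}: {len(rows)} rows but {len(ids)} columns; matrix must be square"
        )
    values = np.empty((len(ids), len(ids)))
    for i, (lineno, row) in enumerate(zip(range(2, 2 + len(rows)), rows)):
        if row[0] != ids[i]:
            raise FormatError(
                f"{path}: row {lineno} id {row[0]!r} does not match column order"
            )
        for j, cell in enumerate(row[1:]):
            values[i, j] = _parse_float(path, cell, lineno, ids[j])
    return AniMatrix(ids, values)


def write_ani_matrix(path: str | Path, ani: AniMatrix) -> None:
    _write_rows(
        path,
        ["name"] + ani.ids,
        (
            [mag] + [_fmt(v) for v in ani.values[i]]
            for i, mag in enumerate(ani.ids)
        ),
    )


# ---------------------------------------------------------------------------
# abundance table


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a wide sample x MAG relative-abundance table with a final
    ``unmapped`` column; percentages, each row summing to 100."""
    header, rows = _read_rows(path)
    _require_columns(path, header, ("sample_id", "unmapped"))
    features = [c for c in header[1:] if c != "unmapped"]
    i_unmapped = header.index("unmapped")
    samples, values, unmapped = [], [], []
    for lineno, row in enumerate(rows, start=2):
        sid = row[0]
        if sid in samples:
            raise FormatError(f"{path}: duplicate sample_id {sid!r} at row {lineno}")
        samples.append(sid)
        vals = []
        for j, col in enumerate(header[1:], start=1):
            if j == i_unmapped:
                continue
            vals.append(_parse_float(path, row[j], lineno, col))
        values.append(vals)
        unmapped.append(_parse_float(path, row[i_unmapped], lineno, "unmapped"))
    frame = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"),
                         columns=features)
    return AbundanceTable(frame, pd.Series(unmapped, index=frame.index,
                                           name="unmapped"))


def write_abundance_table(path: str | Path, abund: AbundanceTable) -> None:
    _write_rows(
        path,
        ["sample_id"] + abund.features + ["unmapped"],
        (
            [sid]
            + [_fmt(v) for v in abund.values.loc[sid]]
            + [_fmt(abund.unmapped[sid])]
            for sid in abund.samples
        ),
    )


# ---------------------------------------------------------------------------
# module completeness table (long, modules-mode style)


def read_module_table(
    path: str | Path,
    completion_threshold: float = MODULE_COMPLETION_THRESHOLD,
) -> ModuleCompletenessTable:
    """Read a long (mag_id, module_id, stepwise_completeness) table.

    Pairs absent from the file get completeness 0.  If the optional
    ``stepwise_module_is_complete`` column is present, each row's boolean
    must equal (completeness >= threshold) or a consistency error is raised.
    """
    header, rows = _read_rows(path)
    _require_columns(path, header, ("mag_id", "module_id", "stepwise_completeness"))
    idx = {c: header.index(c) for c in
           ("mag_id", "module_id", "stepwise_completeness")}
    i_bool = (header.index("stepwise_module_is_complete")
              if "stepwise_module_is_complete" in header else None)
    cells: dict[tuple[str, str], float] = {}
    for lineno, row in enumerate(rows, start=2):
        mag, module = row[idx["mag_id"]], row[idx["module_id"]]
        value = _parse_float(path, row[idx["stepwise_completeness"]], lineno,
                             "stepwise_completeness")
        if not 0 <= value <= 1:
            raise FormatError(
                f"{path}: row {lineno}: stepwise_completeness {value} outside [0, 1]"
            )
        if (mag, module) in cells:
            raise FormatError(
                f"{path}: duplicate (mag_id, module_id) pair at row {lineno}"
            )
        if i_bool is not None:
            declared = row[i_bool].strip().upper() in ("TRUE", "T", "1")
            if declared != (value >= completion_threshold):
                raise FormatError(
                    f"{path}: row {lineno}: stepwise_module_is_complete="
                    f"{row[i_bool]!r} inconsistent with completeness {value} "
                    f"at threshold {completion_threshold}"
                )
        cells[(mag, module)] = value
    mags = sorted({m for m, _ in cells})
    modules = sorted({mo for _, mo in cells})
    frame = pd.DataFrame(0.0, index=pd.Index(mags, name="mag_id"),
                         columns=modules)
    for (mag, module), value in cells.items():
        frame.loc[mag, module] = value
    return ModuleCompletenessTable(frame)


def write_module_table(
    path: str | Path,
    table: ModuleCompletenessTable,
    completion_threshold: float = MODULE_COMPLETION_THRESHOLD,
    sparse: bool = True,
) -> None:
    """Write the long module table; with ``sparse`` only nonzero cells are
    written (zero completeness is the implicit default on read)."""
    rows = []
    for mag in table.mags:
        for module in table.modules:
            value = table.values.loc[mag, module]
            if sparse and value == 0.0:
                continue
            rows.append(
                (mag, module, _fmt(value),
                 "TRUE" if value >= completion_threshold else "FALSE")
            )
    _write_rows(
        path,
        ("mag_id", "module_id", "stepwise_completeness",
         "stepwise_module_is_complete"),
        rows,
    )


# ---------------------------------------------------------------------------
# cluster assignment table


def read_clusters(path: str | Path) -> list[MagCluster]:
    header, rows = _read_rows(path)
    _require_columns(path, header, ("cluster_id", "representative", "member"))
    idx = {c: header.index(c) for c in ("cluster_id", "representative", "member")}
    by_cluster: dict[str, MagCluster] = {}
    for row in rows:
        cid, rep, member = (row[idx[c]] for c in
                            ("cluster_id", "representative", "member"))
        cluster = by_cluster.get(cid)
        if cluster is None:
            cluster = by_cluster[cid] = MagCluster(cid, rep, [rep])
        if member not in cluster.members:
            cluster.members.append(member)
    return list(by_cluster.values())


def write_clusters(path: str | Path, clusters: Sequence[MagCluster]) -> None:
    _write_rows(
        path,
        ("cluster_id", "representative", "member"),
        (
            (c.cluster_id, c.representative, member)
            for c in clusters
            for member in c.members
        ),
    )
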