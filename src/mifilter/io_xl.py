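"""Readers and writers for cross-link identification tables.

Two input dialects are supported: the tab-separated export of xQuest
(header row with ``Protein1``/``Protein2``, ``AbsPos1``/``AbsPos2``,
``Type`` and ``ld-Score`` columns) and a generic CSV whose column names
are supplied by the caller as a mapping. Decoy status is parsed from
accession prefixes (configurable; ``decoy_``, ``rev_``, ``REV_`` by
default) so the same tables work for any target-decoy database
convention. Output formats: the same TSV dialect (round-trip safe) and
the cross-link CSV consumed by the xiNET network viewer.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .records import (
    CrossLinkRecord,
    DecoyClass,
    FormatError,
    ConfigError,
    LinkDataset,
    LinkType,
)

log = logging.getLogger(__name__)

#: Accession prefixes marking reversed/shuffled decoy sequences.
#: Matching is case-sensitive; override for other database conventions.
DEFAULT_DECOY_PREFIXES: tuple[str, ...] = ("decoy_", "rev_", "REV_")

#: Canonical field -> column name in the xQuest TSV dialect. The exact
#: header names vary between xQuest versions; pass a ``columns`` override
#: (or use :func:`read_generic_csv`) for other exports.
XQUEST_COLUMNS: dict[str, str] = {
    "record_id": "Id",
    "protein_a": "Protein1",
    "protein_b": "Protein2",
    "pos_a": "AbsPos1",
    "pos_b": "AbsPos2",
    "raw_type": "Type",
    "ld_score": "ld-Score",
}

MANDATORY_FIELDS = ("protein_a", "pos_a", "raw_type", "ld_score")

# Optional columns written by write_dataset for lossless round trips.
_EXTRA_COLUMNS = {"link_type": "XLClass", "decoy_class": "DecoyClass",
                  "replicate_id": "Replicate"}

_EMPTY_CELLS = {"", "-", "NA", "nan"}


def classify_decoy(
    protein_a: str,
    protein_b: Optional[str],
    decoy_prefixes: Sequence[str],
) -> DecoyClass:
    """Derive the TT/TD/DD class from accession prefixes.

    A single-protein record (monolink) on a decoy accession is wholly
    decoy and classified DD.
    """

    def hit(acc: str) -> bool:
        return any(acc.startswith(p) for p in decoy_prefixes)

    a = hit(protein_a)
    if protein_b is None:
        return DecoyClass.DD if a else DecoyClass.TT
    b = hit(protein_b)
    if a and b:
        return DecoyClass.DD
    if a or b:
        return DecoyClass.TD
    return DecoyClass.TT


def _cell(row: Mapping[str, str], col: Optional[str]) -> Optional[str]:
    if col is None:
        return None
    val = row.get(col)
    if val is None:
        return None
    val = val.strip()
    return None if val in _EMPTY_CELLS else val


def _read_table(
    path: str | Path,
    columns: Mapping[str, str],
    decoy_prefixes: Sequence[str],
    *,
    delimiter: str,
    strict: bool,
    replicate_id: Optional[str],
) -> LinkDataset:
    path = Path(path)
    for field in MANDATORY_FIELDS:
        if field not in columns:
            raise ConfigError(f"column map does not cover mandatory field {field!r}")

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: file is empty (no header row)")
        header = set(reader.fieldnames)
        for field in MANDATORY_FIELDS:
            if columns[field] not in header:
                raise FormatError(
                    f"{path}: missing mandatory column {columns[field]!r}"
                )
        has_extra = {
            field: col for field, col in _EXTRA_COLUMNS.items() if col in header
        }

        default_rep = replicate_id if replicate_id is not None else path.name
        records: list[CrossLinkRecord] = []
        reps_seen: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    _parse_row(row, columns, decoy_prefixes, has_extra, default_rep)
                )
            except (ValueError, KeyError) as exc:
                msg = f"{path}, line {lineno}: {exc}"
                if strict:
                    raise FormatError(msg) from exc
                log.warning("skipping unparsable row: %s", msg)
                continue
            rep = records[-1].replicate_id
            if rep not in reps_seen:
                reps_seen.append(rep)

    if not records:
        reps_seen = [default_rep]
    return LinkDataset(
        records=records,
        source_files=reps_seen,
        metadata={"path": str(path)},
    )


def _parse_row(
    row: Mapping[str, str],
    columns: Mapping[str, str],
    decoy_prefixes: Sequence[str],
    extra: Mapping[str, str],
    default_rep: str,
) -> CrossLinkRecord:
    protein_a = _cell(row, columns["protein_a"])
    if protein_a is None:
        raise ValueError("empty first protein accession")
    protein_b = _cell(row, columns.get("protein_b"))
    pos_a_raw = _cell(row, columns["pos_a"])
    if pos_a_raw is None:
        raise ValueError("empty first position")
    pos_a = int(pos_a_raw)
    pos_b_raw = _cell(row, columns.get("pos_b"))
    pos_b = int(pos_b_raw) if pos_b_raw is not None else None
    if (protein_b is None) != (pos_b is None):
        raise ValueError("second protein and second position must co-occur")
    score_raw = _cell(row, columns["ld_score"])
    if score_raw is None:
        raise ValueError("empty ld-score")
    ld_score = float(score_raw)
    raw_type = _cell(row, columns["raw_type"])
    if raw_type is None:
        raise ValueError("empty link type")
    rid = _cell(row, columns.get("record_id"))
    if rid is None:
        rid = f"{protein_a}:{pos_a}:{raw_type}:{ld_score:g}"

    link_type_cell = _cell(row, extra.get("link_type"))
    link_type = LinkType(link_type_cell) if link_type_cell is not None else None
    decoy_cell = _cell(row, extra.get("decoy_class"))
    decoy_class = (
        DecoyClass(decoy_cell)
        if decoy_cell is not None
        else classify_decoy(protein_a, protein_b, decoy_prefixes)
    )
    rep = _cell(row, extra.get("replicate_id")) or default_rep

    return CrossLinkRecord(
        record_id=rid,
        raw_type=raw_type,
        protein_a=protein_a,
        pos_a=pos_a,
        protein_b=protein_b,
        pos_b=pos_b,
        ld_score=ld_score,
        link_type=link_type,
        decoy_class=decoy_class,
        replicate_id=rep,
    )


def read_xquest_tsv(
    path: str | Path,
    decoy_prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES,
    *,
    columns: Optional[Mapping[str, str]] = None,
    strict: bool = True,
    replicate_id: Optional[str] = None,
) -> LinkDataset:
    """Read an xQuest-dialect tab-separated result table.

    One :class:`CrossLinkRecord` per row, in file order; raw type labels
    are preserved (normalization is a separate step). ``is_decoy`` is set
    when either accession starts with a configured decoy prefix. The
    replicate label defaults to the file name.

    With ``strict=True`` (default) an unparsable row raises
    :class:`FormatError` naming the line; with ``strict=False`` bad rows
    are skipped with a logged warning.
    """
    cols = dict(XQUEST_COLUMNS)
    if columns:
        cols.update(columns)
    return _read_table(
        path, cols, decoy_prefixes,
        delimiter="\t", strict=strict, replicate_id=replicate_id,
    )


def read_generic_csv(
    path: str | Path,
    column_map: Mapping[str, str],
    decoy_prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES,
    *,
    delimiter: str = ",",
    strict: bool = True,
    replicate_id: Optional[str] = None,
) -> LinkDataset:
    """Read a result table via a caller-supplied column mapping.

    ``column_map`` maps canonical field names (``protein_a``,
    ``protein_b``, ``pos_a``, ``pos_b``, ``raw_type``, ``ld_score``,
    optionally ``record_id``) to the source file's column names, so
    exports from MeroX, XlinkX, pLink2 etc. can be ingested without
    reformatting.
    """
    for field in MANDATORY_FIELDS:
        if field not in column_map:
            raise ConfigError(
                f"column_map does not cover mandatory field {field!r}"
            )
    return _read_table(
        path, dict(column_map), decoy_prefixes,
        delimiter=delimiter, strict=strict, replicate_id=replicate_id,
    )


def write_dataset(ds: LinkDataset, path: str | Path) -> None:
    """Write a dataset as an xQuest-dialect TSV.

    Adds ``XLClass``/``DecoyClass``/``Replicate`` columns so that
    ``read_xquest_tsv`` on the output reproduces every field, including
    normalized types and multi-replicate provenance.
    """
    fields = list(XQUEST_COLUMNS.values()) + list(_EXTRA_COLUMNS.values())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(fields)
        for rec in ds:
            writer.writerow([
                rec.record_id,
                rec.protein_a,
                rec.protein_b if rec.protein_b is not None else "-",
                rec.pos_a,
                rec.pos_b if rec.pos_b is not None else "-",
                rec.raw_type,
                repr(rec.ld_score),
                rec.link_type.value if rec.link_type is not None else "-",
                rec.decoy_class.value,
                rec.replicate_id,
            ])


def export_xinet_edges(ds: LinkDataset, path: str | Path) -> None:
    """Write unique inter-protein links as a xiNET cross-link CSV.

    One row per unique inter-protein site (``Protein1, Protein2,
    LinkPos1, LinkPos2``), first-occurrence order; monolinks and
    intra-protein links are omitted. This is the edge list of the
    protein-protein interaction network the dataset supports.
    """
    seen: set[str] = set()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["Protein1", "Protein2", "LinkPos1", "LinkPos2"])
        for rec in ds:
            if rec.link_type is not LinkType.INTER:
                continue
            key = rec.unique_key
            if key in seen:
                continue
            seen.add(key)
            writer.writerow([rec.protein_a, rec.protein_b, rec.pos_a, rec.pos_b])
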