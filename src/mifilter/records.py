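"""Core record and dataset containers for cross-link identifications.

A cross-linking MS search yields three evidence classes: monolinks
(cross-linker reacted on one side only — evidence that a residue of one
protein was accessible), intra-protein cross-links (both residues on the
same protein) and inter-protein cross-links (residues on two different
proteins — the sole evidence class for protein-protein interactions).
Search engines additionally report decoy identifications against reversed
or shuffled sequences, used for error-rate estimation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional


class MiFilterError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MiFilterError):
    """A file does not conform to the expected table dialect."""


class ConfigError(MiFilterError):
    """A configuration value is missing, unknown or inconsistent."""


class StateError(MiFilterError):
    """An operation was invoked on a dataset in the wrong state
    (e.g. the mi-filter on records whose link types are not normalized)."""


class LinkType(enum.Enum):
    """Canonical link classes after normalization."""

    MONO = "mono"
    INTRA = "intra"
    INTER = "inter"


class DecoyClass(enum.Enum):
    """Target/decoy composition of an identification.

    TT: both sequences target; TD: one decoy; DD: both decoy. A decoy
    monolink involves a single (decoy) sequence and is recorded as DD,
    i.e. wholly decoy.
    """

    TT = "TT"
    TD = "TD"
    DD = "DD"


@dataclass(frozen=True)
class CrossLinkRecord:
    """One cross-link identification (one row of a result table).

    Positions are 1-based residue indices, following the xQuest
    convention. ``link_type`` is ``None`` until the raw type label has
    been normalized to one of the three canonical classes. MONO records
    have no ``protein_b``/``pos_b``.
    """

    record_id: str
    raw_type: str
    protein_a: str
    pos_a: int
    ld_score: float
    protein_b: Optional[str] = None
    pos_b: Optional[int] = None
    link_type: Optional[LinkType] = None
    decoy_class: DecoyClass = DecoyClass.TT
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.pos_a < 1:
            raise ValueError(f"pos_a must be >= 1, got {self.pos_a}")
        if self.pos_b is not None and self.pos_b < 1:
            raise ValueError(f"pos_b must be >= 1, got {self.pos_b}")
        if (self.protein_b is None) != (self.pos_b is None):
            raise ValueError(
                "protein_b and pos_b must both be present or both absent"
            )
        if self.link_type is LinkType.MONO and self.protein_b is not None:
            raise ValueError("MONO records must not carry a second site")

    @property
    def is_decoy(self) -> bool:
        """True iff any constituent sequence is a decoy (TD or DD)."""
        return self.decoy_class is not DecoyClass.TT

    @property
    def unique_key(self) -> str:
        """Canonical cross-linking-site identity.

        Sorted (accession, position) pairs joined with the link class, so
        the key is invariant under swapping the two sides of a record.
        Identity is at the site level, not the spectrum/PSM level: the
        same site seen in several replicates shares one key.
        """
        sites = [(self.protein_a, self.pos_a)]
        if self.protein_b is not None:
            sites.append((self.protein_b, self.pos_b))
        sites.sort()
        cls = self.link_type.value if self.link_type is not None else self.raw_type
        return "|".join(f"{acc}:{pos}" for acc, pos in sites) + f"|{cls}"

    def swapped(self) -> "CrossLinkRecord":
        """Return the record with its two sides exchanged (no-op for MONO)."""
        if self.protein_b is None:
            return self
        return replace(
            self,
            protein_a=self.protein_b,
            pos_a=self.pos_b,
            protein_b=self.protein_a,
            pos_b=self.pos_a,
        )


@dataclass
class LinkDataset:
    """An ordered collection of cross-link records with per-file provenance.

    ``source_files`` lists the input file labels (one per biological
    replicate, in read order); every record's ``replicate_id`` must name
    one of them. Record order within a source file is preserved on read.
    """

    records: list[CrossLinkRecord] = field(default_factory=list)
    source_files: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.source_files)
        for rec in self.records:
            if rec.replicate_id not in known:
                raise ValueError(
                    f"record {rec.record_id!r} has replicate_id "
                    f"{rec.replicate_id!r} not listed in source_files"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CrossLinkRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        """Record-wise equality; replicate labels compared as a set
        (their listing order is provenance, not data)."""
        if not isinstance(other, LinkDataset):
            return NotImplemented
        return (
            self.records == other.records
            and sorted(self.source_files) == sorted(other.source_files)
        )

    @property
    def is_normalized(self) -> bool:
        return all(rec.link_type is not None for rec in self.records)

    def with_records(self, records: Iterable[CrossLinkRecord]) -> "LinkDataset":
        """Copy of the dataset holding ``records`` (provenance preserved)."""
        return LinkDataset(
            records=list(records),
            source_files=list(self.source_files),
            metadata=dict(self.metadata),
        )

    def filter_score(self, ld_cutoff: float) -> "LinkDataset":
        """Retain records with ld_score >= cutoff."""
        return self.with_records(
            r for r in self.records if r.ld_score >= ld_cutoff
        )

    @staticmethod
    def concatenate(datasets: Iterable["LinkDataset"]) -> "LinkDataset":
        """Concatenate datasets in order, merging provenance.

        Duplicate file labels across inputs are rejected: replicate
        identity relies on labels being distinct.
        """
        records: list[CrossLinkRecord] = []
        files: list[str] = []
        meta: dict = {}
        for ds in datasets:
            for label in ds.source_files:
                if label in files:
                    raise ValueError(f"duplicate source file label {label!r}")
                files.append(label)
            records.extend(ds.records)
            meta.update(ds.metadata)
        return LinkDataset(records=records, source_files=files, metadata=meta)
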