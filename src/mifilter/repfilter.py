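"""Biological-replicate consistency filter on cross-linking sites.

A cross-linking site (the unique pair of linked residues, or the single
residue for a monolink) is retained only when it was identified in a
minimum number of distinct replicates. Identity is at the site level by
default; ``pair_level=True`` relaxes it to the protein pair, so a site
counts as reproduced when the same two proteins are linked anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ConfigError, CrossLinkRecord, LinkDataset


@dataclass(frozen=True)
class ReplicateRequirement:
    """Minimum number of distinct replicates a site must appear in."""

    min_replicates: int
    pair_level: bool = False

    def __post_init__(self) -> None:
        if self.min_replicates < 1:
            raise ConfigError("min_replicates must be >= 1")


def _site_key(rec: CrossLinkRecord, pair_level: bool) -> str:
    if not pair_level:
        return rec.unique_key
    accs = [rec.protein_a]
    if rec.protein_b is not None:
        accs.append(rec.protein_b)
    cls = rec.link_type.value if rec.link_type is not None else rec.raw_type
    return "|".join(sorted(accs)) + f"|{cls}"


def filter_by_replicates(
    ds: LinkDataset, req: ReplicateRequirement
) -> LinkDataset:
    """Keep records whose site occurs in >= ``min_replicates`` replicates.

    All occurrences of a passing site are retained (the filter removes
    sites, not individual observations). Raises :class:`ConfigError`
    when the requirement exceeds the number of source files.
    """
    if req.min_replicates > len(ds.source_files):
        raise ConfigError(
            f"min_replicates={req.min_replicates} exceeds the "
            f"{len(ds.source_files)} available replicate(s)"
        )
    seen: dict[str, set[str]] = {}
    for rec in ds:
        seen.setdefault(_site_key(rec, req.pair_level), set()).add(
            rec.replicate_id
        )
    return ds.with_records(
        rec
        for rec in ds
        if len(seen[_site_key(rec, req.pair_level)]) >= req.min_replicates
    )
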