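"""The mono-/intralink filter and the standard processing pipeline.

The filter encodes one rule: an inter-protein cross-link is trustworthy
evidence for a protein-protein interaction only if both partner proteins
are independently seen in the same dataset — i.e. each carries at least
one monolink or intra-protein link. Proteins present at workable
abundance produce mono- and intralinks at much higher rates than
interlinks, so a protein with interlinks but no mono/intralink support
is most likely a false identification.

Eligibility is computed over the full concatenated dataset at the active
score cutoff, and decoy records establish eligibility for decoy
accessions: targets and decoys pass through exactly the same rule, so
the decoy proportion remains an unbiased error estimate after filtering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .io_xl import DEFAULT_DECOY_PREFIXES, read_generic_csv, read_xquest_tsv
from .linktypes import TypeMapping, normalize_types
from .records import (
    CrossLinkRecord,
    DecoyClass,
    LinkDataset,
    LinkType,
    MiFilterError,
    StateError,
)
from .repfilter import ReplicateRequirement, filter_by_replicates


@dataclass
class EligibleSet:
    """Proteins eligible to participate in inter-protein links.

    ``provenance`` counts the supporting MONO and INTRA records per
    accession; every member has at least one.
    """

    proteins: set[str] = field(default_factory=set)
    provenance: dict[str, dict[str, int]] = field(default_factory=dict)

    def __contains__(self, accession: str) -> bool:
        return accession in self.proteins

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class FilterReport:
    """Accounting of one mi-filter application.

    ``removed_records`` lists (record_id, ineligible partner accessions)
    for every removed inter-link — removals are reported, never silent.
    ``class_counts_before``/``after`` tally records per (link class,
    decoy class), keyed like ``("inter", "TD")``.
    """

    n_input_inter: int = 0
    n_retained_inter: int = 0
    n_removed_inter: int = 0
    removed_records: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    class_counts_before: dict[tuple[str, str], int] = field(default_factory=dict)
    class_counts_after: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable form."""
        def flat(c: Mapping[tuple[str, str], int]) -> dict[str, int]:
            return {f"{lt}/{dc}": n for (lt, dc), n in sorted(c.items())}

        return {
            "n_input_inter": self.n_input_inter,
            "n_retained_inter": self.n_retained_inter,
            "n_removed_inter": self.n_removed_inter,
            "removed_records": [
                {"record_id": rid, "ineligible": list(partners)}
                for rid, partners in self.removed_records
            ],
            "class_counts_before": flat(self.class_counts_before),
            "class_counts_after": flat(self.class_counts_after),
        }


def _class_counts(ds: LinkDataset) -> dict[tuple[str, str], int]:
    return dict(
        Counter(
            (rec.link_type.value, rec.decoy_class.value) for rec in ds
        )
    )


def _require_normalized(ds: LinkDataset, op: str) -> None:
    if not ds.is_normalized:
        raise StateError(
            f"{op} requires normalized link types; run normalize_types first"
        )


def build_eligible_set(ds: LinkDataset) -> EligibleSet:
    """Collect proteins carrying >=1 monolink or intra-protein link.

    Decoy accessions qualify through decoy mono/intralinks — eligibility
    is symmetric between targets and decoys.
    """
    _require_normalized(ds, "build_eligible_set")
    provenance: dict[str, dict[str, int]] = {}
    for rec in ds:
        if rec.link_type is LinkType.INTER:
            continue
        kind = rec.link_type.value
        accessions = {rec.protein_a}
        if rec.protein_b is not None:
            accessions.add(rec.protein_b)
        for acc in accessions:
            counts = provenance.setdefault(acc, {"mono": 0, "intra": 0})
            counts[kind] += 1
    return EligibleSet(proteins=set(provenance), provenance=provenance)


def apply_mi_filter(
    ds: LinkDataset, eligible: EligibleSet
) -> tuple[LinkDataset, FilterReport]:
    """Remove inter-protein links whose partners lack mono/intra support.

    An INTER record is retained iff *both* partner proteins are in the
    eligible set; MONO and INTRA records always pass through. Returns the
    filtered dataset and a :class:`FilterReport`.
    """
    _require_normalized(ds, "apply_mi_filter")
    report = FilterReport(class_counts_before=_class_counts(ds))
    kept: list[CrossLinkRecord] = []
    for rec in ds:
        if rec.link_type is not LinkType.INTER:
            kept.append(rec)
            continue
        report.n_input_inter += 1
        ineligible = tuple(
            acc
            for acc in (rec.protein_a, rec.protein_b)
            if acc not in eligible
        )
        if ineligible:
            report.n_removed_inter += 1
            report.removed_records.append((rec.record_id, ineligible))
        else:
            report.n_retained_inter += 1
            kept.append(rec)
    out = ds.with_records(kept)
    report.class_counts_after = _class_counts(out)
    return out, report


def run_pipeline(
    paths: Sequence[str | Path],
    ld_cutoff: float = float("-inf"),
    min_replicates: Optional[int] = None,
    mi: bool = True,
    *,
    decoy_prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES,
    type_mapping: Optional[TypeMapping] = None,
    column_map: Optional[Mapping[str, str]] = None,
    csv_delimiter: str = ",",
    strict: bool = True,
) -> tuple[LinkDataset, FilterReport]:
    """Run the standard processing chain over one file per replicate.

    Stages, in order: per-file read -> ld-score cutoff per file ->
    concatenation -> optional replicate-consistency filter -> decoy
    annotation (done at read time from ``decoy_prefixes``) -> link-type
    normalization -> eligible-set construction -> mi-filter (when ``mi``
    is true). With ``mi=False`` the report still carries the class
    counts, with nothing removed.

    ``column_map`` switches input parsing to the generic CSV reader.
    Errors from any stage propagate tagged with the stage name.
    """
    if not paths:
        raise MiFilterError("run_pipeline: at least one input file is required")

    def stage(name: str):
        return _StageContext(name)

    datasets = []
    for path in paths:
        with stage(f"read({Path(path).name})"):
            if column_map is not None:
                ds = read_generic_csv(
                    path, column_map, decoy_prefixes,
                    delimiter=csv_delimiter, strict=strict,
                )
            else:
                ds = read_xquest_tsv(path, decoy_prefixes, strict=strict)
        with stage("score-filter"):
            datasets.append(ds.filter_score(ld_cutoff))

    with stage("concatenate"):
        merged = LinkDataset.concatenate(datasets)
    if min_replicates is not None:
        with stage("replicate-filter"):
            merged = filter_by_replicates(
                merged, ReplicateRequirement(min_replicates)
            )
    with stage("normalize-types"):
        merged = normalize_types(merged, type_mapping)
    with stage("eligible-set"):
        eligible = build_eligible_set(merged)
    if mi:
        with stage("mi-filter"):
            return apply_mi_filter(merged, eligible)
    report = FilterReport(
        n_input_inter=sum(
            1 for r in merged if r.link_type is LinkType.INTER
        ),
        class_counts_before=_class_counts(merged),
        class_counts_after=_class_counts(merged),
    )
    report.n_retained_inter = report.n_input_inter
    return merged, report


class _StageContext:
    """Tag exceptions escaping a pipeline stage with the stage name."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self) -> "_StageContext":
        return self

    def __exit__(self, exc_type, exc, tb) -> bool:
        if exc is not None and isinstance(exc, MiFilterError):
            exc.args = (f"[{self.name}] {exc.args[0] if exc.args else ''}",)
        return False
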