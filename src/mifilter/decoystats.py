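"""Target/decoy accounting per link class across score cutoffs.

Two decoy-ratio conventions are in common use and both are reported,
explicitly labelled:

* ``decoy_fraction`` = decoy / (target + decoy) — the proportion of
  decoy hits among all detected hits;
* ``decoy_target_ratio`` = decoy / target — undefined when no targets.

They are mutually consistent: ratio = fraction / (1 - fraction)
whenever both are defined. Counts are at the record (redundant
identification) level by default; ``unique=True`` collapses to unique
cross-linking sites first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import run_pipeline
from .records import LinkDataset, LinkType, StateError

#: Score cutoffs swept by default: loose to stringent spectral agreement.
DEFAULT_CUTOFFS: tuple[float, ...] = (20.0, 25.0, 28.0, 32.0)

CONDITIONS = ("unfiltered", "mi-filtered")


@dataclass(frozen=True)
class ClassCounts:
    """Target/decoy tally for one link class under one condition."""

    n_target: int
    n_decoy: int

    @property
    def decoy_fraction(self) -> Optional[float]:
        return decoy_fraction(self.n_target, self.n_decoy)

    @property
    def decoy_target_ratio(self) -> Optional[float]:
        if self.n_target == 0:
            return None
        return self.n_decoy / self.n_target


def decoy_fraction(n_target: int, n_decoy: int) -> Optional[float]:
    """Proportion of decoy hits among all hits; None when no hits at all."""
    total = n_target + n_decoy
    if total == 0:
        return None
    return n_decoy / total


def count_by_class(
    ds: LinkDataset, unique: bool = False
) -> dict[LinkType, ClassCounts]:
    """Tally targets and decoys (TD and DD alike) per canonical class.

    The partition is exhaustive: summed over classes, target + decoy
    equals the dataset size (or the number of unique sites when
    ``unique=True``).
    """
    if not ds.is_normalized:
        raise StateError("count_by_class requires normalized link types")
    records = ds.records
    if unique:
        seen: dict[str, object] = {}
        for rec in records:
            seen.setdefault(rec.unique_key, rec)
        records = list(seen.values())
    out = {}
    for lt in LinkType:
        target = sum(
            1 for r in records if r.link_type is lt and not r.is_decoy
        )
        decoy = sum(1 for r in records if r.link_type is lt and r.is_decoy)
        out[lt] = ClassCounts(n_target=target, n_decoy=decoy)
    return out


@dataclass
class SweepResult:
    """Per-cutoff, per-class, per-condition target/decoy counts.

    ``counts[(cutoff, link_class, condition)]`` -> :class:`ClassCounts`
    with condition one of ``"unfiltered"``/``"mi-filtered"``.
    """

    cutoffs: list[float]
    counts: dict[tuple[float, LinkType, str], ClassCounts] = field(
        default_factory=dict
    )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format, one row per (cutoff, class, condition)."""
        rows = []
        for (cutoff, lt, cond), cc in sorted(
            self.counts.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2])
        ):
            rows.append({
                "cutoff": cutoff,
                "link_class": lt.value,
                "condition": cond,
                "n_target": cc.n_target,
                "n_decoy": cc.n_decoy,
                "decoy_fraction": cc.decoy_fraction,
                "decoy_target_ratio": cc.decoy_target_ratio,
            })
        return pd.DataFrame(
            rows,
            columns=[
                "cutoff", "link_class", "condition", "n_target", "n_decoy",
                "decoy_fraction", "decoy_target_ratio",
            ],
        )

    def to_dict(self) -> dict:
        return {
            "cutoffs": list(self.cutoffs),
            "counts": self.to_dataframe().to_dict(orient="records"),
        }


def decoy_sweep(
    files: Sequence[str | Path],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    *,
    min_replicates: Optional[int] = None,
    unique: bool = False,
    **pipeline_kwargs,
) -> SweepResult:
    """Run the pipeline at each cutoff with and without the mi-filter.

    Populates a :class:`SweepResult` with per-class target/decoy counts
    under both conditions; extra keyword arguments are forwarded to
    :func:`mifilter.core.run_pipeline` (decoy prefixes, type mapping,
    input dialect).
    """
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    result = SweepResult(cutoffs=[float(c) for c in cutoffs])
    for cutoff in result.cutoffs:
        for mi, cond in ((False, "unfiltered"), (True, "mi-filtered")):
            ds, _ = run_pipeline(
                files, ld_cutoff=cutoff, min_replicates=min_replicates,
                mi=mi, **pipeline_kwargs,
            )
            for lt, cc in count_by_class(ds, unique=unique).items():
                result.counts[(cutoff, lt, cond)] = cc
    return result
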