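"""Validation of cross-links against a 3D structure.

A cross-linker of known spacer length constrains the distance between
the linked residues: for DSS/BS3 chemistry on lysines, Cα–Cα distances
up to about 35 Å are structurally compatible. Mapping identified
inter-protein links onto a high-resolution structure and checking this
bound gives an orthogonal, physics-based estimate of identification
quality.

Structures are read with gemmi (PDB or mmCIF). A ``chain_map`` assigns
each protein accession the structure chain(s) holding its copies;
with multiple copies the minimum distance over all copy combinations is
used, the standard permissive convention for ambiguous copy assignment.
Residue numbering follows the structure's author numbering; per-chain
offsets reconcile sequence-vs-structure numbering shifts
(structure residue = cross-link position + offset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gemmi

from .records import CrossLinkRecord, LinkDataset, LinkType, MiFilterError

#: Maximal lysine Cα–Cα distance (Å) bridgeable by DSS/BS3-class linkers.
DEFAULT_DISTANCE_CUTOFF: float = 35.0


class StructureMappingError(MiFilterError):
    """chain_map names chains absent from the structure."""


@dataclass
class StructureModel:
    """Cα coordinate table plus the accession-to-chain assignment.

    ``coords`` maps (chain id, author residue number) to a Cα position
    in Å. ``chain_map`` maps protein accession to the chain ids of its
    copies; ``offsets`` (per chain id) shift cross-link positions into
    the structure's numbering.
    """

    coords: dict[tuple[str, int], tuple[float, float, float]]
    chain_map: dict[str, list[str]]
    offsets: dict[str, int] = field(default_factory=dict)

    def ca(self, chain: str, pos: int) -> Optional[tuple[float, float, float]]:
        """Cα position for a cross-link position on ``chain``, or None."""
        return self.coords.get((chain, pos + self.offsets.get(chain, 0)))


@dataclass(frozen=True)
class DistanceResult:
    """Minimal Cα–Cα distance for one cross-link record.

    ``satisfied`` is meaningful only when ``mappable`` (both residues
    found on at least one chain copy).
    """

    record_id: str
    mappable: bool
    min_distance: Optional[float] = None
    satisfied: Optional[bool] = None


def load_structure(
    path: str | Path,
    chain_map: Mapping[str, Sequence[str]],
    offsets: Optional[Mapping[str, int]] = None,
) -> StructureModel:
    """Extract the Cα table of the mapped chains from a PDB/mmCIF file.

    Only chains named in ``chain_map`` are retained. Raises
    :class:`StructureMappingError` listing any mapped chain missing from
    the file. Uses the first model of multi-model files.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    wanted = {c for chains in chain_map.values() for c in chains}
    present = {chain.name for chain in model}
    missing = sorted(wanted - present)
    if missing:
        raise StructureMappingError(
            f"chain(s) {', '.join(missing)} named in chain_map are absent "
            f"from {Path(path).name} (available: {', '.join(sorted(present))})"
        )
    coords: dict[tuple[str, int], tuple[float, float, float]] = {}
    for chain in model:
        if chain.name not in wanted:
            continue
        for residue in chain:
            atom = residue.find_atom("CA", "*")
            if atom is None or residue.seqid.num is None:
                continue
            coords[(chain.name, residue.seqid.num)] = (
                atom.pos.x, atom.pos.y, atom.pos.z,
            )
    return StructureModel(
        coords=coords,
        chain_map={acc: list(chains) for acc, chains in chain_map.items()},
        offsets=dict(offsets or {}),
    )


def link_distance(
    rec: CrossLinkRecord,
    model: StructureModel,
    cutoff: float = DEFAULT_DISTANCE_CUTOFF,
) -> DistanceResult:
    """Minimal Cα–Cα distance of a cross-link over all chain-copy pairs.

    The record must be a two-site link (INTER or INTRA) whose proteins
    appear in the chain map. Unmappable residues yield
    ``mappable=False`` rather than an error.
    """
    if rec.link_type is LinkType.MONO or rec.protein_b is None:
        raise TypeError("link_distance requires a two-site (INTER/INTRA) record")
    for acc in (rec.protein_a, rec.protein_b):
        if acc not in model.chain_map:
            raise StructureMappingError(
                f"protein {acc!r} has no chain assignment in chain_map"
            )
    best: Optional[float] = None
    for chain_a in model.chain_map[rec.protein_a]:
        xyz_a = model.ca(chain_a, rec.pos_a)
        if xyz_a is None:
            continue
        for chain_b in model.chain_map[rec.protein_b]:
            xyz_b = model.ca(chain_b, rec.pos_b)
            if xyz_b is None:
                continue
            d = math.dist(xyz_a, xyz_b)
            if best is None or d < best:
                best = d
    if best is None:
        return DistanceResult(record_id=rec.record_id, mappable=False)
    return DistanceResult(
        record_id=rec.record_id,
        mappable=True,
        min_distance=best,
        satisfied=best <= cutoff,
    )


def validate_dataset(
    ds: LinkDataset,
    model: StructureModel,
    cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    *,
    link_types: tuple[LinkType, ...] = (LinkType.INTER,),
) -> list[DistanceResult]:
    """Distance-check every mappable link of the given classes.

    Records whose proteins lack a chain assignment are reported as
    unmappable instead of raising, so a partial chain map still yields a
    summary over the covered subcomplex.
    """
    results = []
    for rec in ds:
        if rec.link_type not in link_types or rec.protein_b is None:
            continue
        try:
            results.append(link_distance(rec, model, cutoff))
        except StructureMappingError:
            results.append(DistanceResult(record_id=rec.record_id, mappable=False))
    return results


def satisfaction_summary(
    results: Sequence[DistanceResult], cutoff: float = DEFAULT_DISTANCE_CUTOFF
) -> tuple[int, int, Optional[float]]:
    """(n_mappable, n_satisfied, fraction) at the given distance cutoff.

    Unmappable links are excluded from the denominator; the fraction is
    None when nothing is mappable. Satisfaction is re-evaluated from the
    stored distances, so a different cutoff than the one used during
    measurement may be summarized.
    """
    mappable = [r for r in results if r.mappable]
    n_sat = sum(1 for r in mappable if r.min_distance <= cutoff)
    if not mappable:
        return 0, 0, None
    return len(mappable), n_sat, n_sat / len(mappable)


def results_to_rows(results: Sequence[DistanceResult]) -> list[dict]:
    """Flatten distance results for CSV export."""
    return [
        {
            "record_id": r.record_id,
            "mappable": r.mappable,
            "min_distance": r.min_distance,
            "satisfied": r.satisfied,
        }
        for r in results
    ]
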