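"""Normalization of raw link-type labels to the three canonical classes.

Search engines label link types inconsistently ("xlink", "intralink",
"looplink", "monolink", ...). Downstream filtering only distinguishes
three classes: monolinks, intra-protein links and inter-protein links.
Two rules apply on top of the label mapping:

* a cross-link whose two accessions are identical is intra-protein
  regardless of label (homodimeric "inter" calls are conservatively
  read as intra-protein without stoichiometric evidence);
* looplinks join two residues of one peptide, hence one protein, and
  map to INTRA by default — they are evidence that the protein is
  present and cross-linkable, which is what the mi-filter consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .records import ConfigError, LinkDataset, LinkType


class UnmappedPolicy(enum.Enum):
    """What to do with a raw label absent from the mapping."""

    ERROR = "error"
    DROP = "drop"


#: Raw label -> canonical class. Matching is done on the lower-cased,
#: stripped label. ``None`` means the record is dropped.
DEFAULT_TYPE_MAPPING: dict[str, Optional[LinkType]] = {
    "monolink": LinkType.MONO,
    "mono": LinkType.MONO,
    "intralink": LinkType.INTRA,
    "intra": LinkType.INTRA,
    "xlink": LinkType.INTER,
    "crosslink": LinkType.INTER,
    "inter": LinkType.INTER,
    "interlink": LinkType.INTER,
    "looplink": LinkType.INTRA,
    "loop": LinkType.INTRA,
}


@dataclass
class TypeMapping:
    """Raw-label to canonical-class mapping with an unmapped-label policy."""

    mapping: dict[str, Optional[LinkType]] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MAPPING)
    )
    unmapped: UnmappedPolicy = UnmappedPolicy.ERROR

    @classmethod
    def from_config(
        cls,
        raw: Mapping[str, str],
        unmapped: str | UnmappedPolicy = UnmappedPolicy.ERROR,
    ) -> "TypeMapping":
        """Build from plain-string pairs, e.g. ``{"looplink": "drop"}``.

        Values are canonical class names (``mono``/``intra``/``inter``)
        or ``drop``; entries extend/override the default mapping.
        """
        mapping = dict(DEFAULT_TYPE_MAPPING)
        for label, target in raw.items():
            t = target.strip().lower()
            mapping[label.strip().lower()] = (
                None if t == "drop" else LinkType(t)
            )
        if isinstance(unmapped, str):
            unmapped = UnmappedPolicy(unmapped.lower())
        return cls(mapping=mapping, unmapped=unmapped)

    def resolve(self, raw_label: str) -> Optional[LinkType]:
        key = raw_label.strip().lower()
        if key not in self.mapping:
            if self.unmapped is UnmappedPolicy.ERROR:
                raise ConfigError(
                    f"unmapped link-type label {raw_label!r}; extend the type "
                    "mapping or set the unmapped policy to 'drop'"
                )
            return None
        return self.mapping[key]


def normalize_types(
    ds: LinkDataset, mapping: Optional[TypeMapping] = None
) -> LinkDataset:
    """Assign every record one of the canonical classes MONO/INTRA/INTER.

    A record labelled as a cross-link but joining two identical
    accessions is reclassified INTRA. Records whose label maps to
    ``None`` (policy DROP) are removed. The operation is idempotent.
    """
    mapping = mapping or TypeMapping()
    out = []
    for rec in ds:
        canonical = mapping.resolve(rec.raw_type)
        if canonical is None:
            continue
        if canonical is LinkType.INTER and (
            rec.protein_b is None or rec.protein_b == rec.protein_a
        ):
            canonical = LinkType.INTRA
        if canonical is LinkType.MONO and rec.protein_b is not None:
            # a two-site record cannot be a monolink; trust the sites
            canonical = (
                LinkType.INTRA
                if rec.protein_b == rec.protein_a
                else LinkType.INTER
            )
        out.append(
            rec if rec.link_type is canonical else replace(rec, link_type=canonical)
        )
    return ds.with_records(out)
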