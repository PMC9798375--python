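"""Shared fixtures: tiny hand-written tables and random record factories.

The random factories here are deliberately independent of the package's
own synthetic-data module, so oracle comparisons (brute-force scans of
generated records) do not share code with the implementation under test.
"""

from __future__ import annotations

import random

import pytest

from mifilter.records import CrossLinkRecord, DecoyClass, LinkDataset, LinkType

XQUEST_HEADER = "Id\tProtein1\tProtein2\tAbsPos1\tAbsPos2\tType\tld-Score\n"


def write_xquest(path, rows):
    """Write an xQuest-dialect TSV from (id, p1, p2, pos1, pos2, type, score)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(XQUEST_HEADER)
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
    return path


@pytest.fixture
def xquest_file(tmp_path):
    """Three-row fixture, one record of each raw type."""
    return write_xquest(tmp_path / "rep1.tsv", [
        ("id1", "P1", "P2", 10, 20, "xlink", 30.5),
        ("id2", "P1", "P1", 5, 15, "intralink", 28.0),
        ("id3", "P2", "-", 7, "-", "monolink", 22.25),
    ])


def random_record(rng: random.Random, rep: str, n_proteins: int = 12,
                  decoy_prob: float = 0.2) -> CrossLinkRecord:
    """One random record; decoys get 'decoy_'-prefixed accessions."""
    kind = rng.choice([LinkType.MONO, LinkType.INTRA, LinkType.INTER])

    def acc() -> str:
        base = f"P{rng.randrange(n_proteins)}"
        return "decoy_" + base if rng.random() < decoy_prob else base

    a = acc()
    pos_a = rng.randrange(1, 200)
    score = round(rng.uniform(10, 45), 2)
    rid = f"{rep}-{rng.randrange(10**9)}"
    if kind is LinkType.MONO:
        b, pos_b = None, None
    elif kind is LinkType.INTRA:
        b, pos_b = a, rng.randrange(1, 200)
    else:
        b = acc()
        while b == a:
            b = acc()
        pos_b = rng.randrange(1, 200)

    def is_d(x):
        return x is not None and x.startswith("decoy_")

    if b is None:
        dc = DecoyClass.DD if is_d(a) else DecoyClass.TT
    elif is_d(a) and is_d(b):
        dc = DecoyClass.DD
    elif is_d(a) or is_d(b):
        dc = DecoyClass.TD
    else:
        dc = DecoyClass.TT
    raw = {LinkType.MONO: "monolink", LinkType.INTRA: "intralink",
           LinkType.INTER: "xlink"}[kind]
    return CrossLinkRecord(
        record_id=rid, raw_type=raw, protein_a=a, pos_a=pos_a,
        protein_b=b, pos_b=pos_b, ld_score=score, link_type=kind,
        decoy_class=dc, replicate_id=rep,
    )


def random_dataset(seed: int, n: int = 200, n_reps: int = 3,
                   n_proteins: int = 12) -> LinkDataset:
    rng = random.Random(seed)
    reps = [f"rep{i}" for i in range(1, n_reps + 1)]
    records = [
        random_record(rng, rng.choice(reps), n_proteins) for _ in range(n)
    ]
    used = {r.replicate_id for r in records}
    return LinkDataset(records=records,
                       source_files=[r for r in reps if r in used])


@pytest.fixture
def random_ds():
    return random_dataset(seed=42, n=300)
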