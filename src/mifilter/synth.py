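"""Synthetic XL-MS identification datasets with ground truth.

The generator emulates the generative structure of a cross-linking
search so the filter's error-reduction and sensitivity behaviour can be
tested without any experimental download:

* a sample of *present* proteins with log-normal abundances, plus a
  larger tail of *absent* proteins that are in the search database but
  not in the sample (the proteome-wide search setting);
* abundance-dependent detectability — per-protein link counts are
  Poisson with rates proportional to abundance, and mono- and
  intra-protein links form at much higher rates than inter-protein
  links (mono >= intra >> inter);
* injected false inter-links whose endpoints are biased toward absent
  proteins — the error mode the mono-/intralink filter targets;
* decoy records emitted symmetrically to targets: every generated link
  is independently re-emitted as a TD or DD copy. A decoy match goes to
  a *random* sequence of the reversed database, so the decoy-side
  accession is a random ``decoy_``-prefixed protein; decoy accessions
  can still acquire mono/intra support (via decoy mono/intralinks) the
  same way targets do, just rarely — as in a real search. Mono- and
  intralink decoys are wholly decoy (DD): a one-target-one-decoy pair
  would by construction be an inter-link. Inter-links carry higher
  decoy emission rates than mono/intralinks, reflecting the
  quadratically larger inter-peptide decoy search space;
* class-conditional identification scores: true links score high;
  false and decoy mono/intralinks score low; false and decoy
  inter-links score intermediately, so a tail of them survives even
  stringent cutoffs — mirroring the observation that inter-protein
  decoys persist at cutoffs where mono/intra decoys are negligible.

Absent proteins emit no mono/intralinks at all by default (an
idealization of "not addressable in this sample"); ``leak_rate`` relaxes
this to probe the filter's failure modes.

Output is one xQuest-dialect TSV per replicate plus a ground-truth CSV
labelling every record true/false and every protein present/absent.
A fixed seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .records import ConfigError

#: Raw labels used in generated tables (xQuest vocabulary).
RAW_LABELS = {"mono": "monolink", "intra": "intralink", "inter": "xlink"}

_HEADER = ["Id", "Protein1", "Protein2", "AbsPos1", "AbsPos2", "Type", "ld-Score"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic identification model.

    Rates are expected link counts per protein, per replicate, at unit
    abundance; ``false_inter_mean`` is the expected number of injected
    false inter-links per replicate. Scores are unitless identification
    scores (Normal, truncated at 0).
    """

    n_proteins_present: int = 60
    n_proteins_absent: int = 120
    n_replicates: int = 3
    seed: int = 0

    #: log-normal abundance scale (location set so the mean is 1)
    abundance_sigma: float = 1.0

    mono_rate: float = 6.0
    intra_rate: float = 4.0
    inter_rate: float = 1.0

    #: expected injected false inter-links per replicate
    false_inter_mean: float = 100.0
    #: probability a false inter-link endpoint is drawn from the absent pool
    absent_bias: float = 0.85

    #: per-record probability of re-emission of an inter-link as a
    #: TD / DD decoy copy
    decoy_td: float = 0.15
    decoy_dd: float = 0.05
    #: per-record probability of re-emission of a mono/intralink as a
    #: (wholly decoy) DD copy
    decoy_mono_intra: float = 0.03

    true_score_mu: float = 30.0
    true_score_sigma: float = 4.0
    false_score_mu: float = 18.0
    false_score_sigma: float = 4.0
    false_inter_score_mu: float = 25.0
    false_inter_score_sigma: float = 5.0

    #: probability per replicate that an absent protein leaks a monolink
    leak_rate: float = 0.0
    #: when true, every present protein is guaranteed >=1 mono/intra
    #: record (a monolink is appended in replicate 1 if needed) — the
    #: idealized full-support regime used for sensitivity checks
    guarantee_support: bool = False

    min_protein_length: int = 100
    max_protein_length: int = 600

    def validate(self) -> None:
        if self.n_proteins_present < 1 or self.n_proteins_absent < 0:
            raise ConfigError("protein counts must be positive")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        for name in ("mono_rate", "intra_rate", "inter_rate",
                     "false_inter_mean", "abundance_sigma",
                     "true_score_sigma", "false_score_sigma",
                     "false_inter_score_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("absent_bias", "decoy_td", "decoy_dd",
                     "decoy_mono_intra", "leak_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if self.decoy_td + self.decoy_dd > 1.0:
            raise ConfigError("decoy_td + decoy_dd must be <= 1")
        if self.min_protein_length < 2:
            raise ConfigError("min_protein_length must be >= 2")

    @classmethod
    def from_dict(cls, raw: dict) -> "SynthConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown synth parameter(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class SynthResult:
    """Generated replicate files plus ground truth."""

    files: list[Path]
    truth: pd.DataFrame        # per record: id, replicate, class, is_true, is_decoy
    proteins: pd.DataFrame     # per protein: accession, present, abundance, length
    records: list[list[dict]] = field(repr=False, default_factory=list)


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    return float(max(rng.normal(mu, sigma), 0.0))


class _Emitter:
    """Accumulates rows and ground-truth entries with sequential ids."""

    def __init__(self) -> None:
        self.rows: list[list[dict]] = []
        self.truth_rows: list[dict] = []
        self._n = 0

    def new_replicate(self) -> None:
        self.rows.append([])

    def emit(
        self,
        link_class: str,
        protein_a: str,
        pos_a: int,
        protein_b: Optional[str],
        pos_b: Optional[int],
        score: float,
        *,
        is_true: bool,
        is_decoy: bool,
        replicate: Optional[int] = None,
    ) -> None:
        self._n += 1
        rid = f"R{self._n:06d}"
        rep = replicate if replicate is not None else len(self.rows)
        self.rows[rep - 1].append({
            "Id": rid,
            "Protein1": protein_a,
            "Protein2": protein_b if protein_b is not None else "-",
            "AbsPos1": pos_a,
            "AbsPos2": pos_b if pos_b is not None else "-",
            "Type": RAW_LABELS[link_class],
            "ld-Score": f"{score:.4f}",
        })
        self.truth_rows.append({
            "record_id": rid,
            "replicate": rep,
            "link_class": link_class,
            "protein_a": protein_a,
            "protein_b": protein_b if protein_b is not None else "",
            "is_true": is_true,
            "is_decoy": is_decoy,
        })


def generate(config: SynthConfig, outdir: str | Path) -> SynthResult:
    """Generate one xQuest-dialect TSV per replicate plus ground truth.

    Writes ``replicate_1.tsv`` ... ``replicate_N.tsv`` and
    ``ground_truth.csv``/``proteins.csv`` into ``outdir`` and returns a
    :class:`SynthResult`. Decoy copies use the ``decoy_`` accession
    prefix, matching the package's default decoy convention.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n_pres, n_abs = config.n_proteins_present, config.n_proteins_absent
    present = [f"P{i:04d}" for i in range(1, n_pres + 1)]
    absent = [f"A{i:04d}" for i in range(1, n_abs + 1)]
    everything = present + absent
    lengths = {
        acc: int(rng.integers(config.min_protein_length,
                              config.max_protein_length + 1))
        for acc in everything
    }
    # log-normal abundances with mean 1 for present proteins
    mu = -0.5 * config.abundance_sigma ** 2
    abundance = {
        acc: float(rng.lognormal(mu, config.abundance_sigma))
        for acc in present
    }

    em = _Emitter()

    def pos(acc: str) -> int:
        return int(rng.integers(1, lengths[acc] + 1))

    def decoy_acc() -> str:
        """Random sequence of the reversed (decoy) database."""
        return "decoy_" + everything[int(rng.integers(len(everything)))]

    def maybe_decoys(link_class, a, pa, b, pb, is_true) -> None:
        """Possibly re-emit the link as a decoy copy.

        The decoy side matches a random reversed-database sequence; the
        position is re-drawn on that sequence. Mono/intralinks only
        yield DD copies (a TD pair of distinct proteins would be an
        inter-link).
        """
        u = rng.random()
        if link_class == "inter":
            if u >= config.decoy_td + config.decoy_dd:
                return
            score = _truncated_normal(
                rng, config.false_inter_score_mu, config.false_inter_score_sigma)
            if u < config.decoy_td:
                d = decoy_acc()
                dpos = pos(d.removeprefix("decoy_"))
                if rng.random() < 0.5:
                    em.emit("inter", d, dpos, b, pb, score,
                            is_true=False, is_decoy=True)
                else:
                    em.emit("inter", a, pa, d, dpos, score,
                            is_true=False, is_decoy=True)
            else:
                d1, d2 = decoy_acc(), decoy_acc()
                while d2 == d1:
                    d2 = decoy_acc()
                em.emit("inter", d1, pos(d1.removeprefix("decoy_")),
                        d2, pos(d2.removeprefix("decoy_")), score,
                        is_true=False, is_decoy=True)
        else:
            if u >= config.decoy_mono_intra:
                return
            score = _truncated_normal(
                rng, config.false_score_mu, config.false_score_sigma)
            d = decoy_acc()
            base = d.removeprefix("decoy_")
            p1 = pos(base)
            if link_class == "mono":
                em.emit("mono", d, p1, None, None, score,
                        is_true=False, is_decoy=True)
            else:
                p2 = pos(base)
                if p2 == p1:
                    p2 = p1 % lengths[base] + 1
                em.emit("intra", d, p1, d, p2, score,
                        is_true=False, is_decoy=True)

    for _rep in range(config.n_replicates):
        em.new_replicate()
        # mono- and intralinks of present proteins, abundance-scaled
        for acc in present:
            a = abundance[acc]
            for _ in range(rng.poisson(config.mono_rate * a)):
                score = _truncated_normal(
                    rng, config.true_score_mu, config.true_score_sigma)
                em.emit("mono", acc, pos(acc), None, None, score,
                        is_true=True, is_decoy=False)
                maybe_decoys("mono", acc, pos(acc), None, None, True)
            for _ in range(rng.poisson(config.intra_rate * a)):
                p1, p2 = pos(acc), pos(acc)
                if p1 == p2:
                    p2 = p1 % lengths[acc] + 1
                score = _truncated_normal(
                    rng, config.true_score_mu, config.true_score_sigma)
                em.emit("intra", acc, p1, acc, p2, score,
                        is_true=True, is_decoy=False)
                maybe_decoys("intra", acc, p1, acc, p2, True)

        # occasional leaked monolinks from absent proteins
        if config.leak_rate > 0:
            for acc in absent:
                if rng.random() < config.leak_rate:
                    score = _truncated_normal(
                        rng, config.true_score_mu, config.true_score_sigma)
                    em.emit("mono", acc, pos(acc), None, None, score,
                            is_true=False, is_decoy=False)

        # true inter-links between present proteins, abundance-weighted
        lam = np.array([config.inter_rate * abundance[acc] for acc in present])
        weights = lam / lam.sum() if lam.sum() > 0 else None
        n_true_inter = rng.poisson(lam.sum() / 2.0)
        for _ in range(n_true_inter):
            ia, ib = rng.choice(n_pres, size=2, replace=False, p=weights)
            a, b = present[ia], present[ib]
            score = _truncated_normal(
                rng, config.true_score_mu, config.true_score_sigma)
            pa, pb = pos(a), pos(b)
            em.emit("inter", a, pa, b, pb, score, is_true=True, is_decoy=False)
            maybe_decoys("inter", a, pa, b, pb, True)

        # injected false inter-links, endpoints biased toward absent proteins
        for _ in range(rng.poisson(config.false_inter_mean)):
            def endpoint() -> str:
                if n_abs > 0 and rng.random() < config.absent_bias:
                    return absent[int(rng.integers(n_abs))]
                return everything[int(rng.integers(len(everything)))]
            a = endpoint()
            b = endpoint()
            while b == a:
                b = endpoint()
            score = _truncated_normal(
                rng, config.false_inter_score_mu, config.false_inter_score_sigma)
            pa, pb = pos(a), pos(b)
            em.emit("inter", a, pa, b, pb, score, is_true=False, is_decoy=False)
            maybe_decoys("inter", a, pa, b, pb, False)

    if config.guarantee_support:
        supported = {
            t["protein_a"] for t in em.truth_rows
            if t["link_class"] in ("mono", "intra") and not t["is_decoy"]
        }
        for acc in present:
            if acc not in supported:
                score = _truncated_normal(
                    rng, config.true_score_mu, config.true_score_sigma)
                em.emit("mono", acc, pos(acc), None, None, score,
                        is_true=True, is_decoy=False, replicate=1)

    files = []
    for i, rows in enumerate(em.rows, start=1):
        path = outdir / f"replicate_{i}.tsv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write("\t".join(_HEADER) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in _HEADER) + "\n")
        files.append(path)

    truth = pd.DataFrame(
        em.truth_rows,
        columns=["record_id", "replicate", "link_class", "protein_a",
                 "protein_b", "is_true", "is_decoy"],
    )
    proteins = pd.DataFrame({
        "accession": everything,
        "present": [acc in set(present) for acc in everything],
        "abundance": [abundance.get(acc, 0.0) for acc in everything],
        "length": [lengths[acc] for acc in everything],
    })
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    proteins.to_csv(outdir / "proteins.csv", index=False)
    return SynthResult(files=files, truth=truth, proteins=proteins,
                       records=em.rows)
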