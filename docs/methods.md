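# Methods

## The filter

The mono-/intralink filter operates on a table of cross-link
identifications that has been reduced to three canonical classes
(monolink, intra-protein, inter-protein). Its eligible set `E` contains
every protein accession that appears in at least one MONO or INTRA
record of the dataset *at the active score cutoff*; an INTER record is
retained iff both partner accessions are in `E`. Three design points
deserve justification:

* **Eligibility is global, not per replicate.** The pipeline
  concatenates all replicate files before building `E`, so a monolink
  seen only in replicate 1 licenses an inter-link seen only in
  replicate 3. When the optional replicate-consistency filter is
  active it runs *before* eligibility construction, so supporting
  mono/intra evidence must itself meet the replicate requirement.
* **Decoy records confer eligibility on decoy accessions.** Targets
  and decoys pass through the identical rule. Any asymmetry (e.g.
  requiring target support only) would deflate the decoy count
  relative to the surviving false targets and bias downstream FDR
  estimates.
* **Support is assessed at the same score cutoff as the dataset.**
  The score filter is the first pipeline stage; there is no separate,
  looser cutoff for mono/intra support. A looser support cutoff would
  admit more eligible proteins and trade error reduction for recall;
  it can be emulated by running the pipeline at the looser cutoff and
  post-filtering, but is deliberately not a built-in mode.

The pipeline stage order is fixed: per-file score cutoff →
concatenation → optional replicate filter → decoy annotation → type
normalization → eligible set → mi-filter. The filter is idempotent
(MONO/INTRA records are never removed, so `E` is unchanged by a second
pass) and symmetric under swapping the two sides of a record; both
properties are enforced by tests.

## Link-type normalization

Raw labels are mapped case-insensitively to MONO/INTRA/INTER via a
configurable table. Two overriding rules: a two-site record whose
accessions are identical is INTRA regardless of label (without isotope
or stoichiometry evidence, a homodimeric "inter" call is read
conservatively), and looplinks default to INTRA — a looplink joins two
residues of one polypeptide and is exactly the kind of evidence the
filter consumes (the protein is present and cross-linkable). Both are
overridable in the type-mapping config (e.g. `looplink: drop`); the
unmapped-label policy is `error` by default so unexpected vocabularies
fail loudly.

## Replicate filtering

Site identity is the canonical `unique_key`: the sorted (accession,
position) pairs plus the link class, invariant under endpoint swap. A
site passes when it occurs in at least `min_replicates` distinct
source files; all its occurrences are then retained. A `pair_level`
option relaxes identity to the sorted protein pair, for workflows that
consider any link between the same two proteins as reproducing
evidence.

## Target/decoy accounting

Decoy status is parsed from accession prefixes (`decoy_`, `rev_`,
`REV_` by default, case-sensitive, overridable). TD and DD records
both count as decoy. Two ratio conventions are reported side by side
because both are in circulation: `decoy_fraction = d/(t+d)` and
`decoy_target_ratio = d/t`; they satisfy `ratio = fraction /
(1 − fraction)` and the sweep output carries both explicitly. A
monolink on a decoy accession is recorded as DD (the identification is
wholly decoy; a "TD monolink" has no meaning for a single-sequence
record). Counts are at the record level by default — redundant
identifications included — with a `unique` option that collapses on
`unique_key` first; both modes exist because published counts are
reported in either convention and rarely say which.

The default sweep cutoffs are 20, 25, 28 and 32, spanning loose to
stringent spectral agreement for ld-score-like composite scores.

## Structure validation

Distances are measured between Cα atoms, the convention for
lysine-reactive linkers; the default cutoff of 35 Å is the maximal
lysine Cα–Cα span bridgeable by DSS/BS3-class reagents. For structures
with several copies of a subunit the minimum distance over all chain-
copy combinations is taken — the permissive standard for ambiguous
copy assignment; as a consequence adding a chain copy can only
decrease a distance. Residue numbering follows the structure's author
numbering, with optional per-chain offsets (`structure residue =
cross-link position + offset`) for sequence-vs-structure shifts.
Unmappable residues are reported as such and excluded from the
satisfaction denominator, never silently counted as failures. No
solvent-accessible-surface distance is computed; Cα Euclidean distance
is the sole metric.

## The synthetic-data generator

The generator emulates the statistical structure of a cross-linking
search against a database larger than the sample:

* `n_proteins_present = 60` proteins in the sample with log-normal
  abundances (σ = 1, mean normalized to 1), plus
  `n_proteins_absent = 120` database-only proteins — the situation of
  a complex searched in a proteome-wide setting, where most database
  entries are not in the sample.
* Per replicate (3 by default) each present protein emits
  Poisson-distributed monolinks (rate 6·abundance), intralinks
  (4·abundance) and inter-link endpoints (1·abundance): the
  mono ≥ intra ≫ inter formation-rate ordering, scaled by abundance so
  low-abundance proteins can genuinely lack support. True inter-links
  connect abundance-weighted pairs of present proteins.
* An expected 100 false inter-links per replicate are injected, each
  endpoint drawn from the absent pool with probability 0.85 (otherwise
  uniformly) — false inter-protein identifications concentrate on
  proteins that are not actually addressable in the sample.
* Every record is independently re-emitted as a decoy copy. The decoy
  side matches a *random* reversed-database sequence (not the decoy
  twin of the same protein — decoy PSMs are random matches), so decoy
  accessions only rarely acquire mono/intra support, as in real
  searches. Mono/intralinks yield only DD copies (a TD pair of
  distinct sequences would be an inter-link by definition) at rate
  0.03; inter-links yield TD at 0.15 and DD at 0.05, reflecting the
  quadratically larger inter-peptide decoy space.
* Scores are truncated normal: true links N(30, 4); false/decoy
  mono/intralinks N(18, 4); false/decoy inter-links N(25, 5). The
  higher false-inter mean makes inter-link decoys persist at cutoffs
  where mono/intra decoys are already negligible — the empirically
  observed error structure that motivates the filter — and places the
  default cutoffs 20–32 across the signal/noise overlap.

A fixed seed produces byte-identical output files. Two knobs exist
purely for probing edge regimes: `leak_rate` lets absent proteins leak
occasional monolinks (default 0, i.e. the idealization that absent
proteins emit no support), and `guarantee_support` appends one
monolink for any present protein that drew none — the fully-supported
regime in which the filter provably removes no true inter-link, used
for sensitivity checks.

What the generator does **not** model: spectra and spectral rescoring,
retention time and charge, peptide-level detectability sequence
effects, shared peptides between proteins, and any geometry. Passing
tests therefore demonstrate the combinatorial and statistical
behaviour of the filter under these assumptions, not its performance
on any particular instrument's data; on real data the recall of true
inter-links is bounded below 100 % by genuinely present proteins that
escape mono/intra detection.

## Numerical and degenerate-input choices

* Score filtering keeps records with `ld_score ≥ cutoff` (closed
  bound); a cutoff of −∞ is the explicit no-op.
* `decoy_fraction` is undefined (reported as absent, not 0) when a
  class has no hits; `decoy_target_ratio` is undefined when targets
  are 0. The identity between the two ratios is exact in real
  arithmetic and verified to machine precision.
* Empty input tables with a valid header are valid empty datasets.
* Strict parsing is the default — an unparsable row aborts with its
  line number; a lenient flag downgrades this to a logged skip.
  Silent row drops hide corruption.
* Replicate labels are compared as sets in dataset equality; a
  replicate that contributes no records cannot be reconstructed from a
  written table, which bounds round-trip fidelity for empty replicates.
* Distance validation at 0.001 Å coordinate precision (the PDB fixed
  format) limits cross-format agreement to ~5×10⁻³ Å; computed
  distances themselves are exact to double precision.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: oracle comparisons use datasets of up to 1 000 records over 50
seeds; the decoy-reduction property is measured over 100 seeded
datasets of roughly 2 500 records each (three replicates); structure
checks use toy coordinate sets written by the tests. These sizes give
stable statistics for every property while keeping a full run in the
tens of seconds.
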