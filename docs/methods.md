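# Methods

## The filter model

`hairpinscan` operates on pairs of a protein sequence and a per-residue
β-aggregation propensity profile. The profile is treated as an opaque
nonnegative signal on the predictor's percentage-like scale (typically
0–100); the package makes no assumption about how it was produced beyond
1:1 alignment with the sequence.

A candidate β-hairpin is a triple (N-strand, turn, C-strand):

* **β-stretches** are maximal runs of positions whose score passes the
  threshold test (default: strictly greater than 1.06). Maximality means
  a stretch cannot be extended in either direction; consequently two
  stretches are always separated by at least one sub-threshold position,
  so the minimum possible turn length is 1 and is asserted rather than
  configured.
* The **length filter** keeps stretches of 5–23 residues, both bounds
  inclusive.
* **Pairing** is between consecutive length-filtered stretches. The turn
  is the positional gap `c_start − n_end − 1` and must be ≤ 9. A middle
  stretch may serve as C-strand of one candidate and N-strand of the
  next. A stretch discarded by the length filter does not block pairing
  of its neighbours, but its residues count toward their gap — in
  practice such a gap almost always exceeds the turn bound.
* **Composition criteria** are evaluated on the strand subsequences only
  (turn residues excluded): the N-strand needs ≥ 1 aromatic residue
  (F/W/Y; histidine is excluded, following conventional usage in the
  amyloid literature, and the set is configurable) and an I+L+V fraction
  in [0.32, 0.50]; the C-strand needs 1–3 glycines and an I+L+V fraction
  in [0.32, 0.61].

Candidates are counted as pairs: two overlapping candidates sharing a
strand are two regions, and per-protein hit counts are pair counts. This
is consistent with the observed ratio of regions to hit proteins in
proteome-scale screens (≈ 1.2 at the strict stage).

### Numerical choices

* Fraction bounds are compared with exact rational arithmetic
  (`Fraction(count, length)` against `Fraction("0.32")`), never floating
  tolerance, so boundary cases such as 8/25 = 0.32 behave
  deterministically.
* The threshold comparison is strict (`> 1.06`) by default. The
  alternative inclusive reading (`≥ 1.06`) is one switch
  (`strict_greater=false`); both readings appear in descriptions of this
  kind of screen and the numbered operational definition uses the strict
  form. Likewise, `turn_requires_zero` optionally demands that every
  turn residue score exactly 0; the default places no requirement on
  turn scores, only on the gap length.
* Failure codes are reported in a fixed order (`C2_N`, `C2_C`, `C3`,
  `C4_1`, `C4_2`, `C5_1`, `C5_2`), and a candidate passes iff its code
  list is empty. In diagnostic mode (`include_failed`), length failures
  are evaluated on consecutive maximal runs and turn failures on
  consecutive length-filtered stretches, so each rejected planted decoy
  surfaces with exactly its one violated criterion.

## Funnel modes and summary statistics

The screen runs in two modes mirroring a two-stage funnel: criteria 1–3
(stretch/length/turn topology only) and criteria 1–5 (with composition).
The 1–3 hit set is a superset of the 1–5 set on any input. Summary
statistics are: sequences analyzed, sequences skipped (explicit skip-list
plus missing profiles, tracked separately), candidate count, proteins
with ≥ 1 candidate, their fraction of analyzed sequences, and the mean
number of candidates per hit-containing protein (conditional mean;
reported as 0 when no protein has hits, with the unconditional mean per
analyzed sequence emitted alongside for transparency). Missing profiles
are fatal by default (`missing_profile_tolerance=0`) to prevent silent
undercounting.

## I/O contracts

FASTA parsing uses Biopython; ids are the first whitespace token with
UniProt `sp|ACC|NAME` / `tr|ACC|NAME` headers unwrapped to the accession.
The 20 standard residues plus {X, U, B, Z, O} are accepted (they occur in
reviewed UniProt entries); a terminal `*` is stripped; anything else is a
format error naming the position. Nonstandard residues never count as
aromatic/ILV/Gly but do count toward strand lengths and gaps — the
conservative choice, since it can only deflate composition fractions.

Batch files for the external predictor contain one line per sequence,
`<id> N N 7 298 0.1 <sequence>` under default parameters (unmodified
termini, pH 7, 298 K, 0.1 M ionic strength), chunked at 1000 lines per
file, the predictor's input limit. Numeric fields are rendered without
trailing zeros to match the expected line shape byte-for-byte.

Per-residue score tables are one file per sequence, located by
`<accession>` filename stem. The default dialect (whitespace-delimited,
header, residue column `aa`, score column `Aggregation`) is an assumption
about the external predictor's layout and is therefore fully configurable
(`TableDialect`: delimiter, header, name- or index-addressed columns,
comment prefix). When a residue column is present it is cross-checked
letter-by-letter against the sequence.

## Synthetic fixtures

The generator emulates the screen's study conditions at desk scale: a
proteome in which a chosen fraction of proteins (default regimes use
10%, echoing the strict-stage hit rate observed on the human proteome)
carry exactly one true hairpin motif, while the remaining proteins are
single-criterion decoys or disorder-only background.

A planted protein is `flank + N-strand + turn + C-strand + flank`.
Strand residues are sampled so the composition bounds hold exactly: one
aromatic and an ILV count drawn uniformly from
[⌈0.32·len⌉, ⌊0.50·len⌋] for the N-strand; 1–3 glycines and an ILV count
in [⌈0.32·len⌉, ⌊0.61·len⌋] for the C-strand; remaining positions are
filled from residues that are neither aromatic nor ILV nor glycine.
Flanks and turns use disorder-promoting residues (P, G, S, E, K).
Profiles are assigned directly: strand scores uniform in [2, 80], all
other positions 0, so the planted strands are exactly the maximal
stretches and the ground truth is exact by construction. Decoys minimally
break one named criterion (e.g. `C1` sets one strand's scores to exactly
1.06, which fails the strict threshold; `C2_*` shortens a strand to 4
residues; `C3` forces a 10-residue turn; composition decoys move one
count just outside its window) while keeping everything else valid. All
randomness flows from the spec seed; identical specs produce
byte-identical output. Default strand lengths in generated corpora are
5–12 residues with turns of 1–9 and flanks of 6–15 — compact motifs
typical of the hairpin regions the filter was designed around.

The surrogate propensity backend computes
`score = clip(30·(⟨Pβ⟩₅ − 1) + 5·⟨KD⟩₅ − 10, 0, 100)` from centred
5-residue window means of the Chou–Fasman β-sheet preference and
Kyte–Doolittle hydropathy scales (shipped as data). The weights were
chosen once so that disorder-promoting residues score 0 and aliphatic or
aromatic runs score well above the 1.06 stretch threshold. It is a
pipeline exerciser, not a model of the external predictor: passing tests
on surrogate or planted profiles demonstrate the correctness of the
filter logic and I/O, not agreement with TANGO scores, and surrogate
output is tagged `backend=surrogate` everywhere. What the fixtures do not
emulate about real data: realistic score distributions, overlapping or
nested stretch topologies beyond what random instances produce,
low-complexity and transmembrane regions, and proteome-scale length
distributions.

## Peptide descriptors

The isoelectric point is the unique root of the Henderson–Hasselbalch
net charge `q(pH) = Σ_basic n/(1+10^(pH−pKa)) − Σ_acidic n/(1+10^(pKa−pH))`,
which is strictly decreasing in pH; bisection on [0, 14] runs to
|q| < 1e-6. pKa tables ship as data with two named sets (EMBOSS default,
Lehninger selectable); since pI values depend noticeably on the table,
none is treated as ground truth. Sequences with no ionizable groups
(possible only with suppressed termini) have no root and raise a domain
error. Nonstandard residues contribute zero charge.

## Problem sizes and verification

The test suite cross-checks the scanner against an independent
brute-force enumerator (positions classified one by one, every pair of
runs tested literally against the criteria) on 1000 random boundary-rich
instances of length ≤ 60, recovers ≥ 200 planted motifs at exact
coordinates, exercises every numeric boundary (1.06, lengths 4/5/23/24,
turns 9/10, fractions 8/25, 10/20, 61/100), checks funnel-superset and
summary invariants over 100 seeded corpora, and screens a 2000-sequence
surrogate corpus end-to-end with byte-identical repeat output. The
acceptance script reruns the same measurements from scratch at seeds of
the caller's choosing with a 500-protein corpus at a 10% hit fraction.

## Known limitations

* Reproducing proteome-scale counts from a real screen requires the
  original proteome snapshot and the external predictor's per-residue
  output; the package supports that as an external-data mode but cannot
  regenerate the scores itself.
* Pairing only consecutive kept stretches means a candidate can never
  span across an intervening length-valid stretch; whether over-long
  stretches should instead block their neighbours entirely is a design
  choice (they are transparently discarded here, with their residues
  counted in the gap).
* The per-residue table dialect defaults are assumptions about the
  external predictor's output layout and may need adjustment per
  version.
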