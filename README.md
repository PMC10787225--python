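# hairpinscan

Sequence-based detection of candidate **amyloidogenic β-hairpin segments**
in protein sequences and whole proteomes.

Aggregation-prone amyloidogenic proteins such as amyloid-β, α-synuclein
and islet amyloid polypeptide can populate a β-hairpin conformation: two
antiparallel β-strands rich in hydrophobic and aromatic residues,
connected by a short turn. `hairpinscan` finds sequence segments with the
same architecture by scanning per-residue β-aggregation propensity
profiles (e.g. from the TANGO predictor) with a cascade of filters:

1. **β-stretch** — residues with aggregation propensity score > 1.06 are
   "in β-stretch"; stretches are maximal runs of such residues.
2. **Stretch length** — only stretches of 5–23 residues are kept.
3. **Turn** — two consecutive kept stretches must be separated by at most
   9 residues (the potential turn).
4. **N-terminal strand composition** — at least one aromatic residue
   (F/W/Y) and an Ile+Leu+Val fraction between 0.32 and 0.50.
5. **C-terminal strand composition** — between 1 and 3 glycines and an
   Ile+Leu+Val fraction between 0.32 and 0.61.

All bounds are inclusive and fraction comparisons use exact rational
arithmetic (an ILV count of 8 in a 25-residue strand is exactly 0.32 and
passes). Every threshold and policy choice (strict vs. inclusive
comparison at 1.06, whether turn residues must score zero, the residue
sets themselves) lives in a `FilterConfig` and can be overridden from a
YAML file.

The package does **not** implement the TANGO algorithm. It prepares batch
input for the external binary, parses per-residue output tables, and
ships a clearly-labelled surrogate propensity backend (a windowed
combination of β-sheet preference and hydropathy scales) plus a
synthetic-fixture generator so that the whole pipeline is testable
without the external predictor. Surrogate-derived tables always carry a
`backend=surrogate` provenance tag.

## Worked example

Generate a 100-protein synthetic proteome in which 10% of the sequences
carry one planted hairpin motif (the remainder are single-criterion
decoys and disorder-only background), then screen it:

```sh
$ hairpinscan synth --n 100 --hit-fraction 0.1 --seed 7 --out demo
wrote demo/corpus.fasta, demo/profiles/, demo/truth.tsv

$ hairpinscan screen demo/corpus.fasta --profiles demo/profiles \
      --hits demo/hits.tsv --summary demo/summary.json
10 candidate(s) in 10 of 100 analyzed protein(s) (10.0%); 1.00 per hit protein; 0 skipped
```

The screen found exactly the 10 planted motifs: 10% of the proteins carry
a hit, with 1.0 candidate per hit-containing protein, and none of the
decoys (each of which violates exactly one criterion) passed. The hit
table lists one candidate per row with strand coordinates (1-based
inclusive), turn length and the composition metrics each criterion was
evaluated on:

```
protein_id  n_start  n_end  n_seq      turn_len  c_start  c_end  c_seq       n_aromatic  n_ilv_fraction  c_gly  c_ilv_fraction  passed
SYN00005    11       19     KNVKQAFLL  1         21       25     GDLGI       1           0.3333          2      0.4000          True
SYN00022    13       20     AQINIVYI   5         26       35     GIGLVTIAIQ  1           0.5000          2      0.5000          True
...
```

`demo/summary.json` holds the same funnel statistics in machine-readable
form (`n_candidates`, `n_proteins_with_hits`,
`mean_candidates_per_hit_protein`, ...).

Other subcommands:

* `hairpinscan batchprep proteome.fasta --out batches/` — write batch
  input for the external predictor, one sequence per line
  (`P12345 N N 7 298 0.1 MKVL...`), chunked at 1000 lines per file;
* `hairpinscan scan` — per-sequence scanning, optionally printing
  rejected pairs with their failure codes (`--emit-failed`);
* `hairpinscan screen --criteria 1-3` — the relaxed funnel stage
  (stretch/length/turn topology only, no composition filters);
* `hairpinscan report peptides.fasta --out report.tsv` — per-peptide
  descriptors: length, isoelectric point (bisection on the
  Henderson–Hasselbalch net-charge function; EMBOSS or Lehninger pKa
  tables), aromatic/glycine counts, ILV fraction, net charge at pH 7.

To screen a real proteome, run the external predictor on the batch files,
place its per-residue output tables in a directory as `<accession>.txt`
(whitespace-delimited, columns `aa` and `Aggregation` by default; the
dialect is configurable), and pass that directory to `--profiles`.
Accessions the predictor fails on can be excluded with `--skip`; a
ready-made skip-list for the 2017 reviewed human proteome ships with the
package data.

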