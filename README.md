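# nrpsarch

A toolkit for parsing non-ribosomal peptide synthetase (NRPS) protein
sequences into a standardized **motif-and-intermotif architecture**, and
for the downstream sequence statistics that architecture enables:

- **Motif catalog** (`nrpsarch.catalog`) — curated core motifs for the
  C/A/T/E/TE/ACP domains (7 C, 10 A, 1 T, 7 E, 1 TE), the optional
  extended motifs (the conserved-glycine "G" motif between A5 and A6,
  the A-domain start motif `Aa1`, the T-domain first-helix motif `Ta1`),
  reference domain sequences, and the ten binding-pocket code positions
  of the adenylation domain.
- **Locator** (`nrpsarch.locator`) — reference-anchored global alignment
  (affine-gap Needleman–Wunsch/Gotoh, BLOSUM62, gap open 10 / extend
  0.5) that transfers catalog motif spans onto query domains, derives
  intermotif segments, applies the dead-domain length filter, groups
  domains into C+A+T(+C/+E) modules with length windows, and extracts
  the ten-residue specificity code.
- **Subtype classifier** (`nrpsarch.subtypes`) — 18 condensation-
  superfamily subtype profile HMMs (plus an optional epimerization-domain
  model), full-forward log-odds scoring in bits, and the 200-bit
  confidence rule (`confident` / `Low-confidence`).
- **Architecture statistics** (`nrpsarch.stats`) — per-column
  frequency/gap profiles, conservation scans for candidate new motifs,
  mutual information between alignment columns and categorical labels,
  intermotif length tables (span or anchored boundary conventions), and
  pathway organization counts.
- **SCA** (`nrpsarch.sca`) — statistical coupling analysis in the binary
  approximation: conservation weights, coupling matrix, eigen-spectrum,
  column-scramble null spectrum, signed-threshold sector extraction,
  matrix cleaning, and label-column augmentation for substrate-related
  modes.
- **Loop analysis** (`nrpsarch.loops`) — five binding-pocket loop
  lengths per A domain (A3–A4, A4–S4, S4–S6, S6–A5, A5–G), capped
  Euclidean distance matrices, average-linkage loop groups, loop-profile
  normalization, and (conditional) entropies of the specificity code.
- **Synthetic fixtures** (`nrpsarch.fixtures`) — deterministic
  generators for domains/modules with ground-truth motif spans, labeled
  alignments with planted covariation, and loop-length mixtures.

All user-facing coordinates are 1-based inclusive.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (catalog
constants, classifier panel and round-trip rate, loop machinery rules,
and the property suites: alignment-vs-oracle, MI identities, relative
entropy closed forms, planted-sector recovery, null-spectrum
determinism, loop-group recovery, conditional-entropy monotonicity).

## CLI

```sh
nrpsarch synth --out out/synth --seed 3 --n 5 --domain-type C
nrpsarch parse --input out/synth/synthetic.fasta --out out/parsed --domain-type C
nrpsarch classify --input queries.fasta --out out/calls --threshold 200
nrpsarch stats --input aln.fasta --labels labels.tsv --label subtype --out out/stats
nrpsarch sca --input aln.fasta --labels labels.tsv --label substrate --out out/sca --seed 0
nrpsarch loops --input adomains.fasta --out out/loops
```

Every run writes its effective configuration to `config.json` in the
output directory and logs per-stage counts.

## Bundled data

`src/nrpsarch/data/` holds the serialized motif catalog (TSV/JSON/FASTA)
and the per-subtype reference alignments used to build the classifier
panel; `scripts/build_reference_data.py` regenerates them
deterministically from the layout tables in `nrpsarch._layouts`.
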