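# hgscan

Screening and quantification of mercury-cycling genes (*hgcA*, *hgcB*,
*merA*, *merB*) in marine metagenome protein catalogs, with the single-copy
marker *rpoB* for normalization.

The pipeline:

1. **Profile-HMM detection** (`hgscan.profile_hmm`) — builds per-family
   match/insert/delete profiles from reference alignments, scores candidates
   (Viterbi + forward, local along the model with free flanks), and converts
   bit scores to E-values via a seeded Gumbel calibration against background
   sequences.  Family thresholds: 1e-5 for *hgcA*/*hgcB*/*merB*, 1e-10 for
   *merA*.
2. **Conserved-residue curation** (`hgscan.motif_screen`) — residue rules
   anchored to 1-based positions of a named reference (e.g. *merA*
   C207/C212/Y264/Y-or-F605/C628/C629; *merB* C96/D99/C117/C159; *hgcA* C93)
   mapped onto candidates by global alignment, plus the twin `CX2CX2CX3C`
   cysteine-cluster pattern required of *hgcB*.  A gap at a rule position
   fails the rule, so fragments cannot pass.
3. **Quantification** (`hgscan.quantify`) — validated counts per sample and
   family expressed as a percentage of *rpoB* hits; lineage assignment by
   best-scoring labeled reference, with lineage proportion tables (optionally
   stratified by station and depth).
4. **Dereplication** (`hgscan.core_align`) — affine-gap global alignment
   (BLOSUM62, gap open −11 / extend −1) and greedy identity clustering at a
   90% cutoff (shorter-sequence denominator) before lineage tabulation.
5. **Hydrographic statistics** (`hgscan.hydro_stats`) — Spearman rank
   correlation (average ranks for ties, two-sided asymptotic p via the t
   transform, optional exact/Monte-Carlo permutation p) between gene
   abundances and environmental depth profiles.
6. **Synthetic benchmarks** (`hgscan.synthetic_data`) — seeded generators
   for reference families with planted rule residues, sample catalogs of
   valid / rule-ablated / decoy proteins with a planted mesopelagic depth
   trend, and environment tables with monotone depth structure.  All outputs
   are deterministic functions of their seeds.

## CLI

```sh
hgscan simulate --out sim --seed 1              # synthetic benchmark + truth
hgscan run-all --config config.yaml             # full pipeline
hgscan build-profiles --references sim/references --out profiles
hgscan search --profile profiles/hgcA.profile.txt --catalog sim/catalogs/S1_200m.fasta --out hits.tsv
hgscan validate --hits hits.tsv --catalogs sim/catalogs --references sim/references --out validation.tsv
hgscan dereplicate --fasta validated.fasta --threshold 0.9 --out clusters.tsv
hgscan quantify --validation validation.tsv --hits hits.tsv --env sim/env.tsv --out abundance.tsv
hgscan correlate --abundance abundance.tsv --env sim/env.tsv --out correlations.tsv
```

A minimal `config.yaml` for `run-all`:

```yaml
out_dir: out
references_dir: sim/references
catalogs_dir: sim/catalogs
env_path: sim/env.tsv
```

All stages read/write plain FASTA and TSV; `run-all` writes a manifest with
per-stage counts and echoes its configuration, and rerunning an identical
configuration reproduces byte-identical tables.  Exit codes: 0 success,
2 input error, 3 internal error.

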