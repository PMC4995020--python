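# nadda

Alignment-free detection of conserved regions in protein sequences.

Protein domains and motifs are stretches of sequence preserved by evolution.
The classical way to find them — all-vs-all alignment followed by clustering —
scales quadratically in the number of sequences. `nadda` (a no-alignment
domain detection algorithm) instead exploits a purely lexical signal: a
subsequence that is conserved across a family recurs, nearly verbatim, in
many sequences of a large dataset, so its constituent k-mers have high
*dataset frequency*, while background k-mers over the 20-letter amino-acid
alphabet almost never collide. The package is aimed at anyone who needs
putative domain footprints on large protein sets without running BLAST-tier
pairwise comparison: sequence-analysis pipelines, domain-database curation,
and teaching material on alignment-free methods.

## Method

Given a set *S* of *n* protein sequences:

1. **k-mer frequency** (default *k* = 6): the frequency of a k-mer is the
   number of *distinct* sequences in *S* containing it at least once (not an
   occurrence count).
2. **k-mer profile**: each sequence *s* becomes an integer vector of length
   |*s*| whose entry at index *i* is the frequency of the k-mer starting at
   *i*. Only the first |*s*| − k + 1 indices originate a k-mer; the tail is
   zero.
3. **Per-index classification**: index *i* is described by the 2*w* + 1
   profile values in the window [*i* − *w*, *i* + *w*] (default *w* = 10,
   zero-padded at sequence ends). A Random Subspace ensemble of decision
   trees — each tree trained on 7 features drawn at random from the 21, with
   pre-pruning MSS = 100 (minimum node size eligible for splitting) — votes
   whether *i* is conserved. The trees' split thresholds realize a learned
   per-window-position threshold set {τ₁ … τ₂ᵥ₊₁}.
4. **Regions and evaluation**: maximal runs of conserved indices become
   conserved regions; against reference annotations the per-index confusion
   counts give AC = (TP+TN)/N, SN = TP/(TP+FN), SP = TN/(TN+FP).

Because the classifier sees only frequencies, never residues, a model trained
once can detect *de novo* conserved regions — domains absent from its
training data — as long as the query dataset itself contains enough copies of
the region to lift its k-mer frequencies.

A synthetic-family simulator (`nadda.synthetic`) generates families with a
shared domain implanted between random flanks, with per-residue substitution
noise and exact truth intervals, so the entire pipeline is testable without
any database download.

## Worked example

Simulate two families of 50 sequences (domain 40 aa, flanks ~60 aa, 5%
substitution noise), train on the truth annotations, predict, and score:

```sh
nadda simulate --n-seqs 50 --domain-len 40 --flank-len 60 \
      --mutation-rate 0.05 --n-families 2 --seed 7 \
      --out-fasta families.fa --out-annotations truth.tsv
nadda profile families.fa -k 6 --out-profiles profiles.tsv --out-table table.tsv
nadda train families.fa truth.tsv --n-trees 100 --seed 0 --model-out model.joblib
nadda predict families.fa --model model.joblib --out predicted.tsv
nadda evaluate predicted.tsv truth.tsv families.fa --name demo --out report.tsv
```

which logs:

```
INFO nadda: n=100 N=16333 mean_freq=6.7116 freq_variance=171.2376
INFO nadda: trained on 16333 instances (positive fraction 0.245); model -> model.joblib
INFO nadda: predicted 105 conserved region(s) on 100 sequence(s) -> predicted.tsv
INFO nadda: AC=99.2% SN=96.9% SP=100.0% (tp=3877 tn=12329 fp=4 fn=123)
```

`mean_freq` is the average k-mer frequency over all valid profile positions
(domain k-mers sit near 50 here, flank k-mers near 1). The final line is the
per-index confusion against the implanted truth: 96.9% of truly conserved
indices were recovered and only 4 of 12,333 background indices were
mislabeled. `predicted.tsv` holds 0-based half-open intervals
(`fam00_seq000	58	98` is the implanted domain of that sequence);
`--format gff3` emits 1-based `conserved_region` features instead.

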