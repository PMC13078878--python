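# dnbpipe

Tipping-point analysis of time-course transcriptomes with dynamic network
biomarkers (DNB), plus temporal fuzzy clustering and gene-set scoring.

## What problem this solves

Cell populations under a sustained perturbation — the motivating case is an
EGFR-mutant lung cancer line under gefitinib, passing from drug-sensitive
growth through dormancy into resistance — often do not drift smoothly
between states but cross a *critical transition*: a tipping point where the
regulatory network reorganizes abruptly. DNB theory predicts that just
before such a transition a specific gene group shows three simultaneous
signals: its within-group Pearson correlation rises sharply (PCC_in), its
correlation with all other genes falls (PCC_out), and its per-gene standard
deviation rises (SD_in). `dnbpipe` detects this from an ordinary bulk
RNA-seq time course (a genes × samples matrix with a few replicates per
time point) by scoring gene modules per sliding window with the composite
index

```
CI = SD_in · PCC_in / PCC_out
```

and reporting the window of maximal CI as the tipping point and the winning
module as the DNB gene set, with a calibrated permutation p-value. Around
this core it provides:

* a **seeded synthetic-data generator** that plants a transition with all
  three DNB properties in a latent factor model, so the whole pipeline is
  testable against ground truth;
* **fuzzy c-means clustering** of standardized temporal profiles (soft
  clusters of co-varying expression patterns, with "core gene" membership
  thresholds);
* **exact hypergeometric over-representation** of modules/clusters against
  GMT gene-set collections, with Benjamini–Hochberg FDR;
* **rank-AUC signature scoring** per sample (recovery-curve area over the
  top fraction of the expression ranking — monotone-transform invariant),
  for pathway activities such as cholesterol-biosynthesis or dormancy
  signatures.

It is aimed at computational biologists analyzing multi-time-point,
few-replicate expression designs. See `docs/methods.md` for the model,
defaults, and known limitations.

## Worked example

Simulate a 500-gene course (8 days, 5 replicates/day) with a 25-gene module
planted to tip at day 2, then run the detector:

```bash
$ dnbpipe simulate --out demo --seed 8 --n-genes 500 --module-size 25 --replicates 5
wrote simulated course (tipping day 2) to demo

$ dnbpipe dnb --matrix demo/matrix.tsv --metadata demo/metadata.tsv \
      --min-size 10 --max-size 60 --n-perm 99 --seed 8 --out demo/dnb
tipping point at days (1.0, 2.0) (CI=4.854, p=0.09)
```

The CI series over the seven 2-day windows is
`[2.01, 4.85, 4.61, 2.17, 2.21, 2.25, 1.70]` — a clear peak on the windows
containing the planted day 2. The add-one permutation p-value over 99
sample-relabelings is 0.09: suggestive, and deliberately conservative
(permutations relocate rather than destroy covariance; see the methods
note). Testing the recovered module against the simulated gene-set
collection:

```bash
$ cut -f1 demo/matrix.tsv | tail -n +2 > universe.txt
$ dnbpipe enrich --genes demo/dnb/dnb_genes.txt --gmt demo/gene_sets.gmt \
      --universe universe.txt
          set_name  universe_size  set_size_in_universe  query_size  overlap      p_value          fdr
planted_module_set            500                    50          16       16 8.604288e-18 1.720858e-16
     random_set_03            500                    50          16        3 2.085425e-01 9.643313e-01
```

All 16 recovered DNB genes lie in the planted set (hypergeometric
p ≈ 9·10⁻¹⁸); random sets are flat. `dnbpipe pipeline --config run.yaml`
chains simulate/load → normalize → DNB → clustering → enrichment → scoring
and writes a manifest with checksums so identical configs reproduce
identical outputs.

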