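# riboprof

Ribosome-profiling (Ribo-seq) translatome analysis for developing plant
seeds — and any other bulk Ribo-seq + RNA-seq study — exercised end to
end on synthetic data with known ground truth.

Ribo-seq sequences the ~28–34 nt mRNA fragments protected by translating
ribosomes. Each footprint's P-site localises the decoded codon, so
footprints carry a reading-frame signature (three-nucleotide
periodicity) that distinguishes genuine translation from background.
Combining footprint density with matched RNA-seq yields translational
efficiency (TE), and scanning untranslated regions for ribosome-occupied
small ORFs reveals upstream ORFs (uORFs) that repress downstream
translation. This package implements that full analysis chain:

* **Footprint QC** (`riboqc`) — read-length spectrum, P-site offset
  inference, metagene profiles around start/stop codons, frame
  fractions, and 5'UTR/CDS/3'UTR read partitioning.
* **Small-ORF discovery** (`orf_discovery`) — every `ATG…stop` in the
  5'UTR (uORF) or 3'UTR (dORF), with reinitiation-distance and
  Kozak-flank features.
* **Coding-potential calling** (`coding_potential`) — four statistics
  per candidate ORF, thresholded at the 95th percentile of a null set
  (an ORF is called translated when all four exceed their thresholds):
  - ORFscore: with frame counts $(F_0,F_1,F_2)$ and $M=\sum F_i/3$,
    $\mathrm{ORFscore} = \log_2\!\big(1+\sum_i (F_i-M)^2/M\big)$,
    negated when frame 0 is not the unique maximum;
  - ribosome release score
    $\mathrm{RRS} = \frac{(R_\mathrm{in}+1)/(R_\mathrm{down}+1)}{(N_\mathrm{in}+1)/(N_\mathrm{down}+1)}$
    for footprint ($R$) and RNA ($N$) counts inside the ORF vs a
    length-matched window after its stop;
  - Fickett TESTCODE (codon-position asymmetry + composition via the
    published lookup tables);
  - hexamer score: mean $\ln f_c(h)/f_{nc}(h)$ over in-frame hexamers.
* **Expression and TE** (`expression_te`) — FPKM, TE = RPF-FPKM /
  RNA-FPKM, Welch-t differential tests with Benjamini–Hochberg FDR,
  the nine-quadrant (transcription × translation) classification, and
  the qPCR $2^{-\Delta\Delta Ct}$ helper.
* **uORF features** (`uorf_features`) — length spectrum, rank-sum
  comparison of normalized uORF→CDS distances, per-position chi-squared
  Kozak-context tests, flanking GC profiles, cumulative TE curves.
* **TF co-expression network** (`coexpress_network`) — Pearson edges
  kept at r > 0.7 and P < 0.05.
* **Synthetic data** (`synthetic_data`) — a generative model of the
  whole study (transcript structures, Kozak-dependent uORF translation,
  32–33 nt footprint lengths, ~87% CDS share, 90% in-frame P-sites,
  log-normal TE, two conditions with replicates and planted
  fold-changes) whose truth tables let every stage be scored.

## Worked example

The numbered scripts under `analysis/` run the study step by step and
write their tables under `results/run/`:

```bash
python analysis/01_simulate_study.py
python analysis/02_footprint_qc.py
python analysis/03_orf_discovery_and_calling.py
python analysis/04_expression_quadrants.py
python analysis/05_uorf_features.py
python analysis/06_tf_network.py
```

Output of the first three steps (seed 42):

```
simulated study written to results/run
  transcripts: 300
  planted uORFs: 109 (64 translated)
modal footprint length: 32 nt
frame-0 fraction (periodicity): 0.900
CDS footprint share: 0.871
category
dORF    413
mORF    300
uORF    109
translated-uORF calling: sensitivity 0.922, false-positive rate 0.000
```

The library peaks at 32 nt with 90% of CDS P-sites in the annotated
frame and 87% of footprints inside coding regions — the hallmarks of a
clean Ribo-seq library. All 109 planted uORFs are re-discovered from
sequence, and the four-score percentile rule recovers 92% of the truly
translated ones without false positives. Step 4 prints the differential
counts per layer and the nine-quadrant occupancy (most genes in quadrant
E, unchanged at both layers; concordantly up-regulated genes in C);
step 5 reports that genes with a translated uORF have lower TE, that
translated uORFs sit closer to the main start codon, and that guanine at
Kozak position +4 is enriched in translated uORFs; step 6 recovers all
10 planted co-expressed regulators with 2.5% false edges.

The same pipeline is available as one command:

```bash
riboprof run-all --out run --seed 42
```

and each stage separately (`riboprof simulate|qc|orfs|score|te|quadrant|
features|network`), configured by a YAML file (`--config`).

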