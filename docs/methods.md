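# Methods

## Coordinate conventions

All analysis happens in transcript space: 0-based, half-open intervals
on the mature (spliced, strand-resolved) transcript. `cds_start` is the
A of the annotated start codon and `cds_end` one past the stop codon. A
P-site position is the first nucleotide of the decoded codon, so the
reading frame of a footprint relative to any ORF is
`(position − orf_start) mod 3` with no further offsets. When raw
records carry footprint 5' ends instead of P-sites,
`riboqc.infer_psite_offsets` estimates one offset per read length as the
argmax over 8–20 nt of 5'-end pile-ups upstream of annotated start
codons (ties toward the smaller offset; lengths with fewer than 50 reads
fall back to the pooled offset). One transcript is kept per gene
(longest CDS); CDS lengths not divisible by three are skipped with a
warning.

## The synthetic study

The generator emulates a two-timepoint, three-replicate Ribo-seq +
RNA-seq experiment on a toy genome (1–2-exon genes on both strands, so
the GFF3/FASTA reader is exercised on real splicing and
strand-resolution work). Per transcript:

* geometry: 5'UTR 90–300 nt, CDS 60–400 codons, 3'UTR 60–240 nt;
* abundance `2^N(0,1)`, TE `2^N(0, te_log2_sd)` (default sd 1);
* condition effects: 20% of genes get a ±2 log2 transcription effect,
  an independent 20% a ±2 log2 translation-efficiency effect;
* RNA fragments: Poisson totals (`mean_depth` × abundance), uniform
  positions. Counts are Poisson rather than negative binomial: it is
  the simplest generative model that exercises every estimator, and an
  overdispersed variant can be layered on by mixing the per-replicate
  means.
* footprints: Poisson totals (`mean_depth` × abundance × TE), placed
  in the CDS with probability `cds_read_share` (default 0.87, the CDS
  fraction a clean library shows), in frame 0 with probability
  `in_frame_fraction` (default 0.9), with 8% of frame-0 reads on the
  start codon to create the initiation peak. Read lengths are drawn
  from a distribution peaked at 32–33 nt, the predominant footprint
  size in plant seeds.

uORFs are planted in 35% of 5'UTRs (one, sometimes two). The
9.67%-style rates reported from real data are detection outcomes, not
generative rates; 35% reflects how commonly plant 5'UTRs contain an
ATG and gives the recovery analyses usable group sizes. Planted
lengths are 60–150 nt — real uORF length spectra concentrate in the
60–460 nt band with ~80% below 160 nt, truncated here so uORFs fit the
simulated UTRs. The 5'UTR is scrubbed of all other ATGs (any frame), so
the truth table is by construction the complete set of upstream ORFs;
3'UTRs are left unscrubbed and their spontaneous ORFs serve as dORF
candidates and as the ribosome-evidence null.

Translation of a uORF is decided by its Kozak context: a strong context
(A/G at −3 and G at +4) multiplies the base translation probability
(default 0.5) by `kozak_strong_boost` (default 2, capped at 0.95). This
plants the +4 G enrichment among translated uORFs that the position
tests must find. Translated uORFs:

* are written with the same position-biased codon model as annotated
  CDSs (untranslated uORFs get uniform codons). Sequence-composition
  scores can only separate the groups if translated small ORFs actually
  look coding-like — which is the premise of applying
  Fickett/hexamer-style statistics to them;
* receive a Gamma(3, 0.5) occupancy (mean 1.5, little mass near zero:
  "translated" in the truth table means firmly occupied), doubled for
  strong Kozak contexts, drawing up to half the transcript's UTR
  footprint mass in their own frame;
* sit closer to the main ORF: normalized stop→ATG distances are drawn
  U(0.10, 0.90) for translated vs U(0.30, 1.10) clipped to [0, 1] for
  untranslated uORFs (a ~0.2 shift). The floor at 0.10 also reflects
  that a stop codon abutting the main ATG leaves no release window for
  the RRS;
* halve the gene's TE (`uorf_te_penalty` = 0.5), the repression the
  cumulative TE curves must detect.

With the seed fixed, generation and simulation are bit-reproducible;
`run-all` twice with one seed produces byte-identical outputs.

### What the generator does not emulate

No sequencing error, no adapter or rRNA contamination, no mappability
or multi-mapping structure, no isoforms, no overdispersion beyond
Poisson, no codon-level pausing, and uORF/mORF footprints are additive
on shared coordinates. Passing recovery tests therefore show the
statistics and thresholds behave correctly under the stated generative
assumptions — not that the pipeline is robust to alignment artifacts or
biological overdispersion in real libraries.

## Scoring and calling

Candidate ORFs are every ATG…in-frame-stop in a UTR, at least 9 nt
(ATG + one codon + stop). uORFs whose stop falls beyond the annotated
start are excluded by default (`overlap_policy="clip"` keeps them with
distance 0), keeping uORF/mORF footprint assignment unambiguous.

Each candidate receives four statistics (ORFscore, RRS, Fickett,
hexamer; formulas in the README). Details:

* RRS uses +1 pseudocounts throughout and a length-matched downstream
  window truncated at the end of the host region.
* The Fickett implementation transcribes the published TESTCODE lookup
  tables; note the position parameter max/(min+1) makes the score only
  asymptotically length-invariant (a sequence and its doubled copy can
  differ by one table bin).
* The hexamer table is trained on the annotated CDSs vs their
  per-sequence nucleotide shuffles, +1 smoothing over all 4096
  hexamers, natural log. The score's base only rescales it; thresholds
  are percentile-based, so calls are base-invariant.

Thresholds are the 95th percentile of a null set per score, computed
with the exclusive-step percentile (numpy `method="higher"`), so
"strictly above threshold" means "in the top 5% of the null". The null
populations are: dORF candidates for ORFscore and RRS (they lack
initiation under the generative model), and per-CDS nucleotide shuffles
for Fickett and hexamer. The sequence-score null deliberately uses
CDS-length shuffles rather than shuffles of the small candidates
themselves: both statistics are strongly length-noisy below ~20 codons
(tiny counts inflate max/(min+1) and the per-hexamer mean), and a null
dominated by 9–21 nt spurious dORFs would put the 95th percentile above
what genuinely coding-like sequence reaches. An ORF is called
translated when **all four** scores exceed their thresholds (an `any`
rule is available).

## Differential analysis and quadrants

Differential testing is a Welch t-test on log2(FPKM + 1) (log2 TE for
the TE layer, log2 abundance for protein) with Benjamini–Hochberg
correction per layer; the protein layer is judged on raw p (its source
convention), others on FDR. Two fold-change conventions coexist
deliberately: DEG lists use fold-change ≥ 1.5, the quadrant grid uses
|log2FC| ≥ 1 — both are kept as separate, layer-scoped defaults.
Boundary handling: |log2FC| exactly at the cut counts as changed; FDR
exactly at alpha does not. The quadrant letter grid (transcription
state, translation state) is A=(down,up), B=(ns,up), C=(up,up),
D=(down,ns), E=(ns,ns), F=(up,ns), G=(down,down), H=(ns,down),
I=(up,down); only C and E are fixed by the nine-quadrant convention,
the rest is this package's declared layout.

The pipeline computes FPKM for differential comparisons with
median-of-ratios effective library sizes (DESeq-style size factors):
with a fifth of genes planted at 4-fold effects, raw column totals are
compositionally biased and shift every unchanged gene's log2FC. The
`fpkm` primitive itself keeps the plain definition
count / (kb × millions mapped).

TE is the FPKM ratio (footprints over mRNA) per condition/replicate
pair; genes with zero RNA FPKM are excluded with a log entry. An
interaction-term formulation would need a count model and is out of
scope.

## Feature statistics

The distance comparison uses a two-sided Wilcoxon rank-sum test —
distribution-free and appropriate for skewed, bounded distances; the
implementation enumerates all C(n1+n2, n1) assignments exactly
(tie-correct) when n1+n2 ≤ 16 and uses the tie-corrected normal
approximation above that. Kozak-position tests are per-position 2×4
(group × base) Pearson chi-squared without continuity correction, N
bases excluded, positions +1..+3 (the ATG itself) skipped; position
numbering follows the Kozak convention (A of ATG = +1, no zero).
Testing windows default to −6..+5 and the GC profile to ±25 nt — the
conventional choices, as no standard window exists. Cumulative TE
curves drop genes with TE ≤ 0.5 first (low-TE genes are
quantification-noise dominated) and compare groups by rank-sum.

## Network

Edges are Pearson correlations across samples with the t-transform
p-value (n−2 df); the default rule is the literal signed r > 0.7 with
raw P < 0.05 (an `absolute` flag and a BH option exist but are off).
RNA FPKM is the default correlated layer. Zero-variance genes are
skipped with a warning; at least 3 samples are required.

## Numerical choices and degenerate inputs

* ORFscore of an all-zero frame triple is 0; zero-footprint ORFs are
  scored (ORFscore 0, RRS = pseudocount ratio) and flagged
  low-coverage rather than dropped.
* Zero variance in both groups of a t-test: p = 1 for equal means,
  p = 0 otherwise.
* Offset inference ties break toward the smaller offset; metagene
  windows clip at transcript bounds.
* Empty inputs return empty, typed outputs with warnings (length
  histograms, profiles); contract violations (negative counts,
  positions beyond the transcript, unknown config keys) raise.

## Problem sizes

The default study is 300 transcripts at mean depth 500 with 2×3
replicate libraries (~1.6M footprints); group comparisons that need
≥200 uORFs per arm use 1200 transcripts with uORF probability 0.6.
These sizes give every recovery statistic a stable estimate while a
full test-plus-acceptance run completes in a few minutes on one core.

## Known limitations

Single isoform per gene; ATG-only starts by default (near-cognate
starts are a flag on the discovery scan, off by default); no pause-site
detection; no enrichment analysis against live pathway databases; the
protein layer is consumed as a pre-quantified table only. The Fickett
tables are fixed published constants, not retrained; the hexamer model
is study-internal. Real-data DEG calling would use a count-based model
(the test is pluggable behind `expression_te.differential`).
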