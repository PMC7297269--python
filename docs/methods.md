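# Methods

## Model

`lncm6a` predicts whether a candidate adenosine — the central A of a
DRACH 5-mer on a transcript — carries N6-methyladenosine.  The classifier
is a random forest over a 144-value encoding of the site, and the final
lncRNA probability is an affine blend of two forests:

    P_en = α · P_m + (1 − α) · P_lnc,   α ∈ [0, 1]

where `P_lnc` comes from a forest trained on lncRNA sites and `P_m` from
one trained on the far more abundant mRNA sites.  The blend exists
because base-resolution lncRNA methylation data are scarce (few thousand
sites) while mRNA data are plentiful but distribution-shifted; α trades
the variance of the small matched model against the bias of the large
mismatched one.  α is selected from the 11-point grid {0, 0.1, …, 1} by
maximizing ROC AUC on a validation subset (default 20 %) carved from the
lncRNA *training* split; ties go to the smaller α.  Selecting α on the
test set would leak information, so the package never does, even though
the grid always contains both endpoints and the selected blend therefore
never trails either single model on its selection set by construction.

### Sequence block (84 values)

Each base of the 21-nt window centered on the candidate A contributes
four values: the chemical triple x (purine), y (amino group), z (weak
hydrogen bonding) — A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1), a
bijection — and the cumulative frequency f_i = d_i/i of that base among
window positions 1..i.  Frequencies are computed within the 21-nt window,
not the whole transcript: the window is the model's context unit, and
window-local frequencies are invariant to where the window sits on the
transcript.  Windows overrunning a transcript end are padded with `N`,
encoded (0,0,0,0); pad positions keep their positional denominator so
real bases encode identically whether or not pads precede them.

### Genomic block (60 values, frozen catalog)

| indices | group | definition |
|---|---|---|
| 1–10 | region dummies | exon, intron, first/internal/last exon, 5′-/3′-half of the transcript, within 100 nt of transcript start/end, containing exon ≥ 400 nt |
| 11–12 | splice distances | nt to nearest 5′/3′ junction in the active coordinate mode, capped at 2000 (`dist_sj_5_p2000`, `dist_sj_3_p2000`) |
| 13–14 | lengths | log2 length of the containing exon/intron and of the mature transcript |
| 15–32 | motif | one-hot identity of the DRACH 5-mer, lexicographic order |
| 33–36 | clustering | counts of other DRACH candidates within ±50/±500/±2000 nt, and distance to the nearest one capped at 2000 |
| 37–40 | conservation | mean of each score track over the 21-nt window (two PhastCons-role, two fitCons-role tracks); missing bases impute 0 |
| 41–42 | structure | site base paired (0/1) and paired fraction of the 101-nt window |
| 43–55 | overlaps | 13 configurable interval tracks for m6A-biology annotations (registry defaults to empty tracks `slot_43..slot_55`) |
| 56 | miRNA target | the site's gene overlaps a miRNA-target interval |
| 57–60 | z-scores | isoform count, exon count, gene GC, local GC of the 101-nt window |

Features are computed on the longest mature isoform of each gene
(ties broken by smallest transcript id), which removes isoform ambiguity.
Sites mappable to more than one same-strand gene are excluded from
datasets.  Two coordinate modes exist: *full transcript* (positions on
the unspliced pre-RNA; distances measured on pre-mRNA coordinates,
introns included) and *mature RNA* (spliced positions; intronic sites
have no image and are dropped).  All distance and length features of a
dataset use a single mode.

z-scores use the population (n-denominator) standard deviation over the
dataset's genes (local GC: over the dataset's sites); sd = 0 maps to
z = 0.  The population convention is frozen for reproducibility — the
standardized block has mean 0 and sd exactly 1 over the fitting
population.

### Secondary structure

The two structure descriptors come from a dot-bracket string for the
101-nt window: either precomputed structures supplied by the user
(`key = transcript_id:window_start`) or the package's built-in
maximum-base-pairing dynamic program (Watson–Crick + GU wobble, hairpin
loops ≥ 3 nt, deterministic 5′-most traceback).  Maximum pairing is a
deliberately coarse thermodynamic surrogate: the downstream features are
only "is the site base paired" and "what fraction of the window pairs",
for which pairing topology, not free energy, is what matters.  The DP is
numba-compiled (cubic in window length) and guarded at 200 nt; longer
windows must come from precomputed files.

### Dataset construction

Positives: sites called in at least `min_support` (default 2) replicate
base-resolution experiments, restricted to genomic DRACH adenosines and
single-gene transcripts.  Negatives: a uniform, seeded sample of equal
size from the non-called DRACH adenosines on the transcripts that carry
positives — "non-called" excludes sites appearing in even a single
replicate (configurable, `exclude_any_called`), the conservative reading
of a negative pool.  The split is stratified 4:1 train:test.  The
mature-mode dataset filters the full-mode positives to exonic positions,
re-projects them to spliced coordinates, and re-samples matched
negatives from the exonic pool, so both modes stay balanced.

### Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, and Matthews
correlation (0 when a marginal is empty) at a strict probability
threshold — a site scoring exactly 0.5 is called negative.  AUC is the
rank (Mann–Whitney) statistic, identical to trapezoidal integration of
the returned ROC points; ties receive half credit.

### Feature selection

Features are ranked by their single-feature k-fold (default 10)
cross-validated AUC — a classifier-agnostic importance measure — with
ties broken by catalog order; forward search then evaluates every prefix
of the ranking and keeps the shortest prefix attaining the maximum CV
AUC.  Cross-validation is stratified whenever k fits within the minority
class, plain otherwise (which makes leave-one-out usable); per-fold AUC
is undefined (None) for single-class folds while pooled out-of-fold
metrics always exist.

## Synthetic data generator

`lncm6a.simulate` emulates the statistical structure of replicate
base-resolution m6A experiments on a two-class gene set:

* **architecture** — lncRNA-like genes (2–3 exons of 400–1600 nt, GC ≈
  0.45) and mRNA-like genes (5–9 exons of 150–450 nt, GC ≈ 0.52) laid
  along one chromosome with intergenic gaps; ~30 % of multi-exon genes
  get a shorter second isoform so the isoform-count z-score varies.
* **planted truth** — positives are drawn from each class's DRACH
  candidates with weight `w(motif) · exp(b₃′ (relpos − ½)) ·
  exp(b_gc (gc₁₀₁ − ½)·2)`: a motif preference (default 4:1 for the three
  GGAC-core 5-mers, reflecting the canonical GGACU bias; an independent
  preference can be set for the mRNA class), a 3′-end positional
  enrichment (default strength 1.0, the stop-codon-proximal bias of real
  m6A), and a GC-context weight (default 0.5) standing in for structure
  preference.  Conservation tracks are beta-noise baselines elevated by
  +0.25 (half that for the fitCons-role tracks) over each positive's
  21-nt window.
* **replicates** — each of 6 call sets is the truth minus independent
  dropouts (default rate 0.15) plus false calls at random non-truth DRACH
  positions (default 5 % of the truth size).  With dropout d, consensus
  at support 2 recovers a site with probability P(Bin(6, 1−d) ≥ 2), a
  property the tests check against the binomial tail.
* **defaults** — 2,000 positives per RNA class with 150 genes per class;
  `FixtureConfig.null()` zeroes every effect size, making features
  label-independent.  `mimic_paper_scale()` reproduces the published
  scarce-lncRNA regime (≈1,291 lncRNA positives, a >20× larger mRNA set)
  with a `scale` argument for proportionally smaller designs; the
  ensemble-ordering simulation in the test suite runs at reduced scale
  and 250 sites per class, a size at which the effect is already
  unambiguous.

What the generator does **not** emulate: read-level antibody chemistry,
peak-shaped (≈100 nt) MeRIP evidence, sequencing depth variation,
chromosome-scale synteny, real conservation autocorrelation, or true
thermodynamic structure.  Passing tests therefore demonstrate that the
pipeline recovers signal of the planted kinds at realistic sizes and
stays at chance under the null — not that real-genome AUCs would match;
published headline numbers depend on six real cell-line datasets that are
out of scope here.

## Numerical and design choices

* Genomic coordinates are 1-based inclusive internally (GTF convention);
  all BED/bedGraph I/O is 0-based half-open.
* Splice-junction convention: the junction between transcript positions
  j|j+1 is addressed by j; the 5′ distance is site − j over junctions
  before the site, the 3′ distance j − site over junctions at or after
  it.
* Conservation windows in mature mode are projected base-by-base to the
  genome, so they may straddle introns on the genome side; missing track
  values impute 0 and are counted in the log.
* Window centering: the 21-nt window centers on the methylated A (motif
  position 3), 10 nt per flank.
* DNA input (T) is accepted everywhere and read as U; `N` is legal only
  as boundary padding.
* Random-forest defaults: 500 trees, √p features per split, fixed seed;
  alternative classifiers plug in through the trainer callable accepted
  by every cross-validation entry point.
* Model archives store the feature-catalog hash and refuse to predict
  when the incoming catalog differs.
* One integer seed drives each workflow; the generator derives named
  child seeds deterministically, so equal configurations yield
  byte-identical files.

## Known limitations

* The 13 overlap tracks (43–55) and the two conservation track pairs are
  structural slots: the computation is generic interval overlap / window
  mean, and real analyses must supply the concrete BED/bedGraph inputs.
* The built-in folder maximizes pair count, not free energy; its two
  descriptors are coarse by design.
* Cumulative frequencies are window-local; an alternative reading
  (transcript-global) would change feature values but not the encoder's
  contract.
* `load_fixture_dir` restores data files, not the generating
  configuration.
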