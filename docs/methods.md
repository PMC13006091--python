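# Methods

## Problem setting

Genomic prediction estimates a quantitative phenotype from genome-wide SNP
dosages (0/1/2, the count of the second allele at a biallelic marker). The
regime is p ≫ n: tens of thousands of markers against hundreds-to-thousands
of individuals, where flexible models overfit unless they are given a
structural prior. This package implements a dual-pathway vision-transformer
predictor that injects the VanRaden genomic relationship matrix (GRM) — the
standard marker-derived kinship estimate — as that prior, together with the
quality-control, locus-selection and evaluation machinery around it.

## Pipeline

1. **QC** (`genotype_io`). Markers survive iff call rate > 0.95,
   MAF > 0.01 and the exact Hardy-Weinberg test p-value > 1e-6 (all strict).
   The HWE test enumerates every heterozygote count consistent with the
   observed allele totals via the standard probability recurrence and sums
   the probabilities of configurations no more likely than the observed one;
   monomorphic markers return p = 1. An exact test, rather than χ², keeps
   small fixtures exact and matches common chip-QC tooling.

2. **GRM** (`grm`). G = M\*M\*′ / (2 Σ p_j(1−p_j)) with M\* the dosage
   matrix centered by 2p_j, p_j the second-allele frequency over non-missing
   calls. Missing dosages are filled with 2p_j before centering so they
   contribute exactly zero (the standard VanRaden treatment). Frequencies are
   always estimated on an explicit reference cohort; held-out individuals
   appear only through their relationship vectors G_eval×train and never
   touch frequency estimation — any train/eval overlap is a hard error, not
   a warning. The GRM is computed on the full post-QC panel, not the
   selected subset.

3. **Locus selection** (`locus_selection`). The default selector fits a
   LightGBM regressor on raw dosages (500 trees, 31 leaves, learning rate
   0.05, feature and bagging fractions 0.8, fixed seed, deterministic
   single-thread mode) and keeps every marker whose split-gain importance is
   positive; k is whatever that count turns out to be. `min_child_samples`
   is set to 5, below the LightGBM default, so the selector still splits on
   desk-scale cohorts. Two baselines take the same k (the fixed-k contract):
   linear-kernel SVR ranked by |coefficient| (ties to the smaller index) and
   univariate GWAS (per-marker simple regression, two-sided slope t-test,
   constant markers p = 1) after greedy LD pruning (200 kb window, step 1,
   r² > 0.5 removes the lower-MAF member; ties remove the later marker).
   GWAS runs without structure correction. Selected sets are returned in
   genomic order because patching and attention mapping operate on the
   ordered sequence. Selectors reject samples outside the declared fold.

4. **Tokenization** (`tokenization`). The selected sequence of length L is
   cut into a fixed number of patches N_p (default 400; desk-scale runs use
   50) with patch size P = ⌈L/N_p⌉ and a zero-padded final patch; each patch
   is flattened through one shared linear map to a D-dimensional token and a
   learned [CLS] token is prepended. Fixed patch *count* (not size) keeps the
   sequence length — and hence compute shape — constant across panels. When
   L < N_p the trailing patches are all-padding and are retained so S is
   constant across folds. Variants: FPE patches the full unselected panel;
   SIE maps each selected marker's scalar dosage through a shared 1→D map.
   Before embedding, dosages are mean-filled with the training fold's 2p_j
   and z-scored per marker by training-fold statistics (sd 0 → 1 guard).

5. **Model** (`model`). Pre-LN transformer blocks: x′ = x + MHSA(LN(x)),
   x₊ = x′ + FFN(LN(x′)), with a learnable per-head relative positional bias
   added to the attention logits (table indexed by k−j; [CLS] occupies
   position 0 of the same scheme; zero-initialized). The GRM pathway maps an
   individual's relationship vector through affine → GELU → affine into
   m_g tokens, each layer-normalized. Cross-attention fusion sits between
   L_pre and L_post encoder blocks: queries from LN(SNP tokens), keys/values
   from the GRM tokens, no positional term, wrapped in residual + Pre-LN
   FFN. With the default m_g = 1 the softmax over a single key degenerates
   to a uniform additive injection — documented, not hidden; m_g > 1 is
   available. The regression head is affine(D→D/2) → GELU → dropout →
   affine(→1) on the [CLS] state. GELU everywhere is the tanh approximation
   0.5x(1 + tanh(√(2/π)(x + 0.044715x³))).

   Variants for ablation: `gvit_base` (no fusion), `grm_mlp` (GRM pathway →
   head, tokens ignored), `gvit_concat` ([CLS] ⊕ flattened GRM pathway →
   widened head).

   Defaults where the architecture leaves them open: D = 128, 8 heads,
   L_pre = L_post = 2, ffn_mult = 4, grm_hidden = 512, dropout = 0.1,
   weights N(0, 0.02²), zero biases.

6. **Training & evaluation** (`train_eval`). Seeded 80/20 hold-out plus
   5 disjoint validation folds of the 80%. Per fold: locus selection,
   GRM features, dosage scalers and phenotype z-scoring all from the fold's
   training partition only; AdamW (defaults lr 1e-4, weight decay 0.01,
   batch 64, up to 300 epochs) with cosine-annealed learning rate and early
   stopping on validation MSE (patience 20), best weights restored. After
   the folds, the selector and model are refit on the 80% split minus one
   carved-out validation fold that monitors early stopping (the test set is
   never touched), and the test cohort is scored once. Metrics: Pearson r
   (0 by convention when either side is constant, flagged), R² = 1 −
   SS_res/SS_tot (may be negative), MSE on the standardized scale.
   A GBLUP-style kernel-ridge baseline on the GRM (lambda by inner CV)
   provides a linear reference on synthetic data. Significance of a test
   correlation is assessed with a phenotype-shuffling permutation null.

7. **Interpretability** (`interpret`). The [CLS] row of a chosen
   self-attention layer (default: last post-fusion layer), averaged over
   heads and the evaluation cohort, is mapped back to coordinates: each
   non-padding patch gets the majority chromosome and median bp of its
   member markers. The [CLS]→[CLS] weight is dropped without renormalizing,
   so patch scores plus that weight sum to 1. The significance line is
   mean + 3 sd of patch scores (configurable); layer/head aggregation are
   flags because no single convention is canonical.

## Numerical engine

The network and training loop run on a compact reverse-mode automatic
differentiation engine over numpy (`autodiff`): broadcast-aware arithmetic,
flat-gemm affine maps, batched matmul for attention, primitive softmax /
layer-norm / GELU backward rules, gather for the relative-bias table, AdamW
and the cosine schedule. Default dtype is float32 for memory-bandwidth
efficiency; gradient-check tests switch to float64 and verify every
primitive against central finite differences. Everything is single-threaded
numpy, so a fixed seed reproduces metrics bit-for-bit.

## Synthetic populations

The simulator (`synthetic_data`) generates what the architecture needs to be
testable: founders drawn per marker from Binomial(2, p_j), p_j ~
U(maf_range); local LD from a first-order Markov copying process along each
chromosome (copy probability `ld_rho`, reset at chromosome boundaries) —
enough to make patches locally redundant without the cost of coalescent
simulation; within-family kinship by gene-dropping (offspring inherit one
recombination-free chromosome copy per parent); phenotypes from a minority
of causal loci with additive effects plus centered-product epistatic pairs,
the genetic and noise components rescaled to a target heritability h², and
the phenotype standardized to mean 0 / variance 1. Uniform missingness and
optional appended QC-failing columns complete the picture.

Default conditions: 40 families × (2 founders + 8 offspring) = 400 samples,
2000 markers on 10 chromosomes, ld_rho 0.3, MAF U(0.05, 0.5), 20 additive
causal loci + 5 epistatic pairs, h² 0.7, 2% missingness. The heavier
evaluation scenarios use 80 families (n = 800).

What the simulator does **not** emulate: realistic recombination maps,
selection and drift, allele-frequency spectra from real chips, genotyping
error structure, multi-allelic sites. Passing tests therefore demonstrate
the machinery's correctness and its ability to exploit kinship and sparse
causal signal — not calibrated performance on real breeding panels.

## Desk-scale choices

The property suite and the acceptance script run the heavy scenarios at
n = 800, p = 2000, h² = 0.7 with N_p = 50, D = 64, 8 heads, 2+2 encoder
blocks, ffn_mult 2, grm_hidden 128, and a short schedule (lr 3e-4, batch 64,
≤ 15 epochs, patience 4). These sizes are the package's own choice of a
configuration a single CPU core trains in minutes while leaving the
qualitative structure intact: the GRM-fused model clearly beats the
permutation null, and the fusion ablation reproduces the expected ordering
(gvit_gp ≥ gvit_base). Under this short schedule the pure-token baseline
(`gvit_base`) is far from converged, so the gap overstates what a fully
trained baseline would show; the ordering, not the gap, is the stable
finding.

## Degenerate inputs and tie rules

* All-missing marker within a cohort → explicit undefined-marker error.
* Monomorphic reference panel → degenerate-panel error (VanRaden
  denominator 0); individual monomorphic markers contribute exactly zero.
* Constant dosage in GWAS → p = 1; constant predictions → r = 0, flagged.
* |coefficient| ties in SVR selection → smaller marker index wins;
  equal-MAF LD pairs → the later-position marker is removed.
* LN epsilon 1e-5; constant-marker sd guard 1.0; head hidden width
  max(1, head_in // 2).

## Known limitations

* The two-stage design (selector, then model) inherits LightGBM's bias
  toward main effects; loci that matter only inside interactions can be
  filtered before the transformer sees them.
* m_g = 1 makes cross-attention a uniform injection; the dynamic,
  per-token weighting the mechanism promises only materializes with
  m_g > 1.
* The GRM pathway's input width is the training-cohort size, so a trained
  model only scores individuals against that same reference cohort.
* Pure-numpy training is practical at desk scale only; real-panel scale
  (tens of thousands of markers kept, hundreds of epochs) needs a GPU
  framework.
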