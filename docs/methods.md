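# Methods

This note documents the statistical models and design choices behind
`ccanet`: what the synthetic generators emulate, how the canonical
correlation integration is computed, the conventions adopted where the
underlying study protocol leaves details open, and what the test suite does
and does not establish about real data.

## Study design being modelled

The package targets elicitor time-course experiments on hairy-root
cultures: tissue is treated with methyl jasmonate (MeJA) and harvested at
0, 1, 3, 6, 12 and 24 h with three biological replicates. Transcript
abundances (RNA-seq-quantified, already normalised) are measured for a
panel of ~112 AP2/ERF transcription factors and 8 phenylpropanoid/lignan
pathway genes (PAL, C4H, 4CL, C3H, CCR, CAD, DIR, PLR); four lignan
metabolites (coniferin, lariciresinol, secoisolariciresinol, pinoresinol)
are quantified in the same cultures. The 0 h samples are the control for
all fold changes and the calibrator for qPCR.

Samples enter the integration as 18 separate columns (6 timepoints × 3
replicates) on a shared grid; a timepoint-means layout (n = 6) is available
for sensitivity analysis but is not the default, since discarding replicate
variation with so few timepoints leaves the CCA ill-posed.

## Synthetic data

### Induction time courses

Each gene's noise-free profile is piecewise log-linear through
(0 h, baseline) and (peak time, baseline × peak fold) — the simplest
unimodal shape consistent with gradual induction. After the peak the
ln-fold relaxes linearly to 30% of its peak value at 24 h, keeping
up-regulated genes strictly above baseline (and down-regulated strictly
below) at every post-treatment timepoint. `mixed` genes instead decay
through zero to the reciprocal fold at 24 h, so they are up early and down
late; this requires their peak to precede the final timepoint.
`undetectable` genes carry missing values (NaN, not zero) at a seeded
non-empty subset of post-treatment timepoints — downstream they are
*excluded*, mirroring how heatmaps gray out undetectable signals.

Defaults encode the study conditions: pathway-gene peak folds 2.7 (PAL,
PLR), 3.0 (4CL), 3.9 (C4H), 11.5 (C3H), 4.9 (CAD), 6.0 (CCR), 6.1 (DIR),
peaking at 6 h except 4CL and PLR at 12 h; the TF panel splits 13 up / 30
down / 42 mixed / 27 undetectable, with up-regulated peak folds spanning
2–8.2 and down-regulated 1/2–1/6.5 (the strongest reported TF responses).
Noise is multiplicative log-normal with a given coefficient of variation
(default 0.2 in the pipeline; 0 for exact round-trip checks) and mean one,
so expectations stay on the planted curve; a multiplicative model was
chosen because abundance data are positive and the analysis is
ratio-scaled throughout.

The metabolite time grid matches the expression grid (0–24 h). Later
metabolite-only harvest points that a wet-lab protocol may include cannot
enter a CCA, which needs matched samples, so they are not simulated.

### Latent-factor metabolite coupling

Metabolites couple to transcripts through a single latent induction factor:

- z = standardized linear combination (weights w) of the coupled genes'
  z-scored ln abundances — z lies exactly in the span of the gene block;
- metabolite k = b_k · z + s · ε_k with ε_k independent standard normal.

Because all cross-block dependence flows through z, the population first
canonical correlation is ρ₁ = ‖b‖ / √(‖b‖² + s²) in closed form, and the
population correlation between coupled gene j and metabolite k is
a_j · b_k / √(b_k² + s²) with a_j = corr(ln x_j, z). Setting `target_rho1`
rescales b to plant any requested ρ₁; this is a rank-1 cross-covariance
construction (Σxy = a bᵀ) whose ρ₁ the tests independently re-derive by
whitened-SVD of the assembled joint covariance. With a single coupled gene
a = 1 exactly, which is how tests plant exact pairwise correlations.

### Protein sets, Ct tables

Planted AP2/ERF architectures follow the family definitions (below);
duplicate pairs are made by copying a sequence and mutating
round((1 − identity) · L) positions, which lands within one percentage
point of the target identity. Decoy proteins carry no AP2 domain and each
fails one of the three homology filters in rotation. Ct tables are the
exact inverse image of the expression matrix under the comparative-Ct map
(Ct = const − log_E abundance, reference gene constant), so ddCt
back-transformation reproduces fold changes to machine precision in
noise-free mode.

## AP2/ERF catalogue

- **Homology filtering:** keep hits with E ≤ 1e−5, bit score ≥ 100 and
  alignment length ≥ 100 (the published cutoffs are strict "less than"
  removals, so boundary values survive). The three conditions are
  conjunctive, so their order is immaterial. Alignment length is
  interpreted in the unit of the input table (aa for protein-vs-translated
  searches).
- **Family rules:** ≥2 AP2 domains → AP2; one AP2 + B3 → RAV; flagged →
  Soloist; single AP2 → ERF family, split into DREB vs ERF by the residues
  at AP2-domain positions 14 and 19 (A14 + D19 → DREB, V14 + E19 → ERF) —
  the standard published discriminator for this superfamily; a
  non-matching pair is assigned to the nearer signature, ties to ERF. The
  rule table is configurable.
- **Duplicates:** global alignment (match +1, mismatch −1, linear gap −2;
  the decision statistic is identity, not score, so the exact scheme
  matters little and is configurable). Identity = identical columns /
  total alignment columns, so gaps count against identity and 100 means a
  gap-free exact match. Default threshold 95% identity; where a protocol
  states 90% in its methods and 95% in its results, we follow the results
  and expose both as flags. An all-vs-all E-value table (< 1e−10) can
  additionally gate pairs when provided.
- **Physicochemistry:** molecular weight, Kyte–Doolittle GRAVY and the
  Guruprasad instability index come from Biopython's ProtParam
  implementation; the aliphatic index (mole-% Ala + 2.9·Val + 3.9·(Ile +
  Leu)) is computed directly; pI is the Brent root of Biopython's
  Bjellqvist net-charge curve on (0, 14), converged to |charge| < 1e−6.
  Ambiguous residue codes are rejected rather than guessed.

## Phylogeny

Distances are protein p-distances with pairwise deletion (per pair, only
columns gapped in that pair are excluded); complete deletion is a flag.
p-distance is the default because deletion handling is typically the only
documented choice; distance corrections can be layered on later without
touching the NJ code. Neighbor joining follows Saitou–Nei with the
Q-criterion; ties within 1e−12 break on the lexicographically smallest
cluster-name pair (a cluster is named after its smallest member), making
the topology taxon-order invariant. Negative branch-length estimates are
clamped to zero with the deficit moved to the sibling edge. Bootstrap
support resamples alignment columns with replacement, rebuilds the NJ tree
and counts the fraction of replicates containing each internal bipartition
of the reference tree; the newick writer omits supports ≤ 50% (the usual
figure display rule). NJ is exact on additive matrices to 1e−9, verified
against random generated tree metrics and cross-checked against
scikit-bio's implementation.

## Expression analytics

Fold change = (arithmetic mean abundance at t) / (mean at 0 h); replicate
aggregation by arithmetic mean is the standard for three biological
replicates. Genes missing any timepoint, or with a non-positive control
mean, are flagged *excluded* rather than raising. Regulation calls use
direction only by default (`min_fold` 1.0): *up* requires fold > 1 at
every post-treatment timepoint, *down* < 1 at every one, anything else
*mixed* — this reproduces the usual up/down/mixed trichotomy without
inventing an effect-size threshold; a stricter fold can be requested.

ddCt: technical replicates are averaged on the Ct scale; ΔCt subtracts the
single reference gene per sample, ΔΔCt subtracts the calibrator-condition
mean ΔCt per gene; relative expression = E^(−ΔΔCt) with efficiency E = 2
by default (the comparative-Ct assumption), configurable in (1, 2].
Concordance between platforms is the Pearson correlation of ln fold
changes.

ANOVA + Tukey: one-way ANOVA; only when the omnibus p < α (default 0.01)
is Tukey's HSD computed (scipy's studentized-range implementation), and a
pair is significant when its HSD p < α. The procedure's type-I error —
the rate of reporting any significant pair under a global null — measures
≈0.9% at α = 0.01 with 3 groups of 3, comfortably calibrated.

## CCA integration and networks

`cca_fit` standardizes both blocks and takes the SVD of
Sxx^(−1/2) Sxy Syy^(−1/2). It refuses n ≤ max(p, q) without a ridge; with
ridge r the whitening uses (S + rI)^(−1/2) (default recommendation 1e−3
when needed). Component signs are fixed so each U_i correlates positively
with its largest-|loading| X variable — without a convention, loading
signs are arbitrary and runs are not reproducible. Only the first
canonical pair drives loadings and networks; higher pairs are computed and
reported but unused by default.

With ~18 samples a CCA over a hundred-TF block is singular, so the
pipeline analyses blocks: the 8-gene × 4-metabolite block carries the CCA
proper, and TF associations are scored block-wise (TF–metabolite,
TF–gene). Note that even 8 + 4 variables against 18 samples overfits the
leading sample canonical correlations toward 1; recovery of a planted
population ρ₁ is therefore demonstrated at n ≈ 1000, not at the bench
design size.

The per-pair association score defaults to the direct Pearson correlation
between a gene's and a metabolite's sample profiles — a canonical-variable
loading alone cannot yield one value per *pair* — with two
loading-based alternatives (`cross_loading`, `loading_product`) selectable
for comparison; `cross_loading` by construction assigns each gene one value
repeated across qualifying metabolites. Edges keep pairs with |score| ≥
cutoff (default 0.5), retaining the sign: strong negative regulation is
biologically meaningful even when a study reports only positive retained
values; a signed-only mode reproduces the stricter convention. Regulator
nomination intersects, within each TF family, the TFs holding at least one
edge in each of the two networks, and additionally ranks the top-k TFs per
metabolite/gene by |weight| (ties by id).

## Numerical conventions

Standardization uses the n−1 sample SD and refuses constant columns by
name. Singular correlation blocks raise with an instruction to pass a
ridge. Canonical correlations are clipped to [0, 1] against roundoff.
Identity ties in NJ and score ties in rankings break lexicographically.
All generators are pure functions of (spec, seed); pipeline substreams are
spawned from the single run seed via `numpy.random.SeedSequence`.

## Problem sizes used by the test suite

The suite favours many small, seeded instances: CCA oracle equivalence on
50 random instances with p, q ≤ 3; NJ exactness on 50 random trees of ≤ 8
taxa; planted-ρ₁ recovery over 100 seeds at ~1000 samples; planted-edge
recovery over 200 seeds at the bench design size (18 samples); type-I
calibration over 2000 null ANOVA datasets; bootstrap checks at 50–100
replicates on 8 taxa. These sizes make every claim checkable in seconds
while keeping the estimators in their intended regimes.

## What passing tests do and do not show

The generators plant the *statistical structure* the analysis assumes —
unimodal log-scale induction, a single shared latent factor, log-normal
noise, exact factor-model correlations. Passing tests therefore show that
the estimators recover what the model plants, at the stated sample sizes.
They do not show that real elicitation data satisfy those assumptions:
real time courses have autocorrelated noise, batch structure across
replicates, multiple latent factors and normalisation artefacts, none of
which are simulated. Detection of moderate associations at bench scale is
intrinsically noisy: at n = 18 a pair with population correlation 0.6 is
found at the 0.5 cutoff only ~3 times in 4, a sampling-variance limit no
scorer can evade — network membership near the cutoff should be read
accordingly. The family classifier encodes one published signature rule;
proteins from lineages with divergent signatures will need a custom rule
table.
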