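# Methods

This note documents the models, the synthetic-data generators that stand
in for laboratory inputs, the numerical choices, and the limits of what
the test suite demonstrates.

## Codon models of selection pressure

**Process.** Substitution between sense codons follows the Goldman–Yang
form: zero rate for multi-nucleotide changes, and otherwise
`q_ij = π_j · κ^[ts] · ω^[nonsyn]`, with the matrix scaled so that the
equilibrium mean substitution rate is one — branch lengths are therefore
expected substitutions per codon site. Equilibrium frequencies default
to F3x4 (position-specific nucleotide composition estimated from the
alignment, floored at 10⁻⁶ and renormalized so every sense codon remains
reachable); uniform frequencies are available and used throughout the
simulation batteries so that simulator and estimator share an exactly
known π.

**Model hierarchy.** M0 fits one ω to all sites and branches; the
two-ratio model gives the `#1`-tagged foreground branches their own ω₁;
branch-site Model A mixes four site classes — (0) ω₀ everywhere,
(1) neutral everywhere, (2a) ω₀ background / ω₂ foreground,
(2b) neutral background / ω₂ foreground — with proportions p₀, p₁ and
the remainder split proportionally between 2a and 2b (equally if
p₀ = p₁ = 0). The null of Model A fixes ω₂ = 1; the alternative
constrains ω₂ ≥ 1 so the pair is nested at the boundary. The `np`
bookkeeping counts only ω-distribution parameters (1/2/3/4), matching
the convention of codeml-style reports; κ and branch lengths are
nuisance parameters.

**Likelihood.** Felsenstein pruning over the 61 codon states with
per-node rescaling and site-pattern compression. Transition matrices use
the reversibility of the process: with D = diag(√π), B = DQD⁻¹ is
symmetric, so one `eigh` decomposition serves every branch length.
Correctness is pinned by an exhaustive-enumeration oracle (sum over all
internal-node state combinations) on trees of ≤ 4 taxa × 3 sites; the
acceptance battery requires agreement to |ΔlnL| < 10⁻⁸ over 50 random
parameter draws.

**Optimization.** Bounded L-BFGS-B on log-transformed rates and
branch lengths, softmax-transformed class proportions; bounds
ω ∈ [10⁻⁴, 999], κ ∈ [0.05, 50], branch lengths ∈ [10⁻⁵, 20];
convergence at ftol 10⁻⁸ with optional jittered multi-starts. An ω
estimate reaching the upper bound is reported as exactly 999.0 with a
`ds_zero` flag — the conventional sentinel for a vanishing synonymous
denominator. Nested fits can differ by ~10⁻³ lnL from optimizer path
noise at boundary optima; tests allow that tolerance.

**Site posteriors** are naive empirical Bayes at the MLEs:
P(class c | site) ∝ p_c · L_c(site). Bayes empirical Bayes (which
integrates parameter uncertainty) is not implemented, so published
posterior probabilities computed that way are not expected to reproduce
exactly. Positive-selection sites are reported as position + reference
residue (e.g. `57N`); protein-level polymorphisms between two aligned
sequences use the `I50L` convention (residue A, position, residue B).

**Simulation.** The codon simulator draws the root from π and evolves
each site per branch by exact Gillespie event sampling under the same
scaled rate matrices as the likelihood — no matrix-exponential draws —
which yields exact synonymous/nonsynonymous event counts and per-site
class labels as ground truth. Linearity of substitutions per site in
divergence time (slope 1 within 8% over t ∈ [0.05, 1]) and uniformity of
the equal-frequency root draw (χ² goodness of fit at α = 0.01) are
tested.

**Validation batteries** (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) run at sizes chosen to finish comfortably on a
single CPU: ω recovery uses an 8-taxon balanced tree with all branches
0.1, L = 1000, 24 replicates per ω ∈ {0.2, 1, 2}; the
likelihood-ratio-test null calibration uses a 6-taxon tree, L = 300,
200 replicates. Both batteries fix branch lengths at their simulated
truth so each fit optimizes only 2–3 parameters; free-branch-length
fitting is the default for real analyses. A caveat measured during
development: at these battery conditions the joint (κ, ω) MLE carries a
small positive finite-sample skew at ω = 2 (≈ +0.05 in repeated runs),
which vanishes at L = 4000 and halves when κ is fixed — the expected
consistency behavior of maximum likelihood, but it places the ω = 2
recovery check near its bias bound, so that battery can be marginal for
some seeds.

## The plate-image assay

**Generator.** Plates are rendered as a regular grid of filled disks
(default 8 × 12, radius 18 px, pitch 46 px, optional global rotation up
to ±3°) on a low-saturation gray housing. Growth inside a well is drawn
from a Gaussian-smoothed random field: the top quantile of in-disk
pixels (matching the requested coverage exactly, up to pixel rounding)
becomes growth, and the top sub-quantile of that becomes conidia — so
conidia sit on the most densely colonized cores, as on real colonies.
Class colors are HSV anchors (housing gray, beige medium, bright
low-saturation hyphae, dark saturated-green conidia) with per-well
jitter (SD 0.02/channel) and per-pixel Gaussian noise (SD 0.015). The
label image is the ground truth by construction, and per-well
%hyphae + %conidia + %medium = 100 exactly. One global seed feeds
named per-component RNG streams (CRC-split), so regenerating one input
family never perturbs another.

**Well detection.** The well mask is the union of the Otsu-thresholded
saturation and value channels (smoothed at σ = 1.5): medium and conidia
read as a saturation plateau, while dense aerial mycelium reads as a
brightness plateau. The mask is closed, hole-filled and opened;
connected components are filtered to [0.4, 2.2]× a reference area taken
from the largest plausible wells, so stray specks cannot poison the
filter. Grid reconciliation estimates rotation from nearest-neighbor
displacement angles folded to (−45°, 45°], clusters the derotated
coordinates into rows/columns by gap splitting, fits origin and pitch by
least squares, and assigns each blob to its nearest grid node; nodes
without a blob within half a pitch are imputed from the fitted grid and
flagged. A flat image (saturation contrast < 0.08) yields no wells
rather than noise.

**Crops.** Square crops of side 2.2 × well radius (edge-replicated at
image borders) are resized bilinearly to 256 × 256; a crop whose side is
already 256 passes through untouched. The crop records its source side,
so the in-well disk used for coverage has the exact effective radius
rather than the nominal one.

**Classifiers.** Two implementations satisfy one contract (per-pixel
probabilities over background/hyphae/conidia summing to 1):

* *Rule-based (default and reference).* Each class is one or more HSV
  anchor colors; a pixel is classified by projecting onto every
  anchor-pair segment in **RGB** and taking the dominant endpoint of the
  best-fitting blend. The two-anchor projection matters: bilinear
  resizing blends colors linearly in RGB, and a plain nearest-anchor
  rule would misread conidia/hyphae blends (whose midpoints resemble
  beige medium), biasing coverage low by 2–3 points. With blend
  unmixing the end-to-end mean absolute coverage error is ≈ 1 point.
* *Learned.* A small scikit-learn MLP (one hidden layer, 16 units) over
  seven per-pixel features (HSV plus 5 × 5 local mean/SD of saturation
  and value), trained on subsampled annotated crops with a fixed seed.
  This is a deliberately compact stand-in for a convolutional
  encoder–decoder at fixture scale; the contract, determinism and
  evaluation harness are what the package specifies, not any particular
  architecture. Held-out pixel accuracy on generator plates is ≈ 0.99
  (the acceptance bar is 0.95), and agreement with the rule-based
  reference on low-noise plates exceeds 0.99.

The per-pixel decision is 3-way: "background" covers both the plate
housing and uncolonized medium, and coverage percentages are computed
over in-well pixels only. Both choices are conventions, documented here
because the assay could equally be defined 2-way or over the whole crop.

**What passing tests do not show.** The generator produces idealized
disks with stationary colors; real photographs add specular highlights,
meniscus shadows, condensation and out-of-focus wells. Detection recall
and ≤ 2-point coverage error on generator plates demonstrate the
pipeline's correctness, not photographic robustness; the learned
classifier path (train on annotated crops, evaluate held-out) is the
route to real images.

## Fitness analytics

* **Dispersal index** = raw count / suspension OD; linear
  proportionality is assumed since the normalization is defined only as
  "by OD". Air and water indices are kept separate and clustered
  (complete linkage, Euclidean) to read off dispersal-mode shifts.
* **Dilution series**: each (dilution, volume, colonies) triple implies
  `colonies · dilution / volume` CFU/mL; a titer is *accepted* only when
  at least two series agree within 2-fold (the acceptance rule names two
  series; the 2-fold tolerance is this package's documented choice). An
  all-zero pair of series is accepted as titer zero.
* **Survival** = 100 × treated/control titer; undefined for a zero
  control.
* **Wettability**: hydrophilic iff θ < 90°; the boundary value is
  assigned hydrophobic, a documented tie rule.
* **Expression**: 2^−ΔΔCt with replicate Ct values averaged on the Ct
  scale before fold conversion; gene profiles are clustered with
  complete linkage on Euclidean distances between fold-change rows, and
  genes with missing cells are excluded with a warning rather than
  imputed.
* **Genotype comparison**: one-way ANOVA (scipy) with Tukey HSD
  (statsmodels) at α = 0.05; the compact letter display is built by
  greedy insert-absorb over genotypes in ascending mean order, which is
  deterministic and guarantees that two genotypes share a letter iff
  Tukey does not separate them. With zero within-group variance and
  differing means the p-value is reported as the smallest positive
  float rather than zero.
* **PCA** defaults to unit-variance scaling (constant columns are
  dropped with a warning); components carry a deterministic sign
  (largest-magnitude loading positive).
* **Growth summary** = trapezoidal area under the OD₇₅₀ curve over the
  11 standard timepoints (12–168 h); the scalar choice is this
  package's, made so growth can enter the fitness profile.
* **Fitness profile**: the default eight parameters are growth, aerial
  hyphae %, conidiation %, air dispersal, water dispersal, and
  desiccation/freeze/UV survival. The set is configurable because the
  canonical membership of the eight is a convention, not a law; partial
  profiles record missing traits explicitly.

**Assay generator.** CFU and spore counts are Poisson; OD, contact
angles and Ct values are Gaussian; survival acts multiplicatively on the
treated titer before Poisson plating of two dilution series (10⁵- and
10⁶-fold, 0.1 mL). Default replicate counts mirror common assay designs
(6 dispersal, 8 stress, 12 contact-angle, 3 qPCR/growth replicates).
Under null effects the ANOVA battery rejects at 4.0% over 500 datasets
(within the exact binomial band around 5%), and a programmed 2-fold
air-dispersal effect (Poisson means 50 vs 100, n = 6) is detected with
power ≈ 1.0 — a repository target, not a claim about any laboratory
dataset.

## I/O and pipeline

FASTA codon alignments are read via Biopython with validation (equal
lengths, length divisible by 3, unique names); the default `cleandata`
policy drops columns containing gaps, ambiguity codes or stops (with a
warning), while the strict policy raises naming the taxon and position.
Newick trees use the codeml `#1` branch-tag dialect, parsed and written
by a small recursive-descent reader because general tree libraries do
not round-trip the tag; tags are accepted before or after the branch
length. The demo pipeline (`sporefit.io.run_pipeline`) runs
plate-coverage, fitness-profile and codon-model stages on fully
synthetic inputs from one seed and writes CSV/JSON reports plus a run
log; reruns are byte-identical. The package is a library: its functions
and the `examples/` scripts are the interface, and no shell entry point
is installed.

## Known limitations

* Bayes empirical Bayes posteriors, site models (M1a/M2a/M7/M8), tree
  search and bootstrap support are out of scope; trees are inputs.
* The learned segmenter is a pixel-feature MLP, not a convolutional
  network; it is exchangeable behind the classifier contract.
* The plate generator does not model optics (vignetting, focus,
  specularity), and colony texture is a thresholded random field, not a
  morphological growth model.
* Branch-model ω estimates on single short foreground branches are
  weakly identified; the 999.0 cap reports the resulting dS → 0 fits
  honestly rather than hiding them.
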