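# Methods

This note records the models, conventions and numerical choices behind
each mef2dyn stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Variant design

Per-residue probabilities p_D, p_DD and p_DP are consumed as tab-separated
tables produced by external sequence predictors; the predictors are not
re-implemented.  A toy charge/hydropathy surrogate (`profiles.toy_profile`)
exists solely so end-to-end tests can run without predictor output; it is
synthetic and must never stand in for real predictions.

Conventions and defaults:

* Residue numbering is 1-based, windows inclusive on both ends, in
  full-protein (UniProt Q14814) coordinates.  `full_to_peptide` /
  `peptide_to_full` map to the 37-residue peptide model (full residue 265 ↔
  peptide residue 1).
* The β-domain window is residues 286–292; window means are plain
  arithmetic means.
* The disorder/order boundary on the window-mean p_D is 0.3085,
  inclusive on the disordered side.
* The dynamics class uses ε = 0.05 on Δp_D (configurable): *mobile* for
  Δp_D ≥ ε, *rigid* for Δp_D ≤ −ε, *similar* otherwise.  Candidate ranking
  sorts by |Δp_D| descending (absolute value, so strong rigidifying and
  mobilising mutations rank alike), ties by |Δp_DP| descending, then by
  first mutated position — a stable, deterministic order.
* The droplet landscape takes (p_DP, MBM) in [0,1]²; the signed
  perpendicular distance to the identity diagonal decides the class with a
  0.05 boundary band.  MBM is accepted either as a scalar coordinate or as
  per-residue region flags; with flags only, the coordinate is the
  window's flagged fraction.  No quantitative MBM normalisation is claimed
  beyond this.

## Ensemble analysis

Contacts: a residue pair (i, j), |i−j| ≥ 3, is in contact when any
inter-residue heavy-atom distance is ≤ 0.45 nm.  The criterion lives in a
pluggable `ContactCriteria` object so a multi-criterion engine (hydrogen
bonds, salt bridges…) can be substituted without touching the clustering.

Similarity: f_S = |C_i ∩ C_j| / |symmetric difference|.  The printed
formula divides by zero for identical sets; the package's conventions are:
identical sets (including empty vs empty) → +∞ (they co-cluster at any
threshold); empty vs non-empty → 0.

Clustering is two-stage and deterministic given input order:

1. connected components of the graph with an edge wherever f_S > 0.5
   (strict inequality; equivalent to Jaccard > 1/3);
2. components are joined based on the frequencies of their common
   contacts: each component is summarised by the contacts present in at
   least `merge_fraction` (default 0.5) of its members, and the component
   pair whose summaries have the highest f_S above the threshold is
   merged, iterating to a fixed point (ties resolved toward the lowest
   component indices).  The joining rule is isolated behind this function
   so alternative formalisations can be swapped in.

Stage 1 is computed from a vectorised snapshot-by-pair incidence matrix
with scipy's sparse connected components; the test suite checks it against
an independent per-pair set arithmetic + networkx oracle on every instance
up to 200 snapshots.

Equilibration windows are half-open [start, end) in ns, which makes a
30 ns window at a 10 ps save interval contain exactly 3000 frames and
three pooled replicas 9000.  Frames at exactly the end time are excluded.
Replica windows are concatenated (pooled) before clustering.

Radius of gyration is the mass-weighted RMS distance from the centre of
mass (nm).  Compactness is classified by the median Rg against a reference
with an absolute tolerance of 0.05 nm (roughly the frame-to-frame Rg
scatter of a 37-bead chain); within the band the ensemble is *mixed*.
RMSD to the ensemble-average structure uses Kabsch superposition and is
used only to judge equilibration plateaus — the average structure of a
disordered ensemble is not a physical conformation.

The β-domain contact fraction weights each contact by the number of member
snapshots sampling it and is reported under both membership modes
(`both_in`: both residues inside the window; `any_in`: at least one),
because "fraction of contacts within a domain" is ambiguous; callers
should state which mode they quote.

## NMR dynamics

Secondary shifts are observed − random-coil reference per nucleus (Cα,
Cβ, Hα) after removing a single scalar offset per nucleus (the median of
the raw differences), making Δδ invariant to a global referencing error.
Missing references propagate as absent values, never as zeros.  The
random-coil reference is an input table; no temperature/pH correction is
applied by default.

RCI/S²: the weighted mean absolute secondary shift (package-default
weights CA 0.74, CB 0.72, HA 0.20 — configuration with the carbons
weighted as the more order-sensitive nuclei, replaceable by any published
coefficient set), smoothed over 3 consecutive reported residues, floored
at 0.02 ppm and inverted, gives the RCI; S² = 1 − 0.4·ln(1 + 0.1·RCI)
clamped to [0, 1].  The gain 0.1 is chosen so that the map is
non-degenerate over the RCI range the floor allows (S² spans ≈ 0.28–1
rather than saturating); all S² claims in the package are therefore
ordinal (bounds, monotonicity in RCI, relative ordering), not absolute.
Only labelled residues carry data (leucines in the study design), so all
relaxation operations accept sparse residue coverage without imputation.

Relaxation: I(t) = I₀·e^(−t/T) fitted by nonlinear least squares,
starting values from a log-linear regression on the positive portion of
the trace (noisy near-zero tails at the long T1 delays may dip below
zero and are retained in the fit).  Non-decaying data are flagged as
failures, never clamped.  Default schedules: T1 delays 10–2400 ms,
T2 CPMG durations 17–305 ms, 700 MHz field.

Reduced spectral density mapping collapses J(ωH ± ωN) onto J(0.87 ωH),
with the ¹⁵N–¹H dipolar constant (r_NH = 1.02 Å) and CSA (−160 ppm)
recorded in `NitrogenConstants`.  NOE = 1 maps to J(0.87 ωH) = 0 exactly.
The forward single-Lorentzian model in `simulate` evaluates the same
reduced expressions, so the mapping round-trips it exactly at the three
frequencies; against rates computed with the full five-frequency
expressions the mapping would carry the usual reduced-sampling
approximation error.

DOSY: I(g) = I₀·exp(−D·b), b = (γgδ)²(Δ−δ/3) with the rectangular/bipolar
correction Δ−δ/3 (alternative corrections can be substituted by editing
`DosyDecay.b_values`).  The default fit is weighted least squares in the
log domain (weights ∝ I², the correct propagation of additive intensity
noise); a raw-domain nonlinear fit is available via `fit("nonlinear")`.
Gradients are given in G/cm and converted internally (1 G/cm = 10⁻² T/m),
so D comes out in m²/s.

## FRAP

The double normalization is implemented exactly as stated in the module
docstring, with the t₀ quantities taken as means over all pre-bleach
frames (robust to frame noise).  Equal multiplicative acquisition
bleaching on both ROIs cancels identically; the normalization is also
invariant to a common positive rescaling of all channels.  Traces are
assumed drift-corrected on input; registration is out of scope.

Recovery kinetics default to a single exponential
N(t) = N∞ − (N∞−N₊)e^(−t/τ) on the post-bleach points; mobile fraction
= (N∞−N₊)/(1−N₊) with the pre-bleach level fixed at 1, half-time τ·ln 2.
A double-exponential model is available behind `model="double"`.  Flat
curves (recovery amplitude < 10⁻³) are flagged: mobile fraction ≈ 0 and
the half-time reported absent rather than fitting an unconstrained τ.

The mobile-fraction standard error combines the fit covariance (delta
method) with the uncertainty of the t₀ normalization reference, estimated
from the pre-bleach scatter of N around 1.  The reference error acts as a
common scale factor on the entire curve, which the fit covariance alone
cannot see; omitting it makes the reported error anticonservative at high
mobile fractions.

Mobility classification: liquid-like iff the fraction recovered within
the horizon (120 s, matching the acquisition length) reaches the 0.5
threshold, inclusive; both are configurable, and the liquid/solid contrast
they encode is a qualitative convention.

## Cell metrics

Fusion index = nuclei in ≥2-nucleus myocytes / all nuclei in the field;
pooling sums raw counts, equal to the total-weighted mean of per-field
indices.  Reporter activity is luciferase/galactosidase per sample,
normalized to the in-batch wild-type mean (×100) before pooling, so the
wild type is 100 % in every batch and the measure is invariant to
rescaling both raw signals.  Batches lacking a wild-type sample are
excluded with a warning.  Weighted summaries use sample counts as weights
for both the mean and its standard error.  Group tests: two-sided
two-sample t-tests, or one-way ANOVA with Bonferroni–Holm-adjusted
pairwise post-hocs against the reference.  The dynamics–activity relation
uses Spearman rank correlation by default because the claimed relation is
monotone, not linear.

## Synthetic generators

All generators take a seed (or Generator) and return their ground truth;
`GeneratorConfig` derives per-stage streams from a run seed and a CRC32 of
the stage name, so stage order never perturbs reproducibility.

Defaults mirror the study's data shapes: 37-residue chains, 3 replicas of
100 ns at 10 ps saves, the printed T1/T2 delay lists, the 32-step 5–95 %
of 57.7 G/cm gradient schedule with Δ = 75 ms / δ = 2 ms, and 120
post-bleach FRAP points over 120 s with 10 pre-bleach frames.  Planted
effect sizes default to ±0.2 on the window p_D (one variant per dynamics
class), a 1.78× activity ratio for the rigid reporter variant, and 2 %
noise where a noisy condition is exercised.

What they do *not* emulate: physically realistic force-field energetics
(conformers are self-avoiding biased random walks, not Boltzmann
ensembles), spectral processing and peak picking (NMR inputs are
tabulated intensities), image formation and segmentation (FRAP inputs are
ROI traces), and biological variability beyond simple log-normal/binomial
noise.  Passing tests therefore demonstrate correctness of the analysis
algorithms under their stated models — not that the models capture every
feature of the real measurements.

The contact generator warns when the expected per-frame noise-contact
count approaches the bound beyond which same-motif frames are no longer
guaranteed to exceed f_S = 0.5; below the bound, exact membership
recovery is a tested property.

## Problem sizes

The test suite and acceptance script use 100 random trajectories of 20–200
snapshots for the clustering-oracle check, 80-frame trajectories for
planted-cluster recovery, 100 seeds per noisy-recovery sweep, and
150-frame bead-chain ensembles — sizes chosen so each property is
exercised well away from trivial regimes while the whole suite stays in
the seconds-to-a-minute range on a single CPU.

## Known limitations

* The cluster-joining rule is one reasonable formalisation of "joined
  based on the frequencies of the common contacts"; other formalisations
  (single-pass joins, different frequency cuts) can produce different
  cluster counts on borderline data.
* S² values are ordinal under the package-default RCI coefficients;
  absolute comparisons require supplying a published coefficient set.
* DOSY uncertainties come from the fit covariance; replicate-to-replicate
  spread (often much larger for aggregating samples) must be assessed by
  fitting replicates separately.
* The β-domain contact fraction depends on the contact criterion and the
  membership mode; cross-study comparisons must match both.
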