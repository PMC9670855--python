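# Methods

## Per-residue scores

**Regions and p_DD.** For residue *A_i* in a sequence of length *L*, the
binding regions are all contiguous windows of 5–9 residues that contain
*i* and lie fully inside the sequence (no virtual padding). An interior
residue (≥ 9 from both termini) has N = 5+6+7+8+9 = 35 regions; residues
near a terminus simply average fewer windows, consistent with dividing by
"the number of possible regions". The disordered-binding probability is
the arithmetic mean

    p_DD(A_i) = (1/N) · Σ π_DD(R)

over those regions. The enumeration takes the inclusive reading of
"regions around *A_i*": every window containing the residue, not only
centred ones (centred-only enumeration is ill-defined for even lengths).

**Binding-mode surrogate.** Genuine per-region binding-mode probabilities
come from an external trained predictor and can be supplied as a plugin
or as a `p_dd` score track. The shipped baseline scores a region by its
local sequence bias: π_DD = 1 − JSD(composition of region, composition of
flanks), where JSD is the Jensen–Shannon divergence with base-2 logarithm
(symmetric, bounded in [0, 1], so 1 − JSD is a probability). Flanks are up
to 15 residues per side, clipped at the ends and concatenated — comparable
in scale to the 5–9-residue regions while giving a stable composition
estimate. If the region spans the whole sequence the flank is empty and
π_DD is defined as 0.5 (no evidence either way). Compositionally unbiased
regions (π_DD → 1) favour disordered binding; strongly biased regions
(π_DD → 0) favour ordered binding. The baseline is a clearly-labelled
surrogate: it reproduces the qualitative structure (low π_DD inside a
compositionally distinct core) but not the numerical output of a trained
predictor.

**MBM.** The multiplicity of binding modes is the Shannon entropy of the
binned π_DD values of a residue's regions: equal-width bins partition
[0, 1] (default 10; bin *k* is [k/10, (k+1)/10), the last bin closed at
1.0 so π_DD = 1 is counted), frequencies f_k = n_k / N, and

    MBM = S_bind = −Σ_k f_k ln f_k,   0·ln 0 := 0.

The natural logarithm is used: with 10 bins the maximum is ln 10 ≈ 2.303,
which is the only base under which the landscape thresholds 2.0 and 2.25
are attainable; MBM is taken as identical to S_bind, the only reading
consistent with plotted MBM ranges up to ~2.3. Both conventions
(log base, bin closure) are frozen by test.

**p_D and p_AP baselines.** The disorder track is a centred sliding-window
mean (window 21, clipped at the termini) of the TOP-IDP disorder
propensity scale min-max-normalised to [0, 1]. The amyloid-promoting
track is the windowed mean (window 7) of the Kyte–Doolittle hydropathy
index rescaled to [−1, 1]; the solubility track is its negation
(p_AP = −p_CS). Window lengths follow common practice for
disorder (long-range context) and aggregation (short hot-spot) profiles
and are configurable. User-supplied tracks from genuine external
predictors replace any baseline; they are validated for coverage
(every position exactly once) and range.

## Droplet propensity and landscape

p_DP = logistic(λ₁·p_D + λ₂·p_DD + γ). The coefficients of the published
logistic fit are not available; the shipped defaults
λ₁ = λ₂ = ln 19 ≈ 2.944, γ = −ln 19 are calibrated so that
p_D = p_DD = 1 maps to p_DP = 0.95 and p_D = p_DD = 0 to 0.05. Users with
genuine upstream output can bypass the logistic entirely via a `p_dp`
track. The decision threshold p_DP ≥ 0.60 (droplet-promoting residue) is
inclusive; p_AP > 0.90 (aggregation-prone) is exclusive, following the
"above which" wording; both frozen by test.

Landscape classes use strict inequalities — droplet: p_DP > 0.85 and
MBM < 2.0; amyloid: p_DP < 0.75 and MBM > 2.25; hot-spot:
0.75 < p_DP < 0.85 and MBM > 2.25 — so boundary values are
`unclassified`, as are points outside all three boxes (e.g. high p_DP
with low MBM but p_DP ≤ 0.85). A separate query flags residues with
p_DP ≥ 0.75 and MBM > 2.25, the regime where mutations most readily
shift behaviour toward aggregation; it is deliberately not folded into
the three-class map.

## Variant features

Single mutants: Δp_DP, Δp_AP, ΔMBM are (mutant − wild-type) values at the
mutated position, each profile computed on the full domain. Double
mutants: the three tracks are averaged over the fixed window 312–341
(amyloid core plus both flanking hot-spots, 30 residues) in each profile
and the deltas are differences of those averages — regardless of where
the mutations fall, mirroring the region-average construction. Variants
are labelled amyloid_core (321–330), hotspot (312–320, 331–341), droplet
(262–311, 342–414) when all mutated positions share a class, else
`mixed`; mixed doubles stay in the feature table but are excluded from
per-region comparisons.

The k·σ effect filter retains variants with |Δe_tox| ≥ k·σ (k = 3 by
default). σ defaults to the standard deviation of the measured changes
(`sd`), the conventional reading; `mean_abs` (mean absolute change) is
available where the literal "average change" definition is wanted. The
filter is applied to absolute values and is inclusive at the threshold;
the σ, k and mode used are recorded in the output metadata.

## Toxicity model

A `RandomForestRegressor` (scikit-learn) maps the three delta features to
Δp_tox. Hyperparameters are grid-searched — ntree ∈ {100, 250, 500,
1000}, mtry (max_features) ∈ {1, 2, 3}; the published grid ranges are
not stated, so these cover the standard span for a three-feature
problem — and scored by the Pearson correlation between out-of-bag
predictions and targets (each tree's bootstrap uses about two-thirds of
the data; OOB prediction uses the trees that did not see the row). Ties
break toward smaller ntree, then smaller mtry. All stochasticity flows
from one recorded seed; training requires ≥ 30 rows, finite features and
non-degenerate targets. Models persist as versioned joblib bundles whose
round-trip reproduces predictions bit-identically.

## Synthetic data

The generator emulates an LC-domain deep-mutagenesis study: a 153-residue
G/S/N/Q-rich background drawn i.i.d. from a fixed composition, numbered
262–414, with a 10-residue hydrophobic segment (letters W/F/I/V/L) at
321–330 providing an amyloid-core-like region of strong local bias;
498 single mutants (the full scan size) and 2,000 double mutants — a
computational down-sample of the 23,802-pair scan chosen to keep a full
study generable in about half a minute; pass `n_double=23802` for the
full size. Measured toxicity is

    e_tox = b_dp·Δp_DP + b_ap·Δp_AP + b_mbm·ΔMBM + N(0, σ_noise),

default coefficients (2, 1, 1) and σ_noise = 10% of the standard
deviation of the noiseless signal. Features are computed through the
full pipeline, so the planted map is expressed in exactly the quantities
training consumes; the noiseless signal is kept in the table as a test
oracle. A sign-preserving cubic form is available to exercise the
forest's advantage over a linear fit. The generator does **not** emulate
growth-assay error structure, epistasis beyond the region-average
construction, or the composition of any real protein — passing tests
show the pipeline recovers structure it planted under its own generative
assumptions, not that the surrogates reproduce trained-predictor output
on real sequences.

## Numerical choices and degenerate inputs

* π_DD values are clipped to [0, 1] after the JSD round-trip through a
  square root (guards 1e−17-scale overshoot).
* Sliding windows require odd lengths; windows are clipped, never padded.
* Sequences shorter than 5 residues (below the smallest region) are
  rejected; a length-5 sequence has one region, so p_DD is constant and
  MBM = 0 at every position.
* Duplicate mutated positions, silent substitutions and wild-type
  mismatches are rejected at parse/apply time with diagnostics naming
  the position and letters.
* The empty variant table round-trips as an empty CSV with a header.

## Limitations

* The compositional surrogates stand in for trained predictors; absolute
  p_DP/p_AP values (and hence landscape class occupancy) under the
  baselines are not comparable to output obtained with the genuine
  upstream methods. Under the shipped baselines a typical LC background
  rarely exceeds p_DP ≈ 0.8, so the strict landscape boxes are sparsely
  populated; supply real predictor tracks for landscape analyses of real
  proteins.
* The logistic coefficients are a documented calibration, not a fit.
* Insertions, deletions and non-canonical residues are out of scope
  (missense-only design).
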