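# Methods

This note documents the models, defaults, and design choices behind
`zfpdx`, and what the synthetic-data calibration does and does not show
about real data.

## Coordinate frame and region atlas

Foci are points in an embryo-fixed frame: origin at the injection site in
the pericardial space (PCS), x along the anteroposterior axis in µm
(positive caudal), y dorsoventral (positive dorsal). Ten regions chosen by
larval hemodynamics — PCS, Yolk, CHT, CF, ISV, PHBC, PCV, PMBC, DLAV,
AA1 — are modeled as axis-aligned rectangles tiling a 4,800 × 800 µm
bounding box (`src/zfpdx/data/atlas_default.yaml`, editable). Published
region schematics for this assay carry no coordinates, so the shipped
geometry is a schematic stand-in: anterior brain channels and mandibular
arch, medial yolk/trunk vessels, posterior cardinal vein → caudal
hematopoietic tissue → caudal fin. Containment is half-open
([x0,x1)×[y0,y1)) so assignment is total and unambiguous on shared edges;
out-of-frame points attach to the nearest rectangle.

## Synthetic-study generator

The generator emulates the three input layers with explicit ground truth;
every distribution is a documented stand-in (measured studies of this
design report only raw counts and coordinates, never the generating law).

* **Embryos.** An injected embryo engrafts with probability
  `engraft_prob`; engrafted embryos carry Poisson(`foci_mean`) foci at
  1 dpi and Poisson(`foci_mean × survival_decay`) at 2 dpi. Poisson was
  chosen because only raw counts are ever reported; an optional
  negative-binomial switch (`foci_nb_dispersion`) adds overdispersion and
  is off by default. Defaults follow the pilot design: 24 embryos injected
  per sample, 6 scored for survival/migration, ~50,000 flow events per
  tube.
* **Foci coordinates.** Region from `tropism_weights` (forced uniform when
  `dispersion_mode="random"`), then uniform within the region rectangle
  plus isotropic Gaussian jitter (default 10 µm). With the default atlas
  the expected fraction of jitter-induced border crossings is
  (interior-edge length × 2 × σ/√(2π)) / area ≈ 1.8 %, which bounds
  achievable region-label agreement at about 98 %.
* **Flow events.** A log-normal main population (FSC-A ~ LN(ln 50 000,
  0.25), SSC-A ~ LN(ln 30 000, 0.35)), 5 % low-FSC debris and 2 %
  FSC-H ≈ FSC-A/2 doublets by default (unreported in the assay
  description; set non-zero so the viability and singlet gates are
  exercised non-trivially), and — in the DEAB⁻ tube only — an
  ALDH-bright/SSC-low subpopulation of expected fraction
  `aldh_bright_frac` of singlet-like events, FITC ~ LN(ln 8 000, 0.3)
  against background LN(ln 300, 0.5), SSC ~ LN(ln 12 000, 0.3). The DEAB⁺
  control shares the background FITC law exactly (idealized complete
  inhibition), which makes the thresholding contract testable. CD34 is
  bimodal (LN(ln 150, 0.5) negative, LN(ln 5 000, 0.4) positive) with
  probability `cd34_frac_within` inside the bright gate and
  `cd34_frac_background` (default 0.2) elsewhere.
* **Determinism.** One `numpy` Generator seeded from `StudyConfig.seed`
  drives everything; fixed seed ⇒ byte-identical CSV/JSON outputs.

What the generator does **not** emulate: spectral spillover/compensation,
instrument drift, autofluorescence tails, doublet shapes beyond the H/A
ratio, proliferation (CFSE dilution), vasculature-constrained migration
paths, or embryo-to-embryo anatomical variability. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
sampling models, not robustness to those real-data effects.

## Gating chain

All percentages are relative to **singlet** events (published per-sample
tables do not state their denominator; this choice is fixed here and
documented). Defaults, all configurable: FSC-A floor 26,000 (between the
synthetic debris and main modes), singlet band ±0.15 around the median
FSC-H/FSC-A ratio, DEAB quantile q = 0.999 (the standard ALDEFLUOR
0.1 %-background convention; the assay description gives no numeric
placement rule), SSC-low cutoff = singlet median SSC-A (the published
gate is graphical only), CD34 cutoff at the valley of a Gaussian-KDE
density of log(1+intensity) between its two tallest modes (fallback:
log-scale midpoint of the 5th/95th percentiles; a fixed cutoff can be
supplied). The numerous/rare boundary is **strictly** greater than 1.9 %:
the published rule brackets with ">1.9 %" and "<1.9 %", leaving equality
unassigned, and equality maps to rare here. An empty CD34 gate is flagged
undefined rather than reported as 0 %. A reported combined LSC % that
disagrees with the product of its two gate percentages beyond printed
rounding (±0.011) is flagged, never silently reproduced.

## Behavioral statistics

* **Survival.** Conjugate Gamma–Poisson with prior Gamma(1, 1)
  (weakly-informative; no prior is stated for the assay, and conjugacy
  keeps the posterior closed-form and the HDI exactly testable).
  Configurable via `gamma_prior`.
* **HDI.** Shortest interval with the requested mass, found by bounded
  minimization of `ppf(a+mass) − ppf(a)` with explicit edge handling
  (mode-at-zero posteriors get [0, q]); flat densities return the central
  interval; multimodal densities warn and return the shortest single
  interval. Two posteriors are "different" iff their closed HDIs are
  disjoint (touching endpoints ⇒ not different).
* **Dispersion.** The standard deviational ellipse uses the
  eigendecomposition of the sample covariance (ddof = 1); semi-axes are
  √(2λ) (the one-standard-deviation ellipse convention) and θ ∈ [0, π) is
  the major-axis angle. Bootstrap CIs (default B = 9 999 resamples with
  replacement — the assay's "9 999 permutations" is read as bootstrap
  resampling, which matches its own description "bootstrapping of foci
  coordinates"; a permutation-test variant is exposed via
  `method="permutation"`) are percentile intervals per parameter, with θ
  handled on the doubled-angle circle to avoid wrap-around. Two samples
  differ when both semi-axis CIs are pairwise disjoint (different spread)
  or at least one center-coordinate CI pair is disjoint (different
  location; a shift along a single axis already separates two patterns,
  so requiring both coordinates would be unable to detect a purely
  axial displacement). Percentile bootstrap at these sample sizes
  (n ≈ 40–50) undercovers slightly: measured coverage ≈ 93 % at nominal
  95 %, the expected small-sample behavior.
* **Tropism.** Dirichlet(1,…,1) prior (uniform; conjugacy gives exact
  Beta marginals), posterior Dirichlet(1 + counts), marginal 95 % HDIs.
  *Clumped* ⇔ at least one of the 45 region pairs has disjoint HDIs;
  *preferred* regions are those whose HDI lies entirely above the uniform
  expectation 0.1. **Operating characteristics:** the pairwise rule makes
  no multiplicity correction, so while truly clumped cohorts (one region
  weight ≥ 0.4, ≥ 100 foci) are detected essentially always, uniform
  cohorts are falsely called clumped in roughly 15–25 % of replicates at
  100–300 foci (central intervals behave the same). This family-wise
  false-positive rate is an inherent property of the verbal rule as
  operationalized and is deliberately left uncorrected; users comparing
  many cohorts should treat "clumped" calls near-uniform profiles with
  caution.

## Outcome discrimination

Features (standardized to mean 0, sd 1; constant columns dropped with a
warning): age-band midpoint, % blasts, platelets, leukocytes, risk code
(favorable/standard = 0, intermediate = 1, adverse = 2); ALDH-bright %,
CD34⁺-within %, combined LSC %, pattern code (rare = 0, numerous = 1);
engraftment %, posterior-mean survival, the ten region probabilities,
dispersion code (random = 0, clumped = 1), ellipse area, mean |AP| and
|DV| migration. Patients with unknown remission are excluded from
supervised fits.

PLS-DA is NIPALS PLS1 on the centered 0/1 response, written from scratch
(per component: w ∝ Xᵀy unit-norm, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt,
deflate both blocks) and cross-checked in the tests against an SVD-based
recursion and scikit-learn to 1e-6 up to sign. Explained Y-variance after
k components is 1 − SS(y resid)/SS(y); VIP follows the standard
√(p Σ q²tᵀt w² / Σ q²tᵀt) form. Prediction is nearest class centroid
along component-1 scores, ties to class 0. With pilot-sized cohorts
(n ≈ 6) only resubstitution and permutation-style nulls are meaningful;
no cross-validation is offered at that n.

Association tests: the exact Wilcoxon rank-sum p is the doubled smaller
tail of the rank-sum over all C(nA+nB, nA) assignments (computed by a
subset-sum dynamic program on doubled midranks; ties warn and condition
on the tie pattern), capped at 1. The 2×2 χ² uses the Yates continuity
correction with the |ad−bc| − n/2 term floored at 0, p from χ²₁; zero
marginals are flagged undefined. Logistic fits use IRLS (tol 1e-8, 100
iterations), detect quasi-complete separation for a monotone univariate
predictor, and report McFadden, Cox–Snell and Nagelkerke pseudo-R²
(published pilot analyses do not always name their R² variant, so all
three are exposed) plus a likelihood-ratio p. No multiple-testing
correction is applied by default, matching small-pilot practice; a
Benjamini–Hochberg step would be a trivial addition downstream.

## Recovery experiments and problem sizes

`zfpdx.recovery` fixes the calibration conditions:

* **Tropism classification** — 200 replicate cohorts, 24 scored embryos,
  ~140 foci each; clumped truth puts weight 0.45 on CHT.
* **Gating** — single studies at 200,000 events across bright fractions
  0.001–0.4; recovered gate percentages land within 1 pp of truth
  (binomial noise at that depth is ≈ 0.1 pp; the residual error is
  dominated by the 0.1 % control-quantile allowance and the ~0.1 % of
  bright events above the SSC median).
* **PLS driver recovery** — 200 replicate studies of 16 patients
  (outcomes balanced), 15,000 events per tube, behavioral point features
  only (no bootstrap CIs enter the model). Outcomes are driven by two
  latent axes at 3-SD group separation: one moves the ALDH-bright and
  CD34 fractions through a shared factor with anticorrelated noise, so
  the *combined* LSC burden carries the signal while each gate
  percentage alone is attenuated (≈ 1.2 % vs ≈ 6.5 % combined LSC
  between outcome groups); the other moves the PHBC tropism weight
  (0.17 vs 0.44 between groups), the remaining mass redistributed by a
  Dirichlet draw. PHBC is used as the driver region both because
  anterior-region migration is the favorable-outcome predictor reported
  for this assay and because a far-caudal driver (CHT) would be
  confounded with mean migration distance, making "which feature drives
  outcome" ill-posed. Sixteen patients per replicate is the smallest
  size at which the ranking experiment is adequately powered.

## Known limitations

* The generator's parametric families are stand-ins; none of the
  recovery results certify behavior under real instrument artifacts.
* The random/clumped rule's family-wise false-positive rate (above) means
  "clumped" is liberal for near-uniform cohorts.
* The viability gate is a 1-D FSC-A floor, not a polygon; no
  compensation or spillover handling; flow I/O is CSV event tables with
  the canonical channel names.
* Survival HDIs are defined on the Gamma–Poisson mean-count posterior;
  other constructions (e.g., on smoothed densities) would give different
  intervals for the same data.
* Ellipse-based two-sample comparison by disjoint CIs is conservative
  (measured false-positive rate ≈ 0 at n = 50); the permutation variant
  is more powerful but less comparable to interval non-overlap reporting.
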