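# Methods

This note records the models, estimators, numerical choices and known
limitations of `phylomorph`, in the package's own terms. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Trees and the Brownian backbone

Trees are rooted, time-calibrated (branch lengths in Myr), stored as
parent-pointer arrays with tips first and the root last. Polytomies are
accepted everywhere (likelihood, simulation, pruning). Near-ultrametricity
is checked at relative tolerance 1e-6 and reported as a warning, not an
error, since Newick round-trips perturb the last digits. Taxon matching is
exact after normalizing whitespace to underscores; case is preserved.

Pruning keeps the selected tips, collapses degree-2 nodes with branch
lengths summed, and re-roots at the retained most-recent common ancestor
(the stem above it is dropped, the usual convention); path lengths among
retained tips are exactly preserved.

All comparative statistics use the Brownian-motion tip covariance
C[i, j] = depth of MRCA(i, j) and its inverse square root from an
eigendecomposition; a non-positive eigenvalue (relative tolerance 1e-10)
raises rather than silently regularizing. Ancestral values under BM are the
GLS/ML reconstructions a + C_at C_tt^(-1) (Y - a), with a the GLS mean.

## Microhabitat classification schemes

Primary/secondary records over six categories (A, C, F, S, T, W) collapse
to one state per species under six schemes: majority (primary) vs lenient
(a terrestrial-plus-other species takes the other category); a
semiaquatic state SA for species whose two categories are exactly {T, W}
(the standard meaning of semiaquatic — the rule is logged so users can
override); and two variants that splice an external obligate/facultative
arboreal survey into the arboreal category. A species with survey status
"none" is treated as *not surveyed* — its own classification stands. This
is what makes unambiguous records (no secondary, no survey flag) classify
identically under all six schemes, which the suite asserts. A species with
two non-terrestrial categories keeps its primary, with a logged warning.

## Mk models

* Likelihood: Felsenstein pruning with per-node rescaling (log scale
  factors accumulated), so 500-tip trees with extreme rates stay finite.
* Transition matrices for all edges come from one eigendecomposition of Q
  per likelihood evaluation, with a per-edge `expm` fallback when the
  eigenbasis condition number exceeds 1e8. Zero-length edges use the
  identity.
* Root prior: flat (1/K) by default; stationary or explicit vectors are
  accepted. The flat default matches common ML ancestral-state practice.
* Fitting: L-BFGS-B on log rates, bounds [1e-9, 1e3] per Myr, ftol 1e-8,
  from 10 random log-uniform starts around a parsimony-flavoured central
  rate (minimum number of state changes / total tree length) plus that
  central start itself. Fits are reproducible given the seed. Rates driven
  to the lower bound print as 0 at four decimals.
* Model choice: AIC, ties broken toward fewer parameters.

Caveat observed while validating: for the 2-state ARD model the tip
pattern constrains the gain/loss *ratio* much more tightly than the overall
rate magnitude (a likelihood ridge). Under the 20x-asymmetry recovery
experiment (400 tips, 200-Myr tree, rates 0.002/0.04) roughly one fifth of
realizations yield an MLE more than a factor 2 from the truth on one rate,
even though the estimator is exact (it agrees with an independent R
implementation to full precision on the same data). Users should read
individual ARD rate magnitudes with that sampling variability in mind; the
asymmetry ratio is the robust quantity.

## Stochastic mapping

Node states are drawn jointly root-to-tips from their conditional
distributions; each branch path is then sampled conditioned on its
endpoints by uniformization (dominating rate = max total leave-rate; the
number of dominated-chain jumps is drawn by inverting its series, the jump
states by a forward pass weighted by remaining steps to the endpoint).
Rejection sampling — forward simulation until the endpoint matches — is
deliberately kept as an independent test oracle and never used in the
pipeline, because it stalls on long branches with unlikely endpoint pairs.

Summaries: per-node state frequencies; mean realized transition counts;
origins of a focal state counted one per gain event, including regains
after a loss (consistent with the transition-count bookkeeping); and
per-edge gain frequencies for locating origins. The default number of maps
is 1,000.

## Morphometrics

* Imputation: missing linear measurements are predicted on the log scale
  by least squares from the observed variables, fitted on complete cases
  from the narrowest pool with enough of them (conspecifics, else
  congeners, else everything; "enough" = observed-variable count + 2, at
  least 3). Observed entries are bit-identical in the output and the
  procedure is deterministic.
* Shape ratios: species means of the raw measurements first, then
  division by mean SVL, then natural log (the standard choice for Mosimann
  ratios; the base only shifts scale).
* Thin-plate splines use the U(r) = r^2 log r^2 kernel; missing-landmark
  completion fits reference -> specimen on the shared points and maps the
  missing reference points through; collinear or too-few (< 3) shared
  points raise. At most 6 of the 21 points may be missing.
* GPA: center, scale to unit centroid size, rotate (proper rotations) to
  the running consensus; consensus re-normalized each iteration;
  convergence when the consensus moves < 1e-8. Configurations whose
  orthogonal fit to the consensus requires a reflection are mirror-corrected
  (flagged in `reflected_`) — digitizing-orientation errors, not shape.
* Semilandmark sliding minimizes thin-plate bending energy against the
  consensus, moving each semilandmark along the chord between its
  bracketing neighbors; the Newton step is shrunk uniformly so points stay
  between their brackets (a convex quadratic decreases along the whole
  Newton segment, so shrinking preserves descent), and a slide is accepted
  per specimen only if it lowers energy — per-pass monotonicity is
  therefore exact. Because the consensus co-updates, sliding has no exact
  fixed point; passes stop when the relative energy improvement drops
  below 1e-4 or after 10 passes (both configurable), after which plain
  alignment converges.
* Species means: GPA within species, average, then GPA across the species
  consensuses; per-species mean centroid size is kept for allometry.
* Phylomorphospace: centered PCA (SVD) of species values; internal nodes
  are GLS ancestral estimates projected on the same axes.

## Comparative statistics

* Phylogenetic ANOVA: trace statistics on C^(-1/2)-transformed data; the
  null permutes reduced-model (intercept-only) transformed residual rows
  (RRPP); p = (1 + exceedances)/(1 + permutations); the effect size Z is
  the standard deviate of log F in the permutation distribution (observed
  value included). On a star tree this reduces exactly to ordinary
  MANOVA-trace statistics, which the suite asserts to 1e-9.
* Pairwise comparisons: Euclidean distances between GLS group means,
  evaluated against the same residual-randomization null. Distances are
  computed on the transformed-model means (the GLS estimates), one of two
  defensible readings; it is the one consistent with the ANOVA's
  transformation.
* sigma^2_mult: sum of squared transformed deviations from the GLS mean
  over (N x p). Per-group rates keep the full-tree transformation and
  common mean and partition the transformed residual rows by group;
  heterogeneity is tested by simulating the null (single pooled rate,
  empirical trait covariance R'R/N preserved) on the full tree and
  recomputing the max/min ratio. Groups of one species are excluded with a
  warning. Defaults: 999 simulations/permutations everywhere, matching the
  cited methods' conventions.
* C1: for each focal pair, 1 - (tip distance)/(max distance between any
  two values on the two tip-to-MRCA paths, tips included), averaged over
  pairs; degenerate pairs (all values identical) count 0 with a warning.
  The null simulates BM at the empirical evolutionary rate matrix and
  recomputes C1 with ancestral states re-estimated per draw.
* C5: tips and ancestral estimates are ordinated on the first 2 principal
  axes by default (full dimensionality available via `dims`); the focal
  region is the convex hull of the focal tips; a lineage counts once if its
  root-to-tip polyline enters the hull from outside (segment-hull
  intersection by halfplane clipping). The 2D default keeps hulls stable
  and matches how morphospaces are usually drawn.
* Allometric convergence: per-group linear regression of shape on log
  size; D_small and D_large are the between-group distances of predicted
  shapes at the shared minimum and maximum observed size; the statistic is
  D_small - D_large, its null from permuting species (with their sizes)
  between groups. Non-overlapping size ranges warn that predictions are
  extrapolated.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analyses assume:
pure-birth chronograms (default heights rescaled; 200 Myr is used where a
realistic salamander-scale chronogram is wanted), exact forward CTMC
characters, BM traits with state-dependent rates (including a clade-painted
regime, the clean construction when tip membership must match branch
history), an OU-style attraction regime for convergence positive controls,
isotropic digitizing noise and random similarity transforms for landmarks,
and lognormal allometric measurement tables. Defaults mirror the study
scale: hundreds of tips, 6 states, p = 6 ratios or 21x2 landmark
coordinates.

They deliberately do not emulate: correlated digitizing error, allometric
curvature, measurement error correlated with size, non-Brownian trait
evolution (OU/EB) outside the attraction regime, extinction, or biased
taxon sampling. Passing calibration tests therefore demonstrates
correctness of the estimators under their own assumptions, not robustness
to violations of them.

The attraction regime uses the exact OU-toward-point transition per
sub-step (step <= 1% of tree height) rather than an Euler update; the two
agree in the small-step limit but the exact transition is stable at any
attraction strength. The convergence power experiment uses strength 6 per
tree height: the pull's half-life, ln(2)/6 of tree height, is comparable
to a typical pendant branch on a 100-tip Yule tree, so focal terminal
branches are drawn most of the way to the attractor while deeper history
stays Brownian — a regime that is strong enough to be reliably detectable
yet leaves focal tips visibly distinct.

## Validation experiment sizes

The experiments behind `scripts/acceptance.py` and the acceptance tests
use: 20 random trees (<= 5 tips, <= 3 states) for the enumeration check;
10,000 draws for the path-sampler comparison; 50 syntheses at 400 tips for
ARD recovery; 100 syntheses at 300 tips (p = 6) for rate-ratio recovery and
400 replicates x 99 simulations for its type-I error; 1,000 syntheses at
100 tips x 199 permutations for ANOVA calibration; 100 syntheses at 100
tips x 99 simulations for C1 power; and a 400-tip end-to-end pipeline run.
These sizes complete in a few minutes on one CPU while keeping Monte-Carlo
error well inside the asserted bands.

## Known limitations

* ARD rate magnitudes on few-state characters carry the ridge variance
  described above; report ratios where possible.
* Hidden-rate models, model averaging, and correlated-character tests are
  out of scope, as are OU/EB trait models and diversification analyses.
* C5 counts each lineage once; it does not weight multiple re-entries.
* The allometric-convergence test is non-phylogenetic (as is the
  permutation procedure it follows); group labels are exchangeable under
  its null only if phylogenetic clustering of size is mild.
* GPA assumes landmark correspondence across specimens; the foot template
  in the generators is a synthetic stand-in, not a digitized specimen.
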