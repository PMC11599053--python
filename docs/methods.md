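# Methods

`isletnet` models one mechanism in islet physiology: electrical coupling from
insulin-secreting beta-cells to somatostatin-secreting delta-cells through
connexin-36 gap junctions. At low glucose, K_ATP-channel-driven beta-cell
hyperpolarisation spreads into neighbouring delta-cells and silences
somatostatin secretion; when autoimmune destruction of beta-cells (type-1
diabetes) removes this "electric brake", somatostatin rises and paracrinally
suppresses counter-regulatory glucagon secretion. The package quantifies three
facets of this picture: how robust the delta-to-beta *contact network* is to
beta-cell loss, what the passive *coupling circuit* between a beta- and a
delta-cell transmits, and how secretion relates to insulin content through
*Hill dose-response models*.

## Synthetic islet architectures

Real 3-D islet reconstructions are generally not redistributable, so all
network experiments run on synthetic architectures with the published summary
statistics of islet cytoarchitecture.

Cells are represented by their nuclear coordinates. Placement is random
sequential addition (RSA): candidate points are drawn uniformly inside a
sphere and rejected when closer than `min_separation` to any accepted point,
with a cap of 5000 attempts per cell. The islet radius follows from the cell
count n, the separation d (read as a nominal cell diameter) and a packing
fraction phi via R = (d/2) (n/phi)^(1/3).

Defaults (the "human" preset): n = 1000 cells, composition beta 0.50 /
alpha 0.35 / delta 0.15, intermingled type assignment, d = 10 um,
phi = 0.35. The composition and intermingled arrangement are
literature-typical for human islets; the "mouse" preset instead uses
beta 0.75 / alpha 0.19 / delta 0.06 with a beta-core / alpha-delta-mantle
layout (beta cells assigned to the innermost radial ranks). The packing
fraction default of 0.35 is set by the generator's own algorithm: RSA in 3-D
saturates ("jams") near a volume fraction of 0.38, so densities at or above
that are unreachable regardless of attempt budget — at phi = 0.55 RSA places
only ~two-thirds of 1000 cells, while phi = 0.35 succeeds on every seed we
tried and still yields a dense contact network (~75 cells within 30 um of an
interior cell, mean beta neighbours per delta-cell ~25). Type assignment uses
exact largest-remainder apportionment of the composition followed by a seeded
shuffle, so observed fractions deviate from requested ones by less than one
cell.

What the generator does *not* emulate: lobular and vascular substructure,
cell-size heterogeneity, surface flattening of peripheral cells, and the
spatially organised (rather than uniformly random) beta-cell loss of real
insulitis. Consequences for interpretation: passing the connectivity tests
shows that the *random-graph geometry* of dense islets makes delta-to-beta
contact robust to random deletion; it does not rule out faster connectivity
loss under spatially clustered autoimmune attack, which is deliberately out
of scope.

## Contact networks and ablation

Two cells are in contact when their nuclear Euclidean distance is strictly
less than a threshold, 30 um by default — a surrogate for the reach of
delta-cell membrane projections. Ties at exactly the threshold are excluded;
candidate pairs come from a k-d tree but each is re-checked with the exact
distance, so the graph is identical to the brute-force all-pairs computation
(asserted against an independent oracle in the tests).

Ablation deletes beta-cells one at a time in a uniformly random order and
records, after every deletion, the fraction of delta-cells with at least one
remaining beta neighbour. The update is incremental (per-delta beta-neighbour
counts), which is exactly equivalent to recomputation from scratch and is
likewise oracle-tested. Because islets differ in beta-cell count,
trajectories are aligned on a deleted-fraction grid (default step 0.01) by
last observation carried forward. Within each islet, 20 random deletion
orders are averaged (the replicate count is a package choice; one order is
the minimum meaningful experiment); across islets the mean of per-islet
means is reported with a 95% confidence interval from the t-distribution
over islet means (n − 1 degrees of freedom; the interval degenerates to the
mean for a single islet). The headline readout is the mean connectivity at
75% deletion and the first grid point at which the mean drops below 0.90.

Default experiment size: 6 islets x 1000 cells x 20 replicates, which runs
in a few seconds on one CPU; all numbers in the README were produced at this
size.

## Coupling circuit

At steady state, a beta-cell deflection dV_pre reaches a follower delta-cell
of input resistance R through a junctional conductance g attenuated by the
voltage-divider coupling coefficient k = gR/(1 + gR). The package adopts this
passive two-cell form; capacitive (time-to-peak) behaviour and active
delta-cell conductances are out of scope. Units are fixed project-wide as
pS / GOhm / mV / pA, with the 1e-3 factors from pS*GOhm and pS*mV applied in
one place. The inverse map g = k/((1 − k)R) is an exact algebraic inverse of
k(g, R) and round-trips to machine precision. With the reported deflection
pair (driver 78 mV, follower 15 mV), plausible GOhm-scale follower
resistances (6–22 GOhm) place g between ~10.8 and ~39.7 pS; R = 10.35 GOhm
reproduces the 23 pS working estimate exactly. Measurement uncertainty on the
deflections can be propagated to k and g by the first-order delta method
(independent errors assumed); this is optional output, checked against a
Monte-Carlo oracle in the tests. Ohm's-law input resistance R = dV/dI returns
IEEE infinity as the explicit flag when dI = 0. The minimal suppressive
current is the Ohmic estimate |I| = dV_required/R, reported negative for
hyperpolarising injection.

## Hill secretion models

Secretion versus insulin content is modelled as y = A/(1 + (EC50/x)^h); the
sign of h sets the direction (h > 0 rising, glucagon-type; h < 0 falling,
somatostatin-type) and x = EC50 gives A/2 for any h. A is a free amplitude
normalised to 1 in synthetic data, since published secretion axes are in
unnormalised assay units that are not tabulated. Fitting is plain nonlinear
least squares (`scipy.optimize.curve_fit`) from five jittered starts
(initial A = max(y), EC50 = median(x), sign of h from the slope of y against
log x); standard errors come from the Jacobian-based covariance at the
optimum, and non-convergence or degenerate (constant) data is flagged, never
silent. The Pearson correlation between somatostatin and glucagon uses the
exact t-transform p-value, with no multiple-testing correction (a single
planned test).

The synthetic secretion generator draws insulin contents log-uniformly over
(5, 500) nmol per islet group — a range chosen so that both limbs of sigmoids
with EC50 near 55 nmol are sampled — and adds Gaussian noise (default
sd 0.1), truncating final values at zero because measured secretion is
non-negative.

Known limitation: the zero-truncation makes the noise at the flat limb
asymmetric, which biases fitted |h| slightly toward zero (mean fitted h 1.82
when the generating h is 1.9 at noise sd 0.1). For a joint two-parameter
"within 2 standard errors" recovery event this costs real coverage: about
81-82% of datasets instead of the ~91% an unbiased Gaussian setting would
give. The fitted standard errors themselves are well calibrated (z-score
standard deviation 0.98–1.03 in repeated runs). Analyses that need unbiased
recovery should generate with `noise_sd=0` or fit on untruncated data.

## Numerical and design choices

- Strict `<` at the contact threshold; Euclidean 3-D distance; no periodic
  boundary or surface correction.
- Determinism: every stochastic step takes an explicit seed. Cohort islets
  use fixed integer offsets (seed + i); ablation replicates use
  `numpy.random.SeedSequence` spawning keyed on (islet index, replicate
  index). Identical seeds give bit-identical outputs, including written
  files.
- Architecture TSVs store coordinates at 6 decimal places (sub-nanometre);
  read-write round-trips are exact at that precision.
- Pipeline configs are YAML with unknown keys rejected (fail-fast) and a
  SHA-256 config hash echoed into every summary.
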