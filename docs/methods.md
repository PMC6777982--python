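# Methods

This note documents the models implemented in `lagnav`, the choices made
where the procedure admits more than one reasonable reading, what the
synthetic cohort does and does not emulate, and the problem sizes the test
suite and `scripts/acceptance.py` run at.

## Synchronization lag estimation

Signals are standardized once over the full series, using the population
(1/T) standard deviation; the windowed cross-correlation then divides by
the overlap length n_τ = T − |τ|. This convention makes the zero-shift
self-correlation exactly 1 and needs no per-window re-standardization. The
alternative — re-standardizing each overlap window — changes estimates by
O(1/T) for band-limited signals; we did not find it better behaved and it
breaks the C(0) = 1 identity.

The shift grid is ±10 s rounded down to an integer number of TRs
(±5 samples at TR = 2 s). The integer argmax is refined by the vertex of
the parabola through the peak and its two neighbours:

    δ = (C[k−1] − C[k+1]) / (2 (C[k−1] − 2 C[k] + C[k+1])),  |δ| ≤ 1/2,

clipped to half a sample. Peaks on the grid boundary are returned
unrefined and flagged, so saturated estimates can be excluded; argmax ties
are resolved toward the smallest |shift| and then toward negative shifts,
for determinism and a bias toward synchrony. Constant signals and flat
correlograms raise a typed degenerate-signal error rather than returning
NaN.

Group summaries average the *absolute* lag. Signed lags (positive = right
hemisphere leads) are retained per pair for inspection, but a signed
average would let opposite-direction delays cancel.

Estimator accuracy, measured by the suite: integer-sample delays of
sparse-support test signals are recovered exactly (the correlogram is
symmetric around the peak by construction, see below); band-limited
fractional delays are recovered within 0.1 TR noiseless and within
0.25 TR at noise sd 0.1 — the parabola is an approximation to the smooth
autocorrelation peak, not an unbiased estimator.

## Connectome communication

Weights (streamline counts) are remapped to lengths
L = −log10(W / (max W + 1)), computed on the matrix actually analyzed
(i.e. after density thresholding), which is strictly positive and strictly
decreasing in weight. The variant −log10(W / max W + 1) is exposed behind
`printed_form=True` for auditability only: it maps every edge to a
non-positive length and cannot serve as a cost.

Proportional thresholding keeps the ⌈d · N(N−1)/2⌉ strongest undirected
edges; ties at the cutoff are broken toward the lexicographically smaller
upper-triangle index so thresholding is deterministic. Shortest paths are
Dijkstra on the length matrix. Navigation progresses from the current node
to its neighbour closest in Euclidean distance to the target (ties to the
lower node index), fails on any node revisit or when stranded without
neighbours, and reports three per-pair quantities: summed length Λ^nav,
summed Euclidean hop distance D^nav, and hop count. Efficiency counts
failed or disconnected pairs as zero contribution (1/∞ = 0), not missing.
Navigation efficiency is computed from the length-weighted Λ^nav; hop
counts are retained but not used in the headline statistics.

AUC summaries integrate efficiency over densities 0.10–0.50 in 0.05 steps
by the trapezoid rule (a constant measure c integrates to 0.40 c).

Region-to-lesion distance is the Euclidean distance from the ipsilesional
region's centre of mass to the nearest lesion centroid. Voxelwise lesion
masks are out of scope; with centroid geometry this is the natural reading.

## Synthetic cohort

The generator emulates a clinical resting-state cohort at region level:
2 × 40 mirror-symmetric regions labelled by seven canonical resting-state
subnetworks, TR 2 s, 240 volumes, 14 stroke subjects and 12 controls, one
spherical lesion per stroke subject (radius 10–30 mm).

Pair signals are Gaussian processes band-limited to 0.009–0.08 Hz,
constructed in the frequency domain; the left-hemisphere member is the
right member delayed by the planted lag via exact phase rotation, plus
independent band-limited noise (sd 0.1). Because phase rotation is exact
for periodic signals, fractional-TR lags are planted without
discretization error. For exactness tests a second construction is
provided (`gen_pure_shift_bold`): signals supported on every other sample
with zero-mean support values, for which all odd-lag products vanish
identically, making the windowed correlogram exactly symmetric around an
integer-sample shift and the parabolic estimate exact.

The planted lag field couples the functional effect to lesion geometry:

    τ*(pair) = 2.6 s · exp(−d_surface / 30 mm)
             + 0.25 s · [pair's subnetwork contains a lesioned region]
             + 0.003 s/mm · d_homotopic
             + 0.10 s,

where d_surface is the distance from the ipsilesional region's centre of
mass to the lesion surface. Controls receive a uniform 0.25 s baseline.
The decay term plants the lag–lesion-distance association; the subnetwork
term plants the affected-network effect including intact pairs; the
homotopic-distance term plants the geometric gradient; the coefficients
are calibrated so the group means land near the clinical values the
pipeline is meant to operate at (stroke ≈ 1.05 s, controls ≈ 0.24 s).
ARAT scores decrease linearly in the subject's mean planted lag
(30 − 16 τ̄ plus noise, clipped to 0–57), and homotopic functional
connectivity degrades mechanically with the planted delay and noise.

Connectomes are spatially embedded random graphs: edge probability and
expected integer weight both decay as exp(−d / 40 mm); homotopic pairs are
always connected (a callosal backbone); residual components are patched by
their closest internode edge so the template is connected at full density.
All subjects share one template topology, individualized by multiplicative
lognormal weight jitter (sd 0.1). Stroke connectomes receive
distance-tapered damage: edge weights are attenuated by
1 − 0.9 · exp(−max(0, d − radius)/20 mm) at both endpoints and edges
touching nodes inside the lesion sphere are removed. The taper matters:
with pure node deletion, proportional thresholding re-spends the fixed
edge budget on the intact remainder and lesioned networks can appear
*more* efficient; diffuse attenuation reproduces the expected monotone
loss of efficiency with lesion extent, which is what couples
inter-individual lag to efficiency.

All randomness descends from a single integer seed through named
`SeedSequence` child streams keyed by stage and subject index, so subject
order cannot change any draw and equal seeds give byte-identical cohorts.

What the generator does **not** emulate: hemodynamic response variability
and vascular-territory structure (the lag field is a geometric stand-in,
not a mechanistic claim about neural vs hemodynamic origin), voxelwise
lesion anatomy, tractography biases, negative or bidirectional lags within
a subject, and scanner differences between groups. Passing tests therefore
show that the estimators recover the planted structure under realistic
noise and geometry — not that the clinical effect sizes would replicate.

## Statistical layer

Unpaired comparisons use the pooled-variance Student t test; the
affected-vs-unaffected contrast is a paired t test across stroke subjects,
since both means come from the same individuals. Pair-level Pearson
analyses use natural-log-remapped lag (zeros floored at TR/100 before the
transform); Spearman analyses use raw lag, being rank-invariant. Partial
correlations residualize both variables on the covariates by OLS and use
df = n − 2 − k. FDR control is Benjamini–Hochberg at q = 0.05, applied
within the 40 per-pair tests and, separately, across the headline
statistics. Homotopic functional connectivity for the motor-score
comparison is the zero-lag Pearson correlation averaged over pairs.

On very dense graphs every homotopic pair navigates in a single hop and
D^nav equals the Euclidean distance exactly; the variance-partition OLS is
then rank deficient and those two rows are omitted rather than reported
from a degenerate design.

Calibration, recomputed by the suite and the acceptance script: the t test
rejects at 5.2% on 2,000 matched null Gaussian replicates; across 100 null
cohorts (lag field flattened to the control baseline) at most a few
percent show any per-pair FDR rejection.

## Problem sizes and determinism

Unit tests run on 6–10-pair parcellations and 120–200 volumes; oracle
comparisons use 50 random signal pairs (T ≤ 32), 50 random graphs (N ≤ 7)
against exhaustive path enumeration and step-simulated greedy walks, and
100 random p-vectors against a brute-force step-up. The end-to-end
analyses run the full 40-pair, 26-subject cohort. The complete suite and
the acceptance script each finish in a few minutes on one CPU.

## Known limitations

* The lag estimator is bounded by the shift grid; true lags beyond
  ±10 s saturate at the boundary (flagged, excluded from averages only if
  degenerate — boundary estimates are retained, as in the averaging of
  clinical lag maps).
* Parabolic refinement is biased toward the grid point for very broad
  correlation peaks; the 0.1 TR noiseless bound is empirical, not a
  guarantee for arbitrary spectra.
* Navigation is evaluated on symmetric connectomes only; directed routing
  and other communication measures (diffusion efficiency, communicability)
  are out of scope.
* The per-subject lag–distance correlation loop exists
  (`region_to_lesion_distance` per subject) but no summary statistic is
  attached to it in the results table.
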