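# Methods

This note documents the models, numerical choices and known limitations of
`tunnelgate`. Quantitative claims below are the ones the test suite and
`scripts/acceptance.py` actually compute.

## Geometric tunnel model

A *tunnel* is represented as a spine of spheres from a buried start point
to the molecular surface. Detection works on a regular grid over the
snapshot's padded bounding box:

- **Free-radius field.** The value at a voxel center `v` is
  `min_a (|v − x_a| − r_a)` over all atoms — the radius of the largest
  probe centered at `v` that touches no atom. The reference implementation
  (one KD-tree per distinct van der Waals radius) is exact; the detection
  path uses a capped variant (scatter-min over each atom's influence ball)
  that is exact for every value below the cap (`shell_radius`) and clamps
  the rest, which changes no decision the algorithm makes: the bulk
  predicate compares against the cap and capped voxels are never
  traversed.
- **Bulk and surface.** Bulk solvent is the flood fill, from the grid
  boundary, of voxels with free radius ≥ `shell_radius` (3 Å): wide
  internal voids disconnected from the boundary stay interior. The
  *outside* region is the volume swept by the shell probe — every voxel
  within `shell_radius` of a bulk voxel (a Euclidean distance transform of
  the bulk mask). This closing step is essential: without it a thin
  traversable layer hugs the protein surface between the atom envelope and
  the bulk boundary, and shortest paths can crawl along it to produce
  spurious exits all around the structure. With it, the search domain ends
  exactly where a 3 Å probe can reach, which is the intended meaning of a
  shell-probe surface definition.
- **Search.** Dijkstra over the 26-connected graph of voxels with free
  radius ≥ `probe_radius` (0.7 Å) and outside the surface region, with
  edge weight `|Δv| × r(target)^(−cost_exponent)` and `cost_exponent = 2`,
  the classical inverse-squared-radius cost that makes wide paths cheap.
  Ties are broken by lexicographic voxel index, so results are exactly
  deterministic and independent of atom order. Every voxel adjacent to the
  outside region is an exit candidate with the cost of its path; candidates
  are accepted cheapest-first, suppressing any exit within
  `duplicate_threshold` (4.5 Å) of an accepted one. Accepted paths are
  trimmed by `shell_depth` (4 Å) of arc length from the surface end
  (keeping at least two spheres) and reported as spines; the bottleneck
  radius is the minimum sphere radius, the length the polyline length.
- **Accuracy.** The bottleneck of a straight channel is recovered within
  about one grid spacing: the path runs through voxel centers that may sit
  up to `spacing·√3/2` off the channel axis. The default spacing is 0.5 Å;
  synthetic end-to-end runs use 0.8 Å (detection decisions there hinge on
  radii differences of ≥ 0.9 Å, far above the grid error), and the
  recovery tests use 0.25 Å.
- **Start point.** Either explicit coordinates or the mass-weighted
  centroid of named residues (optionally heavy atoms only — whether
  hydrogens should participate is exposed as a flag rather than assumed).
  A start with free radius below the probe is snapped to the nearest
  admissible voxel within 3 Å (logged); a start inside the bulk/outside
  region is an error ("start point not buried").

The grid search is a deliberate approximation of Voronoi-based tunnel
detection: the two share the probe constraint, the inverse-power cost and
the shell-probe surface, but voxelization quantizes both geometry and
cost, so results are validated against engineered ground truth, not
against any external tool sphere-for-sphere.

## Clustering model

The tunnel-to-tunnel distance resamples each spine to `spine_samples`
(20) points equidistant in arc length and averages the point-wise
Euclidean distances under that correspondence; it is symmetric, zero for
identical spines, and equals the offset for parallel equal-length spines.
Within a replicate, average-linkage agglomerative clustering is cut at
`within_threshold` (4.5 Å); per cluster and frame only the cheapest tunnel
is kept, and clusters observed in no more than `min_occurrence_fraction`
(5 %, strict inequality) of frames are discarded. Cluster ids are assigned
by descending occurrence.

For the cross-replicate merge, tunnels with bottleneck < 0.7 Å or length
< 5 Å are excluded, each surviving cluster is represented by the
point-wise mean of its members' resampled spines, and Ward linkage over
representative distances is cut at `merge_cutoff` (1 Å). Supercluster ids
follow descending total tunnel count. Because Ward merge heights are not
raw distances, the absolute cutoff is calibrated on the synthetic system
(where representative spines of the same channel nearly coincide across
replicates and different channels are tens of Å apart) and is not directly
comparable to thresholds of other implementations. Batch processing of
long trajectories is provided as frame-batched detection whose
concatenated output is identical to unbatched processing by construction;
clustering always runs on the full tunnel set, because per-batch
clustering with re-merging cannot guarantee result invariance.

## Dynamics statistics

- Detection frequency: fraction of frames with a present bottleneck
  strictly above `detection_threshold` (0.7 Å, the probe radius).
- Open-state dwells: maximal runs of consecutive frames with BR ≥
  `open_threshold` (1.4 Å); an undetected frame is closed (an undetected
  tunnel has no radius above the threshold). A run's duration is its frame
  count × frame spacing, so a single open frame counts one spacing
  (0.02 ns). Runs touching either end of the series have unknown true
  duration; the default policy (`flag`) keeps them, flagged, and excludes
  them from histograms — uncensored statistics without discarding the
  bookkeeping — with `drop` and `include` as alternatives. With `include`,
  run durations sum exactly to spacing × open-frame count.
- Histograms: half-open bins with a final open overflow bin, normalized by
  the count of contributing values, so masses sum to one. BR bins default
  to 0.1 Å steps from 0.7 to 3.0 Å; dwell bins to a 13-edge geometric
  ladder from 0.02 to 8 ns (the bin ladder is configurable; no canonical
  set of edges exists for dwell data). Dwell histograms are averaged
  across replicates with an across-replicate SD (ddof = 1).
- Discovery curves: per replicate, the step function counting distinct
  superclusters first detected by time t; the aggregate reports mean and
  min/max envelope on the union time grid and each replicate's saturation
  time (last first-detection).

## Synthetic data and what it does (not) establish

The generator emulates the statistical structure of a gated-tunnel MD
study: several tunnel branches of differing prevalence, two-state gating
with exponential dwell laws, fixed 20 ps observation spacing, Gaussian
radius noise, and 3–4 independent replicates per condition, with two
conditions allowed different kinetics. Gating is simulated in continuous
time and then sampled — not per-frame Bernoulli — so latent dwell times
are exactly exponential and sub-frame excursions are aliased precisely as
a 20 ps trajectory writer would alias them. Radius noise is truncated at
zero; with the default `noise_sd = 0.05 Å ≤ r_closed/3` the truncation
bias is negligible. Channels must be carved wider than
`r_open + ~6·noise_sd` so the noisy open state never exceeds the geometric
maximum.

Default toy scale: shell outer radius 18 Å, cavity 6 Å, lattice 1.2 Å,
pseudo-atom radius 1.7 Å. The end-to-end study tests use a compact variant
(outer 11 Å, cavity 4 Å, shell thickness 7 Å, two antipodal channels of
free radius 2.0 Å, gate ring one Å beyond the cavity) and 2 conditions ×
3 replicates × 2,000 frames at a 0.8 Å grid; the reproduction script uses
800 frames per replicate. These sizes make every statistic's sampling
error analytically predictable while keeping full per-frame detection
practical on one CPU.

What passing these tests shows: the geometry engine recovers engineered
bottlenecks to grid accuracy; the clustering recovers the true branch
structure and per-frame membership (≥ 99 % agreement with the latent
states); the statistics recover stationary probabilities and dwell laws
within their sampling error. What it does not show: behavior on real
proteins with flexible backbones (the toy moves only gate atoms), curved
or branching tunnels, water molecules, or radii assignments matching any
particular force field.

## Statistical calibration

Welch's unequal-variance t-test (two-sided, α = 0.05, Welch–Satterthwaite
degrees of freedom) compares conditions per (supercluster, metric) cell;
cells with fewer than two replicate values in either condition are marked
untestable. Both-zero-variance samples are handled explicitly (equal
means → t = 0, p = 1; unequal → ±∞, p = 0) instead of dividing by zero.
No multiple-testing correction is applied by default, matching the
raw-per-metric reporting convention; Holm adjustment and a pooled-variance
Student's t variant are available as options.

At three replicates per group Welch's test is conservative by
construction — under exact normality its measured type-I error is ≈ 0.034
at nominal 0.05, because the Satterthwaite approximation over-corrects at
tiny n. The calibration test therefore checks the two-sided binomial band
around α at four replicates (where the empirical rate is ≈ 0.04–0.05) and
a one-sided no-inflation bound at three. Users comparing 3-replicate
studies should read non-significance with this conservatism in mind.

## Known limitations

- Grid quantization bounds bottleneck accuracy by roughly the spacing;
  halving the spacing costs ~8× memory and time per frame.
- The spine metric uses arc-length correspondence without reversal or
  partial matching; tunnels sharing a mouth but diverging internally can
  land in one cluster if their mean point distance stays under threshold.
- PDB round trips re-derive vdW radii from the element table, so
  pseudo-atom radii differing from their element's table value survive
  in memory but not through PDB serialization.
- Absent frames are closed for dwell purposes by definition; if detection
  misses a genuinely open frame (grid error near threshold), a dwell run
  splits in two. The synthetic tests place state radii far from the
  thresholds so this is not exercised; near-threshold gating on real data
  will fragment dwells.
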