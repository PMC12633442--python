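# Methods

## Problem and scope

`safconn` evaluates reconstructions of the short association fibers (U-fibers)
of the human prefrontal cortex (PFC) against the ground truth available from
primate tract-tracing histology. Fourteen Brodmann-style areas — grouped into
the five canonical PFC partitions (dl-PFC: 8, 9, 9/46, 46; vl-PFC: 44, 45, 47;
frontal pole: 10; OFC: 11, 13, 14; ACC: 24, 25, 32) — define C(14, 2) = 91
candidate connections. The package covers everything downstream of fiber
tracking: bundle cleaning, voxel density maps, presence calls, classification
against the histology reference, confusion statistics, and test-retest /
between-subject reproducibility. Diffusion modelling, tracking, surface
parcellation and spatial normalization are out of scope; a synthetic phantom
generator supplies geometrically realistic inputs in a common space instead.

## Packaged reference tables

Two plain-text tables ship in `safconn/data/`:

* `histology_reference.csv` — present/absent status per connection from the
  tract-tracing literature: 72 present, 19 absent.
* `outcome_table.csv` — the per-connection population outcome label
  (RTP / TP / TN / FP / FN) of the reference tractography analysis.

The outcome table was transcribed from the published per-connection
descriptions and reconciled against the published per-partition tallies. The
published tallies are **not globally self-consistent**: under the stated
convention (a connection counts toward every partition containing one of its
endpoints, so the partition totals are 46 + 36 + 36 + 36 + 13 = 167 = 91 + 76),
the label-wise identity `intra = 2·overall − Σ(partition)` gives −1
intra-partition false negatives, which is impossible. The packaged table
therefore reproduces the published overall counts (49 TP / 41 RTP / 17 TN /
13 FP / 12 FN), the dl-PFC, vl-PFC, frontal-pole and ACC count vectors, every
per-partition RTP count, and all published rounded percentages (overall
accuracy 73, sensitivity 80, precision 79, specificity 57; partition
accuracies 74 / 75 / 61 / 58 / 100; vl-PFC sensitivity 87), while the OFC
TP/TN/FP/FN split deviates by two reclassified connections (ours
12/10/10/5/9 against the published 14/10/8/4/10 — the published OFC vector
cannot coexist with the others). Entries whose label required reconciliation
(conflicting subsection descriptions, or tally-driven adjustment) carry a
note in the table's `provenance` column.

Two published figures disagree with their own counts and are deliberately
*not* reproduced as printed; the package always reports computed values:

* dl-PFC sensitivity prints as 82% where the counts give 26/32 = **81.25%**
  (reported rounded as 81);
* OFC specificity prints as 66% where the counts give **66.7%** (reported
  rounded as 67);
* the frontal pole is summarized in one place as 12 TP (9 RTP) / 1 TN with
  100% accuracy and in another as 11 TP (8 RTP) / 1 TN / 1 FP with 92%; the
  packaged table follows the first (the summary-level figures).

Rounding of percentages for display is half-away-from-zero (66/91 = 72.5 →
73); unrounded values are always exposed alongside.

The histology reference reconstructs the present/absent matrix from the
classification rules: every TP/RTP/FN connection is histology-present, every
TN is histology-absent, and of the 13 FPs exactly two are histology-absent
(19 = 17 + 2) with the remaining eleven being *trajectory* false positives
(histology-present but consistently implausible reconstructions). The two
histology-absent FPs are (44, 25) and (46, 32), the endpoints the anatomical
descriptions single out as lacking cingulate precedence; this is an inference,
flagged in the provenance column, since the original matrix figure is not
machine-readable.

## Bundle model and cleaning

Streamlines are polylines in world RAS mm. Per-tract constraints follow the
reference analysis: a tract-specific maximum length in [38, 125] mm (length
filtering keeps streamlines at or below the cap) and a ceiling of 2 × 1,000
streamlines per connection.

Outlier rejection is a transparent re-implementation of script-based bundle
cleaning, not a wrap of the original tool: streamlines are resampled to 20
equidistant points; pairwise distance is the symmetrized mean closest-point
distance (orientation-invariant); the medoid minimizes the summed distance;
streamlines farther from the medoid than `median + 3·MAD` are removed
(threshold factor configurable, default 3; the medoid itself is never
removed). The rule is deterministic, idempotent on the shipped fixtures, and
returns sub-two-streamline bundles unchanged.

## Density maps and metrics

Density maps live on isotropic, axis-aligned grids (default 1 mm, matching
the resampled resolution of the reference analysis), 0-based indices,
half-open voxel intervals, floor-based point-to-voxel mapping. A voxel's
count is the number of *distinct streamlines* that traverse it, with
traversal computed exactly: each segment is split at every integer grid-plane
crossing and each sub-interval assigned to the voxel containing its midpoint.
The per-streamline (binary) counting rule is the track-density-imaging
convention; the reference publication does not state its counting rule, so
this choice is fixed here and validated against a dense-supersampling oracle
in the tests.

* **Dice** — binary overlap of supports; defined as 1 for two empty maps.
* **Weighted Dice (wDice)** — with per-bundle normalized weights
  `w_x(v) = counts_x(v)/Σ counts_x`,
  `wDice = Σ_{v ∈ A∩B} (w_a(v) + w_b(v)) / 2`. This is the
  streamline-density-weighted form from the tractography-reproducibility
  literature; it is 1 iff the supports coincide and 0 iff they are disjoint.
* **Bundle adjacency (BA)** — mean nearest-neighbour distance (mm) between
  voxel centres of the non-overlapping support portions, averaging the two
  directed means over the directions whose difference set is non-empty
  (a nested pair yields the one-sided mean; identical supports give 0).
  Whether the reference analysis pooled voxels across directions or averaged
  directed means is unstated; the directed-means average is fixed here.
  Nearest neighbours are exact (KD-tree).

## Presence and classification

A subject expresses a connection when its cleaned bundle retains at least
`min_streamlines_present` streamlines (default 5 of a 2,000 ceiling; the
reference analysis's "no or few streamlines" is not quantified). At the
population level (all thresholds strict):

| histology | present in > 50% of subjects | plausible | label |
|-----------|------------------------------|-----------|-------|
| present   | yes                          | yes       | TP; **RTP** if > 80% |
| present   | yes                          | no        | FP (trajectory) |
| present   | no                           | —         | FN |
| absent    | yes                          | —         | FP |
| absent    | no                           | —         | TN |

Population plausibility is a majority vote (strict > 0.5) over the present
subjects' flags. Plausibility itself is a recorded visual-QA flag; when no
flag is supplied a geometric heuristic substitutes: a streamline is irregular
when its end-to-end distance is below 0.25 of its arc length (looping) or its
summed turning angle exceeds 3π; a bundle is implausible when more than half
its streamlines are irregular. The heuristic is a stand-in for human QA and
is validated only against the phantom's constructed plausible/spurious modes.

Confusion statistics: accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), precision = TP/(TP+FP), each ×100; RTP counts
inside TP. A statistic with a zero denominator is reported as missing (None),
never as 0 or 100. Partition summaries include every connection with at
least one endpoint in the partition.

## Reliability designs

Within-subject reliability compares each subject's test and retest density
maps; between-subject variability compares all unordered subject pairs (an
option subsamples pairs with a fixed seed for large cohorts). Pairs with an
absent bundle on either side are excluded from the means and reported as an
exclusion count, since both metrics are undefined on empty supports. Reported
means ± sd pool all compared pairs globally (the pooling order in the
reference analysis — per-connection first versus global — is unstated; global
pooling is fixed here). The population-scale magnitudes of the reference
analysis (e.g. dl-PFC within-subject wDice 0.67 ± 0.25 versus between-subject
0.29 ± 0.15) depend on real diffusion data and are not reproduced; the
package's tests assert the *ordering* property instead: whenever
between-subject displacement dominates session displacement, within-subject
wDice exceeds between-subject wDice and within-subject BA is below
between-subject BA.

## Phantom generator

The phantom emulates the geometry the pipeline consumes, in a common 120³
1-mm grid standing in for normalized group space:

* **Layout** — the 14 ROIs are 6-mm spheres placed by a Fibonacci spiral (with
  a seeded azimuthal rotation) on a 50-mm hemispheric shell capped at 72°,
  chosen so that every centroid arc falls within the [38, 125] mm tract-length
  window (arcs for the closest pairs are deepened adaptively to reach ≥ 40 mm).
* **Plausible bundles** — quadratic Bézier arcs from uniformly sampled points
  inside the two ROI spheres, apex displaced outward from the shell by the arc
  depth (default 10 mm), Gaussian control-point jitter giving a within-bundle
  spread of 1.5 mm (sd). Streamlines violating the 125-mm cap are redrawn.
* **Spurious bundles** — 1.5-turn loops around a jittered centre between the
  ROIs; end-to-end distance far below a quarter of arc length, so the
  plausibility heuristic rejects them by construction.
* **Population structure** — presence is a per-subject Bernoulli draw per
  connection (default probability 0.9; both sessions of a subject share the
  draw, since presence models a stable anatomical property), a per-subject
  Gaussian bundle displacement (sd 3 mm) shared across sessions models
  individual anatomy, and a smaller per-session displacement (sd 1 mm) models
  scan-rescan variation — matching the qualitative structure of the reference
  cohort (high test-retest reliability, larger between-subject variability).
  The default bundle size is 800 streamlines against the 2,000 ceiling.
* **Seeding** — one root seed expands through spawn keys
  `(purpose, subject, [session,] connection)` (purposes: presence, subject
  shift, session shift, geometry), so any single bundle regenerates in
  isolation, bit-identically. An observation-level fast path draws the same
  presence stream without synthesizing geometry, for large replicate studies
  of the classification stage.

What the phantom does **not** model: diffusion signal and tracking error,
cortical folding, fiber crossings, partial-volume effects, or realistic
streamline count variation. Consequently, passing phantom tests demonstrates
correctness of the evaluation machinery under known ground truth — not
tractography fidelity on real data.

## Numerical and design choices

* Canonical area order (8, 9, 46, 9/46, 44, 45, 47, 10, 11, 13, 14, 24, 25,
  32) fixes connection-key serialization and joins.
* Grids are isotropic-only; the NIfTI affine is diagonal with the translation
  at the centre of voxel (0, 0, 0); anisotropic volumes are rejected on read.
* TCK is the supported streamline dialect (round-trips exactly in count and
  to float32 precision in coordinates).
* Degenerate inputs: empty bundles are valid (absent connections); two empty
  supports give Dice 1 but undefined wDice/BA; classification requires at
  least one observation; reliability requires at least one complete pair.
* Problem sizes in the shipped tests and acceptance script are deliberately
  desk-scale (tens of subjects, tens of streamlines per bundle, one or a few
  connections for the voxel-heavy stages; 200 observation-level replicates at
  n = 50 for classification recovery), chosen as the package's own default
  study conditions for a laptop-class reproduction.

## Known limitations

* The OFC count vector of the packaged outcome table cannot simultaneously
  match the published OFC figures and the (mutually inconsistent) published
  overall/partition tallies; the deviation is confined to two OFC-partition
  connections and documented above.
* The plausibility heuristic is a geometric caricature of expert visual QA.
* Bundle adjacency is support-based; two bundles differing only in density
  within identical supports are indistinguishable to BA (and have wDice 1).
* The phantom's Bézier arcs have no thickness gradient; density cores are
  sampling artifacts of endpoint/control jitter rather than modelled axon
  packing.
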