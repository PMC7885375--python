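# Methods

`tactconn` analyses sensor-space EEG functional connectivity in a
two-condition (baseline vs tactile stimulation), two-forearm,
two-group (stroke vs unimpaired control) design, and ships a synthetic
cohort generator so that every stage of the analysis can be validated
end to end without access to patient recordings.

## Signal conditioning

Continuous recordings are band-pass filtered (default 1–45 Hz),
re-referenced to the instantaneous average over all channels, passed
through a pluggable artifact hook, and cut into trials: 12 s retained
from each condition onset, segmented into three non-overlapping 4-s
epochs at 1000 Hz. Subjects with left-hemisphere lesions can be flipped
along the mid-sagittal plane (homologous channel exchange, exact
involution on the shipped symmetric montage) so affected hemispheres
align across a group.

The band-pass is zero-phase (forward–backward), realized as a cascade of
a 4th-order Butterworth high-pass and a 12th-order Butterworth low-pass.
The asymmetric orders reflect the asymmetric demands: the high-pass must
reach 40 dB one octave below its edge (easy), while the low-pass must
reach 40 dB only 10 Hz above a 45 Hz edge — a 0.3-octave transition that
requires the steeper filter even with the doubled (two-pass)
attenuation. Pass-band ripple is < 1 dB away from the band edges; at the
edges themselves any Butterworth is 6 dB down by construction.

## Connectivity: imaginary coherence

Per trial, cross-spectra are Welch estimates on 2-s Hann windows with
50% overlap (three segments per 4-s trial; 0.5 Hz grid). Connectivity
between channels i and j is the absolute imaginary part of coherency
`C_ij(f) = S_ij / sqrt(S_ii S_jj)`, averaged (or peaked) over a band —
by default beta-2 (20–25 Hz, 11 bins, inclusive edges); beta-1
(15–19 Hz) and beta-3 (26–30 Hz) are predefined. The imaginary part
vanishes for zero-lag shared signals, so volume-conducted common sources
produce no spurious connectivity; only phase-lagged coupling survives.

Two estimator routes exist:

* **per-trial** (default): `|Im C|` per trial, band-collapsed; these
  values feed trial-wise and subject-wise statistics. With only three
  segments the estimator has a large folded-noise floor (~0.34 for
  independent signals), which is common to both conditions and cancels
  in paired contrasts.
* **pooled**: cross-spectra averaged over all segments of all trials
  *before* normalization. The signed imaginary parts of incoherent pairs
  cancel, so the floor shrinks like 1/sqrt(total segments). Used for
  condition-level spectra and the volume-conduction null check, where
  the per-trial floor would mask the comparison.

## Stimulation-induced connectivity (SFC)

Per group and stimulated forearm, each channel pair's subject-wise mean
connectivity under stimulation is compared to baseline with a paired t
across subjects. Suprathreshold edges (two-sided p below the
cluster-forming threshold, default 0.005) of like t-sign are grouped
into clusters; two edges are adjacent when they share an endpoint
(default) or, optionally, when their endpoints are montage neighbours
(Delaunay triangulation with long edges pruned at 1.5x the median edge
length). Isolated suprathreshold edges are discarded. Each cluster is
scored by its summed t; the null distribution of the maximum |score| is
built by exchanging condition labels within subjects (sign flips of the
paired differences). The maximum score is invariant under the global
sign mirror, so the 2^n flip patterns form 2^(n-1) classes; with 8
subjects and the default 1000 requested permutations all 128 classes are
enumerated and the test is exact. Sampled permutations use the +1
Monte-Carlo correction. All clusters with permutation p < 0.05 are
retained; the maximum statistic enters only the null.

Two defaults depart from the loosest conventional choices, for
localization: the cluster-forming threshold is 0.005 (at 8 subjects the
t distribution has heavy tails; at 0.05 roughly 5% of the 1891 pairs are
suprathreshold by chance and percolate into any significant cluster,
diluting its topography), and edge adjacency is shared-endpoint only
(the neighbour closure percolates on a 62-channel montage). Calibration
was checked by null simulation: at cluster-forming 0.05 the family-wise
error is indistinguishable from nominal (0.048, n=500 sims at 16
channels / 8 subjects / 200 permutations); at 0.005 the test is
conservative (0.029) because rejection becomes formation-limited. It is
never anticonservative.

Topography: retained edges' t-values are normalized by the maximum
absolute retained t and summed per channel. The hemispheric
lateralization (HL) degree is 100 x (SFC channels contralateral to the
stimulated forearm) / (all SFC channels); integer display rounds half
away from zero. Midline channels count in the denominator only.

## Binary networks and multiscale indices

Per subject and forearm, the k-th stimulation trial is paired with the
k-th baseline trial (session order); a paired t across the 9 trial pairs
per channel pair, Benjamini–Hochberg corrected over all 1891 pairs at
q = 0.05, yields the subject's 0/1 adjacency matrix. On it:

* **large scale** — global efficiency `E_glo` (mean inverse BFS
  shortest-path length over ordered pairs; disconnected pairs contribute
  0), local efficiency `E_loc` (mean of `E_glo` over each node's
  neighbour-induced subgraph; nodes with < 2 neighbours contribute 0),
  smallworldness `SW = (E_loc/E_loc_r) / (E_glo/E_glo_r)` against the
  mean of 100 seeded G(n, m) random references with matched node and
  link counts. `SW` is NaN (with a warning) when the references carry no
  triangles.
* **intermediate scale** — interdensity `K_inter` = inter-hemispheric
  links / N_s^2 and per-hemisphere intradensity `K_intra` = within-
  hemisphere links / (N_s(N_s-1)/2), N_s = 28 channels per hemisphere.
  The intra normalization counts unordered pairs so that a complete
  hemisphere gives exactly 1. Equal hemisphere sizes are required;
  midline channels belong to neither set.
* **small scale** — per-node interdegree `D_inter` (links crossing
  hemispheres) and intradegree `D_intra` (links within the node's
  hemisphere); midline nodes report 0 by convention.

All indices are verified exactly against a brute-force path-enumeration
oracle on graphs of <= 8 nodes and against networkx.

## Group statistics

Each scalar index is compared between stimulated forearms with a
two-sided paired t after a Shapiro–Wilk screen on the differences
(p <= 0.05 adds a Wilcoxon signed-rank p alongside, with a warning).
Effect size is Cohen's d_z (mean difference / SD of differences); the
common-language effect size is reported as a labelled secondary
estimator. 95% CIs are t-based per limb. Node-level (D_inter, D_intra)
limb contrasts are Benjamini–Hochberg corrected across the 62 channels,
separately per index family.

## Synthetic cohorts

The generator reproduces the study design: per group, 8 subjects x
2 forearms x 2 conditions x 9 four-second trials at 1000 Hz on a
62-channel 10–20 montage (standard 64-channel cap minus ground and
reference; positions symmetrized so the mid-sagittal flip is exact) —
288 trials per group. Randomness is counter-based: one global seed
expands to per-(group, subject, limb, condition, trial) substreams, so
cohorts are bit-reproducible and independent of generation order.

Each trial consists of:

* **background noise** — pink (1/f) noise per channel, SD 1 (arbitrary
  units standing for microvolts).
* **planted edges** — per edge, a band-limited Gaussian source injected
  into one channel and an integer-sample delayed copy into the other
  (default 20–25 Hz, 12.5 ms ~ a quarter cycle at 20 Hz). Source
  amplitudes are jointly calibrated by fixed-point iteration so each
  edge's in-band coherence magnitude matches its requested strength
  despite shared channels and mixer power; per-channel strength sums are
  projected below 0.9 (a channel's sources cannot claim more than its
  whole band power). Default stimulation layout: three chains of
  strength-0.45 edges over the somatosensory and temporal region
  contralateral to left-forearm stimulation (12 edges, 16 channels).
* **lateralization** — a fraction `f` (default 0.9) of the planted
  stimulation edges stays contralateral; the complementary
  round((1-f) n) edges are mirrored to the ipsilateral side, the same
  subset for every subject of a group x limb.
* **diffuse recruitment** — a few latent sources, each broadcast to ~15
  channels with lags drawn from three phase groups a third of a beta-2
  cycle apart. Every cross-group pair sharing a source carries genuine
  imaginary coherence, and the tri-partite structure supplies the
  triangles that give subject networks nonzero local efficiency. Channel
  sets are disjoint per source, avoid planted-edge channels (power
  sharing would dilute both below the 3-segment detection floor), and
  are redrawn per subject — so the diffuse component sets network
  density without aligning into group-level SFC. The stroke
  specification plants a denser diffuse component plus distributed
  frontal/temporal/parietal edges for the affected forearm and a sparser
  one for the unaffected forearm, yielding the expected
  affected-vs-unaffected differences in E_glo, E_loc and K_inter.
* **volume-conduction nuisance** — one instantaneous (zero-lag) source
  mixed into four central channels; it adds real coherency only and is
  suppressed by the imaginary part.

What the generator does *not* emulate: dipole forward models and
realistic scalp topographies, physiological artifacts (ocular, muscle),
non-stationarity within trials, and realistic inter-subject variability
beyond layout randomization. Passing tests therefore demonstrate that
the estimators, statistics and indices recover planted structure under
controlled conditions — not that the pipeline's defaults are optimal for
any particular real recording.

## Numerical and procedural choices

* Welch scaling matches `scipy.signal.csd` (density, one-sided);
  segments are demeaned before tapering.
* ImCoh is clipped to [0, 1]; the signed coherency remains available.
* Identical conditions give t = 0, p = 1 (a well-defined null);
  constant *nonzero* paired differences raise (t would be infinite).
* BH FDR uses `statsmodels.stats.multitest.multipletests`.
* G(n, m) references and all other randomness accept explicit seeds;
  pipeline reports are byte-identical across runs with equal seeds.
* Problem sizes in the test suite: oracle equivalence uses 200 random
  graphs of <= 8 nodes; null calibration uses 500 simulations at 16
  channels / 8 subjects / 200 permutations; lateralization recovery uses
  8 subjects x 9 trials on one forearm (144 trials per run); the
  determinism check runs the pipeline at 4 subjects x 5 trials with 150
  permutations and 20 random references.

## Known limitations

* The per-trial ImCoh estimator at three segments is strongly biased
  upward for weak true coherence; analyses relying on per-trial absolute
  values should treat them as contrast material only.
* The exact (mirror-class) permutation test is only available for paired
  two-condition designs; nothing beyond sign-flip exchange is
  implemented.
* Smallworldness of sparse FDR-thresholded networks is noisy and can be
  undefined (NaN) when random references carry no triangles; group
  comparisons skip undefined values with a logged warning.
* EDF writing supports whole-second recordings at integer sampling rates
  (one-second records); arbitrary lengths round-trip through the
  delimited format.
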