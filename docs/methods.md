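# Methods

## Visibility graphs

The natural visibility criterion connects samples (t_a, y_a) and
(t_b, y_b) iff every intermediate sample lies *strictly* below the
straight line between them. The inequality is taken literally: an
intermediate sample exactly on the sight line blocks visibility, and no
numerical epsilon is applied. This makes the construction deterministic
and exactly reproducible, at the cost that data containing exactly
collinear runs (e.g. quantised integer plateaus) may produce sparser
graphs than a jittered version of the same data would; users with such
data should add a small jitter before graph construction. Consecutive
samples are always adjacent, so every visibility graph contains the
temporal Hamiltonian path and is connected. The implementation scans,
for each left endpoint, the running maximum of slopes to later samples
(O(n²)); tests verify it edge-for-edge against the direct O(n³)
definition.

Two useful consequences, both covered by property tests: the graph is
invariant under affine rescaling of either axis (y → a·y + b with a > 0,
t → c·t + d with c > 0), and strictly convex stretches of signal
collapse into complete subgraphs while strictly concave stretches give
bare paths. These two facts drive everything about waveform
discrimination below.

## Maxclique enumeration and the K(G) operator

Maximal cliques are enumerated with Bron–Kerbosch with pivoting
(`networkx.find_cliques`) and reported in a canonical order (each clique
sorted, cliques sorted lexicographically) so that K(G) vertex ids and
exports are reproducible run to run. The maxclique graph K(G) — one
vertex per maxclique, edges between intersecting cliques — is built by
pairwise intersection tests over the canonical list. Clique counts can
grow exponentially (Moon–Moser graphs reach 3^(n/3)), so enumeration
aborts with a clear error beyond a configurable ceiling (default 10⁶);
the decimated burst graphs this package builds stay orders of magnitude
below it.

The per-burst feature set applies the parameter trio (Δ, ω, number of
maxcliques) to both G and K(G); the "number of maxcliques of K(G)"
applies the operator twice, i.e. it is |K(K(G))|.

## Burst segmentation

The recording is cut around amplitude peaks: candidate peaks are local
maxima above the upper threshold; peaks closer than the minimum peak
distance are pruned greedily, tallest first (`scipy.signal.find_peaks`
`distance` semantics); a peak is only accepted as a *separate* burst if
the trace falls below the lower threshold between it and the previously
retained peak; each retained peak receives a fixed-width window centred
on it, clipped at the recording bounds, with overlapping windows
truncated at the midpoint between peaks. Widths and distances are in
samples; the CLI converts from seconds when a sampling rate is given.

A practical note that shaped the defaults: a window wider than its burst
includes burst-free baseline, and the visibility structure of a noise
floor is invariant to the noise amplitude (the affine invariance above),
so baseline stretches inject clique counts that no amount of noise
reduction removes. The default window width in the synthetic pipeline
therefore equals the *shortest* burst duration, keeping windows inside
their bursts.

## Decimation

"Reducing the sampling frequency to p percent" keeps every k-th sample,
k = round(100/p) (ties away from zero), preserving exact amplitudes.
No anti-alias filter is applied on purpose: the visibility condition
compares raw sample values, and interpolated values would change the
graph.

## K-means classification

Lloyd's algorithm with k = 2, k-means++ initialisation from a caller
seed, 10 restarts, ≤ 300 iterations (scikit-learn). Default feature
pair: clique number and number of maxcliques of the maxclique graph,
the best-separating pair. The cluster whose centroid has the larger
number-of-maxcliques coordinate is labelled "sigh"; for pairs without a
count feature, the cluster with the larger raw centroid norm.

Standardization (on by default) z-scores the *log10* of the features.
All six features are positive counts, and |K(K(G))| is heavy-tailed:
across bursts of one synthetic recording it ranges over several orders
of magnitude. On a linear scale a single extreme burst dominates the
within-cluster sum of squares and K-means degenerates into splitting
that burst off; on the log scale cluster separation reflects ratios,
which is the scale on which the two waveform classes actually differ.
`standardize=False` clusters in raw feature space.

## Classifier-comparison statistics

Pearson's chi-squared on sigh/non-sigh count tables goes through
`scipy.stats.chi2_contingency`; the Yates continuity correction applies
only at df = 1 and moves observed counts at most halfway to their
expectation, so identical count rows give exactly 0. McNemar's
statistic is computed from the off-diagonals b, c of whatever 2×2 table
it is given: (|b−c|−1)²/(b+c) with continuity correction (the
R `mcnemar.test` convention, no clamping), (b−c)²/(b+c) without. Two
table builders cover the two analyses in circulation:
`successes_failures_table` stacks each classifier's (correct, incorrect)
counts against a reference — McNemar on this matrix compares one
classifier's failures with the other's successes — while
`discordance_table` builds the orthodox paired table whose off-diagonals
count bursts on which exactly one classifier is right. They are not
equivalent; choose deliberately. P-values use the χ²₁ survival
function and a Bonferroni helper caps adjusted p at 1.

## Synthetic recordings

The generator emulates integrated inspiratory motor output: non-sigh
bursts every 7–8 s, sighs replacing the due burst every 30–40 s, burst
durations 0.3–0.8 s, amplitudes ~1.0 (non-sigh) vs ~2.5 (sigh) arbitrary
units with Gaussian jitter, additive baseline noise (sd 0.0005 by
default), all at a 4 kHz sampling rate typical of nerve-recording
acquisition. After the standard reduction to 5% of the sampling
frequency, one analysis window holds ~60 samples.

Waveform shapes encode the two classes' known character:

* **Non-sigh** — a raised-cosine dome with a gentle "garland" scallop:
  convex sub-lobes meeting at upward cusps every 30 ms (depth 15% of the
  local envelope), a stylised picture of stepwise motor-unit
  recruitment. Convex lobes collapse into single maxcliques, so the
  graphs are small and — because the lobe curvature everywhere dominates
  the baseline noise — stable against the noise draw: |K(K(G))| sits in
  single digits for essentially every non-sigh burst.
* **Sigh** — a longer, flat-topped envelope carrying a smaller leading
  hump and a tall, narrow main peak (the biphasic shape; with noise and
  ripple switched off the envelope has exactly two local maxima above
  half-maximum, for any biphasic-gap setting), multiplied out with a
  band-limited stochastic ripple (correlation time 15 ms) whose local
  RMS is normalised so every sigh carries the same fluctuation density.
  The ripple is the defining feature: many small fluctuations fragment
  the visibility graph into dozens of interlocking maxcliques, inflating
  every graph parameter and |K(K(G))| most of all.

The biphasic gap defaults to 0.15 of the burst duration so that both
humps of every sigh fit inside the fixed analysis window; the window in
turn equals the shortest burst duration so that no window contains
baseline (see segmentation above).

All randomness flows through a single `numpy` Generator seeded from the
config; the per-burst draw order (duration, amplitude, ripple, noise) is
fixed, so fixtures are stable across releases.

**What the generator does and does not capture.** It reproduces the
timing statistics, the amplitude ordering, the biphasic sigh shape, and
— by construction — the "smooth burst vs fluctuation-rich burst"
contrast that drives the graph parameters in real recordings. It does
not model slow baseline drift, movement artefacts, inter-burst
amplitude correlations, bursts overlapping at pathological rates, or
the variable segment lengths an expert would draw (windows here are
fixed-width). Passing the end-to-end test therefore shows the pipeline
is correct and self-consistent under these idealised conditions; it
does not by itself establish performance on any particular laboratory's
recordings.

## End-to-end bar and problem sizes

The end-to-end check simulates 330 s recordings (~43 bursts, ~9 sighs)
for 20 seeds, segments them, extracts features at 5% decimation, and
requires a median ground-truth agreement of at least 95% for K-means on
the maxclique pair, plus larger sigh means on ω(K(G)) and |K(K(G))|.
These sizes keep the full suite under half a minute while leaving ~60
samples per burst graph, enough for the clique structure to express the
class difference.

## Degenerate inputs and tie-breaks

Non-finite samples and non-increasing time stamps are rejected at
`TimeSeries` construction. Series shorter than 2 samples cannot form a
visibility graph; segments that decimate below 2 samples are skipped
with a warning. K-means refuses identical feature clouds ("degenerate
feature cloud") and fewer than 2 records. Zero-margin contingency
tables and zero-discordance McNemar tables raise instead of returning
NaN. Decimation stride ties (100/percent exactly halfway) round away
from zero.
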