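# Methods

This note documents the models and procedures implemented in
`spikewell`, the defaults that matter, the design choices made where the
method leaves room, and what the synthetic-data tests do and do not show
about real recordings.

## Data model and input handling

A recording is a plate-wide set of spike trains (sorted timestamps in
seconds, recording-relative) with a well/electrode layout and a time
window [start, end]. Electrode ids follow the `<well>_<rowcol>`
convention ("A6_34"); the parsing regex is configurable for other
vendors. When the end time is not supplied by the acquisition file it
defaults to the ceiling of the last spike time — spike-list CSVs carry
no duration field, so some convention is required; the ceiling avoids
biasing rate estimates upward on truncated files. Amplitudes are parsed
and preserved but feed no downstream feature. Spike lists, layouts and
the generic two-file format (times + electrode positions) are plain CSV;
all readers are order-independent and report malformed rows by line
number.

## Active electrodes

Every analysis is gated on an activity criterion: an electrode is active
when its mean firing rate is at least `min_rate` (default 5 spikes/min).
The threshold is a convention, not part of any algorithm, and is exposed
as configuration; `min_rate=0` admits any electrode with a spike.

## Spiking statistics

Eleven well-level statistics are emitted: number of active electrodes,
spike count, electrode-MFR mean and SD, well MFR, ISI mean, ISI CV,
spike-count CV, mean STTC, mean pairwise MI and mean normalized entropy.
The first eight are the "spike features" that enter aggregated
multi-recording tables; the synchrony triple is reported alongside but
not aggregated, which is what makes the aggregated inventory 8 spike +
19 burst + 10 NS + 33 NB = 70 features. The exact composition of both
lists is this package's reconstruction of a conventional feature set;
wells with no active electrodes report statistics as missing (never
zero) so that downstream means are not dragged toward 0 by silent wells.

## Burst detection

*Maximum Interval* (NeuroExplorer-style heuristic): a burst starts at an
ISI ≤ `max_begin_isi` (0.1 s), extends while ISIs ≤ `max_end_isi`
(0.25 s); bursts separated by less than `min_ibi` (0.8 s) are merged
(merging happens before the final filters); bursts shorter than
`min_duration` (0.05 s) or with fewer than `min_spikes` (6) are
discarded. All five values are tuning parameters.

*Poisson Surprise* (Legendy–Salcman-style): each candidate run scores
S = −log₁₀ P(X ≥ n | X ~ Poisson(λ·d)) with λ the electrode's mean rate
and d the run's span. Runs are seeded at two consecutive ISIs below half
the mean ISI, extended forward while S does not decrease (ties resolve
toward the longer burst), trimmed from the front while S strictly
improves, and kept when S ≥ `s_min` (5). Trains with fewer than three
spikes yield nothing.

The 19 well-level burst features are mean and SD over *bursting*
electrodes of eight per-electrode quantities (bursts per electrode,
duration, rate in bursts/min, spikes per burst, spike rate in burst,
IBI, ISI within burst, % spikes in bursts) plus the number of bursting
electrodes, the well's total burst count, and the well-level % of spikes
in bursts. Averaging over bursting rather than all active electrodes is
a deliberate choice (configurable by passing a different electrode set):
electrodes without bursts carry no burst statistics, and imputing zeros
would conflate "no bursts" with "short bursts".

## Network spikes

Distinct electrodes firing per tumbling 10 ms bin are counted; a network
spike is a contiguous run of bins at or above the electrode threshold
(default max(4, 25% of the well)), its peak the largest-count bin
(earliest on ties), its extent the full run, and its participating
spikes the well's spikes inside the run. Tumbling rather than sliding
bins keep the count definition simple and deterministic; a sliding
variant would detect marginally more events at bin boundaries. The
around-peak profile counts distinct active electrodes in 100 ms bins
over ±1 s around each peak. Because the profile bin (100 ms) is wider
than the detection bin (10 ms), the central profile value is at least —
not exactly — the peak electrode count; equality holds when all
recruitment falls inside the central bin. Wells without events report
count and rate 0 and the remaining eight features missing: a zero count
is an observation, but "mean peak size of no events" is not.

Event counts are not strictly monotone in the electrode threshold: a
higher threshold can split one dipping run into two events. The number
of above-threshold bins is monotone and is what the tests assert.

## Network bursts

Each electrode's train is binned at 2 ms (one spike per bin by
construction; duplicates collapse), smoothed with a Gaussian filter and
standardized to maximum 1. The filter's σ equals the nominal window
(10/20/50 ms) expressed in bins, truncated at ±3σ with a unit-sum kernel
and zero-padded edges — "window" is not defined more precisely by
convention, so σ = window is documented here and configurable.
Electrode signals are averaged (arithmetic mean — the combined signal is
then proportional to the fraction of electrodes active, which is the
quantity of interest), re-smoothed with the same filter and
re-standardized. Standardization before combination follows the stated
order of operations of the original procedure; standardizing only after
combination would weight electrodes by firing rate instead.

Otsu's threshold is computed over a 256-bin equal-width histogram of the
combined signal, returning the bin-edge value that maximizes
between-class variance; on the flat maxima that arise when the histogram
has an empty region between modes, the middle of the plateau is taken
(with a 1e-10 relative tolerance so that floating-point noise does not
pick an arbitrary plateau edge). A constant signal is degenerate: no
threshold, no network bursts.

Contiguous above-threshold intervals are the network bursts, with one
added filter: intervals in which fewer than 25% of the well's electrodes
(at least 2) fire are discarded. This filter is this package's addition:
per-electrode max-1 standardization makes a single isolated spike reach
signal 1, so in a sparse asynchronous well every stray spike would
otherwise become a "network burst". The threshold mirrors the NS
electrode criterion and is configurable.

Eleven features per window (count, rate, duration mean/SD, spikes in
NBs, % spikes in NBs, spikes per NB, spike intensity mean/SD — spikes
per NB-second —, inter-NB interval, participating electrodes per NB),
33 across the default three windows. Because thresholding crops the
smoothed packet tails, % spikes in NBs approaches but does not reach
100% even for perfectly synchronized wells.

## Synchrony metrics

*STTC* uses Δt = 0.05 s by default (unstated by convention; 50 ms is a
common choice for culture-wide synchrony). Tiles (±Δt around each spike)
are merged where they overlap and clipped to the recording window. The
well value is the unweighted mean over all N(N−1)/2 active-electrode
pairs; electrode distance is deliberately ignored. Pairs with an empty
train are undefined (error), wells with fewer than two active electrodes
report a missing value. The degenerate denominator 1 − P·T = 0 (a train
tiling the whole recording with P = 1) contributes a zero term.

*Entropy* uses 0.1 s bins; the bin-count mass function p(xᵢ) =
countᵢ/total gives H = −Σ p log₂ p. Base 2 is used throughout (the MI
definition is conventionally in bits; entropy follows for consistency).
The normalized variant divides by log₂(n bins), so 1 = uniform firing.

*Mutual information* first binarizes each electrode's binned counts at
the 75th percentile (linear interpolation; strict ">", so ties at the
percentile map to 0 — with mostly-zero bins the indicator then marks
burst-like bins). MI is computed on the 2×2 joint mass with 0·log 0 = 0;
a constant indicator yields MI = 0, not an error. MI shares the entropy
bin size. The well feature is the mean over pairs; the full pairwise
distribution is retained for distribution-level comparisons.

## Burst-feature distributions

Five features (IBI, ISI-in-burst, spikes per burst, duration, spike
frequency in burst) are histogrammed per electrode on fixed grids of 30
bins: duration on [0, 3 s] and frequency on [0, 300 Hz] (the
conventional user-set maxima), IBI on [0, 20 s], ISI-in-burst on
[0, 0.5 s], spikes per burst on [0, 200] (package defaults). Values
beyond the range are clipped into the edge bins so heavy tails are not
silently dropped. Electrodes need ≥ 5 bursts to contribute. Histograms
are averaged (unweighted, renormalized) first within wells, then across
wells per treatment.

EMD between two normalized histograms on a shared grid is the area
between their CDFs (Σ|ΔCDF|·bin width, the 1-D Wasserstein distance);
MD is max|ΔCDF| ∈ [0, 1]. Permutation testing shuffles treatment labels
of whole wells, keeping each well's electrode histograms intact, and
reports p as the proportion of permuted distances ≥ observed — exactly
that proportion, without +1 smoothing, so p can be 0 (and the observed
labeling itself appears among permutations only by chance). For a
single recording a two-sample K-S test on values pooled across
electrodes is provided; pooling raw values (rather than comparing
histogram means) is an interpretation choice and is flagged as such.

## Multi-recording statistics

Feature tables have wells as rows and recordings as columns. Wells must
have ≥ `min_ae` (4) active electrodes in strictly more than
`min_fraction` (50%) of recordings to survive filtering; exactly half is
removed. The filter is idempotent.

The Mann–Whitney test pools each well's values across recordings into
its treatment's sample (two-sided, tie-corrected; SciPy's automatic
exact/asymptotic switch). The permutation scheme reassigns whole wells
to labels — never splitting a well's time series, which preserves
within-well temporal correlation under the null — and the permutation p
is the proportion of permuted MW p-values ≤ observed. Label shuffles are
simple resamplings without enforcing distinctness. All-identical data
yields MW p = 1 and permutation p = 1. No multiple-testing correction is
applied across the 70 features; a Benjamini–Hochberg helper is available
as an explicit opt-in.

Outputs per feature: a CSV of treatment means and SEMs (SD/√n) per
recording with both p-values, and an optional mean ± SEM plot across
recordings.

## Synthetic data

The generator produces what the analysis consumes: per electrode,
homogeneous Poisson background firing plus injected fixed-ISI burst
packets (10 ms ISI, 6–20 spikes); per well, injected network-burst
events placing coincident packets on a sampled electrode subset
(default 75% participation) with ≤ 20 ms onset jitter to exercise the
smoothing windows; treatment labels scale rates multiplicatively.
Defaults describe a typical active culture on a 48-well, 16-electrode
plate: 1 Hz background, 2 bursts/min per electrode, 2 NBs/min, 900 s.
Injected NB times keep a ≥ 2 s spacing so ground-truth events are
individually resolvable. Ground truth (burst and NB intervals) is
returned with every recording; the same seed reproduces byte-identical
output.

`simulate_mfr_table` is a reduced generator for permutation-test
calibration: it draws well-level MFR directly as the mean of
per-electrode Poisson counts, which is distributionally identical to
simulating background-only trains and extracting MFR, at a small
fraction of the cost. Calibration studies (type-I error and power) use
it with the 12 vs 11 wells × 8 recordings design at 50 permutations and
200 (null) / 100 (power) replicates — sizes chosen so the whole
calibration runs in seconds while leaving the binomial check on the 5%
level well-powered.

What passing these tests shows — and does not. The generator's trains
are stationary, independent across wells, with rectangular burst
packets and exact Poisson backgrounds. Real cultures drift across days
in vitro, have refractory periods, correlated baseline activity,
heterogeneous per-electrode rates and non-stationary bursting. Recovery
of injected effects and correct null calibration on synthetic plates
therefore validates the *statistical machinery and detectors*, not the
biological sensitivity of any particular feature on real data.

## Numerical choices and degenerate inputs

- Times are float seconds; readers sort non-monotone trains with a
  warning and reject unparseable rows by line number.
- Empty trains: statistics report missing; STTC and MI on empty trains
  are errors at the pair level and skipped at the well level.
- SDs use ddof=1 and are missing (not 0) for single observations.
- The feature inventory counts 70 aggregated features; the platform
  additionally computes the three well-level synchrony statistics,
  which some summaries elsewhere count toward a 73-feature total — the
  tables emitted here keep the two groups separate.
- Percentile (MI binarization) uses linear interpolation, matching
  NumPy's default.
- All stochastic procedures (simulation, permutations) take a seed or a
  NumPy Generator; the pipeline derives every stream from its single
  seed.

## Known limitations

- Burst detectors are the Maximum Interval and Poisson Surprise pair
  only (no CMA or logISI variants).
- NB detection uses global Otsu thresholding; slowly drifting baselines
  would bias the threshold (adaptive thresholding is out of scope).
- The MW test treats pooled well×recording observations as exchangeable
  within treatment; the permutation calibration is what protects
  against the within-well correlation this ignores.
- No amplitude-based features; amplitudes are carried through I/O only.
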