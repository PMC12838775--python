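# Methods

This note records the models, conventions and numerical choices behind
`eegfc`, and what the synthetic validation does and does not establish.

## Signal model and phase extraction

The pipeline assumes cleaned, artifact-free multichannel EEG (the montage
defaults to the eight 10–20 sites F3, F4, T3, C3, C4, T4, O1, O2). Simple
plumbing for a 50 Hz notch, a 0.5–45 Hz broadband pre-filter and
common-average re-referencing is provided as optional flags (all off by
default, since synthetic input needs none of them); artifact removal
itself (ICA-style decomposition, manual segment rejection) is out of scope.

Band isolation uses a 4th-order Butterworth band-pass applied
forward–backward (`sosfiltfilt`), i.e. zero-phase with effective order 8.
Zero-phase filtering is essential: the object of measurement is phase, and
a causal filter would inject a frequency-dependent lag into every channel.
Instantaneous phase is the four-quadrant angle of the analytic signal
(Hilbert transform), wrapped to (−π, π]. A single-argument arctan of the
ratio HT(u)/u is ambiguous by π; the four-quadrant convention is the only
one that yields a continuous ramp for a sinusoid and is what the PLV
formula presumes.

Filter and Hilbert transients are handled by trimming `trim_s` (default
1.0 s) from each end of every band's phase series; all connectivity is
computed on the surviving "valid range" only.

## Connectivity

* **PLV** is the modulus of the time-averaged unit phasor of the phase
  difference. For independent phases its magnitude concentrates near
  √(π/4N), which the null tests use as a reference scale.
* **LOFC** is the all-pairs PLV matrix of one band, computed once over the
  full valid range for the static analysis (unit diagonal by convention,
  never used by metrics).
* **HOFC** correlates the connectivity profiles of two nodes: take columns
  i and j, delete rows i and j from both (self-connection removal), clip
  entries to ≤ 1 − 1e−12, apply Fisher's z (atanh), and Pearson-correlate.
  The clip keeps z finite when a PLV reaches 1 exactly without materially
  affecting correlations. A reduced column with zero variance (e.g. a
  perfectly uniform LOFC) gives a 0 edge plus a `DegenerateEdgeWarning`
  rather than NaN, so graph metrics downstream stay defined.
* **Between-frequency networks** compute PLV between band-a and band-b
  phases for every ordered channel pair including the same channel. The
  literal 1:1 phase difference is the default; because 1:1 locking between
  harmonically unrelated rhythms is non-stationary, an optional n:m mode
  computes |mean exp(i(nφ_a − mφ_b))| with the ratio rounded from the band
  centers (e.g. 4:1 for delta→alpha). Band-pair matrices are not
  symmetrized: entry (i, j) couples channel i in the lower band to channel
  j in the higher.
* **Supra-adjacency.** For B bands and C channels the supra matrix is
  (B·C)², with within-band matrices on the diagonal blocks and each
  band-pair matrix placed above the diagonal and its transpose below, so
  the whole matrix is symmetric by construction. The cross-band global
  metric is the arithmetic mean per off-diagonal block (and overall);
  it is linear in the block weights. The same assembly is applied to
  high-order blocks.

## Graph metrics

All metrics operate on prepared weights: diagonal zeroed; low-order weights
pass through; high-order weights have negatives clipped to 0 by default
(absolute value optional — both modes exist because the treatment of
negative profile correlations in weighted metrics is a genuinely open
convention). Weight-to-length mapping is ℓ = 1/w (configurable to −log w);
w = 0 means no edge.

* Clustering coefficient: mean over nodes of
  Σ_{j,h}(w_ij w_ih w_jh)^{1/3} / (k_i(k_i−1)) with k_i the binary degree
  (geometric-mean triangle intensity); degree < 2 contributes 0.
* Characteristic path length: mean shortest-path distance over ordered
  pairs (Dijkstra on ℓ). Any unreachable pair makes CPL = +∞ with a
  `disconnected` flag; the finite-pair mean is always reported alongside,
  and it is that fallback that enters group statistics when needed.
* Global efficiency: mean of 1/d with 1/∞ = 0 (handles disconnection
  natively). GE·CPL ≥ 1 whenever CPL is finite (harmonic–arithmetic mean
  inequality) — used as a property test.
* Local efficiency: per node, shortest paths among its neighbors restricted
  to the neighborhood subgraph on cube-root lengths, averaged with
  cube-root weight terms (w_uj w_uh / d_jh)^{1/3} / (k(k−1)).

All four are verified against independent brute-force oracles
(Floyd–Warshall triple loops, explicit triplet/neighborhood enumeration)
to 1e−10 over hundreds of random graphs.

## Dynamics and state entropy

Windows are half-open sample ranges with step = round(length·(1−overlap)·fs)
and the trailing partial window dropped, so every PLV estimate averages the
same number of samples. The six default lengths are 0.5, 1, 2, 4, 6, 8 s at
20 % overlap. Windows holding under two cycles of a band's low edge (the
0.5 s delta case) give unstable PLV estimates; the pipeline runs them as
configured but emits a warning rather than silently adjusting.

Each window's prepared network yields node-wise participation coefficients
PC_i = 1 − Σ_s (κ_is/k_i)² over a module partition (default: the four
left/right anatomical pairs frontal/central/temporal/occipital; an explicit
partition can be supplied). The per-window feature is the node-PC vector by
default (a scalar network-mean option exists). K-means with k = 2,
Euclidean distance and 50 seeded restarts labels the cluster with higher
mean participation as integration (1). State entropy is the Shannon entropy
of the empirical distribution of the four consecutive-window pairs,
normalized by log 4 (natural log; the normalization makes the base
irrelevant): 0 iff a single pair type occurs, 1 for the uniform
distribution.

## Group statistics

Pooled-variance independent t-tests by default (Welch optional); degenerate
zero-variance inputs resolve to t = 0, p = 1 (equal means) or signed ±∞,
p = 0 (unequal) instead of NaN. FDR control is Benjamini–Hochberg within
each analysis family — per band × order for the 28 within-band edges, per
pair × order for band-pair edges, per band × order for the six
window-length entropies, per order for the global metrics. Correction scope
across families is deliberately not guessed: raw and adjusted p are both
always reported so any pooling can be audited. Significance stars follow
the usual bands (* 0.01<p<0.05, ** 0.001<p<0.01, *** p<0.001).

## Synthetic cohorts

Per band b and channel i the phase obeys the stochastic Kuramoto equation
dφ_i = 2πf_i dt + Σ_j K_ij sin(φ_j − φ_i) dt + σ dW_i, integrated by
Euler–Maruyama at the recording rate (at 200–1000 Hz the step is far below
the oscillation and noise timescales; halving the step changes measured
PLVs well within Monte-Carlo noise). Defaults: center frequencies 2.5, 6,
10, 20 Hz with per-channel jitter sd 0.2 Hz (clipped into the band);
phase-noise σ = 1 rad/√s; unit amplitude per band; 1/f background noise of
amplitude 0.5 (spectral exponent 1); all-to-all baseline coupling
0.3 rad/s. The default cohort is 8 channels, 1000 Hz, 300 s, 36 subjects
per group; tests and the acceptance script use shorter recordings at
200–250 Hz since every quantity checked is invariant to that scaling.

Planted effects raise the "ASD" group's delta coupling to 1.2 rad/s and
lower its alpha coupling to 0.05 rad/s. These values were chosen once so
that the subject-level edge-PLV effect size is at least 1 standard
deviation (measured |d| ≈ 3–5), the regime the recovery checks specify.
Cross-band linkage overwrites the target channel's phase with (n/m) times
the source phase plus an independent Wiener jitter scaled by (1 −
strength); with strength 0.9 and ratio 4:1 (delta→alpha) the n:m-mode
band-pair block mean rises by ≈ 0.05 in the linked group (8 linked
same-channel entries out of 64).

What the generator does *not* emulate: volume conduction / sensor mixing
(an optional linear mixing matrix exists but is off by default, because
instantaneous mixing inflates zero-lag PLV and would blur the planted
ground truth), ocular/myogenic artifacts, non-stationary amplitude
dynamics, and realistic cross-frequency amplitude coupling. Passing the
recovery tests therefore shows the pipeline measures planted phase
structure correctly — not that real-EEG confounds are handled.

## Determinism

Subject seeds derive from the truth's base seed, group and index via
`SeedSequence`; every stochastic analysis stage (K-means restarts) is
seeded from the pipeline config seed plus stable stage indices. Re-running
with identical config and inputs reproduces every numeric CSV bit for bit
(checked by SHA-256 in the acceptance suite).

## Known limitations

* The supra-adjacency is built generically as (B·C)² = 32 × 32 for the
  default four bands and eight channels.
* 1:1 between-frequency PLV on harmonically unrelated rhythms is
  non-stationary; interpret the default-mode band-pair values as relative,
  not absolute, coupling strengths. The n:m mode is the stationary
  statistic when a harmonic relation is hypothesized.
* CPL on disconnected graphs is reported as +∞; the finite-pair fallback
  used in group features slightly underestimates path length for such
  networks (flagged per metric set).
* EDF input requires `mne`; cohort output is CSV (plus YAML truth/config
  and a manifest), which round-trips bit-exactly.
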