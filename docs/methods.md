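# Methods

This note documents the models implemented in `smtpatch`, the parameter
conventions, the numerical choices made where the design was open, and
what the synthetic-data tests do and do not establish about real data.

## Turnover models

All three simulators produce an `EventSet` of paired arrival/departure
times for `n_molecules` (default 900) in a patch of total lifetime `T`
(default 20 s), repeated `n_repeats` times (default 50) and pooled, with
per-repeat means retained to mirror per-movie summaries of real data.

* **random** — arrivals ~ N(T/4, T/10), departures ~ N(3T/4, T/10),
  paired at random. Mean residence = T/2; SD = √2 · T/10 (difference of
  independent normals). A pair with departure < arrival (probability
  ≈ 2×10⁻⁴ under these marginals) has its departure re-drawn; this
  preserves the marginals to a part in ~10³ and guarantees non-negative
  residence.
* **fifo** — same marginals, arrivals and departures sorted and paired
  by rank. Residence concentrates near T/2 with only order-statistic
  noise.
* **turnover** — arrivals ~ |N(T/3, T/5)|, residence ~ Gamma(shape 2,
  scale 1 s), a two-step dwell kinetic with mean 2 s and mode 1 s.

Occupancy at bin edge t (1 s bins by default) counts molecules with
arrival ≤ t and departure > t; cumulative consumption counts arrivals
≤ t. The discriminating signature is final consumption normalized to
peak occupancy: within [1.0, 1.2] for both discrete-phase mechanisms
versus > 3 for continuous turnover at the default parameters. These are
deliberately *logical* models — no mass-action kinetics, no spatial
structure — because their purpose is to separate hypotheses by
residence-time statistics alone.

## Synthetic movies

`EmitterSimParams` describes sparse membrane-bound emitters: Poisson
appearance at `birth_rate`, residence drawn from a gamma (default),
exponential or fixed model, an independent Exp(`bleach_rate`) bleach
time (observed lifetime = min of the two, end cause recorded), and 2D
Brownian motion with per-axis step variance 2·D·dt. Defaults place the
simulation in the operating regime of the real recordings: 0.1 s
frames, residence of order 1–2 s, D in the 500–4000 nm²/s band, bleach
≈ 0.15 s⁻¹, and a photon budget giving peak SNR ≈ 5–6.

Conventions chosen where several were defensible:

* A molecule is rendered in a frame iff it is alive at the frame
  midpoint — an unbiased discretization of its lifetime.
* Emitters reflect at the field boundary rather than vanish, so
  boundary loss cannot masquerade as unbinding in recovery tests.
* The PSF is a pixel-integrated symmetric Gaussian (erf differences),
  not point-sampled: at 178 nm pixels with σ = 160 nm, σ ≈ pixel and
  point sampling would misstate pixel fractions by several percent. The
  PSF width is not printed for the real instrument; 160 nm sits
  mid-band of the accepted 100–300 nm spot-size filter and is
  configurable.
* `pool_bleach_rate > 0` makes the appearance rate decay as exp(−k·t),
  emulating depletion of the labeled pool — the feature the
  photobleach-rate estimator reads out of real movies. The default is a
  constant birth rate (stationary conditions), under which the
  spot-count series does not decay and that estimator is not meaningful.

### EMCCD noise

For expected photons n the camera model is: Poisson photon draw k,
electron multiplication with gain g and excess noise factor F
(variance F²·g²·n), Gaussian read noise r, conversion at e electrons
per count, offset, and rounding. Counts have mean `offset + n·g/e` and
variance `(F²·g²·n + r²)/e² + 1/12` (quantization). The excess noise is
implemented as a variance-matched Gaussian spread of k·g with variance
(F²−1)·g²·k, which reproduces the printed F = 1.41 exactly; a gamma
cascade would force F² = 2 and a full register Monte Carlo is out of
scope. Defaults are the printed constants: r = 88.8 e⁻, F = 1.41,
e = 49 e⁻/count, g = 167, offset = 105 counts.

## Localization

Detection: difference-of-Gaussians band-pass (σ = 1 and 3 px), robust
noise scale from the MAD of the band-passed frame, candidates = local
maxima above `threshold_factor × 5 × σ_noise` (the published analysis
quotes the 0.8 factor but not its estimator; ours is documented here
and configurable), then debounce — candidates closer than 3 px merge
into the brighter, since two fluorophores that close are unresolvable.

Fitting: least squares over a 9×9 px window with a volume-normalized
pixel-integrated symmetric Gaussian plus a *planar* local background
(constant + tilt). A broad-Gaussian background over a 9 px window is
ill-constrained (its center and width are unidentifiable at that
support), so the plane is used directly; it absorbs the camera offset
and local cytoplasmic gradients. Windows clipped by the image border
and non-convergent fits are refused, not repaired.

Intensity is reported in AU = fitted Gaussian volume in counts divided
by a configurable constant (default 20), calibrated once so that the
single-fluorophore photon regime (~100–1500 photons/frame at the
default camera constants) spans the 20–200 AU acceptance band.

Precision is a closed-form CRLB-style estimate
`var = F²·(σₐ²/N)·(16/9 + 8π·σₐ²·b/(N·a²))` with σₐ² = σ² + a²/12,
N detected photons, b background photons/pixel, a the pixel size, and
the EMCCD excess-noise variance factor applied. At ~120 photons/frame
over 20 background photons/pixel it evaluates to ≈ 50 nm, the typical
precision regime of the real data; Monte-Carlo RMS fit errors agree
with the estimate within a factor of 2 across 100–2000 photons.

Filter bounds (20–200 AU, 100–300 nm, ≤ 150 nm) are inclusive.
Temporal background subtraction is not implemented (the real analysis
ran with it off).

## Linking

Pure proximity linking, no motion prediction: spots within 100 nm of an
open track end are candidates; conflicts within a frame pair are
resolved by minimal-total-distance assignment (linear-sum assignment),
which is deterministic and keeps purity high at near-radius
separations, with an infinitesimal preference for the more recent track
end on exact ties. The gap limit is stored as "frames including both
endpoints": the default 6 links spots up to 5 frame indices apart, i.e.
at most 4 consecutive missed detections; a value of 1 degenerates to
plain successive-frame linking. The same 100 nm radius applies to gap
links (the source method states a single limit). Tracks need ≥ 3 spots;
an optional binary cell mask drops tracks whose centroid falls outside.

Diagnostics: the within-track gap-length histogram (geometric decay at
the per-frame miss rate when linking is honest; a heavy tail flags
over-linking) and a gap-limit sweep reporting track counts and mean
lifetimes per limit.

## Track statistics

* Lifetime of an m-spot track = (last − first timestamp) + one frame
  interval, making the ≥3-spot rule equivalent to the 0.3 s minimum at
  0.1 s frames. Tracks outside 0.3–40 s are excluded.
* Start cutoff: candidates 0, 1, 2, … s; the first c where a KS test
  between lifetimes of tracks starting ≥ c and ≥ c+1 s gives p > α
  (α = 0.05 default, not stated in the source analysis) is selected.
  Candidates with fewer than 20 tracks are skipped with a warning;
  exhaustion raises an error naming the last p-value. Note the two
  samples are nested, which makes the test conservative — appropriate
  for a stopping rule.
* Per-movie SD: standard deviation across per-movie mean lifetimes,
  counting only movies with > 40 tracks (NaN when fewer than two
  qualify); pooled statistics use all tracks. The 95th percentile uses
  linear interpolation.
* MSD: all m(m−1)/2 within-track pairs, binned at multiples of the
  frame interval; OLS of mean dr² on dt over the 10 smallest bins
  ≤ 1 s ("first 10 points" includes dt = 0.1 s); D = slope/4 with its
  95% OLS interval, b = intercept. With static localization error σ
  the intercept is ≈ 4σ².
* Mobility classes: a pair is *low* if dr < 2.5 × average precision
  (125 nm at 50 nm precision); otherwise *high* above a reference curve
  dr(dt) = √(4·D_ref·dt + b_ref) and *mid* below it. The reference is
  an explicit input (default D_ref = 3000 nm²/s, the fast
  actin-associated regime) or a tabulated curve, because in the source
  analysis that boundary was derived from its own dataset.
* Photobleach rate: weighted log-linear fit of spot counts per frame
  (weights ∝ counts, the inverse variance of log counts under Poisson
  statistics), zero-count frames dropped.
* Distribution comparisons use the two-sided Mann–Whitney test.

## Problem sizes and what the tests show

The validation suite uses desk-scale problems chosen to keep Monte-Carlo
error well below the tolerances being checked: turnover models at the
full 900 × 50; noise moments at 10⁵ pixels; 100-frame detection and
300-fit precision Monte-Carlos; one 300-frame sparse movie for tracking
fidelity; three 400-frame movies for end-to-end recovery; 100 seeded
replicates of the cutoff procedure at 5000 tracks each.

The end-to-end recovery check (residence Gamma(2, 0.75 s), D =
3000 nm²/s, bleach 0.15 s⁻¹) compares pipeline output to an oracle
computed from the kinetic distributions alone: the expected mean of
min(residence, bleach) after frame discretization and the ≥3-frame /
0.3–40 s filter. It uses 1000 photons/frame (precision ≈ 11 nm). This
is deliberate: when localization noise approaches the 100 nm link
radius (4σ² ≈ 10⁴ nm² at 50 nm precision), the radius censors the
apparent displacement distribution, splitting tracks and biasing the
fitted D downward by ~25–35% *regardless of implementation* — which is
why measurements in that regime are apparent D, not D. True-parameter
recovery is therefore demonstrated in the bright regime where censoring
is negligible; the dim regime is exercised by the precision and
detection tests instead.

What passing these tests does **not** show: the generator has a flat
background (no cytoplasmic autofluorescence structure, no illumination
profile), a single in-focus plane (no defocus along the invagination
axis), isotropic free diffusion (no confinement or directed transport),
no blinking, and exactly one fluorophore per emitter. Conclusions about
real movies inherit those caveats; in particular, tracking fidelity on
real data will be bounded by crowding and background texture that the
synthetic movies do not contain.

## Known limitations

* No multi-emitter (overlapping-PSF) fitting, 3D/astigmatic fitting or
  drift correction; no merging/splitting or probabilistic tracking.
* Trajectories are not aligned to the invagination axis and no FRAP
  modelling is included.
* Recall/purity scoring excludes truth emitters whose visible positions
  sit within half a fit window of the field border, because clipped
  windows are refused by design and such emitters cannot be localized.
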