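# smtpatch

Single-molecule speckle tracking of endocytic patches: simulation and
analysis tools for asking whether a dense, transient protein assembly —
the actin/coat machinery of clathrin-mediated endocytosis (CME) in yeast —
is built once and torn down once, or turns its components over continuously.

The bulk fluorescence of a CME patch rises and falls over ~20 s, which is
compatible with very different single-molecule behavior. `smtpatch`
provides both sides of the comparison:

* **Turnover simulators.** Three logical mechanisms generate paired
  arrival/departure timestamps for `n` molecules in a patch of lifetime
  `T`: discrete assembly/disassembly with random departure order
  (arrivals ~ N(T/4, T/10), departures ~ N(3T/4, T/10)), the same
  marginals with first-in/first-out rank matching, and continuous
  turnover (arrivals ~ |N(T/3, T/5)|, residence ~ Gamma(2, 1 s)). The
  discriminating statistics are the residence-time distribution, the peak
  occupancy, and the cumulative number of molecules consumed normalized
  to the peak — ≈ 1 for discrete phases, ≫ 1 for turnover.
* **A synthetic-movie generator.** Sparse emitters appear as a Poisson
  process, dwell with gamma/exponential/fixed residence, diffuse in 2D
  (variance 2·D·dt per axis), photobleach, and are rendered with a
  pixel-integrated Gaussian PSF (178 nm pixels, σ = 160 nm) and a full
  EMCCD noise chain (shot noise, excess noise factor 1.41, read noise
  88.8 e⁻, 49 e⁻/count, EM gain 167, offset 105 counts).
* **Localization → linking → track statistics.** Band-pass detection with
  a robust local threshold (factor 0.8) and 3 px debounce; symmetric 2D
  Gaussian + planar-background fits with CRLB-style precision estimates;
  quality filtering (20–200 AU, σ 100–300 nm, precision ≤ 150 nm);
  proximity linking within 100 nm with up to a 6-frame gap and a ≥3-spot
  rule; lifetime statistics with a KS-based start-time cutoff, per-movie
  means (SD across movies with >40 tracks), end-to-end distances,
  pairwise-displacement MSD fitted as `dr² = 4·D·dt + b` over the first
  10 lags (≤ 1 s), high/mid/low mobility classification (low cutoff
  125 nm = 2.5 × 50 nm precision), Mann–Whitney comparisons, and a
  photobleach rate from spot-count decay.

Everything downstream of the generator is validated against ground truth,
so the whole pipeline is testable offline with no raw movies.

## Worked example

Simulate the three mechanisms at the standard conditions (900 molecules,
T = 20 s, 50 repeats):

```bash
$ smtpatch simulate --model random   --seed 1 --out out/
random: mean residence 10.015 s, final consumed/peak 1.01
$ smtpatch simulate --model fifo     --seed 2 --out out/
fifo: mean residence 10.000 s, final consumed/peak 1.01
$ smtpatch simulate --model turnover --seed 3 --out out/
turnover: mean residence 2.007 s, final consumed/peak 5.17
```

Both discrete-phase models predict single molecules that stay for half
the patch lifetime (~10 s) and a patch that consumes barely more
molecules than its peak occupancy. Continuous turnover predicts short
~2 s stays and a patch that consumes ~5× its peak — short observed
residence times are the single-molecule fingerprint of turnover.

The same from Python, plus a full imaging-pipeline round trip:

```python
import smtpatch as sp

ev = sp.simulate_turnover_model(sp.ModelParams(model="turnover", seed=3))
print(ev.residence_times.mean())          # 2.007 s

# synthetic movie -> localize -> link -> analyze
em = sp.EmitterSimParams(duration=30.0, birth_rate=1.0, diffusion_D=1000.0,
                         bleach_rate=0.0, seed=11)
truth = sp.generate_truth_tracks(em)
stack = sp.render_movie(truth, rng=12)
locs  = sp.localize_stack(stack, filter_spec=sp.LocFilterSpec())
res   = sp.link_tracks(locs)
print(sp.evaluate_tracking(res.tracks, truth))  # recall 1.0, purity 1.0
```

A complete run (`smtpatch run --config cfg.yaml --out rundir`) writes
localization and track tables, a one-row summary (median/mean/95%ile
lifetime, SD across movies, net distances, apparent D with its CI,
mobility fractions) and a log of every effective parameter.

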