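# Methods

## The model

Consecutive-hybridization FISH keeps every target molecule visible as one
diffraction-limited spot through N cycles of hybridize → image →
photobleach. The channel observed in each cycle is one symbol of an M-ary
barcode; the codebook maps barcodes to targets, with capacity M^N. The
package implements the scheme's four computational layers — codebook,
probe chaining, image formation, and decoding — and ties them together
with a simulator so every decoding claim can be checked against known
ground truth.

### Probe chaining and orthogonal-pool accounting

A pre-decoding probe is `target(20) + TTTTT + landing(20)` (45 nt); a
decoding probe is `revcomp(prev_landing) + TTTTT + landing + TTTTT +
landing` (70 nt), the two recruiting segments being identical so each
bound probe recruits two probes in the next cycle. Landings are drawn from
a user-supplied orthogonal pool, one draw per target per cycle: the draw
for cycle c is the landing the cycle-c probe binds, and the cycle-1 draw
doubles as the pre-decoding landing. The terminal cycle's probe keeps the
full two-landing architecture even though nothing follows it; its
recruiting segments reuse the tier-0 landing. This choice avoids an extra
pool draw (keeping the cost identity n_targets × n_cycles, e.g.
30,000 × 8 = 240,000 exactly) and avoids the self-complementary hairpin
that reusing the terminal draw would create. Cross-hybridization screening
flags sequence pairs whose longest contiguous complementary run reaches a
configurable cutoff (default 12 nt — a conservative screening value, since
the assay itself assumes a pre-validated orthogonal pool); thermodynamic
modeling is out of scope.

### Image formation

The simulator renders 2D fields (the acquisition z-stack is abstracted to
a single plane; decoding logic is z-independent). Parameters, with
defaults chosen as the study conditions:

| parameter | default | meaning |
|---|---|---|
| `pixel_size_nm` | 160 | so the 2-px colocalization radius is 320 nm |
| `psf_sigma` | 1.3 px | Gaussian PSF scale |
| `base_intensity` | 150 photons | cycle-1 peak amplitude |
| `amplification` | 2 | fold growth per cycle (two landing sites) |
| `saturation_cap` | 64 | max fold; models the crowding plateau |
| `brightness_cv` | 0.25 | lognormal sigma of per-spot efficiency |
| `background` | 20 photons/px | autofluorescence floor, cycle-independent |
| `bleach_residual` | 0.01 | fraction of signal surviving photobleaching |
| `read_noise` | 3 photons rms | camera read noise |
| `camera_offset` | 100 counts | added last, echoed in the config |
| `dropout_prob` | 0.002 | per-cycle staining failure (≈ 99.8% re-staining) |
| `nonspecific_rate` | 0.5 /cell/cycle | single-cycle spurious spots |
| `spots_per_cell_per_target` | 8 | Poisson mean |
| `n_cells` | 3 | non-overlapping disk cells, radius 42 px |

Expected amplitude at cycle c is `I0 · min(a^(c−1), cap)`, scaled by a
per-spot lognormal factor that is constant across cycles (hybridization
efficiency is a property of the molecule's local environment more than of
the cycle). A fraction `r` of the previous cycle's amplitude is re-rendered
in the previous cycle's channel (photobleach residual); drift accumulates
linearly across cycles; non-specific spots exist in exactly one cycle and
one channel at unamplified brightness. Noise is Poisson on signal +
background plus Gaussian read noise, offset added last — the standard
CCD/sCMOS abstraction. Spots are sampled uniformly in the 2-px-eroded cell
interior with a minimum separation (default 4 px, disengageable), so the
default conditions probe decoding rather than optical crowding, which the
scheme itself defers to super-resolution/expansion imaging.

What the generator does **not** emulate: structured autofluorescence,
illumination gradients, z-defocus, PSF asymmetry, probe-removal chemistry,
and density-driven spot overlap when minimum separation is on. Passing
tests therefore demonstrate the correctness of the decoding logic under
the scheme's nominal physics, not robustness to every real-microscope
artifact.

A second, point-process-level generator (`simulate_detection_table`)
skips pixels entirely and emits per-cycle detection tables with Bernoulli
per-cycle presence and Gaussian localization jitter. It exists for the
survival/reappearance arithmetic, where the quantities of interest are
functions of presence patterns and the colocalization radius only; it
routes through the same linker and QC as image-derived detections.

## Detection, registration, decoding

* **Detection** — scale-normalized Laplacian-of-Gaussian response at the
  PSF scale; the discrete kernel's DC leakage is removed by median
  subtraction; local maxima above `min_snr` (default 5) × the MAD-based
  robust rms are kept. Sub-pixel refinement fits a 2D Gaussian in a 7×7
  window with the center constrained to ±1.5 px of the discrete maximum;
  fits that drift further (a neighboring spot pulling the fit) or fail
  fall back to per-axis parabolic interpolation. Detections closer than
  2 px are deduplicated (brighter wins); per-cycle detections from
  different channels within 1 px merge into one record, because calling
  needs all channels at one position regardless of which channel fired.
* **Photometry** — per channel, disk sum (radius 3 px) minus disk-area ×
  annulus median (6–9 px). Values may be negative in empty channels;
  positions within 3 px of the border are edge-flagged (NaN vector).
* **Registration** — phase cross-correlation of channel-summed images
  against cycle 1, 0.1-px upsampling; translation only. The
  single-fiducial alignment a bench protocol would use is subsumed:
  correlation over the full field recovers the same translation more
  robustly. Flat images yield zero offset with a low-confidence flag.
* **Linking** — tracks seed from cycle-1 detections; each later cycle's
  detections are assigned to track anchors greedily in ascending distance
  (ties by track creation order), one-to-one, linked only when distance
  < 2.0 px strictly. Unclaimed later-cycle detections are orphans: they
  can never satisfy the real-signal rule, but they are reported, so no
  detection is silently dropped. Greedy assignment rather than optimal
  matching: deterministic, O(k log k), and at single-molecule densities
  (spot spacing ≫ radius) the two coincide.
* **Calling** — per linked cycle, argmax over the channel intensity
  vector; flagged ambiguous when the winner is below 1.5× the runner-up
  (a non-positive runner-up never causes ambiguity, since the contrast is
  then effectively infinite). No absolute threshold anywhere.
* **Decoding and counting** — a track decodes only if complete (present
  in all cycles) and unambiguous and its sequence is in the codebook;
  otherwise UNASSIGNED with reason `incomplete`/`ambiguous`/
  `no-codebook-match`, with `incomplete` taking precedence. Copy numbers
  count decoded complete tracks by the cell-mask label at the track
  anchor; label 0 (outside every cell) is excluded but reported. The
  real-signal flag (cycles 1∧2) and the all-cycles rule are kept as
  separate flags so QC can report both fractions.

## Numerical and design choices

* Channel indices are 0-based internally; fluorophore names
  (Quasar 570/Cy5, plus Alexa 488 for three-channel work) appear only at
  the I/O surface.
* Codebook generation assigns sequences lexicographically in target input
  order — a convention chosen for determinism; explicit entry tables
  override it (needed for the alternating two-gene scheme). No
  error-correcting construction: the scheme uses raw sequences, and
  minimum pairwise Hamming distance is reported as a QC number only.
* The colocalization radius is a strict inequality at 2.0 px, matching
  "less than 2 pixels".
* Ambiguous calls still record the argmax but block decoding; guessing at
  a tie has no justification in a threshold-free design.
* Determinism: one `numpy` Generator seeded from the config/CLI seed
  drives every stochastic step; identical seeds give bit-identical stacks,
  truth tables and decode outputs.

## Problem sizes

Defaults run an entire 16-cycle, 2-channel, 256×256 px, 3-cell experiment
(≈ 50 molecules plus non-specific spots) in a few seconds, which is enough
to exercise every pipeline stage; the survival/reappearance statistics use
10,000 and 5,000 point-process tracks respectively. All sizes are
configurable upward.

## Known limitations

* Translation-only registration; rotation/scaling drift is out of scope.
* No deconvolution of overlapping spots: two molecules within ~2 px
  merge and decode as one (flagged only indirectly via counts).
* The intensity model treats channels as perfectly unmixed; spectral
  bleed-through would enter the calling comparison unmodeled.
* Per-cell counting requires a label mask; cell segmentation itself is
  not provided (the simulator emits its mask; real data needs an external
  segmentation).
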