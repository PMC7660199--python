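# cfish

Toolkit for **consecutive-hybridization FISH (C-FISH) barcoding**: a spatial
transcriptomics/genomics scheme in which every RNA or DNA molecule stays a
fluorescent spot at a fixed cellular position while its color changes from
hybridization cycle to hybridization cycle. The ordered list of channels a
spot shows across cycles — its *color sequence* — identifies the target
against a codebook, so M fluorophores and N cycles address M^N targets
(2^16 = 65,536; 3^9 = 19,683; 4^8 = 65,536) without any error-correcting
code.

The package is for people building or evaluating such assays: it generates
and validates codebooks, assembles the chained probe sets, renders
ground-truthed synthetic image stacks with the scheme's characteristic
physics, and decodes multi-cycle stacks back to per-cell copy numbers with
QC — so the encoding/decoding claims can be tested end to end without a
microscope.

## The scheme in brief

* **Encoding.** Each target is tiled by ~30 unlabeled 45-nt *pre-decoding*
  probes (20-nt target-binding segment + 5T spacer + 20-nt landing segment).
  Every cycle then adds fluorophore-labeled 70-nt *decoding* probes:
  `revcomp(previous landing) + TTTTT + landing + TTTTT + landing`. Because
  each bound probe presents **two identical landing sites**, the next cycle
  recruits two probes per probe — spot intensity grows geometrically
  (~2× per cycle) until molecular crowding caps it, so the
  signal-to-background ratio *improves* in later cycles instead of decaying.
  One orthogonal 20-nt sequence is consumed per target per cycle: profiling
  30,000 targets over 8 cycles costs 240,000 orthogonal sequences.
* **Decoding.** Images from all cycles are registered to the cycle-1 frame;
  spots are detected per cycle and linked by the colocalization rule
  (< 2 px = 320 nm at 160 nm/px). Spots present in both of the first two
  cycles are *real signals* (single-cycle appearances are non-specific
  binding); spots present in **all** cycles are counted. Each cycle's
  channel is called **threshold-free** by comparing intensities across all
  channels — the argmax wins — so weak spots remain decodable and no
  artificial intensity cutoff injects errors.

## Worked example

Simulate the two-gene alternating 16-cycle experiment (GAPDH on
Quasar 570 in odd cycles / Cy5 in even cycles; Ki67 the complement) and
decode it:

```python
from cfish import SimulationConfig, simulate_experiment, run_decode, evaluate_tracks
from cfish.codebook import Codebook

entries = {"GAPDH": tuple(c % 2 for c in range(16)),
           "Ki67":  tuple((c + 1) % 2 for c in range(16))}
codebook = Codebook.from_entries(entries, n_channels=2, n_cycles=16)

config = SimulationConfig(seed=1, drift_per_cycle=(0.5, -0.3))
stack, truth = simulate_experiment(config, codebook)
run = run_decode(stack, codebook, psf_sigma=config.psf_sigma)

print(run.counts.to_string(index=False))
ev = evaluate_tracks(run.tracks, truth)
print(f"recall={ev['track_recall']:.3f}  decode_error={ev['decode_error_rate']:.3f}")
```

prints

```
 cell_id target_id  count
       1     GAPDH      6
       1      Ki67     10
       2     GAPDH      6
       2      Ki67      5
       3     GAPDH      5
       3      Ki67      7
recall=1.000  decode_error=0.000
```

i.e. per-cell transcript counts for both genes, with every simulated
molecule recovered as a track and none decoded to the wrong gene despite
shot noise, photobleach residuals, 0.5/−0.3 px-per-cycle stage drift and
non-specific spots. The QC block (`run.qc`) carries the per-cycle
called-channel intensities — here growing from ~1.5 × 10³ (cycle 1) to
~9.6 × 10⁴ at the saturation plateau — plus the cycle-1→2 reappearance
fraction (0.975 in this run) and the fraction of real-signal tracks present
in all 16 cycles (1.000).

The same pipeline runs from the shell:

```bash
cfish simulate --config config.yaml --out sim/
cfish decode --images sim/ --codebook sim/codebook.csv --out results/
```

writing `detections.csv`, `offsets.csv`, `tracks.csv`, `counts.csv`,
`qc.json`, a run manifest, and `eval.json` whenever a `truth.csv` sits next
to the images. `cfish codebook` and `cfish probes` cover codebook
generation/validation and chained-probe FASTA export.

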