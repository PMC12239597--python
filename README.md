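# gearbelt

Quantification toolkit for three single-cell motility assays driven by
rotary surface motors, plus a stochastic "gearset" simulator that doubles as
the ground-truth generator, so every analysis stage is testable without any
external data:

* **Tethered-cell rotation** (`gearbelt.rotation`) — segment a dark rotating
  rod, unwrap its angle about the tether, report signed rotational frequency
  (+ = CCW), apply the full-revolution inclusion filter, and summarize
  populations into signed speed distributions.
* **Gliding motility** (`gearbelt.motility`) — link per-frame detections
  into trajectories (greedy nearest-neighbor, bounded jump/gap) and compute
  mean speed on smoothed positions, farthest displacement from the start,
  path length, and run/turn/reversal structure.
* **Conveyor-belt spot tracking** (`gearbelt.spots`) — difference-of-Gaussians
  spot detection with subpixel centroids, linking, speed, and trajectory
  shape classification (looped / extended / oscillatory).
* **Gearset simulator** (`gearbelt.gearset`) — an ensemble of two-state
  Markov rotary motors driving a belt: any motor direction flip slips the
  belt, pausing the cell and redrawing its heading (von Mises turn or
  forced reversal), producing run-and-turn trajectories with a known event
  log.
* **Synthetic videos** (`gearbelt.synth`) — seeded renderers for all three
  assays (rotating rod, gliding rods, spot on a closed stadium path with
  Poisson photon noise), each returning exact ground truth.
* **Statistics** (`gearbelt.stats`) — Gaussian KDE (Silverman bandwidth),
  exact two-tailed Mann-Whitney U (full enumeration up to pooled n = 14,
  tie-corrected normal approximation beyond), fraction-in-circle
  probability, optimal spin angle about an axis, and cumulative work
  integration.

## Command line

All commands share `--seed`, `--out`, `--config` (YAML, overridden by
flags) and `--log-level`. Outputs are plain CSV/JSON/JSONL plus
uncompressed multi-page TIFF with a `.meta.json` calibration side-car;
every file carries a schema version. Runs are byte-reproducible for a
fixed seed.

```sh
# full synthetic loop: simulate, render, analyze, print truth vs recovered
gearbelt --seed 7 --out demo_out demo

# gearset simulation -> track CSV + event log
gearbelt --seed 1 --out run simulate --duration-s 60 --bias 0.9

# render a tethered-cell video and analyze it
gearbelt --seed 1 --out run render --kind tethered --signed-freq-hz 1.3
gearbelt --seed 1 --out run analyze-rotation run/tethered.tif

# spot assay
gearbelt --seed 1 --out run render --kind spot --belt-speed-um-s 2.0
gearbelt --seed 1 --out run analyze-spots run/spot.tif

# gliding statistics from a track CSV (columns track_id,frame,t_s,x_um,y_um)
gearbelt --out run analyze-gliding --tracks-csv run/simulated_track.csv

# standalone statistics, e.g. exact Mann-Whitney on two CSV columns x,y
gearbelt --out run stats --test mann-whitney --input values.csv
```

Conventions: micrometers and seconds everywhere outside the image modules;
the analysis frame has y increasing upward, so positive angles/frequencies
are counterclockwise in a conventionally displayed image.

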