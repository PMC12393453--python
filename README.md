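# capnet

Quantification of intravital Ca²⁺ imaging in the skin capillary plexus.

Endothelial cells (ECs) lining skin capillaries show heterogeneous,
spatially patterned Ca²⁺ activity that can be recorded in live mice with a
genetically encoded sensor (GCaMP6s) and a nuclear label (H2B-mCherry) as
the cell proxy. `capnet` implements the full quantification stack for such
recordings, for anyone analyzing timelapse EC Ca²⁺ movies, line-scan flow
data, or vessel morphometry:

- **Event calling** — per-cell traces are normalized to their minimum
  fluorescence over consecutive 100-frame windows; a Ca²⁺ event is a
  maximal run of frames with MFI > 1.5 × windowed minimum (a >50% rise).
  Per cell: activity status, frequency (events/min), average duration
  (total signaling time / event count), and the >1 SD classification of
  high-frequency / high-average-duration cells.
- **Persistent activity** — cells whose MFI stays above 170 (on the 0–255
  scale) for minutes at a time never fall back to a usable minimum, so they
  are detected by time spent above that absolute threshold.
- **Cluster analysis** — the vessel surface is tiled into
  0.0076 × 0.0076 mm² grids; grids carrying events that are spatially
  adjacent and active at the same frame or one frame apart are linked into
  multicellular clusters, and participating ECs are counted from nuclear
  centroids.
- **Longitudinal conservation** — for revisits of the same cells days to
  weeks apart: maintained-status proportion, a χ² goodness-of-fit test
  (df = 1) against the expected Day-0 active proportion p₀, retention of
  dynamics classes, and percent-change-of-per-mouse-means treatment
  comparisons.
- **Line-scan flow** — cells transiting a repeatedly scanned line through
  fluorescent plasma appear as intensity valleys; valleys per 600-sample
  (2 s) block give flux in cells/s, blocks are labeled against the Ca²⁺
  channel (1.5 × minimum block mean), and flow changes are compared between
  signaling and non-signaling periods.
- **Morphometry & permeability** — fully enclosed vascular loops (area,
  perimeter, centroid, equivalent diameter = √(4A/π)); linear EC density
  per skeleton segment (nuclei snapped to the skeleton, retained under
  10 µm; geodesic segment lengths); extravascular dextran intensity
  normalized to the pre-injection recording.
- **Synthetic data** — every input above can be generated with planted
  ground truth (events, transits, loops, segment assignments), so the whole
  stack is testable without microscopy data.

## Worked example

```python
import numpy as np
from capnet import synthetic, traces, events

# a control-like recording: 50 cells, half active, 300 frames at 3.44 s
spec = synthetic.RecordingSpec(n_cells=50, active_fraction=0.5, rng_seed=1)
movie, labels, truth = synthetic.generate_recording(spec)

rec = traces.Recording(movie, frame_interval=3.44)
wide = traces.traces_to_frame(traces.extract_traces(rec, labels))
table = events.call_events_table(wide, frame_interval=3.44)
dyn = events.compute_dynamics(table, rec.n_frames, rec.frame_interval,
                              cell_ids=list(wide.columns))

active = dyn[dyn.status == "active"]
print(f"{len(table)} events; {len(active)}/{len(dyn)} cells active")
print(f"mean frequency {active.frequency.mean():.3f} events/min; "
      f"mean avg duration {active.avg_duration.mean():.1f} s")
```

prints

```
191 events; 25/50 cells active
mean frequency 0.444 events/min; mean avg duration 9.7 s
```

191 planted events are recovered with exact start/end frames; half the
cells are active by construction, and the active cells' mean frequency and
average event duration sit at the generator's homeostatic defaults
(0.45 events/min, ~8–10 s per event). The same pipeline is available from
the shell:

```bash
capnet simulate recording --seed 1 --out sim/
capnet extract --movie sim/movie.tif --labels sim/labels.tif --out traces.csv
capnet events --traces traces.csv --out results/
```

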