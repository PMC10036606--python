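# closecontact

Quantitative image analysis of T-cell **close contacts** — the micron-scale
regions where a T cell pushes its membrane through the glycocalyx on an
antigen-presenting surface. On a supported lipid bilayer (SLB) carrying
fluorescently labeled glycocalyx proteins (CD43/CD45), these contacts appear
in TIRF microscopy as small dark holes in an otherwise uniform fluorescent
layer. Their size, glycocalyx exclusion, persistence, and relation to
calcium signaling are the quantities this package measures.

The package is aimed at quantitative microscopists analyzing SLB–T-cell
TIRFM time-lapses, and provides the full desk-scale pipeline:

- **`scene` / `render`** — synthetic ground-truth scenes rendered into
  realistic multi-channel TIRFM videos: Gaussian PSF (σ = 131 nm), binning
  to 107 nm camera pixels, and an EMCCD noise chain (Poisson photons →
  Gamma-distributed EM gain with excess-noise factor 2 → Gaussian read
  noise + offset). Every downstream stage is testable against known truth.
- **`segmentation`** — cell footprints (DoG + dual threshold + 3-D
  watershed over *(t, y, x)*) and close contacts (temporal rolling mean,
  Laplacian-of-Gaussian, hysteresis threshold at `h·std` of the
  outside-cell pixels, plus an intensity threshold for large late contacts).
- **`calcium`** — bulk calcium assay: track hundreds of cells, classify
  adhesion (speed stays < 0.2 μm/s) and TCR triggering (≥ 3× baseline for
  ≥ 10 s, early spikes excluded), fit population cumulative curves.
- **`features`** — per-cell event tables (first membrane signal, adhesion,
  first close contact, calcium release, maximum footprint), the four
  interaction stages (searching → scanning → spreading → synapsing), and
  per-contact records: area, `exclusion_10 = 1 − p10(I_inside)/mean(I_outline)`,
  contact time.
- **`regions`** — protein enrichment (`mean_in/mean_out`) and CD45-style
  exclusion at contacts, and single-bound-ligand counting with
  motion-blur suppression of unbound molecules.
- **`stats`** — Kaplan–Meier stage-transition curves (exponential-Greenwood
  CIs, log-rank), constrained four-parameter dose-response fits (EC50),
  FCS-based molecular densities (`N = 1/G(0)`, `d = √(8 ln2 · D · τD)`),
  pFCS standard curves, and membrane surface area from confocal z-stacks.

## Worked example

Simulate a cell that forms two close contacts and triggers at t = 60 s,
then run the full segmentation and feature pipeline:

```python
import numpy as np
from closecontact import (GroundTruthScene, ContactTruth, constant_cell,
    simulate_video, correct_membrane_background, segment_membrane,
    label_cells, segment_close_contacts, measure_cell_calcium,
    detect_events, assign_stages, contact_features)

scene = GroundTruthScene(
    field_size_um=(14, 14), n_frames=60, frame_interval_s=2.0,
    cells=[constant_cell((7, 7), 3.0, 60, trigger_s=60.0, frame_interval_s=2.0)],
    contacts=[ContactTruth((6.5, 7.0), 0.35, 0.7),
              ContactTruth((7.5, 6.8), 0.30, 0.5, birth_s=20.0)],
)
channels = simulate_video(scene, rng_seed=1)

membrane = correct_membrane_background(channels["membrane"])
cells = label_cells(segment_membrane(membrane), pixel_size_um=0.107,
                    frame_interval_s=2.0, intensity_video=membrane)
contacts = segment_close_contacts(channels["glycocalyx"], cells)

traces = measure_cell_calcium(channels["calcium"], cells)
events = detect_events(cells, contacts, traces)
print(events.round(1).to_string(index=False))

stages = {1: assign_stages(events.iloc[0], 60, 2.0)}
records = contact_features(contacts, channels["glycocalyx"], cells, stages)
print(records.groupby("contact_id").agg(
    area_um2=("Area (μm^2)", "mean"),
    exclusion_10=("exclusion_10", "mean"),
    lifetime_s=("contact_time (s)", "max")).round(3).to_string())
```

Output:

```
 cell_id  time_CZ_first (s)  time_adhesion (s)  time_CCZ_first (s)  time_Ca (s)  time_to_CZ_max (s)
       1                0.0                0.0                 0.0         62.0                78.0
            area_um2  exclusion_10  lifetime_s
contact_id
1              0.197         0.397       118.0
2              0.120         0.294       98.0
3              0.054         0.229       12.0
4              0.046         0.133        8.0
```

The event table recovers the scripted calcium trigger (truth 60 s, measured
62 s — one frame late) and the cell's interaction events; contact 1 (350 nm,
70% exclusion in truth) is measured at 0.20 μm² with `exclusion_10` ≈ 0.40 —
the PSF blur dilutes the true exclusion, which is exactly the bias the
simulation machinery is there to quantify. Contacts 3 and 4 are short-lived
fragments of the shallower 50%-excluded contact near the detection limit.

The same pipeline is available from the shell:

```bash
closecontact simulate --scene scene.yaml --seed 3 --out sim/
closecontact segment --glyco sim/glycocalyx.ome.tif --membrane sim/membrane.ome.tif --out seg/
closecontact features --labels seg/ --glyco sim/glycocalyx.ome.tif --calcium sim/calcium.ome.tif --out feat/
closecontact stats km --input durations.csv --out survival.csv
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and
its limits, parameter defaults, and numerical choices.
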