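# glmbtrack

Multi-object tracking with labelled random finite sets, for scientists who
need whole trajectories — with identities and, for dividing cells, lineage —
out of cluttered detections or raw image sequences: radar-style point
tracking, track-before-detect on low-SNR images, and cell tracking through
mitosis.

## The model and the estimator

The collection of objects at frame *k* is a labelled random finite set: the
number of objects, their kinematic states *x*, and their distinct labels
*l* are all random. The posterior over this set is kept in generalized
labelled multi-Bernoulli (GLMB) form,

> π(X) = Δ(X) Σ<sub>(I,ξ)</sub> ω<sup>(I,ξ)</sup> δ<sub>I</sub>(L(X)) [p<sup>(ξ)</sup>]<sup>X</sup>,

a weighted mixture over hypotheses (I, ξ) — a label set plus the complete
history ξ of label-to-measurement associations — with one Gaussian density
per label. The forward filter performs a joint prediction–update per scan:
survival/death per label (survival probability p<sub>S</sub>), birth and,
for cell division, spawning decisions (labels `(parent, k+1, i)` encode
ancestry), and a positive 1-1 association map θ from labels to measurement
indices, with miss factor q<sub>D</sub> and detection factor
p<sub>D</sub>·g(z|x)/κ(z) against Poisson clutter intensity κ. High-weight
child hypotheses are found with a systematic-scan Gibbs sampler and the
mixture is truncated to the heaviest `h_max` hypotheses. A hybrid
track-before-detect mode multiplies each miss factor by the image
likelihood ratio σ<sub>T</sub> of a Gaussian point-spread template, so
miss-detected objects are still updated by the raw pixels.

The tracker's second stage is a multi-scan estimator: after each update the
maximum a-posteriori hypothesis (conditioned on the MAP cardinality from
ρ(n) = Σ<sub>h</sub> ω<sub>h</sub> δ<sub>n</sub>(|I<sub>h</sub>|)) is
reduced to trajectory tuples (label, birth state, association history ξ̂);
tuples shorter than τ<sub>t</sub> frames are pruned; and each surviving
trajectory is re-filtered forward from its birth state along its own ξ̂ and
smoothed backward with a Rauch–Tung–Striebel pass (unscented variant for
constant-turn dynamics). Because every label is estimated as one contiguous
trajectory, the output is fragmentation-free by construction. Tracking
quality is scored with OSPA and OSPA(2) miss-distances, and lineage output
is written in Cell Tracking Challenge `L B E P` form.

## Worked example

Simulate a 40-frame constant-velocity scenario (four birth sites, 66
uniform clutter points per scan, p<sub>D</sub> = 0.95, σ<sub>ε</sub> = 15 m
position noise), track it, and score it:

```sh
$ cat cfg.yaml
scenario: {K: 40}
filter: {h_max: 500, gibbs_sweeps: 300}

$ glmbtrack simulate --scenario linear --config cfg.yaml --out sim40 --seed 7
wrote 40 scans, 9 truth tracks to sim40

$ glmbtrack track --scans sim40/scans.csv --scenario linear --config cfg.yaml --out trk --seed 7
tracked 40 frames: 10 trajectories (0 pruned)

$ glmbtrack evaluate --truth sim40/truth.csv --tracks trk/tracks.csv --out ev
mean OSPA 12.425, mean OSPA2 14.660 over 40 frames
```

`trk/tracks.csv` holds the smoothed per-frame states of each trajectory,
`trk/res_track.txt` the lineage lines (`track begin end parent`), and
`ev/metrics.csv` the per-frame breakdown:

```
frame,ospa,ospa_loc,ospa_card,ospa2,cardinality_true,cardinality_est
1,1.7094892570758622,1.7094892570758622,0.0,1.7094892570758622,4,4
2,23.81209650165461,3.8120965016546107,20.0,22.81876701946456,4,5
3,26.577634621786224,6.577634621786221,20.0,24.352562615464706,4,5
```

A mean OSPA of 12.4 m at cutoff c = 100 m means the estimated object sets
sit, on average, within ~12 m of the truth once localization and
cardinality errors are combined; the frame-2/3 spikes are the 20 m
cardinality charge of one extra tentative track before the filter's
evidence settles. The same `track` command with `--mode spawning` on a cell
scenario emits daughters whose `parent` column and `L B E P` lines follow
the decoded spawn ancestry, and `--mode hybrid --images sim/images.tiff`
runs the track-before-detect update.

The same pipeline is available in Python:

```python
import numpy as np, glmbtrack as g

cfg = g.default_config("cell", K=50)
truth, scans = g.generate_cell_scenario(cfg, seed=1)
res = g.run_tracker(scans, g.build_models(cfg),
                    g.FilterSettings(h_max=800, gibbs_sweeps=600),
                    np.random.default_rng(1), mode="spawning", tau_t=3)
for t in res.trajectories:
    print(t.label, "parent:", t.parent, "frames", t.birth_frame, "-", t.last_frame)
```

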