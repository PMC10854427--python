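# ethoarena

Multimodal indoor-arena animal-tracking toolkit, exercised entirely on a
built-in synthetic-arena simulator:

- **`ethoarena.synth`** — arena/scene generator: regime-switching bird
  trajectories with ground-truth behavior labels, harmonic call waveforms,
  and physically consistent multichannel audio rendering (per-channel
  propagation delays via windowed-sinc sub-sample interpolation, 1/r
  spreading, controlled SNR).
- **`ethoarena.acoustics`** — band-pass filtering, energy-envelope event
  detection, SNR-based channel selection, cross-correlation TDOA estimation
  with parabolic sub-sample refinement, bounded nonlinear least-squares 3D
  multilateration, and leave-one-receiver-out error spread.
- **`ethoarena.fusion`** — rigid (6-DOF, no scale) point-set registration via
  Kabsch/SVD with degeneracy checks, and robust constant-offset timestamp
  alignment between event streams.
- **`ethoarena.behavior`** — speed estimation, height/speed behavior
  classification (perching / foraging / flying / other), synchronized
  foraging-initiation chaining, per-category and overall Jaccard similarity,
  directional correlation with delay, and highly-correlated-segment (HCS)
  coordination networks.
- **`ethoarena.bioacoustics`** — spectral features (peak/center frequency,
  90% bandwidth, 90% duration, inflection points, aggregate entropy), PCA
  embedding, call-to-zone assignment, and call-to-individual assignment
  (30 cm / 50%-farther rule).
- **`ethoarena.gaze`** — head-centric frame calibration from eye/beak
  keypoints, marker-label repair by per-section permutation search, horizon
  (median roll/pitch) correction, fovea and red-area ray projection, and
  sky-dome gaze-density histograms.
- **`ethoarena.closedloop`** — Y-maze geometry, turn evaluation, a
  closed-loop trial controller (settle → signal → evaluate → reward, with a
  5 s detour rule), simulated agents, and the exact cumulative binomial
  success test.

## CLI

A single `ethoarena` entry point with subcommands. Every command writes a
`*.meta.json` sidecar with the package version, seed and a hash of the
effective parameters.

```sh
# full synthetic pipeline into one directory
ethoarena demo --out demo_run --seed 0

# individual stages
ethoarena simulate --out scene --seed 1 --n-birds 3 --duration 10
ethoarena localize --audio scene/audio.wav --mics scene/mics.csv \
    --band 300 15000 --out events.json
ethoarena register --pairs pairs.csv --out T.json
ethoarena classify --tracks scene/tracks.csv --out labels.csv
ethoarena coordination --tracks scene/tracks.csv --out edges.csv
ethoarena features --audio scene/audio.wav --events events.json --out feats.csv
ethoarena assign --events events.json --tracks scene/tracks.csv --out assigned.json
ethoarena gaze --poses poses.csv --dome dome.csv
ethoarena ymaze-sim --agent obedient --trials 20 --seed 7 --out log.jsonl
```

## Conventions

- Coordinates in meters; the arena box has its origin at one floor corner.
- Track CSV columns: `frame,time_s,id,x_m,y_m,z_m[,qw,qx,qy,qz]`.
- Microphone CSV columns: `id,x,y,z`.
- Head-frame Euler angles are intrinsic z–x′–y″ (yaw, pitch, roll); gaze
  azimuth is measured clockwise from the beak (+y) toward the right eye
  (+x), elevation from the horizon plane.
- Audio is float32 WAV, channels × time in memory, samples × channels on
  disk.
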