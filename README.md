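# plasmotaste

Simulation and analysis pipeline for a 24-element cross-reactive
plasmonic sensor chip that fingerprints liquids ("artificial taste").

A physics-based simulator renders the hyperspectral frames such an
instrument produces; the analysis pipeline converts frames to
transmission spectra, extracts the plasmonic transmission minimum of
each element by spline fitting, assembles 24-element wavelength-shift
fingerprints against a rolling deionized-water baseline, fits adsorption
kinetics, and classifies liquid samples by class and identity with
PCA / stratified LDA / two-way hierarchical clustering.

## Layout

| module | what it does |
| --- | --- |
| `plasmotaste.synthetic_chip` | chip layout (55 slits: 24 sensors, 23 light references, 8 edge blanks), sensor chemistries, sample catalog and refractive indices, Langmuir + first-order response model, frame rendering, TIFF+sidecar I/O |
| `plasmotaste.readout` | frame combination, aperture sectioning, sensor/reference normalization, resampling to the uniform 0.1 nm grid |
| `plasmotaste.dipfind` | smoothing-spline transmission-minimum extraction and detectable-shift estimation |
| `plasmotaste.fingerprinting` | measurement schedules, rolling DI baselines, fingerprint assembly, full simulated sessions, rinse/baseline-reversion QC |
| `plasmotaste.kinetics` | saturating on-curve fits `a·(1−exp(−k·t))` and per-sensor kinetic feature tables |
| `plasmotaste.chemometrics` | row-mean standardization, PCA, 50:50 stratified LDA with confusion matrices, two-way HCA |

## CLI

```sh
# simulate a full session (35 beverages x 3 replicates) -> 1230-row matrix
plasmotaste simulate --out fingerprints.csv --session-seed 7 --catalog-out catalog.csv

# class-level LDA on a 50:50 stratified split
plasmotaste classify --matrix fingerprints.csv --label class_label --seed 7

# PCA scores/loadings/variance tables
plasmotaste pca --matrix fingerprints.csv --out-prefix pca

# two-way hierarchical clustering of per-replicate mean fingerprints
plasmotaste hca --matrix fingerprints.csv --cut 6
```

The fingerprint matrix CSV (`sample_id, class_label, replicate, time_s,
status, s01..s24`) is the contract between acquisition and chemometrics.

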