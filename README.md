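# ufcosy

Simulation, reconstruction and evaluation toolkit for **interleaved
ultrafast (single-scan spatially encoded) 2D COSY** with multi-band solvent
suppression, aimed at high-dynamic-range mixtures such as wine (water and
ethanol orders of magnitude above the metabolites).

The package forward-models the acquisition — EPSI readout with bipolar
gradient lobes, interleaved scans with incremented pre-acquisition delays,
frequency-selective multi-band suppression, receiver-gain/digitiser noise,
per-transient jitter — reconstructs 2D magnitude spectra with the matching
processing chain, and computes SNR, peak-volume/CV repeatability, ghost
artefact and detectability metrics.

## Modules

| module | role |
| --- | --- |
| `ufcosy.mixture` | spin systems, first-order multiplets, 2D peak lists, wine-like fixture |
| `ufcosy.sequence` | pulse-sequence parameters, derived geometry (sample length, encoding constant, spectral widths, interleave delays, duration) |
| `ufcosy.suppression` | multi-band suppression presets (none/presat/msup/wet), receiver-gain and two-component noise model |
| `ufcosy.simulate` | raw interleaved EPSI transients with jitter/noise, deterministic seeding |
| `ufcosy.recon` | lobe splitting/merging, ultrafast + conventional axis processing, two-point chemical-shift calibration |
| `ufcosy.metrics` | row-extracted SNR, peak volumes, CV, ghost prediction, detectability counts |
| `ufcosy.io` / `ufcosy.cli` / `ufcosy.workflow` | containers, YAML configs, optional Bruker reader, CLI, end-to-end demo |

## CLI

```bash
# simulate the built-in wine fixture with multi-band suppression
ufcosy simulate --suppression msup --seed 1 --out raw.uf

# reconstruct (512 x 1024 magnitude spectrum) and calibrate on TSP/tartrate
ufcosy reconstruct raw.uf --calibrate auto --out spec.uf2 --export-csv spec.csv

# SNR and relative peak volumes for a peak-definition table
ufcosy metrics spec.uf2 --peaks peaks.tsv --out report.json

# predicted interleaving ghost positions for a parent peak
ufcosy ghostmap spec.uf2 --parent-f2 4.79 --ni 8 --factors 1.01,1,1,1,1,1,1,1

# four-scheme suppression comparison (none/presat/msup/wet)
ufcosy demo --seed 1 --out demo_out/
```

Mixtures are TSV tables (`system, site, shift_ppm, n_protons, J_partner,
J_hz, concentration, class, T2_s`); a wine-like fixture ships with the
package (`ufcosy/data/wine_fixture.tsv`) and via
`ufcosy.mixture.wine_fixture()`. Sequence/processing settings live in a
YAML `RunConfig` (see `ufcosy.io.RunConfig`).

## Notes

- The simulator is a first-order (weak-coupling) peak-list model, not a
  density-matrix simulation; cross-peak transfer amplitudes and suppression
  band floors are documented phenomenological knobs.
- The default idealized readout mode freezes chemical-shift evolution
  within a gradient lobe; `mode="realistic"` enables intra-lobe evolution
  (uncorrected peak shear).
- An optional reader for 2D vendor raw directories
  (`ufcosy.io.read_bruker2d`) feeds external data into the same chain.
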