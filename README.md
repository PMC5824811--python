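# synaptoflux

Quantitative fluorescence analysis of synaptic vesicle pools and membrane
order, for the imaging modalities used to study how culture substrates (for
example graphene coatings vs. bare glass) change presynaptic function in
hippocampal neurons:

- **Puncta segmentation** — pooled cell-free background statistics, a common
  mean + 2·SD threshold, marker-controlled watershed splitting, and 0.3–3 µm
  particle-size limits isolate synaptic boutons (~1 µm) in FM-dye, filipin,
  TopFluor-cholesterol or Synaptophysin channels.
- **Per-ROI statistics** — background-subtracted mean intensities, the
  clustering index (within-punctum pixel SD), ΔFM before/after exhaustive
  stimulation, percent differences, channel-vs-channel OLS regression,
  Cohen's *d*, two-sample Kolmogorov–Smirnov tests, and geometric Sholl
  intersection counts.
- **FM destaining kinetics** — first-10-frame normalization, end-window
  destaining extent, and single-exponential-with-plateau rate fits.
- **Quantal quantum-dot analysis** — maximum-likelihood unit (single-Qdot)
  photoluminescence on 30 a.u. bins, background-derived single-Qdot cutoffs,
  vesicle counts (total/unit), five-frame trace smoothing, and fusion-event
  classification into fast-and-reversible fusion (FRF, "kiss-and-run") vs.
  full-collapse fusion (unitary Qdot loss), with FRF-ratio time courses.
- **Generalized polarization (GP) imaging** — G-factor calibration on a
  reference solvent (GP_DMSO = 0.006), per-pixel GP maps
  (I_blue − G·I_green)/(I_blue + G·I_green), pooled-pixel distributions and
  between-condition shifts.
- **Spectra and assays** — Beer–Lambert transmittance (ε = 2460 L g⁻¹ m⁻¹),
  broadband absorbance correction F·(2 − T), nine-point Savitzky–Golay
  smoothing, and cholesterol standard-curve quantification (0–20 µM).
- **Synthetic data generation** — every acquisition mode above can be
  simulated with known ground truth (spot positions and intensities, decay
  rates, unit intensities, event schedules, GP fields, concentrations), so
  the entire pipeline is testable end to end without any external data.

## Worked example

Estimate vesicle pools by quantal analysis: generate 1000 single-Qdot
intensities (378 ± 41 a.u.), fit the unit photoluminescence by maximum
likelihood, then count vesicles per bouton as the background-subtracted
total over the unit for two conditions programmed at 23.2 and 29.2
vesicles/bouton:

```python
from synaptoflux.synthgen import ConditionSpec
from synaptoflux.pipeline import qdot_pool_experiment

report = qdot_pool_experiment(
    ConditionSpec(name="glass", vesicles_per_bouton_mean=23.2),
    ConditionSpec(name="graphene", vesicles_per_bouton_mean=29.2),
    seed=42,
)
print(report["unit_intensity"])      # 377.09843851829083
print(report["mean_vesicle_count"])  # {'glass': 23.9, 'graphene': 29.2}
print(report["ks"])                  # {'D': 0.426..., 'p': 3.47e-16}
```

The fitted unit intensity (377.1 a.u.) recovers the programmed 378 a.u.;
dividing each bouton's total by it recovers the programmed pool sizes, and
the KS test confirms the two pooled intensity distributions differ.

The same composition is available from the shell:

```bash
synaptoflux demo --seed 0 --outdir demo_out      # every experiment, small scale
synaptoflux simulate --kind boutons --outdir sim # one synthetic FOV + truth
synaptoflux segment sim/boutons.tif --bg-mean 100 --bg-sd 10 --out rois.csv
synaptoflux run config.yaml                      # config-driven pipeline
```

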