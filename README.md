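# gammalfp

Band-resolved local-field-potential (LFP) analysis for pulsed-ultrasound
gamma-entrainment experiments, with a ground-truth synthetic LFP generator so
every stage is testable without animal data.

## What it does

- **`gammalfp.synthlfp`** — synthetic recordings with known ground truth:
  1/f background, band-limited oscillators in the five canonical bands
  (delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–70 Hz),
  phase-amplitude-coupled gamma with tunable coupling strength, a 40-Hz
  evoked component with von Mises phase locking to pulse onsets, and a
  deterministic electromagnetic-style artifact shared by a paired
  live/dead recording (`simulate_recording_pair`, `simulate_cohort`).
- **`gammalfp.spectral`** — Welch PSD (1-s Hann windows, 50% overlap,
  per-segment linear detrend) and half-open band-power decomposition; the
  five default bands partition [1, 70) Hz exactly.
- **`gammalfp.pac`** — zero-phase band-pass + Hilbert phase/amplitude, the
  Tort modulation index (normalized KL divergence of the phase-binned
  amplitude distribution, 18 bins by default), and time-shift surrogate
  significance testing.
- **`gammalfp.entrainment`** — trial segmentation around stimulation onsets,
  complex Morlet time-frequency power (7 cycles, L2-normalized wavelets),
  live/dead artifact subtraction (power-domain, floored at zero; an exact
  per-trial complex route is also provided), and inter-trial phase coherence
  ITPC(t) = |(1/N) Σ exp(iθ_k(t))|.
- **`gammalfp.dosimetry`** — pulse-scheme arithmetic: duty cycle,
  I_spta ↔ I_sppa conversion, plane-wave peak-pressure estimate, mechanical
  index, and regulatory flags (I_sppa ≤ 190 W/cm², MI < 1.9).
- **`gammalfp.cohort_pipeline`** — end-to-end orchestration with the
  two-branch group-comparison rule (Shapiro–Wilk per group, then one-way
  ANOVA or Kruskal–Wallis), TSV/JSON ingestion and emission, and a manifest
  of file digests for bitwise reproducibility.

## CLI

```bash
gammalfp simulate  --config sim.json --out pair/          # live/dead pair
gammalfp psd       --signal pair/live.tsv --out psd.tsv
gammalfp bandpower --psd psd.tsv --fs 1000 --out bp.tsv
gammalfp pac       --signal pair/live.tsv --phase-band 4:8 --amp-band 30:70 \
                   --surrogates 200 --seed 7 --out pac.json
gammalfp entrain   --live pair/live.tsv --dead pair/dead.tsv \
                   --events pair/events.tsv --prf 40 --out report/
gammalfp dose      --scheme scheme.json --out dose.json
gammalfp run       --config pipeline.json --out run/
gammalfp demo      --seed 0 --out demo/                    # bundled 3-group cohort
```

Signal files are TSV with `time_s`/`value` columns; events files hold one
onset time (seconds) per line; configs are JSON (`SimConfig.to_json()` /
`from_json` round-trip).

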