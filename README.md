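# chronicsense

Analyses for chronic deep-brain stimulation (DBS) sensing sessions —
evoked-potential extraction, LFP spectral quantification, directional-contact
ranking, stimulation-response suppression scoring, cross-region lag
estimation, and electrode impedance trending — driven by a seeded synthetic
cohort generator so that every stage is testable without recorded animal
data.

## Layout

| module | purpose |
| --- | --- |
| `chronicsense.core_model` | lead geometries, bipolar pairs, recordings, stimulation settings/events |
| `chronicsense.synthetic_cohort` | seeded generator: theta/sharp-wave/sleep LFP states, EP trains, burst ramps, directional sweeps, longitudinal impedance timelines |
| `chronicsense.spectral` | Welch/Hann amplitude spectral density (uV/sqrt(Hz)), spectrograms (dB, 40 dB display range), band power, peak frequency |
| `chronicsense.evoked` | stimulus-artifact detection, artifact-blanked epoch averaging, EP metrics, burst-response classification with suppression / after-discharge thresholds |
| `chronicsense.directional` | 15-pair sense montage for 1-3-3-1 leads, radial spectra, per-segment power ranking, per-minute suppression profiles, rank concordance (R^2 + signed r) |
| `chronicsense.network` | spike-event detection, event-matched cross-correlation lag, propagated / far-field / uncoupled classification |
| `chronicsense.device_health` | scalar impedance \|Z\| = \|V/I\|, stabilization and breakage trending |
| `chronicsense.io` / `cli` / `pipeline` | CSV session bundles, `chronicsense` CLI, end-to-end deterministic pipeline |

Sessions are interchanged as plain-text CSV bundles (a `manifest.json` plus a
`samples.csv` of microvolt columns, channel labels in the `LEAD_Ex-Ey`
dialect); stimulation events travel in the manifest.

## CLI

```sh
chronicsense simulate --seed 1 --months 6 --out cohort/
chronicsense spectra  --session cohort/month01 --channel HC_E0-E3 --out psd.csv
chronicsense ep       --session ep_session/ --channel HC_E0-E3
chronicsense rank     --session sweep/ --lead-id HC
chronicsense suppress --session sweep/ --channel HC_E0-E1a
chronicsense couple   --session night/ --source HC_E0-E3 --target AN_E0-E3
chronicsense impedance --current-ma 1 --voltage-v 1.2
chronicsense run      --seed 1 --out report/
```

`chronicsense run` executes the whole pipeline (simulate → spectra → EP →
burst → rank → suppress → concordance → couple → impedance) and writes tidy
CSV tables, figures, and a `summary.json` that embeds the configuration;
re-running the same config reproduces every numeric output byte for byte.
Exit codes: 0 ok, 1 input error, 2 stage failure.

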