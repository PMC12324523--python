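# dopsig

Signal-processing and behavioral-metric pipeline for in-vivo dopamine
studies, exercised end-to-end on synthetic data with known ground truth.

The package covers five analysis stages plus their generators:

| module             | what it does |
|--------------------|--------------|
| `dopsig.synth`     | synthetic inputs with ground truth: dual-channel photometry (shared bleach/motion, dopamine transients in one channel), operant/gustometer event logs, stimulated FSCV sweeps, circadian activity series, injection sessions |
| `dopsig.photometry`| block-mean downsampling, isosbestic OLS correction, `dFF = 100·(sig − fit)/fit`, full-session z-scoring |
| `dopsig.events`    | peri-event trial alignment, ITI-baseline subtraction, AUC/peak metrics per event window, spontaneous-transient detection by peak prominence, post-injection mean/slope/latency-to-plateau, metric-vs-latency correlation |
| `dopsig.fscv`      | transient quantification (Imax, Tau1 from a single-exponential decay fit), calibration against a 1 µM standard, middle-three session summaries, command-waveform scan-rate bookkeeping |
| `dopsig.circadian` | hourly binning, interdaily stability, intradaily variability, light/dark phase sleep and activity summaries |
| `dopsig.operant`   | CRF/FI completion percentages and latencies, fixed-interval scallop curves, dipper-training retrieval, lick microstructure |

## CLI

One entry point with a subcommand per stage; all formats are plain CSV
(sidecar JSON for metadata):

```sh
dopsig dff       --in rec.csv --out trace.csv --factor 10
dopsig events    --trace trace.csv --events ev.csv --align lever_extension
dopsig spont     --trace trace.csv --iti 10:40 --iti 60:90 --threshold-sd 2
dopsig amph      --trace trace.csv --injection-time 1800 --horizon 3600
dopsig fscv      --in sweep.csv --stim-time 5.0 --calibration 0.01
dopsig circadian --in activity.csv
dopsig operant   --in session.csv --schedule FI --interval 8 --scallop-bins 6
```

File contracts: photometry CSV `time_s,sig_465,ref_405`; events CSV
`event_type,time_s,trial_index` (event types: lever_extension, lever_press,
dipper_up, dipper_down, head_entry); FSCV CSV `time_s,value` + `.csv.json`
sidecar; activity CSV `epoch_start_s,activity,sleep_state`.

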