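# porecount

Amplification-free quantification of mitochondrial DNA (mtDNA) copy number
from solid-state nanopore recordings.

## The problem

The mtDNA:gDNA copy ratio is a disease biomarker, but the standard qPCR
readout depends on amplification efficiency. A solid-state nanopore counts
molecules digitally: each DNA molecule driven through the pore produces a
transient current blockade, and native (protein-complexed) mtDNA produces
blockades with strong internal current fluctuations that clean linear dsDNA
of the same length lacks. Classifying every blockade and counting classes
turns a single-channel current recording into a copy-number assay with
binomial (not bulk) counting error.

`porecount` implements the full analysis chain for this assay, plus a
calibrated synthetic-data generator so every stage is testable without
instrument data:

1. **simulate** — ion-current traces with square translocation pulses,
   exponential-tailed dwell times (characteristic times 57 / 680 / 1,280 μs
   for gDNA fragments, 17 kbp linear dsDNA and mtDNA), truncated-normal
   fractional blockages, and a per-event blocked-level RMS population of
   1.1 ± 0.8 nA for mtDNA vs 0.16 ± 0.04 nA for linear dsDNA (≥6-fold
   separation), realised by a two-state sub-blockade (telegraph-like)
   process inside mtDNA pulses. Also: spike-in count series and synchronous
   1 kHz photon-frame series, all with exact ground truth.
2. **detect** — robust open-pore baseline (windowed medians + MAD noise),
   threshold/hysteresis event calling, and the six per-event parameters:
   i_o, i_b, t_D, ΔI = i_o − i_b, I_B = i_b/i_o, and i_rms (the SD of the
   blocked current).
3. **classify** — the three-feature representation (I_B, log₁₀ t_D, i_rms),
   class balancing, one-vs-one SVM with Gaussian kernel
   K(x,y) = exp(−‖x−y‖²/s²) at kernel scale s = 2 on z-scored features,
   stratified 5-fold cross-validation (standardization refit per fold),
   confusion matrices, TPR/FNR, one-vs-rest AUC, and the
   structural-feature rate.
4. **quantify** — the digital ratio R_NP = n_mt/(n_mt + n_frag) with Wilson
   intervals; the spike-in calibration model
   R(m) = (N_mt + c·m)/(N_mt + c·m + N_g), c = copies per ng at the mtDNA
   length (16,569 bp), fit by weighted nonlinear least squares to recover
   the endogenous copy number; conversions to qPCR-scale copy ratios and
   mass/mass percentages.
5. **optical** — photon-burst detection (background + 10×RMS threshold) and
   electro-optical synchrony of bursts with translocation events against a
   circular-shift null.

## Worked example

```python
import porecount as pc
from porecount.classify import SVMConfig

# train a two-class model on pure-sample feature draws
frames = [pc.sample_event_features(pc.DEFAULT_CLASSES[l], 1500, s)
          for s, l in enumerate(("fragment", "mtDNA"))]
fs = pc.balance_classes(pc.build_features(frames), seed=0)
report = pc.cross_validate(fs, SVMConfig(seed=0))
art = pc.train_svm(fs, SVMConfig(seed=0))

# simulate a biosample recording (fragments ~10x mtDNA), detect, classify
spec = pc.TraceSpec(duration_s=4.0, event_rate_hz=120.0, seed=0)
trace, truth = pc.synth_trace(spec)
baseline = pc.estimate_baseline(trace)
events = pc.events_to_frame(
    pc.extract_features(trace, pc.detect_events(trace, baseline), baseline))
labels, _ = pc.predict(art, pc.build_features(events.assign(label="fragment")))
print(pc.compute_ratio(labels))
```

prints (445 of 445 scheduled events detected; the true mtDNA fraction in
this run is 0.099):

```
CountSummary(n_mt_events=44, n_frag_events=401, R_NP=0.0989,
             ci_low=0.0744, ci_high=0.1303)
```

so the digital count recovers the simulated mtDNA fraction inside its 95%
Wilson interval. Fitting a simulated spike-in series (six masses, 35–300 ng,
2,000 events per run) at the endogenous operating point N_mt = 2.53×10⁹,
N_g = 9.24×10⁹ returns `N_mt = 2.82e9 ± 3.4e8`, recovering the endogenous
copy number within its counting uncertainty.

The same flow is available from the shell:

```
porecount pipeline --seed 5 --outdir out/       # simulate→detect→train→quantify
porecount simulate / detect / train / predict / quantify / fit-spikein /
          optical-correlate --help
```

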