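# Methods

## Signal model

A solid-state nanopore recording is modelled as an open-pore current
baseline i_o with additive white Gaussian noise, interrupted by square
translocation pulses. Each pulse drops the current to a blocked level
i_b = I_B·i_o for a dwell time t_D and carries an in-event fluctuation
process whose sample SD is the event's i_rms. Defaults: i_o = 10 nA,
baseline noise SD 0.03 nA, sampling rate 500 kHz (comfortably above twice
the 100 kHz analog low-pass of the emulated amplifier chain), bias
150 mV. None of i_o, the noise SD or the digitisation rate is critical to
the analysis; all are configurable.

### Event classes

Three event classes model the constituents of an enzymatically prepared
biosample:

| class | dwell tail (μs) | I_B | i_rms (nA) | fluctuation |
|---|---|---|---|---|
| gDNA fragment | 57 | 0.92 ± 0.03 | 0.12 ± 0.04 | Gaussian |
| mtDNA (16.6 kbp, native) | 1,280 | 0.70 ± 0.05 | 1.1 ± 0.8 | telegraph |
| linear dsDNA 17 kbp (syDNA) | 680 | 0.81 ± 0.03 | 0.16 ± 0.04 | Gaussian |

plus a plasmid preset (pcDNA3.1, 5.4 kbp: 546 μs, 0.81 ± 0.03,
0.2 ± 0.07 nA). Dwell tails and the i_rms moments for mtDNA, syDNA and
pcDNA are measured population values; the I_B means/SDs for fragments and
mtDNA and the fragment i_rms are free parameters fixed once from the
observed orderings (fragments shallowest and fastest; mtDNA deepest,
longest, and ≥6-fold higher i_rms than syDNA). The default class mixture
is fragments:mtDNA ≈ 10:1, the steady state of exonuclease-V digestion of
linear gDNA.

### Dwell times

Dwells are drawn as floor + Exp(τ − floor) with floor 20 μs, so the mean
dwell equals the characteristic time τ and the distribution's upper tail
is exponential with scale τ − floor. Only the tail law is empirically
constrained; the floor is a simplification standing in for the unresolved
short-event regime. Consequence: an exponential fit to the tail of mtDNA
dwells recovers τ − floor = 1,260 μs rather than 1,280 μs, a 1.6% shift
well inside the fit uncertainty (±75 μs); for the fragment class
(τ = 57 μs) the shift is material (−35%), so tail-based calibration
checks are made on the mtDNA/syDNA classes.

`fit_dwell_tail` estimates the characteristic time as the mean excess of
dwells above the median — the maximum-likelihood estimator for an
exponential tail, with sampling SD τ/√n_tail (≈ 56 μs at 1,000 events),
several-fold tighter than a log-histogram regression.

### In-event fluctuations and per-event RMS calibration

Each scheduled event draws an i_rms target from a log-normal matched to
its class moments. Inside the pulse the target is realised (on top of
baseline noise, combined in quadrature) by:

- **Gaussian classes** — white noise at the residual SD; models the
  mild excess fluctuation of clean dsDNA blockades.
- **mtDNA (telegraph)** — a two-state switching process at 5 kHz mean
  rate: a majority level slightly above i_b and a minority deep
  sub-blockade level, the picture of transient protein-bound regions
  transiting the pore. The two levels are set per event from the realised
  state occupancy so that the wave has exactly zero mean (leaving I_B
  unbiased) and exactly the target SD over the pulse interior (10% edge
  trim, the same convention under which blocked-level statistics are
  measured downstream). A symmetric telegraph is *not* used for traces:
  its upward excursions would re-cross the detector's close threshold for
  large targets and split events; the symmetric primitive is retained as
  `telegraph_wave` (sample SD → depth/2).

Physical realizability bounds the process: in-pulse current must stay in
(0, i_o − 8σ_baseline), so the largest zero-mean SD a pulse can carry is
√(i_b·(i_o − i_b)) ≈ 4 nA at defaults. Events whose target cannot ride on
the realised duty cycle redraw the switching sequence at the
variance-optimal duty cycle (fast enough that short pulses realise it);
targets beyond the hard ceiling (top ≈1% of the mtDNA population)
saturate. Net effect: the trace→detect path recovers the mtDNA i_rms
population mean to ≈2%, slightly below the nominal 1.1 nA because of the
ceiling truncation.

## Detection

Baseline: median of per-window medians (50 ms windows); noise SD as
1.4826×MAD of samples above an exclusion level six noise-SDs below i_o —
robust to ≤50% of samples sitting inside blockades. Events open when the
current crosses i_o − 6σ and close on re-crossing i_o − 1σ (hysteresis);
events shorter than 20 μs are discarded, longer than 100 ms are treated
as clogs, and events touching the trace ends are dropped. These constants
are configuration, chosen so that 57 μs fragment events are reliably
detectable at 500 kHz. Dwell time spans the full threshold-to-threshold
bounds; i_b and i_rms are computed on the interior with 10% trimmed from
each edge, and i_rms is the sample SD (ddof 1) of the raw blocked current
with no baseline-noise deconvolution.

## Classification

Features are (I_B, log₁₀(t_D/1 μs), i_rms); the log tames the
exponential dwell range. The classifier is a one-vs-one SVM with Gaussian
kernel K(x,y) = exp(−‖x−y‖²/s²), kernel scale s = 2 (the "fine Gaussian"
convention, i.e. sklearn gamma = 1/s² = 0.25) and box constraint C = 1,
applied to z-scored features. Class balancing downsamples to the minority
class so chance level is exactly 1/k. Evaluation is stratified 5-fold
cross-validation with the standardization record refit inside each
training fold (no leakage); reports aggregate out-of-fold predictions
into confusion matrices, per-class TPR/FNR and one-vs-rest AUC from
summed one-vs-one decision margins (which also break prediction ties
deterministically). Whether the original analysis standardized features
before kernel evaluation is not documented; standardization is our
choice, recorded in the model artifact so predictions are portable.

## Quantification

R_NP = n_mt/(n_mt + n_frag) over classified events, with a 95% Wilson
interval (binomial counting error — the digital advantage of the assay).
The spike-in calibration model treats spiked mass m as additional mtDNA
copies c·m with c = copies/ng = 10⁻⁹·N_A/(L·650 g mol⁻¹ bp⁻¹) at
L = 16,569 bp:

    R(m) = (N_mt + c m) / (N_mt + c m + N_g)

with endogenous copies N_mt and adjusted gDNA fragment count N_g free.
The fit is weighted nonlinear least squares (inverse binomial variance
per run), initialised from the line that the count odds R/(1−R) follow in
m, with nonnegativity bounds and curvature standard errors. The qPCR
linkage is a single scale factor κ on the count odds,
ratio_qPCR = κ·R/(1−R), and the mass/mass percentage scales the copy
ratio by L_mt/L_genome (diploid genome 6×10⁹ bp). The exact published
forms of these last three relations were not available; the implemented
forms are the simplest consistent with their described behaviour
(saturating ratio, single linking parameter, mass-per-copy
proportionality) and are isolated behind one interface so they can be
swapped.

## Electro-optical synchrony

Photon frames at 1 kHz carry Gaussian background (defaults: mean 100,
SD 30 counts/frame, floored at 0); labeled translocations elevate
overlapping frames by Poisson bursts (mean 400 counts/frame ≈ 10-fold
the background RMS), starting 0.5–3 ms before the electrical event (a
molecule dwelling at the pore mouth fluoresces before threading). Burst
detection thresholds at background mean + 10×RMS (strict inequality,
maximal runs); an event counts as correlated when a burst overlaps
[start − 5 ms, end + 1 ms]. The chance level uses a circular time-shift
of the burst train — preserving burst rate and durations, which drive
chance overlap — rather than label permutation.

## Problem sizes and determinism

Default verification sizes: 1,000–1,500 events per class for
classification experiments, ≥1,000 trace-simulated events per class for
the detector-path population checks (≈15 s of 500 kHz trace per class),
six spike-in masses × 2,000 events with 100 replicates for coverage.
All randomness flows through numpy Generators seeded explicitly;
fixed seeds reproduce traces, folds, artifacts and reports bit-for-bit.

## Limitations

- The generator emulates population statistics, not pore physics: no
  access-resistance or charge effects, no folded-molecule multi-level
  blockades, no baseline drift or 1/f noise, no clogging dynamics. Passing
  tests demonstrate the analysis chain is correct and well-calibrated on
  this statistical structure, not that it handles every artifact of real
  recordings.
- The i_rms population above ~4 nA is physically unrealisable at the
  default pulse geometry and saturates (top ~1% of mtDNA events).
- Class-abundance mixtures stand in for the enzymatic biochemistry; no
  attempt is made to model digestion kinetics.
- Heteroplasmy/deletion quantification is out of scope.
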