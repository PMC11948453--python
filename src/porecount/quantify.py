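"""Digital-count ratiometry and spike-in calibration.

The nanopore ratio R_NP = n_mt / (n_mt + n_frag) is a digital count over
classified translocation events, so its uncertainty is binomial.  Spiking
known mtDNA masses m into a fixed genomic-DNA background and measuring
R_NP at each mass traces out a saturating calibration curve

    R(m) = (N_mt + c m) / (N_mt + c m + N_g),   c = copies_per_ng(L_mt),

whose weighted nonlinear least-squares fit recovers the endogenous mtDNA
copy number N_mt and the adjusted gDNA fragment count N_g as free
parameters.  A single scale factor kappa links R_NP to qPCR-style
mtDNA:gDNA copy ratios, and a mass-per-copy proportionality converts copy
ratios to mass/mass percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AVOGADRO",
    "BP_GRAMS_PER_MOL",
    "MT_GENOME_BP",
    "DIPLOID_GENOME_BP",
    "CountSummary",
    "SpikeInSeries",
    "SpikeFitResult",
    "compute_ratio",
    "copies_per_ng",
    "spikein_model",
    "fit_spikein",
    "nanopore_to_qpcr",
    "qpcr_to_nanopore",
    "mass_ratio_percent",
]

AVOGADRO = 6.02214076e23
BP_GRAMS_PER_MOL = 650.0   # average molar mass of one dsDNA base pair
MT_GENOME_BP = 16_569      # human mitochondrial genome
DIPLOID_GENOME_BP = 6.0e9  # human diploid nuclear genome


@dataclass(frozen=True)
class CountSummary:
    """Digital event counts and the nanopore ratio with a 95% Wilson CI."""

    n_mt_events: int
    n_frag_events: int
    R_NP: float
    ci_low: float
    ci_high: float


@dataclass
class SpikeInSeries:
    """Paired (spiked mass, observed ratio, event count) calibration records."""

    masses_ng: np.ndarray
    observed_R: np.ndarray
    events_per_run: np.ndarray
    mt_length_bp: int = MT_GENOME_BP

    def __post_init__(self):
        self.masses_ng = np.asarray(self.masses_ng, dtype=float)
        self.observed_R = np.asarray(self.observed_R, dtype=float)
        self.events_per_run = np.asarray(self.events_per_run, dtype=int)
        if not (self.masses_ng.size == self.observed_R.size == self.events_per_run.size):
            raise ValueError("series columns must have equal length")
        if (self.masses_ng < 0).any():
            raise ValueError("masses must be nonnegative")
        if ((self.observed_R < 0) | (self.observed_R > 1)).any():
            raise ValueError("ratios must lie in [0, 1]")


@dataclass(frozen=True)
class SpikeFitResult:
    """Calibration-fit estimates (copies) with curvature standard errors."""

    N_mt_endo: float
    N_gdna_adj: float
    se_N_mt: float
    se_N_gdna: float
    residuals: np.ndarray

    def __post_init__(self):
        if self.N_mt_endo < 0 or self.N_gdna_adj < 0:
            raise ValueError("copy-number estimates must be nonnegative")


def compute_ratio(labels, mt_label: int = 1) -> CountSummary:
    """Count classified events and form R_NP with its 95% Wilson interval.

    Every event not assigned ``mt_label`` counts toward the fragment
    denominator, matching the two-class readout of biological samples.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no classified events")
    n_mt = int((labels == mt_label).sum())
    n_frag = int(labels.size - n_mt)
    lo, hi = proportion_confint(n_mt, labels.size, alpha=0.05, method="wilson")
    return CountSummary(n_mt_events=n_mt, n_frag_events=n_frag,
                        R_NP=n_mt / labels.size, ci_low=float(lo), ci_high=float(hi))


def copies_per_ng(length_bp: float) -> float:
    """Molecule copies per nanogram of dsDNA of the given length."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    return 1e-9 * AVOGADRO / (length_bp * BP_GRAMS_PER_MOL)


def spikein_model(mass_ng: float, N_mt_endo: float, N_gdna_adj: float,
                  mt_length_bp: float = MT_GENOME_BP) -> float:
    """Predicted nanopore ratio after spiking ``mass_ng`` of mtDNA.

    The spiked copies add to the endogenous pool, so the mtDNA event
    fraction saturates toward 1 with mass:
    R = (N_mt + c m) / (N_mt + c m + N_g).
    """
    if mass_ng < 0 or N_mt_endo < 0 or N_gdna_adj < 0:
        raise ValueError("arguments must be nonnegative")
    total_mt = N_mt_endo + copies_per_ng(mt_length_bp) * mass_ng
    denom = total_mt + N_gdna_adj
    if denom == 0:
        raise ValueError("model undefined with zero total copies")
    return total_mt / denom


def fit_spikein(series: SpikeInSeries) -> SpikeFitResult:
    """Weighted nonlinear least-squares fit of the spike-in calibration curve.

    Weights come from the binomial counting variance R(1-R)/n of each run;
    initial values from a linear fit of the count odds R/(1-R) versus mass,
    which the model predicts to be the line N_mt/N_g + (c/N_g) m.  Standard
    errors are taken from the local curvature at the optimum.
    """
    if np.unique(series.masses_ng).size < 3:
        raise ValueError("need at least 3 distinct spiked masses")
    c = copies_per_ng(series.mt_length_bp)
    m = series.masses_ng
    r = series.observed_R
    n = series.events_per_run.astype(float)
    r_safe = np.clip(r, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    sigma = np.sqrt(r_safe * (1.0 - r_safe) / n)

    odds = r_safe / (1.0 - r_safe)
    slope, intercept = np.polyfit(m, odds, 1)
    ng0 = c / slope if slope > 0 else c * m.max() / max(odds.max(), 1e-9)
    nm0 = max(intercept * ng0, 1e-3 * c * max(m.max(), 1.0))

    def model(mass, n_mt, n_g):
        tot = n_mt + c * mass
        return tot / (tot + n_g)

    last_err = None
    for p0 in ((nm0, ng0), (c * max(m.max(), 1.0), c * max(m.max(), 1.0))):
        try:
            popt, pcov = curve_fit(
                model, m, r, p0=p0, sigma=sigma, absolute_sigma=True,
                bounds=(0.0, np.inf), maxfev=20_000,
            )
            break
        except RuntimeError as err:  # pragma: no cover - second start rescues
            last_err = err
    else:
        raise RuntimeError(f"spike-in fit failed to converge: {last_err}")
    se = np.sqrt(np.diag(pcov))
    return SpikeFitResult(
        N_mt_endo=float(popt[0]),
        N_gdna_adj=float(popt[1]),
        se_N_mt=float(se[0]),
        se_N_gdna=float(se[1]),
        residuals=r - model(m, *popt),
    )


def nanopore_to_qpcr(R_NP: float, kappa: float) -> float:
    """Map the nanopore ratio to a qPCR-scale mtDNA:gDNA copy ratio.

    A single scale factor kappa absorbs the efficiency difference between
    the two assays: ratio = kappa * R_NP / (1 - R_NP).
    """
    if not 0.0 <= R_NP < 1.0:
        raise ValueError("R_NP must lie in [0, 1)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return kappa * R_NP / (1.0 - R_NP)


def qpcr_to_nanopore(ratio: float, kappa: float) -> float:
    """Inverse of :func:`nanopore_to_qpcr`."""
    if ratio < 0:
        raise ValueError("ratio must be nonnegative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    x = ratio / kappa
    return x / (1.0 + x)


def mass_ratio_percent(R_NP: float, kappa: float = 1.0,
                       mt_length_bp: float = MT_GENOME_BP,
                       genome_size_bp: float = DIPLOID_GENOME_BP) -> float:
    """Expected mtDNA:gDNA mass/mass ratio in percent.

    The copy ratio from :func:`nanopore_to_qpcr` scales by the mass per
    copy of each species, i.e. by mt_length / genome_size.
    """
    if mt_length_bp <= 0 or genome_size_bp <= 0:
        raise ValueError("lengths must be positive")
    return 100.0 * nanopore_to_qpcr(R_NP, kappa) * mt_length_bp / genome_size_bp
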