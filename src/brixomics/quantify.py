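"""Metabolite quantification from analyte/internal-standard peak-area ratios.

Standard addition: known analyte amounts are spiked into aliquots of the
sample, the response ratio is regressed on the spiked concentration, and
the sample (supernatant) concentration is the magnitude of the x-axis
intercept, ``a / b`` for the line ``ratio = a + b * spike``.  The fruit
concentration follows by undoing the homogenate dilution.  External
calibration fits the same line on standards of known concentration and
predicts unknowns by inversion.  Transcript-metabolite agreement is
summarized by a Pearson correlation with a Fisher-Z confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StandardAdditionFit:
    spikes: np.ndarray            # ng / L added
    ratios: np.ndarray            # dimensionless
    slope: float                  # per (ng / L)
    intercept: float
    r_squared: float
    estimated_conc: float         # ng / L in the supernatant


@dataclass
class CalibrationCurve:
    levels: np.ndarray
    mean_ratios: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    def predict(self, ratio: float) -> float:
        """Invert the calibration line: concentration = (ratio - a) / b."""
        return (ratio - self.intercept) / self.slope


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def fit_standard_addition(spikes, ratios) -> StandardAdditionFit:
    """OLS of response ratio on spiked concentration; estimate = a / b."""
    x = np.asarray(spikes, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.size != y.size or np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct spike levels with matching ratios")
    if (y < 0).any():
        raise ValueError("response ratios must be non-negative")
    slope, intercept, r2 = _ols_line(x, y)
    if slope <= 0:
        raise ValueError("response does not increase with addition "
                         f"(slope {slope:.3g})")
    return StandardAdditionFit(spikes=x, ratios=y, slope=slope,
                               intercept=intercept, r_squared=r2,
                               estimated_conc=abs(intercept / slope))


def correct_dilution(conc_supernatant: float,
                     sample_mass_g: float = 36.0,
                     added_volume_mL: float = 10.0,
                     density_g_per_mL: float = 1.0) -> float:
    """Scale a supernatant concentration back to the undiluted fruit.

    The homogenate volume is sample mass / density plus the added spike
    volume, so the factor is ``(m/d + V) / (m/d)`` — 46/36 with the default
    36 g sample, 10 mL addition and unit density.
    """
    if min(sample_mass_g, density_g_per_mL) <= 0 or added_volume_mL < 0:
        raise ValueError("mass and density must be positive, volume >= 0")
    sample_volume = sample_mass_g / density_g_per_mL
    return conc_supernatant * (sample_volume + added_volume_mL) / sample_volume


def fit_external_calibration(levels, ratios) -> CalibrationCurve:
    """OLS calibration of mean response ratio against standard concentration.

    ``ratios`` may hold replicate measurements per level (2-D, replicates on
    the second axis, or a tidy same-length vector); replicates are averaged
    per level before the fit.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if y.ndim == 2:
        y = y.mean(axis=1)
    if x.size != y.size:
        raise ValueError("levels and ratios must align")
    df = pd.DataFrame({"level": x, "ratio": y}).groupby("level", as_index=False
                                                        ).mean()
    if len(df) < 3:
        raise ValueError("external calibration needs >= 3 distinct levels")
    slope, intercept, r2 = _ols_line(df["level"].to_numpy(),
                                     df["ratio"].to_numpy())
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationCurve(levels=df["level"].to_numpy(),
                            mean_ratios=df["ratio"].to_numpy(),
                            slope=slope, intercept=intercept, r_squared=r2)


def correlate_transcript_metabolite(transcript_means,
                                    metabolite_concs,
                                    confidence: float = 0.95,
                                    ) -> tuple[float, tuple[float, float], float]:
    """Pearson r with a Fisher-Z confidence interval and two-sided p.

    CI = tanh(atanh(r) ± z* / sqrt(n - 3)); at |r| = 1 the interval
    degenerates to the point estimate.
    """
    x = np.asarray(transcript_means, dtype=float)
    y = np.asarray(metabolite_concs, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        return r, (r, r), 0.0
    zstar = stats.norm.ppf(0.5 + confidence / 2)
    z = np.arctanh(r)
    half = zstar / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    p = float(2 * stats.norm.sf(abs(z) * np.sqrt(n - 3)))
    return r, ci, p
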