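"""QconCAT-anchored absolute quantification.

A synthetic unlabeled "gold" peptide of known molar amount fixes the molar
amount of each heavy-labeled QconCAT standard by a light/heavy signal ratio;
a dilution series of the heavy anchor peptides verifies response linearity;
the known copy numbers (ABQ) of the anchor proteins calibrate a log-log
linear map from relative abundance (iBAQ) to copies per cell, which is then
applied proteome-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.stats import linregress

from .errors import InsufficientDataError, ValidationError
from .util import SENTINEL

AVOGADRO = Avogadro


def qconcat_molar_amount(heavy_signal: float, light_signal: float,
                         gold_amount_mol: float) -> float:
    """Moles of heavy QconCAT protein from the heavy/light (gold) signal ratio.

    amount = gold_amount * heavy / light; invariant to a common signal scale.
    """
    for name, v in (("heavy_signal", heavy_signal),
                    ("light_signal", light_signal),
                    ("gold_amount_mol", gold_amount_mol)):
        if not (v > 0):
            raise ValidationError(f"{name} must be positive, got {v}")
    return gold_amount_mol * heavy_signal / light_signal


def copies_per_cell(amount_mol: float, n_cells: float) -> float:
    """Convert a molar amount in a preparation of n_cells to copies per cell."""
    if not (amount_mol > 0 and n_cells > 0):
        raise ValidationError("amount and cell count must be positive")
    return amount_mol * AVOGADRO / n_cells


def dilution_linearity(series: pd.DataFrame, peptide_id: str | None = None
                       ) -> tuple[float, float, float]:
    """OLS fit of log10(signal) on log10(dilution factor) for one peptide.

    ``series`` needs columns dilution_factor and signal (and peptide_id when
    several peptides are stacked). Zero signals are excluded with a warning;
    fewer than three surviving points is an error. A constant signal yields
    slope 0 with R^2 reported as 0 (undefined) with a warning.

    Returns (slope, intercept, r_squared).
    """
    df = series
    if peptide_id is not None:
        df = df[df["peptide_id"] == peptide_id]
    if (df["dilution_factor"] <= 0).any():
        raise ValidationError("dilution factors must be strictly positive")
    zero = df["signal"] <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} non-positive signal point(s)")
        df = df[~zero]
    if len(df) < 3:
        raise InsufficientDataError(
            f"dilution linearity needs >= 3 usable points, got {len(df)}")
    x = np.log10(df["dilution_factor"].to_numpy(dtype=float))
    y = np.log10(df["signal"].to_numpy(dtype=float))
    if np.ptp(y) == 0:
        warnings.warn("constant signal across dilutions: R^2 undefined, "
                      "reported as 0")
        return 0.0, float(y[0]), 0.0
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


@dataclass
class CalibrationModel:
    """log10(copies/cell) = slope * log10(iBAQ) + intercept, fit on anchors."""

    slope: float
    intercept: float
    r_squared: float
    n_anchors: int
    cells_per_sample: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")
        if self.n_anchors < 2:
            raise ValidationError("calibration needs >= 2 anchors")


def fit_anchor_calibration(anchor_abq, anchor_ibaq,
                           cells_per_sample: float = 1.0,
                           anchor_ids=None) -> CalibrationModel:
    """Fit the anchor calibration: OLS of log10(ABQ) on log10(iBAQ).

    ``anchor_abq`` are known copies/cell of the anchor proteins and
    ``anchor_ibaq`` their relative abundances in the same sample.
    """
    abq = np.asarray(anchor_abq, dtype=float)
    ibaq = np.asarray(anchor_ibaq, dtype=float)
    if abq.shape != ibaq.shape or abq.ndim != 1:
        raise ValidationError("anchor lists must be matched 1-D sequences")
    if abq.size < 2:
        raise InsufficientDataError("calibration needs >= 2 anchors")
    bad = np.where(~((abq > 0) & (ibaq > 0)))[0]
    if bad.size:
        name = anchor_ids[bad[0]] if anchor_ids is not None else f"index {bad[0]}"
        raise ValidationError(f"non-positive anchor value at {name}")
    x, y = np.log10(ibaq), np.log10(abq)
    if np.ptp(x) == 0:
        raise ValidationError("anchor iBAQ values are all equal; slope undefined")
    fit = linregress(x, y)
    r2 = float(fit.rvalue ** 2) if np.ptp(y) > 0 else 1.0
    return CalibrationModel(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=min(r2, 1.0), n_anchors=int(abq.size),
                            cells_per_sample=float(cells_per_sample))


def predict_copy_numbers(model: CalibrationModel, ibaq_values):
    """Predict copies/cell for iBAQ values: 10^(slope*log10(iBAQ)+intercept).

    Non-positive and sentinel-filled entries are excluded (returned as NaN).
    Accepts a scalar, array, or pandas Series (index preserved).
    """
    if model is None:
        raise ValidationError("calibration model is not fitted")
    arr = np.asarray(ibaq_values, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    ok = np.isfinite(arr) & (arr > 0) & (arr != SENTINEL)
    out = np.full(arr.shape, np.nan)
    out[ok] = 10.0 ** (model.slope * np.log10(arr[ok]) + model.intercept)
    if scalar:
        return float(out[0])
    if isinstance(ibaq_values, pd.Series):
        return pd.Series(out, index=ibaq_values.index)
    return out
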