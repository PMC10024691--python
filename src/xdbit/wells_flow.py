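"""Well cross-contamination quantification and microfluidic flow modelling.

Multiplexing nine tissue sections on one slide carries the risk of
material leaking between the wells of the 9-well adapter after the
reverse-transcription step.  Because every well receives its own set of
RevT (z) barcodes, the leak rate is measurable: for each sequencing
library (one per physical well), count which z-barcode set its reads
carry.  Off-well percentages are cross-contaminations.

The serpentine channel routing that enables multiplexing also makes the
channels unequal in length, and the pressure-driven volumetric flow rate
falls linearly with channel length (Hagen-Poiseuille).  An ordinary
least-squares fit of flow rate against length, with confidence and
prediction bands, bounds the operable channel length and the wash times
needed to guarantee a minimal volume exchange per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "WellComposition",
    "FlowModel",
    "well_composition",
    "fit_flow_regression",
    "max_operable_length",
    "hagen_poiseuille_flow",
    "wash_volume_check",
    "MIN_WASH_VOLUME_UL",
]

#: minimal volume exchange per channel required for a wash step, µL
MIN_WASH_VOLUME_UL = 15.0


# ---------------------------------------------------------------------------
# cross-contamination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellComposition:
    """Percentages of z-barcode sets observed per physical well.

    ``percentages`` rows are libraries (physical wells), columns z-barcode
    sets; each row sums to 100 over the observed sets.
    """

    percentages: pd.DataFrame
    counts: pd.DataFrame

    @property
    def own_percentage(self) -> pd.Series:
        """Reads carrying the well's own barcode set, percent."""
        shared = [w for w in self.percentages.index if w in self.percentages.columns]
        return pd.Series(
            {w: float(self.percentages.loc[w, w]) for w in shared},
            name="own_pct",
        )

    @property
    def contamination_percentage(self) -> pd.Series:
        """100 minus the own-barcode percentage per well."""
        return (100.0 - self.own_percentage).rename("contamination_pct")

    def to_long(self) -> pd.DataFrame:
        """Stacked-bar-ready long table (library_well, z_set, pct)."""
        long = self.percentages.reset_index().melt(
            id_vars="library_well", var_name="z_set", value_name="pct"
        )
        return long


def well_composition(records: pd.DataFrame) -> WellComposition:
    """Aggregate resolved z-barcodes by sequencing library.

    ``records`` needs one row per read with columns ``library_well`` (the
    physical well the library was made from) and ``well_id`` (the well
    the z-barcode resolved to); rows with unresolved z-barcodes are
    ignored.  Crosstalk-flagged reads must still be present — they are
    exactly the off-diagonal signal.
    """
    df = records.dropna(subset=["well_id", "library_well"])
    if df.empty:
        raise ValueError("no reads with resolved z-barcodes")
    counts = (
        df.groupby(["library_well", "well_id"]).size().unstack(fill_value=0)
    )
    empty_libs = counts.sum(axis=1) == 0
    if empty_libs.any():
        raise ValueError(
            f"libraries without resolved z-barcodes: {list(counts.index[empty_libs])}"
        )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.index.name = "library_well"
    pct.columns.name = "z_set"
    return WellComposition(percentages=pct, counts=counts)


# ---------------------------------------------------------------------------
# flow-rate regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowModel:
    """OLS fit of volumetric flow rate (µL/min) against channel length (mm)."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    length_range_mm: tuple[float, float]
    _results: object = None  # statsmodels RegressionResults, for the bands

    def predict(self, lengths_mm: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(lengths_mm, float)

    def confidence_band(
        self, lengths_mm: np.ndarray, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Mean response with confidence and prediction intervals.

        The prediction interval (for a new observation) always contains
        the confidence interval (for the mean) at the same level.
        """
        if self._results is None:
            raise ValueError("model was not fit from data; no bands available")
        x = np.asarray(lengths_mm, float)
        exog = sm.add_constant(x, has_constant="add")
        pred = self._results.get_prediction(exog)
        frame = pred.summary_frame(alpha=alpha)
        return pd.DataFrame(
            {
                "length_mm": x,
                "mean": frame["mean"].to_numpy(),
                "ci_low": frame["mean_ci_lower"].to_numpy(),
                "ci_high": frame["mean_ci_upper"].to_numpy(),
                "pi_low": frame["obs_ci_lower"].to_numpy(),
                "pi_high": frame["obs_ci_upper"].to_numpy(),
            }
        )

    def slope_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        if self._results is None:
            raise ValueError("model was not fit from data")
        lo, hi = self._results.conf_int(alpha=alpha)[1]
        return float(lo), float(hi)


def fit_flow_regression(
    lengths_mm: np.ndarray, flow_rates_ul_min: np.ndarray
) -> FlowModel:
    """Ordinary least squares of flow rate on channel length.

    Requires >= 3 measurements at >= 2 distinct lengths.  For a constant
    response the slope is 0 and the Pearson r is undefined; it is reported
    as 0 with a warning.
    """
    x = np.asarray(lengths_mm, float)
    y = np.asarray(flow_rates_ul_min, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("lengths and flow rates must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 measurements")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct channel lengths")
    results = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = results.params
    if np.std(y) == 0:
        warnings.warn(
            "constant flow rates: Pearson r undefined, reported as 0",
            stacklevel=2,
        )
        r = 0.0
        p = 1.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
        p = float(results.pvalues[1])
    return FlowModel(
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=r,
        p_value=p,
        length_range_mm=(float(x.min()), float(x.max())),
        _results=results,
    )


def max_operable_length(
    model: FlowModel,
    min_flow_ul_min: float,
    conservative: bool = False,
    alpha: float = 0.05,
) -> float:
    """Longest channel still reaching the minimal flow rate.

    Point estimate: the length where the fitted line crosses
    ``min_flow_ul_min``, i.e. ``(min_flow - intercept) / slope``.  The
    conservative variant instead finds where the lower prediction-interval
    bound crosses the minimum, which is always shorter.
    """
    if model.slope >= 0:
        raise ValueError("operable-length bound requires a negative slope")
    point = (min_flow_ul_min - model.intercept) / model.slope
    if not conservative:
        return float(point)
    if model._results is None:
        raise ValueError("conservative bound needs a data-fitted model")
    # scan outward from 0 to beyond the point estimate for the crossing
    lengths = np.linspace(0.0, max(point * 2.0, 1.0), 4001)
    band = model.confidence_band(lengths, alpha=alpha)
    below = band["pi_low"].to_numpy() < min_flow_ul_min
    if not below.any():
        return float(lengths[-1])
    return float(lengths[int(np.argmax(below))])


# ---------------------------------------------------------------------------
# Hagen-Poiseuille design model
# ---------------------------------------------------------------------------

def hagen_poiseuille_flow(
    length_mm: float,
    pressure_drop_mbar: float,
    width_um: float = 50.0,
    height_um: float = 50.0,
    viscosity_pa_s: float = 1.0e-3,
) -> float:
    """Ideal volumetric flow rate of a rectangular microchannel, µL/min.

    First-order rectangular-duct approximation of pressure-driven laminar
    flow: Q = (w * h^3 * dP) / (12 * mu * L) * (1 - 0.63 * h / w) with
    h <= w (dimensions are swapped otherwise).  For the 50 x 50 µm square
    channel the correction factor is 0.37; the model is an approximation
    and does not reproduce measured chip-to-chip variation.
    """
    if min(length_mm, pressure_drop_mbar, width_um, height_um, viscosity_pa_s) <= 0:
        raise ValueError("all geometry, pressure and viscosity inputs must be > 0")
    w = width_um * 1e-6
    h = height_um * 1e-6
    if h > w:
        w, h = h, w
    length_m = length_mm * 1e-3
    dp_pa = pressure_drop_mbar * 100.0
    q_m3_s = (w * h**3 * dp_pa) / (12.0 * viscosity_pa_s * length_m) * (
        1.0 - 0.63 * h / w
    )
    return q_m3_s * 1e9 * 60.0  # m^3/s -> µL/min


def wash_volume_check(
    flow_rates_ul_min: pd.Series,
    wash_time_min: float,
    min_volume_ul: float = MIN_WASH_VOLUME_UL,
) -> pd.DataFrame:
    """Exchanged volume per channel for a wash step and pass/fail flags.

    Volume = rate x time; a channel passes iff it exchanges at least
    ``min_volume_ul`` (default 15 µL).  The slowest channel governs the
    wash time actually required, reported in attrs as
    ``required_wash_time_min = min_volume / min(rate)``.
    """
    rates = pd.Series(flow_rates_ul_min, dtype=float)
    volumes = rates * wash_time_min
    out = pd.DataFrame(
        {
            "flow_ul_min": rates,
            "volume_ul": volumes,
            "passed": volumes >= min_volume_ul,
        }
    )
    out.attrs["required_wash_time_min"] = float(min_volume_ul / rates.min())
    return out
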