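"""Plate-based cytotoxicity assay quantification and dose-response fitting.

Three normalized-percentage readouts share one affine form

    percent = 100 * (signal - low_control) / (high_control - low_control)

instantiated as hemolysis (0%/100% lysis controls, OD405), LDH release
(spontaneous/maximal, OD492) and MTT viability (blank/untreated, OD570).
Percentages are deliberately not clipped to [0, 100]: noisy wells can fall
outside the range and callers may flag them.

Dose-response curves are summarized by a four-parameter logistic (4PL)

    y(c) = bottom + (top - bottom) / (1 + 10 ** (hill * (log10 c - log10 m)))

fitted on log10 concentration.  The midpoint ``m`` is the relative IC50
(half-hemolysis concentration HC50 for rising curves); the dose where the
fitted curve crosses 50% of control is additionally reported as the
absolute IC50.  Midpoints beyond the highest tested dose are censored and
printed in the ``"> max"`` convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DegenerateControlsError",
    "NoSignalError",
    "hemolysis_percent",
    "ldh_release_percent",
    "mtt_viability_percent",
    "DoseResponseDataset",
    "FitResult",
    "DoseResponseModel",
    "fit_dose_response",
    "hc50",
    "selectivity_index",
    "four_param_logistic",
]


class DegenerateControlsError(ValueError):
    """Positive and negative control wells do not separate."""


class NoSignalError(ValueError):
    """Responses span too little range for a dose-response fit."""


def _normalized_percent(signal, low, high, low_name: str, high_name: str):
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.asarray(high) > np.asarray(low)):
        raise DegenerateControlsError(
            f"{high_name} must exceed {low_name} (got {high} <= {low})"
        )
    out = 100.0 * (signal - low) / (high - low)
    return float(out) if out.ndim == 0 else out


def hemolysis_percent(od_sample, od_zero, od_full):
    """Hemolysis % from OD405: 100*(sample - 0% lysis)/(100% lysis - 0% lysis)."""
    return _normalized_percent(od_sample, od_zero, od_full, "zero-lysis control", "full-lysis control")


def ldh_release_percent(od_exp, od_spont, od_max):
    """LDH release % from OD492: 100*(experimental - spontaneous)/(maximal - spontaneous)."""
    return _normalized_percent(od_exp, od_spont, od_max, "spontaneous release", "maximal release")


def mtt_viability_percent(od_treated, od_untreated, od_blank):
    """MTT viability % of untreated control from blank-corrected OD570."""
    return _normalized_percent(od_treated, od_blank, od_untreated, "blank", "untreated control")


def four_param_logistic(conc, top: float, bottom: float, log10_mid: float, hill: float):
    """4PL response at concentration ``conc``; hill > 0 falls with dose, < 0 rises."""
    logc = np.log10(np.asarray(conc, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log10_mid)))


@dataclass
class DoseResponseDataset:
    """Concentration/response pairs (replicates kept individually) for one curve."""

    concentration: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None
    cell_line: str = ""
    peptide: str = ""

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must have equal length")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        if len(np.unique(self.concentration)) < 4:
            raise ValueError("at least 4 distinct concentrations required for fitting")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cell_line: str = "", peptide: str = "",
                       conc_col: str = "concentration_uM", resp_col: str = "response") -> "DoseResponseDataset":
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(df[conc_col].to_numpy(), df[resp_col].to_numpy(), rep,
                   cell_line=cell_line, peptide=peptide)

    @property
    def doses(self) -> np.ndarray:
        return np.unique(self.concentration)

    def mean_by_dose(self) -> pd.Series:
        return pd.Series(self.response).groupby(pd.Series(self.concentration)).mean()


@dataclass
class FitResult:
    """Fitted 4PL parameters and diagnostics for one dose-response curve."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    converged: bool
    residual_sd: float
    absolute_ic50: float = math.nan
    censored: bool = False
    max_dose: float = math.nan
    extrapolated: bool = False
    message: str = ""
    cell_line: str = ""
    peptide: str = ""

    @property
    def ic50_display(self) -> str:
        """Printable IC50, using the "> max" convention for censored fits."""
        if self.censored:
            return f"> {self.max_dose:g}"
        if math.isnan(self.ic50):
            return "ND"
        return f"{self.ic50:.3g}"

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 41,
        ]
        if self.peptide or self.cell_line:
            lines.append(f"peptide: {self.peptide or '-'}   cell line: {self.cell_line or '-'}")
        lines += [
            f"IC50 (midpoint)    : {self.ic50_display} uM",
            f"IC50 (absolute 50%): {self.absolute_ic50:.4g} uM" if math.isfinite(self.absolute_ic50) else "IC50 (absolute 50%): ND",
            f"hill slope         : {self.hill_slope:.4g}",
            f"top / bottom       : {self.top:.4g} / {self.bottom:.4g} %",
            f"residual sd        : {self.residual_sd:.4g} %",
            f"converged          : {self.converged}",
        ]
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ic50": self.ic50, "hill_slope": self.hill_slope, "top": self.top,
            "bottom": self.bottom, "converged": self.converged,
            "residual_sd": self.residual_sd, "absolute_ic50": self.absolute_ic50,
            "censored": self.censored, "max_dose": self.max_dose,
            "extrapolated": self.extrapolated, "ic50_display": self.ic50_display,
            "cell_line": self.cell_line, "peptide": self.peptide,
        }


class DoseResponseModel:
    """4PL model over a DoseResponseDataset; ``fit()`` returns a FitResult.

    Parameters
    ----------
    data : DoseResponseDataset
        All replicate wells, fitted jointly (pooled residuals).
    direction : {"falling", "rising", "auto"}
        "falling" for viability curves (response drops with dose),
        "rising" for hemolysis/LDH-release.  "auto" infers the direction
        from the rank correlation of mean response with dose.
    min_span : float
        Minimum response range (percentage points) required to attempt a
        fit; below it a :class:`NoSignalError` is raised.
    """

    def __init__(self, data: DoseResponseDataset, direction: str = "falling",
                 min_span: float = 20.0) -> None:
        if direction not in ("falling", "rising", "auto"):
            raise ValueError("direction must be 'falling', 'rising' or 'auto'")
        self.data = data
        self.direction = direction
        self.min_span = min_span

    def _initial_guess(self, means: pd.Series, rising: bool) -> tuple:
        top0 = float(means.max())
        bottom0 = float(means.min())
        mid = (top0 + bottom0) / 2.0
        doses = means.index.to_numpy(dtype=float)
        vals = means.to_numpy()
        # first dose whose mean crosses the half-signal level brackets the midpoint
        crossing = doses[np.argmin(np.abs(vals - mid))]
        hill0 = -1.0 if rising else 1.0
        return top0, bottom0, math.log10(crossing), hill0

    def fit(self) -> FitResult:
        data = self.data
        means = data.mean_by_dose()
        span = float(means.max() - means.min())
        if span < self.min_span:
            raise NoSignalError(
                f"response span {span:.1f} points is below the {self.min_span:.0f}-point minimum"
            )

        rho = means.corr(pd.Series(means.index, index=means.index), method="spearman")
        rising = rho > 0
        if self.direction == "falling" and rising and means.is_monotonic_increasing:
            warnings.warn(
                "response increases monotonically with dose; IC50 undefined for a falling curve",
                stacklevel=2,
            )
            return FitResult(math.nan, math.nan, math.nan, math.nan, False, math.nan,
                             message="monotone increasing response for a falling-curve fit",
                             cell_line=data.cell_line, peptide=data.peptide)
        if self.direction == "rising":
            rising = True
        elif self.direction == "falling":
            rising = False

        p0 = self._initial_guess(means, rising)
        lo_c, hi_c = data.concentration.min(), data.concentration.max()
        spread = max(math.log10(hi_c) - math.log10(lo_c), 1.0)
        bounds = (
            [-np.inf, -np.inf, math.log10(lo_c) - 2 * spread, -10.0],
            [np.inf, np.inf, math.log10(hi_c) + 2 * spread, 10.0],
        )
        try:
            popt, _ = optimize.curve_fit(
                four_param_logistic, data.concentration, data.response,
                p0=p0, bounds=bounds, maxfev=20000,
            )
            converged = True
            message = ""
        except RuntimeError as exc:
            return FitResult(math.nan, math.nan, math.nan, math.nan, False, math.nan,
                             message=f"optimizer failed: {exc}",
                             cell_line=data.cell_line, peptide=data.peptide)

        top, bottom, log10_mid, hill = (float(v) for v in popt)
        ic50 = 10.0 ** log10_mid
        resid = data.response - four_param_logistic(data.concentration, *popt)
        dof = max(len(resid) - 4, 1)
        residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
        absolute = self._absolute_ic50(top, bottom, log10_mid, hill)
        censored = bool(ic50 > hi_c)
        extrapolated = bool(not (lo_c <= ic50 <= hi_c))
        return FitResult(ic50, hill, top, bottom, converged, residual_sd,
                         absolute_ic50=absolute, censored=censored, max_dose=float(hi_c),
                         extrapolated=extrapolated, message=message,
                         cell_line=data.cell_line, peptide=data.peptide)

    @staticmethod
    def _absolute_ic50(top: float, bottom: float, log10_mid: float, hill: float) -> float:
        """Dose where the fitted curve crosses 50% of control, if it does."""
        if not (min(top, bottom) < 50.0 < max(top, bottom)) or hill == 0:
            return math.nan
        ratio = (top - bottom) / (50.0 - bottom) - 1.0
        if ratio <= 0:
            return math.nan
        return 10.0 ** (log10_mid + math.log10(ratio) / hill)

    def plot(self, result: FitResult | None = None, ax=None):
        """Scatter the wells and overlay the fitted curve on a log-dose axis."""
        import matplotlib.pyplot as plt

        if result is None:
            result = self.fit()
        if ax is None:
            _, ax = plt.subplots()
        d = self.data
        ax.semilogx(d.concentration, d.response, "o", alpha=0.6, label="wells")
        if result.converged:
            grid = np.geomspace(d.concentration.min(), d.concentration.max(), 200)
            ax.semilogx(grid, four_param_logistic(
                grid, result.top, result.bottom, math.log10(result.ic50), result.hill_slope),
                "-", label="4PL fit")
        ax.set_xlabel("concentration (uM)")
        ax.set_ylabel("response (% of control)")
        ax.legend()
        return ax


def fit_dose_response(data: DoseResponseDataset, direction: str = "falling",
                      min_span: float = 20.0) -> FitResult:
    """Fit a 4PL curve; convenience wrapper around DoseResponseModel."""
    return DoseResponseModel(data, direction=direction, min_span=min_span).fit()


def hc50(hemolysis_curve: DoseResponseDataset, min_span: float = 20.0) -> FitResult:
    """Half-hemolysis concentration: 4PL midpoint of a rising hemolysis curve.

    A curve that never leaves baseline within the tested range is reported
    censored at the highest tested dose (the ``"> max"`` convention) rather
    than raising, since absent hemolysis is a meaningful assay outcome.
    """
    try:
        return DoseResponseModel(hemolysis_curve, direction="rising", min_span=min_span).fit()
    except NoSignalError:
        max_dose = float(hemolysis_curve.concentration.max())
        if float(hemolysis_curve.mean_by_dose().max()) < 50.0:
            return FitResult(math.nan, math.nan, math.nan, math.nan, False, math.nan,
                             censored=True, max_dose=max_dose,
                             message="hemolysis never reached 50% within the tested range",
                             cell_line=hemolysis_curve.cell_line, peptide=hemolysis_curve.peptide)
        raise


def _parse_maybe_censored(value) -> tuple[float, bool]:
    if isinstance(value, str):
        text = value.strip()
        if text.startswith(">"):
            return float(text[1:].strip()), True
        return float(text), False
    return float(value), False


def selectivity_index(ic50_normal, ic50_tumor):
    """Ratio IC50(normal cells) / IC50(tumor cells); larger means more tumor-selective.

    Censored inputs written ``"> X"`` (below-detection potency against normal
    cells) propagate as lower bounds: the result is the string ``"> r"``.
    """
    normal, normal_censored = _parse_maybe_censored(ic50_normal)
    tumor, tumor_censored = _parse_maybe_censored(ic50_tumor)
    if normal <= 0 or tumor <= 0:
        raise ValueError("IC50 values must be strictly positive")
    if tumor_censored:
        raise ValueError("a censored tumor IC50 gives no usable selectivity bound")
    ratio = normal / tumor
    if normal_censored:
        return f"> {round(ratio, 1):g}"
    return round(ratio, 1)
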