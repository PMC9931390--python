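"""Dose–response analysis of plate-reader growth curves.

Relative growth at an endpoint read is summarized per dose, a
four-parameter logistic (4PL) curve is fitted, and the IC50 — the dose
halving the zero-dose culture density — is solved from the fitted curve.
Also houses the daily-resistance heatmap assembly for serial-transfer
evolution experiments and the generation accounting of a serial-dilution
passaging design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PlateSeries",
    "PassageDesign",
    "DoseResponseModel",
    "DoseResponseResults",
    "relative_growth",
    "fit_4pl",
    "ic50_timecourse",
    "generations",
]

#: sentinel ic50 for censored (non-converged / flat) curves
CENSORED = math.inf


@dataclass
class PlateSeries:
    """Long-format plate-reader time series with a well layout.

    ``readings``: columns ``well``, ``time_min``, ``od600``.
    ``layout``: columns ``well``, ``strain``, ``dose_um``, ``replicate``,
    ``is_blank``.
    """

    readings: pd.DataFrame
    layout: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"well", "time_min", "od600"}
        if not need.issubset(self.readings.columns):
            raise ValueError(f"readings must have columns {sorted(need)}")
        need = {"well", "strain", "dose_um", "replicate", "is_blank"}
        if not need.issubset(self.layout.columns):
            raise ValueError(f"layout must have columns {sorted(need)}")
        if (self.readings["time_min"] < 0).any():
            raise ValueError("negative times in readings")
        nb = self.layout[~self.layout["is_blank"].astype(bool)]
        if nb["dose_um"].isna().any():
            raise ValueError("every non-blank well needs a dose")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.readings["time_min"].unique())


@dataclass(frozen=True)
class PassageDesign:
    """Serial-transfer design: daily 1:``dilution`` transfers for ``days``."""

    days: int
    dilution: float

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.dilution <= 1:
            raise ValueError("dilution must be > 1")


def relative_growth(series: PlateSeries, t_eval: float = 720.0) -> pd.Series:
    """Blank-subtracted, replicate-averaged growth relative to zero dose.

    Reads the OD at the grid time nearest ``t_eval`` (within ±5 min),
    subtracts the mean blank OD at that time, averages replicates per dose
    and divides by the zero-dose mean.  Values are clipped at 0.
    """
    times = series.times
    idx = int(np.argmin(np.abs(times - t_eval)))
    if abs(times[idx] - t_eval) > 5.0:
        raise ValueError(f"t_eval={t_eval} not on the time grid (nearest {times[idx]})")
    t = times[idx]
    snap = series.readings[series.readings["time_min"] == t].set_index("well")["od600"]
    lay = series.layout.set_index("well")
    blank_wells = lay.index[lay["is_blank"].astype(bool)]
    blank = float(snap.loc[snap.index.intersection(blank_wells)].mean()) if len(blank_wells) else 0.0
    sample = lay[~lay["is_blank"].astype(bool)]
    od = snap.loc[sample.index] - blank
    per_dose = od.groupby(sample["dose_um"]).mean()
    if 0.0 not in per_dose.index:
        raise ValueError("zero-dose wells are required for normalization")
    ref = per_dose.loc[0.0]
    if ref <= 0:
        return (per_dose * 0.0).clip(lower=0.0)
    return (per_dose / ref).clip(lower=0.0).sort_index()


def _4pl(d, bottom, top, x50, hill):
    return bottom + (top - bottom) / (1.0 + (d / x50) ** hill)


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters and the absolute IC50.

    ``ic50`` is the dose at which the fitted curve equals half its
    zero-dose value; ``x50`` is the curve's relative midpoint.  Censored
    fits (flat curves, <20% dynamic range, or no half-response within the
    fitted family) carry ``converged=False`` and ``ic50 = inf`` with
    ``max_dose`` recording the top of the tested range.
    """

    bottom: float
    top: float
    x50: float
    hill: float
    rss: float
    converged: bool
    ic50: float
    max_dose: float

    @property
    def censored(self) -> bool:
        return not np.isfinite(self.ic50)

    def predict(self, doses) -> np.ndarray:
        return _4pl(np.asarray(doses, dtype=float), self.bottom, self.top, self.x50, self.hill)

    def summary(self) -> str:
        ic = f"> {self.max_dose:g}" if self.censored else f"{self.ic50:.4g}"
        return "\n".join([
            "4PL dose-response fit",
            "-" * 30,
            f"top:     {self.top:.4g}",
            f"bottom:  {self.bottom:.4g}",
            f"x50:     {self.x50:.4g}",
            f"hill:    {self.hill:.4g}",
            f"RSS:     {self.rss:.4g}",
            f"IC50:    {ic} uM (absolute)",
            f"converged: {self.converged}",
        ])


class DoseResponseModel:
    """4PL model ``r(d) = bottom + (top-bottom)/(1+(d/x50)^hill)``.

    Fitted by least squares with multi-start initialization over
    ``hill in {0.5, 1, 2, 4}`` and ``x50`` at each interior dose, keeping
    the best residual sum of squares (ties broken by start order).
    """

    def __init__(self, doses, responses):
        d = np.asarray(doses, dtype=float)
        r = np.asarray(responses, dtype=float)
        if d.shape != r.shape:
            raise ValueError("doses and responses must align")
        if np.unique(d).size < 4 or 0.0 not in d:
            raise ValueError("need >= 4 distinct doses including 0")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        order = np.argsort(d, kind="stable")
        self.doses = d[order]
        self.responses = r[order]

    def fit(self) -> DoseResponseResults:
        d, r = self.doses, self.responses
        max_dose = float(d.max())
        rng_span = float(r.max() - r.min())
        pos = d[d > 0]

        if rng_span < 0.2:
            # Flat curve: no measurable inhibition over the tested range.
            return DoseResponseResults(
                bottom=float(r.min()), top=float(r.max()), x50=max_dose,
                hill=1.0, rss=float(np.sum((r - r.mean()) ** 2)),
                converged=False, ic50=CENSORED, max_dose=max_dose)

        best = None
        starts = [(h, x) for h in (0.5, 1.0, 2.0, 4.0) for x in sorted(pos)[:-1] or [pos.min()]]
        bounds = ([-0.5, 0.0, pos.min() / 1e3, 0.05], [1.5, 3.0, max_dose * 1e3, 20.0])
        for hill0, x0 in starts:
            p0 = [float(r.min()), float(r.max()), float(x0), hill0]
            p0 = [min(max(v, lo), hi) for v, lo, hi in zip(p0, bounds[0], bounds[1])]
            try:
                popt, _ = optimize.curve_fit(
                    _4pl, d, r, p0=p0, bounds=bounds, maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((_4pl(d, *popt) - r) ** 2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, popt)
        if best is None:
            return DoseResponseResults(
                bottom=float(r.min()), top=float(r.max()), x50=max_dose,
                hill=1.0, rss=float("nan"), converged=False,
                ic50=CENSORED, max_dose=max_dose)

        rss, (bottom, top, x50, hill) = best
        # Absolute IC50: dose where fitted response = half the fitted
        # zero-dose response (= top/2, since r(0) = top).
        half = top / 2.0
        if half <= bottom or top <= bottom:
            ic50 = CENSORED
            converged = False
        else:
            ic50 = x50 * ((top - bottom) / (half - bottom) - 1.0) ** (1.0 / hill)
            converged = True
            if ic50 > max_dose:
                ic50, converged = CENSORED, False
        return DoseResponseResults(
            bottom=float(bottom), top=float(top), x50=float(x50), hill=float(hill),
            rss=rss, converged=converged, ic50=float(ic50), max_dose=max_dose)


def fit_4pl(doses, responses) -> DoseResponseResults:
    """Fit the 4PL curve and solve the absolute IC50 (see model class)."""
    return DoseResponseModel(doses, responses).fit()


def ic50_timecourse(daily_fits: dict) -> pd.DataFrame:
    """Population × day matrix of log10 IC50 values.

    ``daily_fits`` maps ``(population, day)`` to a
    :class:`DoseResponseResults`.  Censored fits propagate as ``inf``
    (top-of-scale category); missing days stay ``NaN`` — no interpolation.
    """
    if not daily_fits:
        raise ValueError("no fits supplied")
    pops = sorted({p for p, _ in daily_fits}, key=str)
    days = sorted({d for _, d in daily_fits})
    mat = pd.DataFrame(np.nan, index=pd.Index(pops, name="population"),
                       columns=pd.Index(days, name="day"))
    for (p, day), fit in daily_fits.items():
        mat.loc[p, day] = math.inf if fit.censored else math.log10(fit.ic50)
    return mat


def generations(design: PassageDesign) -> tuple[int, float]:
    """Completed and exact doublings of a serial-transfer design.

    Each 1:``dilution`` daily transfer regrows to saturation, i.e.
    ``log2(dilution)`` doublings per day; exact = ``days * log2(dilution)``,
    completed = ``floor(exact)``.
    """
    exact = design.days * math.log2(design.dilution)
    return int(math.floor(exact)), exact
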