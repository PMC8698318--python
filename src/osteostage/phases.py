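"""Metabolite time-course smoothing, hourly rates and phase summaries.

Extracellular concentrations of glucose, lactate, glutamine, glutamate and
ammonia measured in spent culture medium reflect cellular uptake (decrease
relative to fresh medium) or secretion (increase). This module turns long
per-donor concentration tables into per-day fitted values, converts those
into hourly rates of concentration change (secretion positive, uptake
negative), summarizes rates within metabolic phases including the
glycolysis/glutaminolysis flux ratios, and provides the alkaline
phosphatase (ALP) activity formula used to verify osteogenic
differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy import stats

__all__ = [
    "RatePanel",
    "PhaseSummary",
    "AlpReading",
    "smooth_timecourse",
    "compute_rates",
    "rates_from_spent_medium",
    "phase_summary",
    "expected_perfect_ratio",
    "alp_activity",
    "EXTINCTION_FACTOR",
    "FLUX_RATIO_PAIRS",
]

#: molar extinction factor of p-nitrophenol in the ALP assay, per µmol
EXTINCTION_FACTOR = 18.8

#: named uptake/secretion rate-ratio pairs with their stoichiometric
#: reference value under the signed convention (uptake < 0 < secretion):
#: 1 glucose -> 2 lactate, 1 glutamine -> 1 glutamate, 1 glutamine -> 1 ammonia
FLUX_RATIO_PAIRS = {
    ("glucose", "lactate"): -0.5,
    ("glutamine", "glutamate"): -1.0,
    ("glutamine", "ammonia"): -1.0,
}


@dataclass
class RatePanel:
    """Day x metabolite matrix of hourly concentration-change rates.

    Rates are in mmol/L/h, secretion positive and uptake negative.
    ``standardized`` records whether each metabolite column has been scaled
    to unit variance (done before change-point analysis).
    """

    days: np.ndarray
    metabolites: list
    rates: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.rates.shape != (len(self.days), len(self.metabolites)):
            raise ValueError("rates must be (n_days, n_metabolites)")
        if np.isnan(self.rates).any():
            raise ValueError("rate panel contains missing entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=pd.Index(self.days, name="day"),
                            columns=self.metabolites)

    def standardize(self) -> "RatePanel":
        """Return a copy with each metabolite scaled to unit variance."""
        sd = self.rates.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        return RatePanel(self.days.copy(), list(self.metabolites),
                         (self.rates - self.rates.mean(axis=0)) / sd,
                         standardized=True)


@dataclass
class PhaseSummary:
    """Per-phase summary of metabolite rates and flux ratios."""

    phase: int
    start_day: int
    end_day: int
    mean_rates: dict
    sem_rates: dict
    flux_ratios: dict
    flags: list = field(default_factory=list)


@dataclass
class AlpReading:
    """One alkaline-phosphatase assay reading."""

    optical_density: float
    time_min: float
    extinction_factor: float = EXTINCTION_FACTOR

    @property
    def activity(self) -> float:
        return alp_activity(self.optical_density, self.time_min,
                            self.extinction_factor)


def _center_offsets(df: pd.DataFrame, column: str) -> pd.Series:
    """Remove group offsets for ``column``, preserving the grand mean."""
    grand = df["concentration"].mean()
    group_means = df.groupby(column)["concentration"].transform("mean")
    return df["concentration"] - group_means + grand


def smooth_timecourse(series: pd.DataFrame) -> pd.DataFrame:
    """Fit per-metabolite smoothing splines to donor concentration series.

    Parameters
    ----------
    series : DataFrame
        Long table with columns ``donor, metabolite, day, concentration``
        and optionally ``batch``. Missing/below-detection values may be NaN.

    Returns
    -------
    DataFrame with columns ``metabolite, day, fitted`` holding one fitted
    value (mmol/L) per metabolite per retained day.

    Notes
    -----
    Per metabolite: days with more than 50% missing values are dropped;
    remaining missing values are substituted with the metabolite's observed
    minimum; donor (and batch) offsets are removed by centering each group
    to the grand mean; a cubic smoothing spline with the smoothing
    parameter chosen by generalized cross-validation is fitted to the
    per-day means and evaluated at each retained day.
    """
    required = {"donor", "metabolite", "day", "concentration"}
    missing_cols = required - set(series.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    out = []
    for metabolite, grp in series.groupby("metabolite", sort=False):
        grp = grp.copy()
        # (1) drop days with >50% missing values
        frac_missing = grp.groupby("day")["concentration"].apply(
            lambda s: s.isna().mean()
        )
        keep_days = frac_missing.index[frac_missing <= 0.5]
        grp = grp[grp["day"].isin(keep_days)]
        days = np.sort(grp["day"].unique())
        if len(days) < 4:
            raise ValueError(
                f"{metabolite}: need >= 4 distinct days, got {len(days)}"
            )
        spans = grp.groupby("donor")["day"].agg(["min", "max"])
        if spans["min"].max() > spans["max"].min():
            warnings.warn(
                f"{metabolite}: donor day ranges do not overlap; "
                "fitting on their union"
            )
        # (2) substitute remaining missing values with the observed minimum
        grp["concentration"] = grp["concentration"].fillna(
            grp["concentration"].min()
        )
        # (3) remove donor and batch offsets
        grp["concentration"] = _center_offsets(grp, "donor")
        if "batch" in grp.columns and grp["batch"].notna().any():
            grp["concentration"] = _center_offsets(grp, "batch")
        # (4) GCV smoothing spline through per-day means, weighted by counts
        per_day = grp.groupby("day")["concentration"].agg(["mean", "count"])
        x = per_day.index.to_numpy(dtype=float)
        y = per_day["mean"].to_numpy()
        w = per_day["count"].to_numpy(dtype=float)
        if len(x) >= 5 and np.ptp(y) > 1e-12:
            spline = make_smoothing_spline(x, y, w=w, lam=None)
            fitted = spline(x)
        else:
            # too few points for GCV, or exactly constant data
            fitted = y.copy()
        out.append(pd.DataFrame({
            "metabolite": metabolite,
            "day": x.astype(int),
            "fitted": fitted,
        }))
    return pd.concat(out, ignore_index=True)


def _dwell_lookup(dwell, days) -> dict:
    if isinstance(dwell, (int, float)):
        return {int(d): float(dwell) for d in days}
    if isinstance(dwell, pd.Series):
        return {int(k): float(v) for k, v in dwell.items()}
    return {int(k): float(v) for k, v in dict(dwell).items()}


def compute_rates(fitted: pd.DataFrame, dwell, standardize: bool = False) -> RatePanel:
    """Hourly rates from fitted values at adjacent retained days.

    The rate on day ``d`` is ``(fitted(d) - fitted(previous retained day))``
    divided by ``dwell[d]``, the hours elapsed between the media change
    preceding ``d`` and the sample at ``d``. Concentration increase in the
    medium (secretion) is positive, uptake negative.
    """
    wide = fitted.pivot(index="day", columns="metabolite", values="fitted")
    wide = wide.sort_index()
    if wide.shape[0] < 2:
        raise ValueError("need fitted values at >= 2 days to form a rate panel")
    lookup = _dwell_lookup(dwell, wide.index)
    days = wide.index.to_numpy()[1:]
    hours = np.array([lookup[int(d)] for d in days], dtype=float)
    if np.any(hours <= 0):
        raise ValueError("dwell hours must be positive")
    rates = np.diff(wide.to_numpy(), axis=0) / hours[:, None]
    panel = RatePanel(days, list(wide.columns), rates)
    return panel.standardize() if standardize else panel


def rates_from_spent_medium(series: pd.DataFrame, baselines: dict,
                            standardize: bool = False) -> RatePanel:
    """Direct per-day rate estimate from spent-medium snapshots.

    Each sample is drawn ``dwell_hours`` after a media change, so
    ``(concentration - fresh-medium baseline) / dwell_hours`` estimates the
    hourly rate for that day directly; rates are averaged across donors.
    Requires columns ``donor, metabolite, day, concentration, dwell_hours``.
    """
    df = series.copy()
    missing = {"dwell_hours"} - set(df.columns)
    if missing:
        raise ValueError("spent-medium rates require a dwell_hours column")
    df["rate"] = df.apply(
        lambda r: (r["concentration"] - baselines[r["metabolite"]])
        / r["dwell_hours"],
        axis=1,
    )
    wide = (df.groupby(["day", "metabolite"])["rate"].mean()
              .unstack("metabolite").sort_index())
    if wide.isna().any().any():
        raise ValueError("rate panel contains missing entries")
    panel = RatePanel(wide.index.to_numpy(), list(wide.columns),
                      wide.to_numpy())
    return panel.standardize() if standardize else panel


def phase_summary(panel: RatePanel, result) -> list:
    """Mean/SEM of rates and flux ratios within each detected phase.

    ``result`` is a :class:`~osteostage.changepoint.ChangePointResult`
    whose phases partition the panel's day range. Flux ratios should be
    computed on unstandardized rates to keep their mmol/mmol meaning.
    """
    days = np.asarray(panel.days)
    covered = np.zeros(len(days), dtype=bool)
    summaries = []
    for phase_idx, start_day, end_day in result.phases:
        mask = (days >= start_day) & (days <= end_day)
        covered |= mask
        if not mask.any():
            raise ValueError(f"phase {phase_idx} covers no panel days")
        block = panel.rates[mask]
        flags = []
        means = {m: float(block[:, j].mean())
                 for j, m in enumerate(panel.metabolites)}
        if block.shape[0] > 1:
            sems = {m: float(stats.sem(block[:, j], ddof=1))
                    for j, m in enumerate(panel.metabolites)}
        else:
            sems = {m: 0.0 for m in panel.metabolites}
            flags.append("single-day phase: SEM set to 0 by convention")
        ratios = {}
        for (num, den) in FLUX_RATIO_PAIRS:
            if num in means and den in means:
                if means[den] == 0:
                    ratios[f"{num}/{den}"] = np.nan
                    flags.append(f"{num}/{den}: denominator mean is 0")
                else:
                    ratios[f"{num}/{den}"] = means[num] / means[den]
        summaries.append(PhaseSummary(
            phase=phase_idx, start_day=int(start_day), end_day=int(end_day),
            mean_rates=means, sem_rates=sems, flux_ratios=ratios, flags=flags,
        ))
    if not covered.all():
        raise ValueError("phases do not partition the panel days")
    return summaries


def expected_perfect_ratio(pair) -> float:
    """Stoichiometric reference value of a named flux-ratio pair.

    Under the signed-rate convention a complete conversion of glucose to
    lactate (1 -> 2) gives a glucose/lactate ratio of -0.5; one-to-one
    conversion of glutamine to glutamate or ammonia gives -1.
    """
    key = tuple(pair)
    if key not in FLUX_RATIO_PAIRS:
        raise KeyError(
            f"unknown pair {key!r}; expected one of {sorted(FLUX_RATIO_PAIRS)}"
        )
    return FLUX_RATIO_PAIRS[key]


def alp_activity(optical_density: float, time_min: float,
                 extinction_factor: float = EXTINCTION_FACTOR) -> float:
    """ALP activity in nmol/min from a p-nitrophenol absorbance reading.

    activity = OD / (18.8 µmol^-1 x time[min]) x 1000 nmol/µmol
    """
    if time_min <= 0:
        raise ValueError("time_min must be positive")
    return optical_density / (extinction_factor * time_min) * 1000.0
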