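"""Utilization of a chosen area: how far a group travels within a cell.

Response: log distance travelled in a visited cell on a day (zero-distance
visits carry no utilization signal and are dropped).  Test predictors are
food availability and the two previous-use statistics, each log-z
transformed and split into a within-group part (deviation from the group
mean) and a between-group part (the group mean), so effects of a predictor
varying day-to-day within a group are separated from effects of groups
differing in their average exposure.

The model is a Gaussian linear mixed model with random intercepts for
group, cell and group x cell, plus a residual-based autocorrelation term: a
Gaussian-weighted mean of the other same-group residuals at nearby dates and
cell centres, with the two kernel scales chosen from a grid by refitted
likelihood.  The joint significance of the six predictor terms is a
likelihood-ratio test (df = 6) against the model with only the intercept,
the autocorrelation term and the random intercepts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .choice import PREDICTORS, TransformState, log_z_transform, transform_predictor
from .lmm import MixedLMFit, fit_lmm

__all__ = [
    "within_between",
    "autocorrelation_term",
    "build_utilization_table",
    "select_autocor_scales",
    "fit_utilization_model",
    "likelihood_ratio_full_null",
    "UtilizationResult",
]

TERM_NAMES = [
    "intercept",
    "food_within", "food_between",
    "prev_self_within", "prev_self_between",
    "prev_nbr_within", "prev_nbr_between",
    "autocor",
]

SIGMA_T_GRID = (1.0, 3.0, 7.0, 14.0, 30.0)      # days
SIGMA_S_GRID = (250.0, 500.0, 1000.0, 2000.0)   # metres


def within_between(values, group_labels):
    """Split a predictor into within-group and between-group parts.

    within = x - group mean; between = group mean.  The parts reconstruct
    the original exactly: within + between = x.
    """
    x = np.asarray(values, dtype=float)
    s = pd.Series(x)
    between = s.groupby(np.asarray(group_labels)).transform("mean").to_numpy()
    return x - between, between


def autocorrelation_term(groups, days, cx, cy, residuals,
                         sigma_t: float, sigma_s: float) -> np.ndarray:
    """Residual smoother capturing temporal and spatial autocorrelation.

    For each row, the Gaussian-weighted mean of the residuals of all *other*
    rows of the same group, with weight
    exp(-dt^2 / 2 sigma_t^2) * exp(-ds^2 / 2 sigma_s^2) on the day gap and
    the distance between cell centres.  Rows with no neighbours (single-row
    groups) or zero total weight get 0.
    """
    if sigma_t <= 0 or sigma_s <= 0:
        raise ValueError("kernel scales must be positive")
    groups = np.asarray(groups)
    days = np.asarray(days, dtype=float)
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    r = np.asarray(residuals, dtype=float)
    out = np.zeros(len(r))
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 2:
            continue
        dt2 = (days[idx, None] - days[None, idx]) ** 2
        ds2 = ((cx[idx, None] - cx[None, idx]) ** 2
               + (cy[idx, None] - cy[None, idx]) ** 2)
        w = np.exp(-dt2 / (2 * sigma_t ** 2)) * np.exp(-ds2 / (2 * sigma_s ** 2))
        np.fill_diagonal(w, 0.0)
        wsum = w.sum(axis=1)
        ok = wsum > 0
        out[idx[ok]] = (w @ r[idx])[ok] / wsum[ok]
    return out


def build_utilization_table(
    cell_visits: pd.DataFrame,
    energy_field,
    ledger,
    grid,
    transform_states: dict[str, TransformState] | None = None,
) -> pd.DataFrame:
    """Model frame for the utilization model from the distance-per-cell table.

    Drops zero-distance visits and visits to masked cells, evaluates the
    three predictors at (group, cell, date), applies the log-z transform and
    the within/between split, and records cell-centre coordinates and day
    numbers for the autocorrelation smoother.
    """
    df = cell_visits.copy()
    df = df[df["distance_m"] > 0]
    has_food = energy_field.has_data(df["cell_i"].to_numpy(int),
                                     df["cell_j"].to_numpy(int))
    df = df[has_food].reset_index(drop=True)
    if df.empty:
        raise ValueError("no usable visits (positive distance + food data)")
    df["response"] = np.log(df["distance_m"].to_numpy(float))
    df["day"] = (pd.to_datetime(df["date"]).values.astype("datetime64[D]")
                 - np.datetime64("1970-01-01", "D")).astype(int)
    cx, cy = grid.cell_center(df["cell_i"].to_numpy(int),
                              df["cell_j"].to_numpy(int))
    df["center_x"], df["center_y"] = cx, cy
    df["food"] = [energy_field.value(i, j)
                  for i, j in zip(df["cell_i"], df["cell_j"])]
    df["prev_self"] = [
        ledger.previous_use(g, (i, j), d)
        for g, i, j, d in zip(df["group"], df["cell_i"], df["cell_j"], df["day"])
    ]
    df["prev_nbr"] = [
        ledger.neighbour_previous_use(g, (i, j), d)
        for g, i, j, d in zip(df["group"], df["cell_i"], df["cell_j"], df["day"])
    ]
    states = {}
    for p in PREDICTORS:
        given = None if transform_states is None else transform_states.get(p)
        z, states[p] = transform_predictor(df[p].to_numpy(), given, name=p)
        w, b = within_between(z, df["group"].to_numpy())
        df[p + "_within"], df[p + "_between"] = w, b
    df.attrs["transform_states"] = states
    return df


def _design(rows: pd.DataFrame, with_predictors: bool, autocor: np.ndarray):
    cols = [np.ones(len(rows))]
    names = ["intercept"]
    if with_predictors:
        for p in PREDICTORS:
            for part in ("_within", "_between"):
                x = rows[p + part].to_numpy(float)
                # constant terms (e.g. neighbour use in data with no
                # inter-group contact) would make the design singular
                if np.ptp(x) > 0:
                    cols.append(x)
                    names.append(p + part)
    if np.ptp(autocor) > 0:
        cols.append(autocor)
        names.append("autocor")
    return np.column_stack(cols), names


def _factors(rows: pd.DataFrame) -> dict[str, np.ndarray]:
    g = rows["group"].astype(str).to_numpy()
    c = (rows["cell_i"].astype(str) + "_" + rows["cell_j"].astype(str)).to_numpy()
    gc = np.char.add(np.char.add(g.astype("U"), "|"), c.astype("U"))
    return {"group": g, "cell": c, "group_x_cell": gc}


def select_autocor_scales(
    rows: pd.DataFrame,
    sigma_t_grid=SIGMA_T_GRID,
    sigma_s_grid=SIGMA_S_GRID,
    starts=(0.1,),
):
    """Choose the autocorrelation kernel scales by refitted likelihood.

    The model is first fitted without the term; its residuals feed the
    smoother for every (sigma_t, sigma_s) pair on the grid, and the pair
    maximising the refitted model's log-likelihood is returned together with
    the per-row term values.
    """
    X0, names0 = _design(rows, True, np.zeros(len(rows)))
    X0, names0 = X0[:, :-1], names0[:-1]  # drop the zero autocor column
    base = fit_lmm(rows["response"].to_numpy(), X0, _factors(rows),
                   term_names=names0, starts=starts)
    resid = rows["response"].to_numpy() - X0 @ base.beta
    best = None
    for st, ss in itertools.product(sigma_t_grid, sigma_s_grid):
        term = autocorrelation_term(
            rows["group"].to_numpy(), rows["day"].to_numpy(),
            rows["center_x"].to_numpy(), rows["center_y"].to_numpy(),
            resid, st, ss)
        if np.ptp(term) == 0:
            continue
        X, names = _design(rows, True, term)
        fit = fit_lmm(rows["response"].to_numpy(), X, _factors(rows),
                      term_names=names, starts=starts)
        if best is None or fit.log_likelihood > best[0].log_likelihood:
            best = (fit, st, ss, term)
    if best is None:
        return None, None, np.zeros(len(rows))
    _, st, ss, term = best
    return st, ss, term


def fit_utilization_model(
    rows: pd.DataFrame,
    autocor: np.ndarray | None = None,
    include_predictors: bool = True,
    starts=(0.1, 1.0),
) -> MixedLMFit:
    """ML fit of the utilization LMM.

    ``autocor`` is the per-row smoother value (zeros if not yet selected);
    ``include_predictors=False`` fits the null model (intercept + autocor +
    random intercepts) used by the likelihood-ratio test.
    """
    if autocor is None:
        autocor = np.zeros(len(rows))
    X, names = _design(rows, include_predictors, np.asarray(autocor, float))
    return fit_lmm(rows["response"].to_numpy(), X, _factors(rows),
                   term_names=names, starts=starts)


def likelihood_ratio_full_null(full: MixedLMFit, null: MixedLMFit,
                               df: int = 6):
    """LRT of the six predictor terms: 2*dLL against a chi-square(df)."""
    stat = 2.0 * (full.log_likelihood - null.log_likelihood)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


@dataclass
class UtilizationResult:
    """Full fit, null fit and LRT for the utilization model."""

    full: MixedLMFit
    null: MixedLMFit
    sigma_t: float | None
    sigma_s: float | None
    lrt_stat: float
    lrt_df: int
    lrt_p: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.full.term_names,
            "estimate": self.full.beta,
            "se": self.full.beta_se,
        })


def run_utilization_analysis(rows: pd.DataFrame,
                             select_scales: bool = True,
                             starts=(0.1, 1.0)) -> UtilizationResult:
    """Select autocorrelation scales, fit full and null models, run the LRT."""
    if select_scales:
        st, ss, term = select_autocor_scales(rows, starts=(starts[0],))
    else:
        st = ss = None
        term = np.zeros(len(rows))
    full = fit_utilization_model(rows, term, True, starts=starts)
    null = fit_utilization_model(rows, term, False, starts=starts)
    # df = number of test-predictor terms actually in the design (6 unless
    # constant columns were dropped)
    df = len(full.term_names) - len(null.term_names)
    stat, df, p = likelihood_ratio_full_null(full, null, df=df)
    return UtilizationResult(full, null, st, ss, stat, df, p)
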