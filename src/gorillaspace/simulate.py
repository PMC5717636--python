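"""Multi-group movement simulator with known choice coefficients.

The generator emulates the study conditions of the gorilla tracking data:
around ten groups of 4-13 weaned individuals on a 500 m grid, a smooth
positive energy landscape spanning 0-13 054 kcal m^-2, roughly 808 m of
travel per day, multi-month tracking with about half of the days observed,
and daily cell choices driven by food, site fidelity (own previous use) and
neighbour avoidance.

Each simulated transition draws the next cell among the in-grid neighbours
with probability proportional to

    exp(beta_food * z(food) + beta_self * z(prev_self)
        + beta_nbr * z(prev_nbr) + log(edge bias)),

where the previous-use statistics come from the same running
:class:`~gorillaspace.previous_use.UsageLedger` machinery the analysis uses,
and the z-scales are fixed a priori (food: log-z fitted on the landscape;
previous use: log(x + 1) unscaled) and exported in the truth record so a
refit can share the parameterisation.  Within-cell travel is lognormal with
a group-level intercept and a configurable loading on the neighbours'
previous use, mirroring the utilization model's between-group avoidance
effect.

Two direct generators bypass the movement machinery for large simulation
studies: :func:`simulate_choice_sets` emits conditional-logit choice tables
and :func:`simulate_utilization_rows` emits mixed-model frames, both from
their exact generating models.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .choice import TransformState, log_z_transform
from .grid import EnergyField, Grid
from .previous_use import UsageLedger

__all__ = [
    "SimConfig",
    "SimOutput",
    "generate_landscape",
    "simulate_movement",
    "simulate_choice_sets",
    "simulate_utilization_rows",
]


@dataclass
class SimConfig:
    """Study conditions for the movement simulator."""

    seed: int = 0
    n_cols: int = 20
    n_rows: int = 20
    cell_size: float = 500.0
    smoothness_cells: float = 2.0        # Gaussian blur of the landscape
    energy_max: float = 13054.0          # kcal m^-2, printed range maximum
    n_groups: int = 10
    group_size_range: tuple[int, int] = (4, 13)   # weaned individuals
    n_days: int = 240
    observed_fraction: float = 0.5       # share of days with collected data
    start_date: str = "2012-05-01"
    beta_food: float = 0.5
    beta_self: float = 0.3
    beta_nbr: float = -0.3
    edge_bias: float = 2.0               # edge- vs corner-adjacent propensity
    daily_mean_travel: float = 808.0     # metres per day
    fix_spacing_m: float = 50.0          # along-path fix interpolation
    fix_noise_sd: float = 3.0            # GPS jitter, metres
    util_log_intercept: float = 5.3      # e^5.3 ~ 200 m within-cell travel
    util_nbr_loading: float = -0.3       # on z(prev_nbr), avoidance
    util_group_sd: float = 0.3
    util_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.observed_fraction <= 1.0:
            raise ValueError("observed_fraction must be in (0, 1]")

    @property
    def grid(self) -> Grid:
        return Grid(0.0, 0.0, self.cell_size, self.n_cols, self.n_rows)

    @property
    def betas(self) -> dict[str, float]:
        return {"food": self.beta_food, "prev_self": self.beta_self,
                "prev_nbr": self.beta_nbr}


@dataclass
class SimOutput:
    """Fix tables plus the generating truth."""

    fixes: pd.DataFrame                  # group,date,time,x,y (observed days)
    all_fixes: pd.DataFrame              # including unobserved days
    true_decisions: pd.DataFrame         # group,date,origin_i/j,chosen_i/j
    group_sizes: pd.DataFrame            # group,year,month,size
    energy_field: EnergyField
    transform_states: dict[str, TransformState]
    config: SimConfig
    true_ledger: UsageLedger = dc_field(default=None, repr=False)  # type: ignore

    def truth_record(self) -> dict:
        return {
            "betas": self.config.betas,
            "transform_states": {
                k: vars(v) for k, v in self.transform_states.items()
            },
            "seed": self.config.seed,
        }


def generate_landscape(config: SimConfig) -> EnergyField:
    """Smoothed positive random energy field rescaled to [0, energy_max]."""
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(size=(config.n_cols, config.n_rows))
    smooth = gaussian_filter(noise, sigma=config.smoothness_cells,
                             mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    energy = (smooth - lo) / (hi - lo) * config.energy_max
    return EnergyField(config.grid, energy)


def _sim_transform_states(field: EnergyField) -> dict[str, TransformState]:
    _, food_state = log_z_transform(field.energy[~field.mask].ravel())
    prev_state = TransformState(shift=1.0, mean=0.0, sd=1.0)
    return {"food": food_state, "prev_self": prev_state,
            "prev_nbr": prev_state}


def _wiggle_path(rng, cx, cy, length, half, margin=60.0, seg=60.0):
    """Random within-cell walk of (approximately) the requested length.

    The walk takes ceil(length/seg) segments, each of the nominal segment
    length except the last remainder, clipped to an inner box so GPS jitter
    cannot push fixes across the cell boundary.  Clipping can shorten a
    segment, so the realised length is approximate — fine for a travel
    proxy whose scale is set stochastically anyway.
    """
    lim = half - margin
    n_seg = int(np.ceil(length / seg))
    lens = np.full(n_seg, seg)
    if n_seg:
        lens[-1] = length - (n_seg - 1) * seg
    pts = [(cx, cy)]
    x, y = cx, cy
    for step in lens:
        ang = rng.uniform(0, 2 * np.pi)
        x = float(np.clip(x + step * np.cos(ang), cx - lim, cx + lim))
        y = float(np.clip(y + step * np.sin(ang), cy - lim, cy + lim))
        pts.append((x, y))
    return pts


def _interpolate(path, spacing):
    """Points along a polyline at the given spacing, keeping every vertex.

    Retaining the vertices means the resampled polyline has (within jitter)
    the same length as the original path, so distances recovered from fixes
    match the distances the generator recorded in its ledger.
    """
    pts = np.asarray(path, dtype=float)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    if total == 0:
        return pts[:1]
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.unique(np.concatenate([np.arange(0.0, total, spacing), s]))
    idx = np.minimum(np.searchsorted(s, targets, side="right") - 1,
                     len(seglen) - 1)
    sl = seglen[idx]
    frac = np.zeros(len(targets))
    nz = sl > 0
    frac[nz] = (targets[nz] - s[idx][nz]) / sl[nz]
    return pts[idx] + frac[:, None] * seg[idx]


def simulate_movement(config: SimConfig,
                      field: EnergyField | None = None) -> SimOutput:
    """Run the multi-group daily movement simulation.

    Returns fixes for the observed days, the full fix table, the true
    chosen-cell record, monthly group sizes and the exported transform
    states.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    grid = config.grid
    if field is None:
        field = generate_landscape(config)
    states = _sim_transform_states(field)
    food_z = np.where(field.mask, np.nan,
                      states["food"].apply(np.nan_to_num(field.energy)))
    prev_state = states["prev_self"]

    start = pd.Timestamp(config.start_date)
    start_day = (start - pd.Timestamp("1970-01-01")).days
    months = pd.period_range(start, start + pd.Timedelta(days=config.n_days),
                             freq="M")
    groups = [f"G{k:02d}" for k in range(config.n_groups)]
    sizes = rng.integers(config.group_size_range[0],
                         config.group_size_range[1] + 1, config.n_groups)
    group_sizes = pd.DataFrame([
        {"group": g, "year": m.year, "month": m.month, "size": int(s)}
        for g, s in zip(groups, sizes) for m in months
    ])
    ledger = UsageLedger(
        pd.DataFrame(columns=["group", "cell_i", "cell_j", "date",
                              "distance_m"]),
        group_sizes)

    # scatter starting cells over the interior, keeping groups apart
    interior = [(i, j) for i in range(2, config.n_cols - 2)
                for j in range(2, config.n_rows - 2)
                if not field.mask[i, j]]
    order = rng.permutation(len(interior))
    starts: list[tuple[int, int]] = []
    for idx in order:
        c = interior[idx]
        if all(abs(c[0] - s[0]) + abs(c[1] - s[1]) > 3 for s in starts):
            starts.append(c)
        if len(starts) == config.n_groups:
            break
    while len(starts) < config.n_groups:  # dense grids: relax the spacing
        starts.append(interior[int(rng.integers(len(interior)))])

    current = dict(zip(groups, starts))
    # calibrate the transition rate so expected daily travel (centre-to-centre
    # transits, edge-biased, plus lognormal within-cell walks) matches the
    # configured mean
    mean_wiggle = float(np.exp(
        config.util_log_intercept
        + 0.5 * (config.util_group_sd ** 2 + config.util_noise_sd ** 2)))
    w_e, w_c = config.edge_bias, 1.0
    mean_transit = config.cell_size * (4 * w_e + 4 * w_c * np.sqrt(2)) \
        / (4 * w_e + 4 * w_c)
    lam = config.daily_mean_travel / (mean_transit + mean_wiggle)
    half = config.cell_size / 2.0
    observed = {
        g: rng.random(config.n_days) < config.observed_fraction
        for g in groups
    }
    util_intercepts = {
        g: rng.normal(config.util_log_intercept, config.util_group_sd)
        for g in groups
    }

    fix_rows = []
    decision_rows = []
    for d in range(config.n_days):
        day = start_day + d
        date = (start + pd.Timedelta(days=d)).date()
        for g in groups:
            n_steps = int(rng.poisson(lam))
            path = []
            day_dist: dict[tuple[int, int], float] = {}
            cell = current[g]
            cx, cy = grid.cell_center(*cell)
            path.append((float(cx), float(cy)))
            for _ in range(n_steps):
                cands = [c for c in grid.neighbours(*cell)
                         if not field.mask[c[0], c[1]]]
                if not cands:
                    break
                util = np.empty(len(cands))
                zf = np.empty(len(cands))
                zs = np.empty(len(cands))
                zn = np.empty(len(cands))
                for k, c in enumerate(cands):
                    zf[k] = food_z[c[0], c[1]]
                    zs[k] = prev_state.apply(
                        ledger.previous_use(g, c, day))
                    zn[k] = prev_state.apply(
                        ledger.neighbour_previous_use(g, c, day))
                    is_corner = (c[0] != cell[0]) and (c[1] != cell[1])
                    util[k] = (config.beta_food * zf[k]
                               + config.beta_self * zs[k]
                               + config.beta_nbr * zn[k]
                               + (0.0 if is_corner
                                  else np.log(config.edge_bias)))
                p = np.exp(util - util.max())
                p /= p.sum()
                k_chosen = int(rng.choice(len(cands), p=p))
                chosen = cands[k_chosen]
                decision_rows.append({
                    "group": g, "date": date,
                    "origin_i": cell[0], "origin_j": cell[1],
                    "chosen_i": chosen[0], "chosen_j": chosen[1],
                    # z-scores the generator actually used (audit trail)
                    "z_food": float(zf[k_chosen]),
                    "z_self": float(zs[k_chosen]),
                    "z_nbr": float(zn[k_chosen]),
                })
                # transit to the chosen cell centre, then utilise it;
                # diagonal moves are routed through the shared corner so the
                # path never clips the two side cells
                ncx, ncy = grid.cell_center(*chosen)
                if chosen[0] != cell[0] and chosen[1] != cell[1]:
                    path.append((
                        grid.origin_x + max(cell[0], chosen[0]) * config.cell_size,
                        grid.origin_y + max(cell[1], chosen[1]) * config.cell_size,
                    ))
                z_nbr_chosen = prev_state.apply(
                    ledger.neighbour_previous_use(g, chosen, day))
                d_util = float(np.exp(
                    util_intercepts[g]
                    + config.util_nbr_loading * z_nbr_chosen
                    + rng.normal(0.0, config.util_noise_sd)))
                wiggle = _wiggle_path(rng, float(ncx), float(ncy), d_util, half)
                path.append((float(ncx), float(ncy)))
                path.extend(wiggle[1:])
                cell = chosen
                cx, cy = ncx, ncy
            current[g] = cell
            # accumulate per-cell distances for the ledger (true usage)
            pts = np.asarray(path)
            if len(pts) > 1:
                segs = np.diff(pts, axis=0)
                mids = pts[:-1] + segs / 2.0
                lens = np.hypot(segs[:, 0], segs[:, 1])
                ci = np.floor(mids[:, 0] / config.cell_size).astype(int)
                cj = np.floor(mids[:, 1] / config.cell_size).astype(int)
                for a, b, L in zip(ci, cj, lens):
                    day_dist[(int(a), int(b))] = \
                        day_dist.get((int(a), int(b)), 0.0) + float(L)
            else:
                day_dist[cell] = 0.0
            for c, dist in day_dist.items():
                ledger.record_visit(g, c, day, dist)
            # emit fixes along the path
            fix_pts = _interpolate(path, config.fix_spacing_m)
            fix_pts = fix_pts + rng.normal(0.0, config.fix_noise_sd,
                                           fix_pts.shape)
            for k, (x, y) in enumerate(fix_pts):
                fix_rows.append({
                    "group": g, "date": date, "time": 8 * 3600 + 30 * k,
                    "x": float(x), "y": float(y),
                    "_observed": bool(observed[g][d]),
                })
    all_fixes = pd.DataFrame(fix_rows)
    all_fixes["date"] = pd.to_datetime(all_fixes["date"])
    fixes = all_fixes[all_fixes["_observed"]].drop(columns="_observed") \
        .reset_index(drop=True)
    all_fixes = all_fixes.drop(columns="_observed")
    decisions = pd.DataFrame(decision_rows)
    if len(decisions):
        decisions["date"] = pd.to_datetime(decisions["date"])
    return SimOutput(fixes, all_fixes, decisions, group_sizes, field,
                     states, config, ledger)


# ---------------------------------------------------------------------------
# direct generators for large simulation studies
# ---------------------------------------------------------------------------

def simulate_choice_sets(
    n_sets: int,
    betas=(0.0, 0.0, 0.0),
    seed: int = 0,
    candidate_counts=(8, 8, 8, 8, 8, 8, 5, 6),
) -> pd.DataFrame:
    """Choice tables drawn from the conditional-logit generating model.

    Candidate predictors are standard-normal z-scores; the chosen candidate
    is drawn with probability proportional to exp(x . beta).  Candidate
    counts cycle through ``candidate_counts`` (full 8-neighbour sets mixed
    with edge-of-range sets); the first four candidates of a full set are
    edge-adjacent, the rest corner-adjacent, mirroring the grid geometry.
    """
    rng = np.random.default_rng(seed)
    betas = np.asarray(betas, dtype=float)
    rows = []
    for s in range(n_sets):
        n_c = candidate_counts[s % len(candidate_counts)]
        X = rng.normal(size=(n_c, 3))
        eta = X @ betas
        p = np.exp(eta - eta.max())
        p /= p.sum()
        chosen = rng.choice(n_c, p=p)
        for k in range(n_c):
            rows.append({
                "choice_id": s, "group": f"G{s % 10:02d}",
                "is_corner": k >= 4,
                "food_z": X[k, 0], "prev_self_z": X[k, 1],
                "prev_nbr_z": X[k, 2],
                "chosen": int(k == chosen),
                "offset": -np.log(n_c),
            })
    return pd.DataFrame(rows)


def simulate_utilization_rows(
    n_groups: int = 10,
    n_cells: int = 40,
    n_rows_total: int = 400,
    betas: dict | None = None,
    group_sd: float = 0.3,
    cell_sd: float = 0.3,
    group_cell_sd: float = 0.2,
    noise_sd: float = 1.0,
    intercept: float = 5.5,
    seed: int = 0,
    cell_size: float = 500.0,
) -> pd.DataFrame:
    """Model frames drawn from the utilization LMM's generating model.

    ``betas`` maps the six predictor terms (``food_within`` ...
    ``prev_nbr_between``) to coefficients (absent terms are zero).  The raw
    per-row predictors are standard normal; within/between parts are the
    empirical split actually used by the fit, with the generating linear
    predictor built from the *true* group-level means so the between-group
    coefficient has its literal meaning.
    """
    from .utilization import within_between

    rng = np.random.default_rng(seed)
    b = {k: 0.0 for k in ["food_within", "food_between", "prev_self_within",
                          "prev_self_between", "prev_nbr_within",
                          "prev_nbr_between"]}
    if betas:
        unknown = set(betas) - set(b)
        if unknown:
            raise KeyError(f"unknown terms: {sorted(unknown)}")
        b.update(betas)
    g_codes = rng.integers(0, n_groups, n_rows_total)
    c_codes = rng.integers(0, n_cells, n_rows_total)
    g_eff = rng.normal(0, group_sd, n_groups)
    c_eff = rng.normal(0, cell_sd, n_cells)
    gc_eff = rng.normal(0, group_cell_sd, (n_groups, n_cells))
    df = pd.DataFrame({
        "group": [f"G{k:02d}" for k in g_codes],
        "cell_i": c_codes % 8,
        "cell_j": c_codes // 8,
        "day": rng.integers(0, 300, n_rows_total),
    })
    df["center_x"] = (df["cell_i"] + 0.5) * cell_size
    df["center_y"] = (df["cell_j"] + 0.5) * cell_size
    lin = np.full(n_rows_total, float(intercept))
    for p, (bw, bb) in zip(["food", "prev_self", "prev_nbr"],
                           [(b["food_within"], b["food_between"]),
                            (b["prev_self_within"], b["prev_self_between"]),
                            (b["prev_nbr_within"], b["prev_nbr_between"])]):
        # group-level mean component + within-group deviation
        mu_g = rng.normal(0, 1, n_groups)
        x = mu_g[g_codes] + rng.normal(0, 1, n_rows_total)
        lin += bw * (x - mu_g[g_codes]) + bb * mu_g[g_codes]
        w, bt = within_between(x, df["group"].to_numpy())
        df[p + "_within"], df[p + "_between"] = w, bt
    lin += g_eff[g_codes] + c_eff[c_codes] + gc_eff[g_codes, c_codes]
    df["response"] = lin + rng.normal(0, noise_sd, n_rows_total)
    return df
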