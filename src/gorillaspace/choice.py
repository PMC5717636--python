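"""Movement-choice model: choice sets, predictor transforms, conditional
logit fit, and the weighted permutation full-versus-null test.

Each decision to enter a surrounding grid cell is a choice set: up to eight
candidate cells, one of which was chosen.  Candidate covariates are
herbaceous food availability, the group's own previous use of the cell and
the neighbours' previous use, each log- then z-transformed.  The probability
of choosing candidate k in a set is the conditional-logit kernel

    P(k) = exp(x_k . beta) / sum_j exp(x_j . beta),

the exact likelihood for "one of the surrounding cells is chosen".  The
log(1/n_candidates) offset is constant within a set, so it cancels from the
conditional likelihood; it defines the null model LL = sum_sets log(1/n_i).

Significance of the predictors as a whole is assessed by a permutation test:
the chosen flag of each set is reassigned to a random candidate — edge- and
corner-adjacent candidates weighted by their observed overall choice
frequencies — and the model refitted, building the null distribution of the
likelihood-ratio statistic 2*(LL_full - LL_null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TransformState",
    "log_z_transform",
    "ChoiceModelFit",
    "PermutationResult",
    "build_choice_table",
    "fit_choice_model",
    "null_log_likelihood",
    "permutation_full_null",
]

logger = logging.getLogger(__name__)

PREDICTORS = ["food", "prev_self", "prev_nbr"]


# ---------------------------------------------------------------------------
# log + z transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformState:
    """Frozen log-shift/mean/sd so a transform can be replayed on new data."""

    shift: float
    mean: float
    sd: float

    def apply(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        return (np.log(x + self.shift) - self.mean) / self.sd


def log_z_transform(values, state: TransformState | None = None):
    """Log-transform non-negative values and z-score them.

    y = (log(x + c) - mean) / sd.  The shift c makes zeros finite: half the
    smallest positive value, or 1 if all values are zero.  When ``state`` is
    given, its constants are replayed instead of being refitted (so held-out
    data or a simulator's truth record share the scale).

    Returns (transformed array, TransformState).
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("log_z_transform requires non-negative values")
    if state is None:
        positive = x[x > 0]
        c = float(positive.min()) / 2.0 if positive.size else 1.0
        logx = np.log(x + c)
        mu = float(logx.mean())
        sd = float(logx.std(ddof=0))
        if sd == 0:
            raise ValueError("zero variance after log transform")
        state = TransformState(c, mu, sd)
    return state.apply(x), state


# ---------------------------------------------------------------------------
# choice table construction
# ---------------------------------------------------------------------------

def build_choice_table(
    decisions,
    energy_field,
    ledger,
    transform_states: dict[str, TransformState] | None = None,
) -> pd.DataFrame:
    """Assemble the model frame for the movement-choice model.

    One row per candidate cell of each decision, with raw and transformed
    predictors, the chosen flag, the log(1/n_candidates) offset and the
    corner-move indicator used by the weighted permutation.

    Parameters
    ----------
    decisions : iterable of :class:`~gorillaspace.tracks.EntryDecision`
        (post burn-in).
    energy_field : per-cell food availability; decisions whose chosen cell is
        masked are dropped with a log entry.
    ledger : :class:`~gorillaspace.previous_use.UsageLedger`.
    transform_states : optional mapping predictor -> TransformState to replay
        (e.g. a simulator's exported states); fitted from the data if absent.
    """
    rows = []
    n_dropped = 0
    for cid, dec in enumerate(decisions):
        if energy_field.mask[dec.chosen_cell[0], dec.chosen_cell[1]]:
            n_dropped += 1
            continue
        for cell in dec.candidate_cells:
            di = cell[0] - dec.origin_cell[0]
            dj = cell[1] - dec.origin_cell[1]
            rows.append({
                "choice_id": cid,
                "group": dec.group,
                "date": dec.date,
                "cell_i": cell[0],
                "cell_j": cell[1],
                "origin_i": dec.origin_cell[0],
                "origin_j": dec.origin_cell[1],
                "is_corner": di != 0 and dj != 0,
                "food": energy_field.value(*cell),
                "prev_self": ledger.previous_use(dec.group, cell, dec.date),
                "prev_nbr": ledger.neighbour_previous_use(dec.group, cell,
                                                          dec.date),
                "chosen": int(cell == dec.chosen_cell),
            })
    if n_dropped:
        logger.info("dropped %d decisions whose chosen cell lacks food data",
                    n_dropped)
    if not rows:
        raise ValueError("no usable decisions")
    df = pd.DataFrame(rows)
    n_cand = df.groupby("choice_id")["chosen"].transform("size")
    df["offset"] = -np.log(n_cand)
    states = {}
    for p in PREDICTORS:
        given = None if transform_states is None else transform_states.get(p)
        df[p + "_z"], states[p] = transform_predictor(df[p].to_numpy(), given,
                                                      name=p)
    df.attrs["transform_states"] = states
    return df


def transform_predictor(values, state=None, name="predictor"):
    """log_z_transform with a graceful constant-column fallback.

    A predictor with no variance (e.g. neighbour previous use in a
    single-group dataset) carries no information; it is centred to zero via
    an identity-scale state and a warning rather than aborting the table
    build.
    """
    try:
        return log_z_transform(values, state)
    except ValueError as exc:
        if "variance" not in str(exc):
            raise
        logger.warning("predictor %r is constant; carried as zeros", name)
        x = np.asarray(values, dtype=float)
        c = 1.0 if x.max() == 0 else float(x.max()) / 2.0
        st = TransformState(c, float(np.log(x.max() + c)), 1.0)
        return st.apply(x), st


# ---------------------------------------------------------------------------
# conditional logit
# ---------------------------------------------------------------------------

@dataclass
class ChoiceModelFit:
    """Conditional-logit ML fit of the movement-choice model."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    log_likelihood: float
    null_log_likelihood: float
    converged: bool
    n_sets: int
    predictor_names: list[str] = field(default_factory=list)

    @property
    def lr_statistic(self) -> float:
        """2*(LL_full - LL_null) against the uniform-choice null."""
        return 2.0 * (self.log_likelihood - self.null_log_likelihood)


def _set_structure(choice_table: pd.DataFrame):
    ids = choice_table["choice_id"].to_numpy()
    # contiguous-run starts (table is built per choice set)
    change = np.flatnonzero(np.diff(ids) != 0) + 1
    starts = np.concatenate([[0], change])
    counts = np.diff(np.concatenate([starts, [len(ids)]]))
    return starts, counts


def _cl_loglik_grad_hess(beta, X, chosen, starts, counts):
    eta = X @ beta
    # within-set log-sum-exp
    m = np.maximum.reduceat(eta, starts)
    m_rep = np.repeat(m, counts)
    w = np.exp(eta - m_rep)
    denom = np.add.reduceat(w, starts)
    lse = m + np.log(denom)
    ll = float(eta[chosen].sum() - lse.sum())
    p = w / np.repeat(denom, counts)
    # gradient: sum over chosen x  -  sum over sets of E_p[x]
    pX = p[:, None] * X
    Ex = np.add.reduceat(pX, starts, axis=0)
    grad = X[chosen].sum(axis=0) - Ex.sum(axis=0)
    # Hessian: -sum_sets (E[xx'] - E[x]E[x]')
    H = -(X.T @ pX - Ex.T @ Ex)
    return ll, grad, H


def null_log_likelihood(choice_table: pd.DataFrame) -> float:
    """LL of the uniform-choice null: sum over sets of log(1/n_candidates)."""
    counts = choice_table.groupby("choice_id")["chosen"].size().to_numpy()
    return float(-np.log(counts).sum())


def _fit_raw(X, chosen, starts, counts, max_iter=50, tol=1e-10,
             beta_bound=50.0):
    """Newton–Raphson on the conditional log-likelihood; returns
    (beta, se, ll, converged)."""
    beta = np.zeros(X.shape[1])
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        ll, grad, H = _cl_loglik_grad_hess(beta, X, chosen, starts, counts)
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            break
        # dampen absurd steps (near-separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(beta)) > beta_bound:
            break
    ll, grad, H = _cl_loglik_grad_hess(beta, X, chosen, starts, counts)
    if np.max(np.abs(grad)) < 1e-5 * max(1.0, abs(ll)):
        converged = True
    if np.max(np.abs(beta)) > beta_bound:
        converged = False
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    # separation leaves a flat likelihood: huge coefficients and/or standard
    # errors on z-scaled predictors mean the MLE is effectively unbounded
    if not np.all(np.isfinite(se)) or np.any(se > 100.0):
        converged = False
    return beta, se, ll, converged


def fit_choice_model(
    choice_table: pd.DataFrame,
    predictors: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
    beta_bound: float = 50.0,
) -> ChoiceModelFit:
    """Maximum-likelihood conditional-logit fit by Newton–Raphson.

    Uses the z-transformed predictor columns (``*_z``).  Divergence of any
    coefficient beyond ``beta_bound`` (complete separation) flags the fit as
    non-converged.
    """
    if predictors is None:
        predictors = [p + "_z" for p in PREDICTORS]
    if choice_table.groupby("choice_id")["chosen"].sum().ne(1).any():
        raise ValueError("each choice set must have exactly one chosen row")
    X = choice_table[predictors].to_numpy(float)
    chosen = choice_table["chosen"].to_numpy() == 1
    starts, counts = _set_structure(choice_table)
    beta, se, ll, converged = _fit_raw(X, chosen, starts, counts,
                                       max_iter, tol, beta_bound)
    return ChoiceModelFit(
        coefficients=dict(zip(predictors, beta.tolist())),
        std_errors=dict(zip(predictors, se.tolist())),
        log_likelihood=ll,
        null_log_likelihood=null_log_likelihood(choice_table),
        converged=converged,
        n_sets=len(starts),
        predictor_names=list(predictors),
    )


# ---------------------------------------------------------------------------
# weighted permutation full-null test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Permutation null distribution of the full-vs-null LR statistic."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    edge_weight: float
    corner_weight: float

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "edge_weight": self.edge_weight,
            "corner_weight": self.corner_weight,
        }


def estimate_direction_weights(choice_table: pd.DataFrame) -> tuple[float, float]:
    """Per-candidate propensity for edge- vs corner-adjacent cells.

    The chance of stepping into one of the four edge-adjacent cells differs
    from stepping diagonally; the weights are the observed per-candidate
    choice frequencies (chosen edge cells / edge candidates, likewise for
    corners), normalised to mean 1.
    """
    is_corner = choice_table["is_corner"].to_numpy(bool)
    chosen = choice_table["chosen"].to_numpy() == 1
    n_edge_cand = (~is_corner).sum()
    n_corner_cand = is_corner.sum()
    w_edge = chosen[~is_corner].sum() / n_edge_cand if n_edge_cand else 1.0
    w_corner = chosen[is_corner].sum() / n_corner_cand if n_corner_cand else 1.0
    if w_edge <= 0:
        w_edge = 1e-12
    if w_corner <= 0:
        w_corner = 1e-12
    mean = (w_edge + w_corner) / 2.0
    return w_edge / mean, w_corner / mean


def permutation_full_null(
    choice_table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    weights: tuple[float, float] | None = None,
    predictors: list[str] | None = None,
) -> PermutationResult:
    """Weighted permutation test of the full model against the uniform null.

    For each permutation, every set's chosen flag is reassigned to one
    candidate drawn with edge/corner weights renormalised within the set
    (predictors are never permuted), the model is refitted and the statistic
    2*(LL_full - LL_null) recomputed.  The add-one estimator gives
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if weights is None:
        w_edge, w_corner = estimate_direction_weights(choice_table)
    else:
        w_edge, w_corner = weights
    if predictors is None:
        predictors = [p + "_z" for p in PREDICTORS]
    fit = fit_choice_model(choice_table, predictors=predictors)
    observed = fit.lr_statistic

    X = choice_table[predictors].to_numpy(float)
    starts, counts = _set_structure(choice_table)
    set_ids = np.repeat(np.arange(len(starts)), counts)
    ll_null = null_log_likelihood(choice_table)
    is_corner = choice_table["is_corner"].to_numpy(bool)
    log_w = np.log(np.where(is_corner, w_corner, w_edge).astype(float))
    null_stats = np.empty(n_perm)
    for b in range(n_perm):
        # Gumbel-max trick: weighted sample of one candidate per set
        score = log_w + rng.gumbel(size=len(log_w))
        set_max = np.maximum.reduceat(score, starts)
        is_max = score >= set_max[set_ids]
        rows = np.flatnonzero(is_max)
        # first max row per set (float ties are measure-zero; guard anyway)
        first_rows = rows[np.unique(set_ids[rows], return_index=True)[1]]
        chosen = np.zeros(len(score), dtype=bool)
        chosen[first_rows] = True
        _, _, ll, _ = _fit_raw(X, chosen, starts, counts)
        null_stats[b] = 2.0 * (ll - ll_null)
    p = (1.0 + np.sum(null_stats >= observed)) / (1.0 + n_perm)
    return PermutationResult(observed, null_stats, float(p), n_perm, seed,
                             float(w_edge), float(w_corner))
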