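"""Step-selection function: step construction, random-step generation, and
stratified conditional-logistic fitting.

The conditional (partial) log-likelihood

    L(beta) = sum_s [ beta.x_case - log sum_{j in s} exp(beta.x_j) ]

is maximized by damped Newton iterations with analytic gradient and Hessian;
standard errors come from the inverse observed information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Raster, RasterStack

logger = logging.getLogger(__name__)

__all__ = [
    "StepSet",
    "StepDistributions",
    "FittedSSF",
    "make_steps",
    "fit_step_distributions",
    "generate_random_steps",
    "attach_covariates",
    "fit_clogit",
    "ssf_surface",
]

DEFAULT_RATES_H = (1.0, 2.0, 4.0, 13.0)


@dataclass
class StepSet:
    """Case/control steps in long form.

    Columns: individual, stratum, x_start, y_start, x_end, y_end, t_start,
    length, turn_angle, case; covariate columns appended by
    :func:`attach_covariates`.
    """

    data: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)

    def strata_sizes(self) -> pd.Series:
        return self.data.groupby("stratum").size()

    def n_cases(self) -> int:
        return int(self.data["case"].sum())


@dataclass
class StepDistributions:
    gamma_shape: float
    gamma_scale: float
    kappa: float

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = (a + np.pi) % (2 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def make_steps(
    tracks: pd.DataFrame,
    min_points: int = 100,
    allowed_rates_h=DEFAULT_RATES_H,
    rate_tolerance: float = 0.10,
) -> StepSet:
    """Case steps from GPS tracks after point-count and rate-uniformity filters.

    An individual passes if it has >= ``min_points`` fixes, its modal fix
    interval matches one of ``allowed_rates_h``, and the median absolute
    deviation of intervals is <= ``rate_tolerance`` x the modal rate.
    """
    rows = []
    stratum = 0
    kept = dropped = 0
    for ind, grp in tracks.groupby("individual", sort=True):
        grp = grp.sort_values("timestamp")
        if len(grp) < min_points:
            logger.info("make_steps: %s dropped (%d < %d points)", ind, len(grp), min_points)
            dropped += 1
            continue
        t = pd.to_datetime(grp["timestamp"]).to_numpy()
        dt_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
        modal = float(pd.Series(np.round(dt_h, 6)).mode().iloc[0])
        if not any(abs(modal - r) <= rate_tolerance * r for r in allowed_rates_h):
            logger.info("make_steps: %s dropped (rate %.2f h not allowed)", ind, modal)
            dropped += 1
            continue
        mad = float(np.median(np.abs(dt_h - modal)))
        if mad > rate_tolerance * modal:
            logger.info("make_steps: %s dropped (non-uniform rate, MAD %.2f h)", ind, mad)
            dropped += 1
            continue
        kept += 1
        x = grp["lon"].to_numpy(float)
        y = grp["lat"].to_numpy(float)
        dx = np.diff(x)
        dy = np.diff(y)
        bearings = np.arctan2(dy, dx)
        turns = np.full(len(dx), np.nan)
        turns[1:] = _wrap_angle(np.diff(bearings))
        rows.append(
            pd.DataFrame(
                {
                    "individual": ind,
                    "stratum": stratum + np.arange(len(dx)),
                    "x_start": x[:-1],
                    "y_start": y[:-1],
                    "x_end": x[1:],
                    "y_end": y[1:],
                    "t_start": t[:-1],
                    "length": np.hypot(dx, dy),
                    "turn_angle": turns,
                    "case": True,
                    "bearing": bearings,
                }
            )
        )
        stratum += len(dx)
    if not rows:
        raise ValueError("no individuals survived the step filters")
    logger.info("make_steps: %d individuals kept, %d dropped, %d steps", kept, dropped, stratum)
    return StepSet(pd.concat(rows, ignore_index=True))


def fit_step_distributions(lengths, turns) -> StepDistributions:
    """ML gamma fit to step lengths and von Mises kappa to turning angles."""
    lengths = np.asarray(lengths, dtype=float)
    lengths = lengths[~np.isnan(lengths)]
    if lengths.size < 30:
        raise ValueError("need at least 30 case steps to fit step distributions")
    if np.ptp(lengths) == 0:
        raise ValueError("degenerate step lengths (all identical)")
    shape, _, scale = stats.gamma.fit(np.maximum(lengths, 1e-9), floc=0)
    turns = np.asarray(turns, dtype=float)
    turns = turns[~np.isnan(turns)]
    if turns.size >= 5:
        kappa, _, _ = stats.vonmises.fit(turns, fscale=1)
        kappa = max(float(kappa), 0.0)
    else:
        kappa = 0.0
    return StepDistributions(float(shape), float(scale), kappa)


def generate_random_steps(
    steps: StepSet,
    dists: dict[str, StepDistributions],
    grid,
    k: int = 15,
    seed=0,
    max_retries: int = 50,
) -> StepSet:
    """Augment each case step with K control steps sharing its start point."""
    if k == 0:
        return StepSet(steps.data.copy(), list(steps.covariate_names))
    df = steps.data[steps.data["case"]]
    missing = set(df["individual"]) - set(dists)
    if missing:
        raise KeyError(f"no step distributions for individuals: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    out = [df]
    n_dropped = 0
    for ind, grp in df.groupby("individual", sort=True):
        d = dists[ind]
        n = len(grp)
        x0 = grp["x_start"].to_numpy(float)
        y0 = grp["y_start"].to_numpy(float)
        prev_bearing = grp["bearing"].to_numpy(float) - np.nan_to_num(
            grp["turn_angle"].to_numpy(float)
        )
        # first step of a track has no previous bearing: draw uniformly
        no_prev = np.isnan(grp["turn_angle"].to_numpy(float))
        prev_bearing[no_prev] = rng.uniform(-np.pi, np.pi, no_prev.sum())
        # draw all strata at once; redraw off-grid endpoints up to max_retries
        lengths = np.full((n, k), np.nan)
        turns = np.full((n, k), np.nan)
        xe = np.full((n, k), np.nan)
        ye = np.full((n, k), np.nan)
        pending = np.ones((n, k), dtype=bool)
        for _try in range(max_retries):
            m = int(pending.sum())
            if m == 0:
                break
            ln = rng.gamma(d.gamma_shape, d.gamma_scale, m)
            tu = (
                rng.vonmises(0.0, d.kappa, m)
                if d.kappa > 0
                else rng.uniform(-np.pi, np.pi, m)
            )
            rows_j = np.nonzero(pending)[0]
            headings = prev_bearing[rows_j] + tu
            cx = x0[rows_j] + ln * np.cos(headings)
            cy = y0[rows_j] + ln * np.sin(headings)
            ok = grid.contains(cx, cy)
            tgt = np.nonzero(pending.ravel())[0][ok]
            lengths.ravel()[tgt] = ln[ok]
            turns.ravel()[tgt] = _wrap_angle(tu[ok])
            xe.ravel()[tgt] = cx[ok]
            ye.ravel()[tgt] = cy[ok]
            pending.ravel()[tgt] = False
        n_dropped += int(pending.sum())
        done = ~pending.ravel()
        jj = np.repeat(np.arange(n), k)[done]
        ctrl = pd.DataFrame(
            {
                "individual": ind,
                "stratum": grp["stratum"].to_numpy()[jj],
                "x_start": x0[jj],
                "y_start": y0[jj],
                "x_end": xe.ravel()[done],
                "y_end": ye.ravel()[done],
                "t_start": grp["t_start"].to_numpy()[jj],
                "length": lengths.ravel()[done],
                "turn_angle": turns.ravel()[done],
                "case": False,
                "bearing": np.nan,
            }
        )
        out.append(ctrl)
    if n_dropped:
        logger.warning("generate_random_steps: dropped %d off-grid controls", n_dropped)
    full = pd.concat(out, ignore_index=True).sort_values(["stratum", "case"], ascending=[True, False])
    return StepSet(full.reset_index(drop=True), list(steps.covariate_names))


def attach_covariates(steps: StepSet, stack: RasterStack, names=None) -> StepSet:
    """Sample covariates at step endpoints; strata with any nodata are dropped."""
    names = list(names) if names is not None else stack.names
    df = steps.data.copy()
    for name in names:
        df[name] = stack[name].sample(df["x_end"].to_numpy(float), df["y_end"].to_numpy(float))
    bad_strata = df.loc[df[names].isna().any(axis=1), "stratum"].unique()
    if len(bad_strata):
        logger.info("attach_covariates: dropped %d strata on nodata", len(bad_strata))
        df = df[~df["stratum"].isin(bad_strata)]
    return StepSet(df.reset_index(drop=True), names)


@dataclass
class FittedSSF:
    covariate_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    log_partial_likelihood: float
    n_strata: int
    dropped_covariates: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"covariate": self.covariate_names, "beta": self.beta, "se": self.se}
        )


def clogit_loglik(X: np.ndarray, case: np.ndarray, strata: np.ndarray, beta: np.ndarray) -> float:
    """Stratified conditional log-likelihood (reference implementation)."""
    eta = X @ beta
    ll = 0.0
    for s in np.unique(strata):
        sel = strata == s
        e = eta[sel]
        ll += e[case[sel]].sum() - np.logaddexp.reduce(e)
    return float(ll)


def fit_clogit(
    stepset: StepSet,
    covariate_names=None,
    max_iter: int = 100,
    tol: float = 1e-10,
    max_beta: float = 50.0,
) -> FittedSSF:
    """Newton-Raphson conditional logistic fit on case/control strata."""
    names = list(covariate_names) if covariate_names is not None else list(stepset.covariate_names)
    if not names:
        raise ValueError("no covariates to fit")
    df = stepset.data
    strata_codes, strata_index = pd.factorize(df["stratum"], sort=True)
    n_strata = len(strata_index)
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    case = df["case"].to_numpy(bool)
    counts = np.bincount(strata_codes, weights=case)
    if not np.all(counts == 1):
        raise ValueError("every stratum must contain exactly one case step")
    X = df[names].to_numpy(float)

    # drop covariates constant within every stratum (no information)
    keep, dropped = [], []
    for j, name in enumerate(names):
        mins = np.full(n_strata, np.inf)
        maxs = np.full(n_strata, -np.inf)
        np.minimum.at(mins, strata_codes, X[:, j])
        np.maximum.at(maxs, strata_codes, X[:, j])
        if np.all(maxs - mins < 1e-12):
            dropped.append(name)
            warnings.warn(f"covariate {name!r} constant within strata; coefficient set to 0")
        else:
            keep.append(j)
    Xk = X[:, keep]
    p = Xk.shape[1]
    beta = np.zeros(p)

    def loglik_parts(b):
        eta = Xk @ b
        # per-stratum softmax weights
        emax = np.full(n_strata, -np.inf)
        np.maximum.at(emax, strata_codes, eta)
        z = np.exp(eta - emax[strata_codes])
        denom = np.bincount(strata_codes, weights=z, minlength=n_strata)
        w = z / denom[strata_codes]
        ll = float(eta[case].sum() - (np.log(denom) + emax).sum())
        return ll, w, eta

    ll, w, _ = loglik_parts(beta)
    converged = p == 0
    for _ in range(max_iter):
        if p == 0:
            break
        # gradient: sum_case x - E[x]; Hessian: -sum Cov_s(x)
        mean_x = np.zeros((n_strata, p))
        for j in range(p):
            mean_x[:, j] = np.bincount(strata_codes, weights=w * Xk[:, j], minlength=n_strata)
        grad = Xk[case].sum(axis=0) - mean_x.sum(axis=0)
        Xc = Xk - mean_x[strata_codes]
        H = (Xc * w[:, None]).T @ Xc  # observed information (positive semidefinite)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in clogit fit") from exc
        # damped update with step-halving
        t = 1.0
        for _half in range(40):
            new_beta = beta + t * step
            new_ll, new_w, _ = loglik_parts(new_beta)
            if new_ll >= ll - 1e-12:
                break
            t /= 2
        else:
            raise RuntimeError("complete separation suspected: step-halving failed")
        improve = new_ll - ll
        beta, ll, w = new_beta, new_ll, new_w
        if np.max(np.abs(beta)) > max_beta:
            raise RuntimeError("complete separation suspected: diverging coefficients")
        if improve < tol and np.max(np.abs(grad)) < 1e-6:
            converged = True
            break
    if not converged:
        raise RuntimeError("clogit failed to converge within iteration cap")
    if p and ll > -1e-6:
        # supremum of the partial likelihood is 0: the case dominates every
        # control in every stratum and the MLE is infinite
        raise RuntimeError("complete separation: partial likelihood attains its supremum")

    se_k = np.full(p, np.nan)
    if p:
        mean_x = np.zeros((n_strata, p))
        for j in range(p):
            mean_x[:, j] = np.bincount(strata_codes, weights=w * Xk[:, j], minlength=n_strata)
        Xc = Xk - mean_x[strata_codes]
        H = (Xc * w[:, None]).T @ Xc
        # pinv + clipping: near-collinear covariate sets (e.g. cover fractions
        # summing to 1) make the information matrix numerically singular
        diag = np.diag(np.linalg.pinv(H))
        se_k = np.where(diag > 0, np.sqrt(np.maximum(diag, 0)), np.nan)

    full_beta = np.zeros(len(names))
    full_se = np.full(len(names), np.nan)
    for i, j in enumerate(keep):
        full_beta[j] = beta[i]
        full_se[j] = se_k[i]
    return FittedSSF(names, full_beta, full_se, ll, n_strata, dropped)


def ssf_surface(fit: FittedSSF, stack: RasterStack) -> Raster:
    """logistic(x . beta) per cell, min-max rescaled to [0, 1] over the map."""
    missing = [n for n in fit.covariate_names if n not in stack]
    if missing:
        raise KeyError(f"stack missing covariate layers: {missing}")
    arr = stack.as_array(fit.covariate_names)
    eta = np.tensordot(fit.beta, np.nan_to_num(arr), axes=1)
    invalid = np.isnan(arr).any(axis=0)
    s = 1.0 / (1.0 + np.exp(-eta))
    s[invalid] = np.nan
    lo, hi = np.nanmin(s), np.nanmax(s)
    out = (s - lo) / (hi - lo) if hi > lo else np.where(np.isnan(s), np.nan, 0.5)
    return Raster(stack.grid, out)
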