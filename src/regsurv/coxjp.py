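"""Age-stratified Cox models with a piecewise-linear calendar-year effect.

The diagnosis year enters the hazard through a continuous hinge basis
``f(y) = (y - y0, max(0, y - tau_1), ...)``, so the log hazard is piecewise
linear in calendar time with slope changes ("joinpoints") at the tau_k. The
number and location of joinpoints are chosen by exhaustive grid search over
integer years, minimising a BIC with the event count as effective sample
size. Baseline cumulative hazards per age stratum come from the Breslow
estimator at the reference year, which yields model-based 5-year survival
``S_a(5 | y) = exp(-Lambda_a(5) * exp(f(y)' beta))`` per stratum and year;
case-pool age weights combine these into an age-standardised series, extended
one year past the last fitted diagnosis year as a flagged model prediction.

The trend magnitude is summarised by the AACS (average absolute change in
survival): the average yearly change of the fitted standardised 5-year
survival over the series, in percentage points. Its confidence interval is a
case-resampling bootstrap that refits the coefficients and baselines under
the already-selected joinpoints.

The partial likelihood uses the Efron tie correction and is maximised by
Newton iterations; everything is vectorised over tie groups so the joinpoint
grid search stays cheap even at registry scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .km import cohort_observations
from .simulate import hinge_eval
from .standardise import AgeGrouping, AgeWeights


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class YearBasis:
    """Hinge basis for the calendar-year effect."""

    reference_year: int
    joinpoints: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        taus = self.joinpoints
        if list(taus) != sorted(set(taus)):
            raise ValueError("joinpoints must be strictly increasing")
        if taus and taus[0] <= self.reference_year:
            raise ValueError("joinpoints must lie after the reference year")

    @property
    def n_params(self) -> int:
        return 1 + len(self.joinpoints)

    def evaluate(self, year) -> np.ndarray:
        """Basis matrix f(year), one row per observation."""
        return hinge_eval(year, self.reference_year, self.joinpoints)

    def segment_slopes(self, beta: np.ndarray) -> np.ndarray:
        """Cumulative sums of the hinge coefficients: slope per segment."""
        return np.cumsum(np.asarray(beta, dtype=float))


# ---------------------------------------------------------------------------
# Stratified partial likelihood (Efron ties), Newton maximisation
# ---------------------------------------------------------------------------

class _PreparedStratum:
    """Sort order and tie structure of one stratum, computed once per dataset
    and reused across every candidate basis and Newton iteration."""

    __slots__ = ("order", "t", "e", "year", "uniq", "gid", "first", "d",
                 "dg_id", "death_rows", "nd", "starts", "frac")

    def __init__(self, time: np.ndarray, event: np.ndarray, year: np.ndarray):
        self.order = np.argsort(time, kind="mergesort")
        self.t = time[self.order]
        self.e = event[self.order]
        self.year = year[self.order]
        self.uniq, self.first = np.unique(self.t, return_index=True)
        self.gid = np.searchsorted(self.uniq, self.t)
        self.dg_id = self.gid[self.e]
        self.d = np.bincount(self.dg_id, minlength=self.uniq.size)
        self.death_rows = np.flatnonzero(self.e)
        self.nd = int(self.e.sum())
        self.starts = np.cumsum(self.d) - self.d
        l = np.arange(self.nd) - self.starts[self.dg_id]
        self.frac = l / np.maximum(self.d[self.dg_id], 1)


def prepare_strata(time, event, year, strata) -> dict:
    """Per-stratum prepared structures keyed by stratum label."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    year = np.asarray(year, dtype=float)
    strata = np.asarray(strata)
    return {lab: _PreparedStratum(time[idx], event[idx], year[idx])
            for lab in pd.unique(strata)
            for idx in [np.flatnonzero(strata == lab)]}


def _stratum_quantities(prep: _PreparedStratum, Xs: np.ndarray, XX: np.ndarray,
                        beta: np.ndarray):
    """Log partial likelihood, gradient, observed information and Breslow
    baseline pieces for one stratum, vectorised over Efron tie groups.

    ``Xs`` is the design matrix already in the stratum's sorted order and
    ``XX`` its row-wise outer products (both beta-free, cached per fit).
    """
    p = Xs.shape[1]
    if prep.nd == 0:
        return 0.0, np.zeros(p), np.zeros((p, p)), 0, {}
    eta = Xs @ beta
    eta_max = float(eta.max())
    r = np.exp(eta - eta_max)  # stabilised; the shift cancels in all ratios

    first, e, dg_id, d = prep.first, prep.e, prep.dg_id, prep.d
    nu = prep.uniq.size
    rev = slice(None, None, -1)
    S0 = np.cumsum(r[rev])[rev][first]
    S1 = np.cumsum((r[:, None] * Xs)[rev], axis=0)[rev][first]
    S2 = np.cumsum((r[:, None, None] * XX)[rev], axis=0)[rev][first]

    T0 = np.bincount(dg_id, weights=r[e], minlength=nu)
    T1 = np.column_stack([
        np.bincount(dg_id, weights=(r * Xs[:, k])[e], minlength=nu)
        for k in range(p)])
    T2 = np.empty((nu, p, p))
    for k in range(p):
        for m in range(k, p):
            col = np.bincount(dg_id, weights=(r * XX[:, k, m])[e], minlength=nu)
            T2[:, k, m] = col
            T2[:, m, k] = col

    frac = prep.frac
    phi = S0[dg_id] - frac * T0[dg_id]
    num1 = S1[dg_id] - frac[:, None] * T1[dg_id]
    num2 = S2[dg_id] - frac[:, None, None] * T2[dg_id]
    z = num1 / phi[:, None]

    # with r = exp(eta - m): log phi drops m per death, matching eta - m in
    # the numerator, so the stabilising shift cancels exactly
    ll = float((eta[prep.death_rows] - eta_max).sum() - np.log(phi).sum())
    grad = Xs[prep.death_rows].sum(axis=0) - z.sum(axis=0)
    info = (num2 / phi[:, None, None]).sum(axis=0) - (
        z[:, :, None] * z[:, None, :]).sum(axis=0)

    # Breslow baseline pieces at this beta; the shift un-cancels here:
    # S0_true = S0 e^m, S1_true = S1 e^m
    with np.errstate(divide="ignore", invalid="ignore"):
        inv0 = np.where(S0 > 0, 1.0 / S0, 0.0)
    baseline = {
        "times": prep.uniq, "d": d,
        "dLambda": d * inv0 * np.exp(-eta_max),
        "v1": d * inv0 ** 2 * np.exp(-2 * eta_max),
        "dq": (d[:, None] * S1 * (inv0 ** 2)[:, None]) * np.exp(-eta_max),
    }
    return ll, grad, info, prep.nd, baseline


def _fit_newton(prepared: dict, basis: "YearBasis", tol=1e-8, max_iter=100,
                init=None):
    """Newton-Raphson maximisation of the stratified Efron partial likelihood."""
    p = basis.n_params
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    X_by_stratum = {lab: basis.evaluate(prep.year)
                    for lab, prep in prepared.items()}
    XX_by_stratum = {lab: X[:, :, None] * X[:, None, :]
                     for lab, X in X_by_stratum.items()}

    def evaluate(b):
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        nd = 0
        bases = {}
        for lab, prep in prepared.items():
            l, g, i, d, base = _stratum_quantities(
                prep, X_by_stratum[lab], XX_by_stratum[lab], b)
            ll += l
            grad += g
            info += i
            nd += d
            bases[lab] = base
        return ll, grad, info, nd, bases

    ll, grad, info, nd, bases = evaluate(beta)
    if nd == 0:
        raise ValueError("no events: partial likelihood undefined")
    # gradient tolerance in per-event units: the score scales with the number
    # of deaths, so an absolute cutoff would be unreachable at registry scale
    crit = tol * max(1.0, float(nd))
    for _ in range(max_iter):
        if np.max(np.abs(grad)) <= crit:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # step-halving if the likelihood does not improve
        for _h in range(30):
            cand = beta + step
            ll_new, grad_new, info_new, _, bases_new = evaluate(cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood")
        moved = np.max(np.abs(cand - beta))
        beta, ll, grad, info, bases = cand, ll_new, grad_new, info_new, bases_new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "divergent coefficients (monotone likelihood / separation in year)")
        if moved < 1e-12 * (1.0 + np.max(np.abs(beta))):
            break  # at numerical precision; gradient noise floor reached
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(|grad|={np.max(np.abs(grad)):.2e})")
    cov = np.linalg.inv(info)
    return beta, cov, ll, nd, bases, info


@dataclass
class StratumBaseline:
    """Breslow baseline cumulative hazard at the reference year, with the
    pieces needed for delta-method variance of Lambda(t)."""

    cum_hazard: float        # Lambda_a(horizon)
    var_iid: float           # sum d / S0^2 (baseline-only variance part)
    q: np.ndarray            # sum d * S1 / S0^2 (couples baseline and beta)
    n_events: int


class JoinpointCoxPH(BaseEstimator):
    """Age-stratified Cox model with a hinge calendar-year effect.

    Parameters
    ----------
    joinpoints : fixed joinpoint years (selection is done by
        :func:`select_joinpoints`).
    reference_year : series start y0 (defaults to the smallest observed year).
    horizon : follow-up truncation for the baseline read-off, in years.
    tol, max_iter : Newton convergence controls (max gradient component and
        iteration cap).

    Fitted attributes: ``coef_``, ``cov_``, ``log_likelihood_``, ``bic_``,
    ``n_events_``, ``basis_``, ``baselines_`` (per-stratum
    :class:`StratumBaseline`), ``strata_``.
    """

    def __init__(self, joinpoints: tuple[int, ...] = (),
                 reference_year: int | None = None, horizon: float = 5.0,
                 tol: float = 1e-8, max_iter: int = 100,
                 count_joinpoints_in_penalty: bool = False):
        self.joinpoints = joinpoints
        self.reference_year = reference_year
        self.horizon = horizon
        self.tol = tol
        self.max_iter = max_iter
        self.count_joinpoints_in_penalty = count_joinpoints_in_penalty

    def fit(self, observations: pd.DataFrame, init=None,
            _prepared: dict | None = None) -> "JoinpointCoxPH":
        """Fit on observations with columns ``time``, ``event``, ``year`` and
        ``stratum`` (already right-truncated at the horizon).

        ``_prepared`` lets the joinpoint grid search reuse the per-stratum
        sort/tie structure across candidate bases.
        """
        obs = observations
        if _prepared is None:
            strata = obs["stratum"].to_numpy() if "stratum" in obs.columns else \
                np.zeros(len(obs), dtype=int)
            _prepared = prepare_strata(obs["time"], obs["event"], obs["year"], strata)
        y0 = int(self.reference_year if self.reference_year is not None
                 else obs["year"].min())
        basis = YearBasis(y0, tuple(int(t) for t in self.joinpoints))

        beta, cov, ll, nd, bases, info = _fit_newton(
            _prepared, basis, tol=self.tol, max_iter=self.max_iter, init=init)

        baselines: dict = {}
        for lab, base in bases.items():
            if not base:
                raise ValueError(f"stratum {lab!r} has no events: baseline unavailable")
            keep = base["times"] <= self.horizon + 1e-12
            baselines[lab] = StratumBaseline(
                cum_hazard=float(base["dLambda"][keep].sum()),
                var_iid=float(base["v1"][keep].sum()),
                q=base["dq"][keep].sum(axis=0),
                n_events=int(base["d"][keep].sum()),
            )

        p_eff = basis.n_params + (len(basis.joinpoints)
                                  if self.count_joinpoints_in_penalty else 0)
        self.basis_ = basis
        self.coef_ = beta
        self.cov_ = cov
        self.information_ = info
        self.log_likelihood_ = ll
        self.n_events_ = nd
        self.baselines_ = baselines
        self.strata_ = tuple(baselines)
        self.bic_ = bic_value(ll, p_eff, nd)
        self.last_fit_year_ = int(obs["year"].max())
        return self

    # -- predictions --------------------------------------------------------

    def predict_survival(self, years, stratum) -> np.ndarray:
        """Model 5-year survival for a stratum across diagnosis years."""
        lam = self.baselines_[stratum].cum_hazard
        mult = np.exp(self.basis_.evaluate(years) @ self.coef_)
        return np.exp(-lam * mult)

    def standardised_series(self, weights: AgeWeights | Mapping[str, float],
                            years: Sequence[int], alpha: float = 0.05) -> "TrendSeries":
        """Age-standardised fitted 5-year survival with a delta-method band.

        The (Lambda_a, beta) estimates are treated as jointly asymptotically
        normal: Cov(Lambda_a, Lambda_b) = delta_ab * V_a + q_a' W q_b and
        Cov(Lambda_a, beta) = -W q_a with W the coefficient covariance, the
        standard large-sample covariance of the Breslow estimator.
        """
        wmap = weights.as_dict() if isinstance(weights, AgeWeights) else dict(weights)
        missing = set(wmap) - set(self.strata_)
        if missing:
            raise ValueError(f"weights name strata absent from the fit: {sorted(missing)}")
        labs = list(wmap)
        w = np.array([wmap[a] for a in labs])
        lam = np.array([self.baselines_[a].cum_hazard for a in labs])
        v1 = np.array([self.baselines_[a].var_iid for a in labs])
        Q = np.vstack([self.baselines_[a].q for a in labs])      # (A, p)
        W = self.cov_

        years = np.asarray(years, dtype=int)
        F = self.basis_.evaluate(years)                           # (Y, p)
        mult = np.exp(F @ self.coef_)                             # (Y,)
        S = np.exp(-np.outer(mult, lam))                          # (Y, A)
        value = S @ w

        # delta-method variance per year
        cov_ll = np.diag(v1) + Q @ W @ Q.T                        # (A, A)
        cov_lb = -(Q @ W)                                         # (A, p)
        var = np.empty(years.size)
        for i in range(years.size):
            g_lam = -w * mult[i] * S[i]                           # (A,)
            g_beta = -(mult[i] * F[i]) * float(w @ (S[i] * lam))  # (p,)
            var[i] = (g_lam @ cov_ll @ g_lam
                      + g_beta @ W @ g_beta
                      + 2.0 * g_lam @ cov_lb @ g_beta)
        z = norm.ppf(1 - alpha / 2)
        se = np.sqrt(np.clip(var, 0.0, None))
        return TrendSeries(
            years=years,
            s5=value,
            band_low=np.clip(value - z * se, 0.0, 1.0),
            band_high=np.clip(value + z * se, 0.0, 1.0),
            extrapolated=years > self.last_fit_year_,
        )


def bic_value(log_likelihood: float, n_params: int, n_events: int) -> float:
    """BIC for a Cox fit: -2 log PL + p * ln(d), d = number of events."""
    if n_events <= 0:
        raise ValueError("BIC undefined without events")
    return -2.0 * log_likelihood + n_params * np.log(n_events)


def bic(model: JoinpointCoxPH) -> tuple[float, dict]:
    """Criterion value of a fitted model with its components."""
    comp = {"log_likelihood": model.log_likelihood_,
            "n_params": model.basis_.n_params, "n_events": model.n_events_}
    return model.bic_, comp


def fit_cox(observations: pd.DataFrame, basis: YearBasis, init=None,
            _prepared: dict | None = None, **kwargs) -> JoinpointCoxPH:
    """Fit an age-stratified Cox model on a fixed year basis."""
    model = JoinpointCoxPH(joinpoints=basis.joinpoints,
                           reference_year=basis.reference_year, **kwargs)
    return model.fit(observations, init=init, _prepared=_prepared)


def candidate_joinpoints(y0: int, y1: int, max_joinpoints: int,
                         min_segment: int) -> list[tuple[int, ...]]:
    """Admissible integer-year joinpoint placements (every segment, including
    both ends of the series, spans at least ``min_segment`` years)."""
    cands: list[tuple[int, ...]] = [()]
    lo, hi = y0 + min_segment, y1 - min_segment
    if max_joinpoints >= 1:
        cands += [(t,) for t in range(lo, hi + 1)]
    if max_joinpoints >= 2:
        cands += [(t1, t2)
                  for t1 in range(lo, hi + 1)
                  for t2 in range(t1 + min_segment, hi + 1)]
    return cands


def select_joinpoints(observations: pd.DataFrame, max_joinpoints: int = 2,
                      min_segment: int = 3, reference_year: int | None = None,
                      horizon: float = 5.0,
                      count_joinpoints_in_penalty: bool = False) -> JoinpointCoxPH:
    """Exhaustive BIC-minimising grid search over joinpoint placements.

    Ties are broken toward fewer joinpoints, then earlier locations. The
    returned model carries the full grid in ``bic_table_``.
    """
    y0 = int(reference_year if reference_year is not None
             else observations["year"].min())
    y1 = int(observations["year"].max())
    cands = candidate_joinpoints(y0, y1, max_joinpoints, min_segment)
    strata = observations["stratum"].to_numpy() if "stratum" in observations.columns \
        else np.zeros(len(observations), dtype=int)
    prepared = prepare_strata(observations["time"], observations["event"],
                              observations["year"], strata)

    best = None
    rows = []
    warm: np.ndarray | None = None
    for taus in cands:
        model = JoinpointCoxPH(
            joinpoints=taus, reference_year=y0, horizon=horizon,
            count_joinpoints_in_penalty=count_joinpoints_in_penalty)
        init = None
        if warm is not None:
            init = np.zeros(1 + len(taus))
            init[0] = warm[0]
        try:
            model.fit(observations, init=init, _prepared=prepared)
        except (ConvergenceError, ValueError) as err:
            rows.append({"joinpoints": taus, "bic": np.nan, "log_likelihood": np.nan,
                         "error": str(err)})
            continue
        if warm is None:
            warm = model.coef_
        rows.append({"joinpoints": taus, "bic": model.bic_,
                     "log_likelihood": model.log_likelihood_, "error": ""})
        if best is None or model.bic_ < best.bic_ - 1e-9:
            best = model
    if best is None:
        raise ConvergenceError("no admissible joinpoint model could be fitted")
    best.bic_table_ = pd.DataFrame(rows)
    return best


# ---------------------------------------------------------------------------
# Trend series and AACS
# ---------------------------------------------------------------------------

@dataclass
class TrendSeries:
    """Fitted age-standardised 5-year survival by diagnosis year."""

    years: np.ndarray
    s5: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    extrapolated: np.ndarray
    aacs: float | None = None
    aacs_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if np.any((self.s5 < -1e-9) | (self.s5 > 1 + 1e-9)):
            raise ValueError("fitted survival outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years, "s5": self.s5, "band_low": self.band_low,
            "band_high": self.band_high, "extrapolated": self.extrapolated,
        })

    def segment_aacs(self, joinpoints: Sequence[int]) -> dict[tuple[int, int], float]:
        """Per-segment AACS between consecutive joinpoints."""
        bounds = [int(self.years[0]), *map(int, joinpoints), int(self.years[-1])]
        out = {}
        for a, b in zip(bounds[:-1], bounds[1:]):
            ia = int(np.searchsorted(self.years, a))
            ib = int(np.searchsorted(self.years, b))
            out[(a, b)] = (self.s5[ib] - self.s5[ia]) * 100.0 / (b - a)
        return out


def aacs(series: TrendSeries | Sequence[float]) -> float:
    """Average absolute change in survival, in percentage points per year:
    (last - first) * 100 / (number of years - 1)."""
    values = series.s5 if isinstance(series, TrendSeries) else np.asarray(series, float)
    if len(values) < 2:
        raise ValueError("need at least two years")
    return float((values[-1] - values[0]) * 100.0 / (len(values) - 1))


def trend_observations(cases: pd.DataFrame, grouping: AgeGrouping | None = None,
                       horizon: float = 5.0) -> pd.DataFrame:
    """Per-case observations for the trend models: follow-up right-truncated
    at the horizon, with the diagnosis year and the (possibly pooled) age
    stratum."""
    obs = cohort_observations(cases, horizon=horizon)
    obs["year"] = cases["diagnosis_year"].to_numpy()
    ages = cases["age_group"].reset_index(drop=True)
    obs["stratum"] = grouping.assign(ages).to_numpy() if grouping is not None \
        else ages.to_numpy()
    return obs


@dataclass
class BootstrapAACS:
    median: float
    ci_low: float
    ci_high: float
    n_failed: int
    samples: np.ndarray = field(repr=False, default=None)


def bootstrap_aacs(observations: pd.DataFrame, basis: YearBasis,
                   years: Sequence[int], weights: AgeWeights | None = None,
                   B: int = 500, seed: int = 0, stratified: bool = False,
                   max_failure_rate: float = 0.10) -> BootstrapAACS:
    """Case-resampling bootstrap of the AACS under the selected model.

    Each replicate resamples cases with replacement (optionally within age
    strata), refits the coefficients and baselines with the joinpoints held
    fixed, recomputes the age-standardised series over ``years`` and its
    AACS. When ``weights`` is None the case-pool weights are re-derived from
    each replicate. Replicates that fail to fit are dropped and counted;
    reported values are the median and the 2.5th/97.5th percentiles.
    """
    rng = np.random.default_rng(seed)
    n = len(observations)
    obs = observations.reset_index(drop=True)
    full = fit_cox(obs, basis)
    strata = obs["stratum"].to_numpy()
    strat_idx = {lab: np.flatnonzero(strata == lab) for lab in pd.unique(strata)}

    vals = []
    n_failed = 0
    for _ in range(B):
        if stratified:
            idx = np.concatenate([rng.choice(ix, size=ix.size, replace=True)
                                  for ix in strat_idx.values()])
        else:
            idx = rng.integers(0, n, size=n)
        rep = obs.iloc[idx]
        try:
            m = fit_cox(rep, basis, init=full.coef_)
            if weights is None:
                shares = rep["stratum"].value_counts(normalize=True)
                wmap = {lab: float(shares.get(lab, 0.0)) for lab in m.strata_}
            else:
                wmap = weights.as_dict()
            series = m.standardised_series(wmap, years)
            vals.append(aacs(series))
        except (ConvergenceError, ValueError, KeyError):
            n_failed += 1
    if n_failed > max_failure_rate * B:
        raise ConvergenceError(
            f"{n_failed}/{B} bootstrap replicates failed to fit")
    samples = np.asarray(vals)
    lo, med, hi = np.percentile(samples, [2.5, 50.0, 97.5])
    return BootstrapAACS(float(med), float(lo), float(hi), n_failed, samples)


def adjusted_s5_series(model: JoinpointCoxPH, weights: AgeWeights | Mapping[str, float],
                       years: Sequence[int]) -> TrendSeries:
    """Age-standardised fitted 5-year survival series (functional form)."""
    return model.standardised_series(weights, years)
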