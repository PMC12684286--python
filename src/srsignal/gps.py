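"""Gamma-Poisson Shrinker: empirical-Bayes EBGM with optional stratification.

Model: the observed count n of a drug-event cell is Poisson(lambda * E) where
E is the expected count under within-stratum independence, pooled over strata,
and the reporting-rate ratio lambda follows the two-component gamma mixture
prior

    lambda ~ w * Gamma(a1, rate b1) + (1 - w) * Gamma(a2, rate b2).

Marginally n is a mixture of negative binomials; the hyperparameters are
fitted by maximizing the marginal likelihood over every cell of the
drug-event universe.  The cell posterior is again a gamma mixture, and
EBGM = 2**E[log2 lambda | n] (geometric-mean form, evaluated with digamma).
EBGM05/EBGM95 are the 5th/95th posterior percentiles (90% interval).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .model import DrugEventPair

__all__ = [
    "GPSHyperParams",
    "GPSConvergenceError",
    "DEFAULT_GPS_INIT",
    "gps_fit",
    "gps_posterior",
    "pair_frame",
    "cell_counts",
    "target_cell",
]

logger = logging.getLogger(__name__)

#: DuMouchel's standard starting point (w, a1, b1, a2, b2)
DEFAULT_GPS_INIT = (1.0 / 3.0, 0.2, 0.1, 2.0, 4.0)


@dataclass(frozen=True)
class GPSHyperParams:
    w: float
    a1: float
    b1: float
    a2: float
    b2: float
    loglik: float = math.nan


class GPSConvergenceError(RuntimeError):
    """Raised when no restart converges; carries the best parameters seen."""

    def __init__(self, message: str, best: Optional[GPSHyperParams] = None):
        super().__init__(message)
        self.best = best


def _nb_logpmf(n: np.ndarray, a: float, b: float, E: np.ndarray) -> np.ndarray:
    # n | lambda ~ Poisson(lambda E), lambda ~ Gamma(a, rate b)
    # => n ~ NegBin with success prob b/(b+E)
    return (
        special.gammaln(a + n)
        - special.gammaln(a)
        - special.gammaln(n + 1.0)
        + a * (np.log(b) - np.log(b + E))
        + n * (np.log(E) - np.log(b + E))
    )


def _loglik(theta: np.ndarray, n: np.ndarray, E: np.ndarray) -> float:
    w = special.expit(theta[0])
    a1, b1, a2, b2 = np.exp(theta[1:5])
    lp1 = _nb_logpmf(n, a1, b1, E) + math.log(w)
    lp2 = _nb_logpmf(n, a2, b2, E) + math.log1p(-w)
    return float(np.sum(np.logaddexp(lp1, lp2)))


def _pack(params: Sequence[float]) -> np.ndarray:
    w, a1, b1, a2, b2 = params
    return np.array(
        [special.logit(w), math.log(a1), math.log(b1), math.log(a2), math.log(b2)]
    )


def gps_fit(
    observed: "Sequence[float] | np.ndarray",
    expected: "Sequence[float] | np.ndarray",
    init: Sequence[float] = DEFAULT_GPS_INIT,
    n_restarts: int = 4,
    seed: int = 0,
    tol: float = 1e-8,
) -> GPSHyperParams:
    """Fit the mixture prior by marginal maximum likelihood.

    Optimization runs on the unconstrained scale (logit w, log a, log b) from
    the standard initialization plus ``n_restarts`` seeded random
    perturbations, keeping the best converged solution.
    """
    n = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if n.shape != E.shape or n.ndim != 1:
        raise ValueError("observed and expected must be 1-d arrays of equal length")
    if np.any(E <= 0):
        raise ValueError("expected counts must be strictly positive")
    if len(n) < 2:
        raise ValueError("need at least two cells to fit the prior")
    if len(n) < 10:
        logger.warning("gps_fit: only %d cells; prior estimates may be unstable", len(n))

    rng = np.random.default_rng(seed)
    starts = [_pack(init)]
    starts += [_pack(init) + rng.normal(0, 0.5, size=5) for _ in range(n_restarts)]

    # Box bounds on the transformed scale keep the gamma components proper:
    # without them the likelihood is maximized by degenerate point-mass
    # priors (a, b -> inf jointly) whenever a cell subset is near-Poisson.
    bounds = [(-7.0, 7.0)] + [(-8.0, 8.0)] * 4
    best_theta, best_ll, any_success = None, -np.inf, False
    for theta0 in starts:
        res = optimize.minimize(
            lambda th: -_loglik(th, n, E),
            np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ll, best_theta = -res.fun, res.x
            any_success = any_success or bool(res.success)

    if best_theta is None:
        raise GPSConvergenceError("all GPS restarts diverged", None)
    w = float(special.expit(best_theta[0]))
    a1, b1, a2, b2 = (float(x) for x in np.exp(best_theta[1:5]))
    fit = GPSHyperParams(w, a1, b1, a2, b2, best_ll)
    if not any_success:
        raise GPSConvergenceError("GPS optimization did not converge", fit)
    return fit


def _posterior_mixture(
    n11: int, E: float, hyper: GPSHyperParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior weights, shapes, and rates of the two gamma components."""
    shapes = np.array([hyper.a1 + n11, hyper.a2 + n11])
    rates = np.array([hyper.b1 + E, hyper.b2 + E])
    n_arr = np.array([float(n11)])
    if hyper.w >= 1.0:
        q = np.array([1.0, 0.0])
    elif hyper.w <= 0.0:
        q = np.array([0.0, 1.0])
    else:
        lp1 = _nb_logpmf(n_arr, hyper.a1, hyper.b1, np.array([E]))[0] + math.log(
            hyper.w
        )
        lp2 = _nb_logpmf(n_arr, hyper.a2, hyper.b2, np.array([E]))[0] + math.log1p(
            -hyper.w
        )
        m = max(lp1, lp2)
        q1 = math.exp(lp1 - m) / (math.exp(lp1 - m) + math.exp(lp2 - m))
        q = np.array([q1, 1.0 - q1])
    return q, shapes, rates


def _mixture_ppf(
    p: float, q: np.ndarray, shapes: np.ndarray, rates: np.ndarray
) -> float:
    dists = [stats.gamma(a=shapes[k], scale=1.0 / rates[k]) for k in range(2)]

    def cdf(x: float) -> float:
        return q[0] * dists[0].cdf(x) + q[1] * dists[1].cdf(x)

    lo = min(d.ppf(p) for d in dists if np.isfinite(d.ppf(p)))
    hi = max(d.ppf(p) for d in dists)
    lo, hi = max(lo * 0.5, 1e-300), hi * 2 + 1e-12
    return float(optimize.brentq(lambda x: cdf(x) - p, lo, hi, xtol=1e-12, rtol=1e-12))


def gps_posterior(
    n11: int,
    E: float,
    hyper: GPSHyperParams,
    level: float = 0.90,
    point: str = "geometric",
) -> "MetricResult":
    """Posterior EBGM and percentile interval for one drug-event cell.

    ``point="geometric"`` gives EBGM = exp(E[ln lambda | n]) via digamma;
    ``point="mean"`` gives the posterior mean of lambda instead.
    """
    from .contingency import MetricResult

    if E <= 0:
        raise ValueError("expected count must be positive")
    q, shapes, rates = _posterior_mixture(n11, E, hyper)
    if point == "geometric":
        mean_log = float(np.sum(q * (special.digamma(shapes) - np.log(rates))))
        est = math.exp(mean_log)
    elif point == "mean":
        est = float(np.sum(q * shapes / rates))
    else:
        raise ValueError(f"unknown point estimator: {point!r}")
    alpha = (1 - level) / 2
    lower = _mixture_ppf(alpha, q, shapes, rates)
    upper = _mixture_ppf(1 - alpha, q, shapes, rates)
    return MetricResult(
        "EBGM",
        est,
        lower,
        upper,
        level,
        {"expected": E, "posterior_weight": float(q[0])},
    )


# ---------------------------------------------------------------------------
# Building the (drug, event) cell universe with stratified expected counts
# ---------------------------------------------------------------------------


def pair_frame(
    pairs: Iterable[DrugEventPair], strata: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Tabulate pairs as a DataFrame with an optional per-case stratum label.

    ``strata`` maps case_id -> label; unmapped cases get ``"unknown"``, which
    forms its own stratum so that no pair is silently discarded when pooling
    expected counts.
    """
    df = pd.DataFrame(
        {
            "case_id": [p.case_id for p in pairs],
            "drug": [p.drug for p in pairs],
            "event": [p.pt_code for p in pairs],
        }
    )
    if strata is not None:
        df["stratum"] = df["case_id"].map(strata).fillna("unknown")
    else:
        df["stratum"] = "all"
    return df


def cell_counts(frame: pd.DataFrame) -> pd.DataFrame:
    """Observed and expected counts for every drug x event cell.

    Expected counts are computed under independence within each stratum and
    pooled:  E_de = sum_s n_d+(s) * n_+e(s) / n_++(s).  The universe is the
    full cross product of drugs and events seen anywhere, so structural zeros
    participate in the prior fit.
    """
    if frame.empty:
        raise ValueError("empty pair universe")
    drugs = sorted(frame["drug"].unique())
    events = sorted(frame["event"].unique())
    obs = np.zeros((len(drugs), len(events)))
    exp_ = np.zeros_like(obs)
    d_idx = {d: i for i, d in enumerate(drugs)}
    e_idx = {e: j for j, e in enumerate(events)}
    for _, sub in frame.groupby("stratum"):
        ct = pd.crosstab(sub["drug"], sub["event"])
        rows = ct.sum(axis=1).to_numpy(dtype=float)
        cols = ct.sum(axis=0).to_numpy(dtype=float)
        total = rows.sum()
        e_s = np.outer(rows, cols) / total
        ii = [d_idx[d] for d in ct.index]
        jj = [e_idx[e] for e in ct.columns]
        obs[np.ix_(ii, jj)] += ct.to_numpy(dtype=float)
        exp_[np.ix_(ii, jj)] += e_s
    out = pd.DataFrame(
        {
            "drug": np.repeat(drugs, len(events)),
            "event": events * len(drugs),
            "n": obs.ravel(),
            "E": exp_.ravel(),
        }
    )
    return out[out["E"] > 0].reset_index(drop=True)


def target_cell(
    frame: pd.DataFrame,
    drug_set: "Iterable[str]",
    event_set: "Iterable[str]",
) -> tuple[int, float]:
    """Observed count and pooled expected count for an aggregate target cell.

    The target drug set and event set are treated as single composite margins
    (in-set vs out-of-set) within each stratum.
    """
    drugs, events = set(drug_set), set(event_set)
    d_in = frame["drug"].isin(drugs)
    e_in = frame["event"].isin(events)
    n11 = int((d_in & e_in).sum())
    E = 0.0
    for _, sub_idx in frame.groupby("stratum").groups.items():
        sub_d = d_in.loc[sub_idx]
        sub_e = e_in.loc[sub_idx]
        total = len(sub_idx)
        if total:
            E += sub_d.sum() * sub_e.sum() / total
    if E <= 0:
        raise ValueError("target cell has zero expected count")
    return n11, float(E)
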