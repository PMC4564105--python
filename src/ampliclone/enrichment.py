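"""Passage-enrichment modelling of mutant-allele counts.

Mutant read counts are regressed on the passage number with log total
reads as an exposure offset, a per-individual random effect, and
negative-binomial (NB2) or Poisson observation error.  Two random-effect
flavours are available:

``beta``
    The classic panel negative-binomial estimator: the group effect acts
    on the NB dispersion and is integrated out analytically under a Beta
    prior, giving a closed-form marginal likelihood.  This is the default
    and reproduces the published per-passage enrichment factors.
``normal``
    A normal random intercept on the log mean, integrated numerically by
    adaptive Gauss-Hermite quadrature (15 nodes by default), the modern
    GLMM default.
``none``
    No random effect (plain fixed-effects count regression).

The headline quantity is ``exp(beta_passage)``: the multiplicative change
in the mutant-read rate per additional culture passage, with a Wald
interval on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import gammaln, polygamma
from statsmodels.tools.numdiff import approx_hess

from .errors import DesignDegeneracyError, InsufficientDataError
from .tables import Cohort, CohortTable

__all__ = [
    "PassageSeries",
    "EnrichmentFit",
    "IccResult",
    "series_from_table",
    "fit_enrichment",
    "fit_enrichment_segments",
    "icc_oneway",
]

Family = Literal["negbin", "poisson"]
RandomEffect = Literal["beta", "normal", "none"]


@dataclass(frozen=True)
class PassageSeries:
    """One individual's counts across culture passages."""

    individual_id: str
    observations: tuple[tuple[int, int, int], ...]  # (passage, total_reads, alt_reads)

    def passages(self) -> set[int]:
        return {p for p, _, _ in self.observations}


@dataclass(frozen=True)
class EnrichmentFit:
    """Per-passage rate ratio with Wald CI/p from the mixed count model."""

    rate_ratio_per_passage: float
    ci_low: float
    ci_high: float
    p_value: float
    dispersion: float
    random_effect_sd: float
    log_likelihood: float
    converged: bool
    n_individuals: int
    n_observations: int
    family: str = "negbin"
    random_effect: str = "beta"
    intercept: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "rate_ratio_per_passage": self.rate_ratio_per_passage,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "dispersion": self.dispersion,
            "random_effect_sd": self.random_effect_sd,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_individuals": self.n_individuals,
            "n_observations": self.n_observations,
            "family": self.family,
            "random_effect": self.random_effect,
            "intercept": self.intercept,
        }


@dataclass(frozen=True)
class IccResult:
    icc: float
    n_pairs: int


def series_from_table(
    table: CohortTable,
    passages: Iterable[int] | None = None,
    include_reference: bool = False,
) -> list[PassageSeries]:
    """Group a count table into per-individual passage series.

    Reference-cohort samples are excluded by default.  Replicates at the
    same passage become separate observations.
    """
    wanted = set(passages) if passages is not None else None
    by_ind: dict[str, list[tuple[int, int, int, int]]] = {}
    order: list[str] = []
    for s in table:
        if s.cohort is Cohort.REFERENCE and not include_reference:
            continue
        if wanted is not None and s.passage not in wanted:
            continue
        if s.individual_id not in by_ind:
            by_ind[s.individual_id] = []
            order.append(s.individual_id)
        by_ind[s.individual_id].append((s.passage, s.replicate, s.total_reads, s.alt_reads))
    out = []
    for ind in order:
        obs = sorted(by_ind[ind])
        out.append(PassageSeries(ind, tuple((p, t, a) for p, _, t, a in obs)))
    return out


# ---------------------------------------------------------------------------
# marginal likelihoods (all vectorized over a flat observation layout)


def _nll_beta_negbin(params, y, x, off, gidx, n_groups):
    """Panel NB with analytically integrated Beta-distributed group effect."""
    b0, b1, log_a, log_b = params
    a, b = math.exp(log_a), math.exp(log_b)
    lam = np.exp(b0 + b1 * x + off)
    sum_lam = np.bincount(gidx, weights=lam, minlength=n_groups)
    sum_y = np.bincount(gidx, weights=y, minlength=n_groups)
    ll_groups = (
        gammaln(a + b)
        + gammaln(a + sum_lam)
        + gammaln(b + sum_y)
        - gammaln(a)
        - gammaln(b)
        - gammaln(a + b + sum_lam + sum_y)
    )
    ll_obs = gammaln(lam + y) - gammaln(lam) - gammaln(y + 1)
    return -(ll_groups.sum() + ll_obs.sum())


def _obs_ll(y, mu, theta):
    if theta is None:  # Poisson
        return y * np.log(mu) - mu - gammaln(y + 1)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _nll_fixed(params, y, x, off, theta_fixed=None):
    """No random effect; last parameter is log theta unless fixed/Poisson."""
    b0, b1 = params[0], params[1]
    if theta_fixed == "poisson":
        theta = None
    elif theta_fixed is not None:
        theta = theta_fixed
    else:
        theta = math.exp(params[2])
    mu = np.exp(b0 + b1 * x + off)
    return -_obs_ll(y, mu, theta).sum()


def _nll_normal_re(
    params, y, x, off, gidx, n_groups, gh_x, gh_w, theta_fixed=None, u_cache=None
):
    """Normal random intercept integrated by adaptive Gauss-Hermite quadrature.

    ``u_cache`` (length ``n_groups``) warm-starts the inner Newton search
    for the conditional modes across outer-optimizer evaluations.
    """
    b0, b1 = params[0], params[1]
    if theta_fixed == "poisson":
        theta = None
        log_sigma = params[2]
    elif theta_fixed is not None:
        theta = theta_fixed
        log_sigma = params[2]
    else:
        theta = math.exp(params[2])
        log_sigma = params[3]
    sigma = math.exp(log_sigma)
    eta0 = b0 + b1 * x + off

    # inner Newton for the per-group conditional mode (log-concave joint)
    u = np.zeros(n_groups) if u_cache is None else u_cache.copy()
    for _ in range(100):
        mu = np.exp(eta0 + u[gidx])
        if theta is None:
            g_obs, h_obs = y - mu, -mu
        else:
            g_obs = y - (y + theta) * mu / (theta + mu)
            h_obs = -(y + theta) * theta * mu / (theta + mu) ** 2
        grad = np.bincount(gidx, weights=g_obs, minlength=n_groups) - u / sigma**2
        hess = np.bincount(gidx, weights=h_obs, minlength=n_groups) - 1.0 / sigma**2
        step = np.clip(-grad / hess, -5.0, 5.0)
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    if u_cache is not None:
        u_cache[:] = u
    tau = 1.0 / np.sqrt(-hess)

    log_prior_const = -log_sigma - 0.5 * math.log(2 * math.pi)
    node_ll = np.empty((n_groups, gh_x.size))
    for k, (xk, wk) in enumerate(zip(gh_x, gh_w)):
        uk = u + math.sqrt(2.0) * tau * xk
        mu = np.exp(eta0 + uk[gidx])
        ll = np.bincount(gidx, weights=_obs_ll(y, mu, theta), minlength=n_groups)
        ll += -0.5 * (uk / sigma) ** 2 + log_prior_const
        node_ll[:, k] = math.log(wk) + xk**2 + ll
    m = node_ll.max(axis=1)
    group_ll = m + np.log(np.exp(node_ll - m[:, None]).sum(axis=1))
    group_ll += 0.5 * math.log(2.0) + np.log(tau)
    return -group_ll.sum()


def _start_values(y, x, off):
    # Poisson moment/IRLS-free start: intercept from the pooled rate,
    # slope from the rate ratio between extreme passages.
    rate = (y.sum() + 0.5) / np.exp(off).sum()
    b0 = math.log(rate)
    lo, hi = x.min(), x.max()
    if hi > lo:
        r_lo = (y[x == lo].sum() + 0.5) / np.exp(off[x == lo]).sum()
        r_hi = (y[x == hi].sum() + 0.5) / np.exp(off[x == hi]).sum()
        b1 = (math.log(r_hi) - math.log(r_lo)) / (hi - lo)
    else:
        b1 = 0.0
    return b0, b1


def fit_enrichment(
    series_set: Sequence[PassageSeries],
    passages: Iterable[int] | None = None,
    family: Family = "negbin",
    random_effect: RandomEffect = "beta",
    n_quad: int = 15,
    fix_theta: float | None = None,
    max_iter: int = 500,
) -> EnrichmentFit:
    """Fit the mixed count regression and return the per-passage rate ratio.

    Series with fewer than two distinct passages after subsetting are
    dropped; raises :class:`InsufficientDataError` if none remain and
    :class:`DesignDegeneracyError` if a single passage value survives.
    """
    if family not in ("negbin", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    if random_effect not in ("beta", "normal", "none"):
        raise ValueError(f"unknown random_effect {random_effect!r}")
    if family == "poisson" and random_effect == "beta":
        raise ValueError("the beta random effect requires the negbin family")

    wanted = set(passages) if passages is not None else None
    rows: list[tuple[int, int, int, int]] = []  # (gidx, passage, total, alt)
    n_groups = 0
    for series in series_set:
        obs = [o for o in series.observations if wanted is None or o[0] in wanted]
        if len({p for p, _, _ in obs}) < 2:
            continue
        for p, t, a in obs:
            rows.append((n_groups, p, t, a))
        n_groups += 1
    if n_groups == 0:
        raise InsufficientDataError(
            "no series with at least two distinct passages after subsetting"
        )
    gidx = np.array([r[0] for r in rows])
    x = np.array([r[1] for r in rows], dtype=float)
    tot = np.array([r[2] for r in rows], dtype=float)
    y = np.array([r[3] for r in rows], dtype=float)
    if np.unique(x).size < 2:
        raise DesignDegeneracyError("a single passage value remains; slope unidentifiable")
    if np.any(tot <= 0):
        raise ValueError("total_reads must be positive for the exposure offset")
    off = np.log(tot)

    b0_start, b1_start = _start_values(y, x, off)
    theta_fixed = "poisson" if family == "poisson" else fix_theta

    if random_effect == "beta":
        nll = lambda p: _nll_beta_negbin(p, y, x, off, gidx, n_groups)
        x0s = [
            [b0_start, b1_start, 0.0, 0.0],
            [b0_start, b1_start, 1.0, 4.0],
            [b0_start, b1_start, 2.0, 1.0],
        ]
    elif random_effect == "normal":
        gh_x, gh_w = hermgauss(n_quad)
        u_cache = np.zeros(n_groups)
        nll = lambda p: _nll_normal_re(
            p, y, x, off, gidx, n_groups, gh_x, gh_w, theta_fixed, u_cache
        )
        base = [b0_start, b1_start]
        if theta_fixed is None:
            x0s = [base + [math.log(5.0), 0.0], base + [math.log(50.0), -1.0]]
        else:
            x0s = [base + [0.0], base + [-1.0]]
    else:
        nll = lambda p: _nll_fixed(p, y, x, off, theta_fixed)
        base = [b0_start, b1_start]
        x0s = [base + [math.log(5.0)]] if theta_fixed is None else [base]

    best = None
    for x0 in x0s:
        try:
            with np.errstate(all="ignore"):
                r = optimize.minimize(
                    nll,
                    x0,
                    method="Nelder-Mead",
                    options=dict(maxiter=max_iter * 4, xatol=1e-6, fatol=1e-9),
                )
        except (FloatingPointError, ValueError):
            continue
        if best is None or r.fun < best.fun:
            best = r
    if best is None:
        raise InsufficientDataError("optimization failed from every starting point")
    with np.errstate(all="ignore"):
        polish = optimize.minimize(nll, best.x, method="BFGS", options=dict(gtol=1e-8))
        if not np.isfinite(polish.fun) or polish.fun > best.fun:
            polish = optimize.minimize(
                nll,
                best.x,
                method="Nelder-Mead",
                options=dict(maxiter=max_iter * 20, xatol=1e-10, fatol=1e-12),
            )
    if polish.fun <= best.fun:
        best = polish

    b1 = float(best.x[1])
    with np.errstate(all="ignore"):
        hess = approx_hess(best.x, nll)
        se = float("nan")
        if np.all(np.isfinite(hess)):
            # symmetrize and clip non-positive curvature directions (ridge in
            # the nuisance parameters, e.g. dispersion at its boundary)
            hess = 0.5 * (hess + hess.T)
            evals, evecs = np.linalg.eigh(hess)
            floor = max(1e-8, 1e-10 * float(np.max(np.abs(evals))))
            evals = np.maximum(evals, floor)
            cov = evecs @ np.diag(1.0 / evals) @ evecs.T
            if cov[1, 1] > 0:
                se = math.sqrt(cov[1, 1])
    converged = bool(best.success or best.fun < np.inf) and math.isfinite(se)

    z = stats.norm.ppf(0.975)
    rr = math.exp(b1)
    ci_low = math.exp(b1 - z * se) if math.isfinite(se) else float("nan")
    ci_high = math.exp(b1 + z * se) if math.isfinite(se) else float("nan")
    p_value = (
        float(2.0 * stats.norm.sf(abs(b1 / se))) if math.isfinite(se) and se > 0 else float("nan")
    )

    if random_effect == "beta":
        a_hat, b_hat = math.exp(best.x[2]), math.exp(best.x[3])
        re_sd = math.sqrt(polygamma(1, a_hat) + polygamma(1, b_hat))
        dispersion = b_hat / (a_hat - 1.0) if a_hat > 1.0 else float("inf")
    elif random_effect == "normal":
        re_sd = math.exp(best.x[-1])
        if theta_fixed == "poisson":
            dispersion = float("inf")
        elif theta_fixed is not None:
            dispersion = float(theta_fixed)
        else:
            dispersion = math.exp(best.x[2])
    else:
        re_sd = 0.0
        if theta_fixed == "poisson":
            dispersion = float("inf")
        elif theta_fixed is not None:
            dispersion = float(theta_fixed)
        else:
            dispersion = math.exp(best.x[2])

    return EnrichmentFit(
        rate_ratio_per_passage=rr,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        dispersion=dispersion,
        random_effect_sd=re_sd,
        log_likelihood=-float(best.fun),
        converged=converged,
        n_individuals=n_groups,
        n_observations=int(y.size),
        family=family,
        random_effect=random_effect,
        intercept=float(best.x[0]),
    )


def fit_enrichment_segments(
    series_set: Sequence[PassageSeries],
    breakpoints: Sequence[int] = (0, 4, 9),
    **fit_kwargs,
) -> list[EnrichmentFit]:
    """One fit per consecutive passage pair, e.g. (0,4) then (4,9)."""
    if len(breakpoints) < 2:
        raise ValueError("need at least two breakpoints")
    fits = []
    for lo, hi in zip(breakpoints[:-1], breakpoints[1:]):
        fits.append(fit_enrichment(series_set, passages={lo, hi}, **fit_kwargs))
    return fits


def icc_oneway(
    pairs: Sequence[tuple[float, float]],
    variant: Literal["oneway", "twoway"] = "oneway",
) -> IccResult:
    """Intraclass correlation for paired replicate measurements.

    ``oneway`` is ICC(1,1) = (MSB - MSW) / (MSB + MSW) for k = 2
    measurements per subject; ``twoway`` is the two-way absolute-agreement
    single-measure flavour ICC(A,1).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (value_a, value_b)")
    n = arr.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    k = 2
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    ms_between = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_within = ((arr - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if variant == "oneway":
        denom = ms_between + (k - 1) * ms_within
        icc = (ms_between - ms_within) / denom if denom > 0 else 1.0
    elif variant == "twoway":
        col_means = arr.mean(axis=0)
        ms_col = n * ((col_means - grand) ** 2).sum() / (k - 1)
        ms_err = (
            ((arr - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        denom = ms_between + (k - 1) * ms_err + k / n * (ms_col - ms_err)
        icc = (ms_between - ms_err) / denom if denom > 0 else 1.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return IccResult(icc=float(icc), n_pairs=n)
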