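"""Biomarker dichotomization and memory-error binning.

CSF Abeta42 is bimodally distributed (amyloid-positive vs -negative), so its
cutoff is estimated unsupervised: a two-component univariate Gaussian
mixture is fit by EM and the cutoff placed at the equal-posterior point
between the two component means — the concentration at which a value is
equally likely to come from either component.  Values at or below the cutoff
are amyloid-positive ("low Abeta42").

CSF P-tau uses fixed published cutoffs (52 ng/l primary, 70 ng/l secondary;
values strictly above are "elevated").  Delayed-recall errors on a 10-word
list are binned 0-1 / 2-3 / 4-5 / 6-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("subaxis")

DEFAULT_ABETA_CUTOFF = 527.0  # ng/l, inclusive: value <= cutoff is positive
DEFAULT_PTAU_CUTOFF = 52.0    # ng/l, exclusive: value > cutoff is elevated
HIGH_PTAU_CUTOFF = 70.0       # ng/l, secondary published cutoff

MEMORY_BINS = ("0-1", "2-3", "4-5", "6-10")
_MEMORY_BIN_EDGES = (1, 3, 5, 10)  # inclusive upper edges
MAX_MEMORY_ERRORS = 10  # 10-word list


@dataclass(frozen=True)
class MixtureCutoffModel:
    """Fitted two-component Gaussian mixture with its equal-posterior cutoff.

    Component "abnormal" is the lower-mean (pathological, low-Abeta42)
    component; "normal" the higher-mean one.  ``cutoff`` lies strictly
    between the two means.
    """

    weight_abnormal: float
    mean_abnormal: float
    sd_abnormal: float
    mean_normal: float
    sd_normal: float
    cutoff: float
    loglik: float
    n_restarts: int
    converged: bool
    separation_ok: bool = True

    @property
    def weight_normal(self) -> float:
        return 1.0 - self.weight_abnormal

    def to_dict(self) -> dict:
        return {
            "weight_abnormal": self.weight_abnormal,
            "mean_abnormal": self.mean_abnormal,
            "sd_abnormal": self.sd_abnormal,
            "mean_normal": self.mean_normal,
            "sd_normal": self.sd_normal,
            "cutoff": self.cutoff,
            "cutoff_rounded": int(round(self.cutoff)),
            "loglik": self.loglik,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "separation_ok": self.separation_ok,
        }


def equal_posterior_point(
    w_a: float, mu_a: float, sd_a: float,
    w_n: float, mu_n: float, sd_n: float,
) -> float:
    """Root of w_a phi(x; mu_a, sd_a) = w_n phi(x; mu_n, sd_n) in (mu_a, mu_n).

    Found by bracketed root-finding; at this point the posterior probability
    of each component is 1/2, so it is the natural dichotomization cutoff.
    """
    if not mu_a < mu_n:
        raise ValueError("mu_a must be below mu_n")

    def f(x: float) -> float:
        return (
            np.log(w_a) + stats.norm.logpdf(x, mu_a, sd_a)
            - np.log(w_n) - stats.norm.logpdf(x, mu_n, sd_n)
        )

    lo, hi = mu_a, mu_n
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo > 0 > f_hi):
        raise ValueError(
            "no equal-posterior crossing between the component means "
            "(components insufficiently separated)"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _em_once(
    x: np.ndarray,
    w: float,
    mu: np.ndarray,
    sd: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> tuple[float, np.ndarray, np.ndarray, float, bool]:
    """Single EM run for a 1-D two-component Gaussian mixture.

    Returns (weight of component 0, means, sds, loglik, converged).  The
    log-likelihood is checked to be non-decreasing at every iteration.
    """
    n = x.size
    weights = np.array([w, 1.0 - w])
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step
        logp = (
            np.log(weights)[None, :]
            + stats.norm.logpdf(x[:, None], mu[None, :], sd[None, :])
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        if ll < ll_prev - 1e-8 * (1.0 + abs(ll_prev)):
            raise AssertionError(
                f"EM log-likelihood decreased: {ll_prev} -> {ll}"
            )
        resp = np.exp(logp - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, var_floor))
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return float(weights[0]), mu, sd, ll_prev, converged


def fit_mixture_cutoff(
    values,
    n_restarts: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureCutoffModel:
    """Fit a 2-component Gaussian mixture by EM and return its cutoff.

    The best of ``n_restarts`` runs by log-likelihood is kept.  Restarts are
    initialized from data quantiles plus seeded jitter; component variances
    are floored at 1e-4 times the sample variance to prevent degenerate
    spikes.  Components are ordered so mean_abnormal < mean_normal and the
    cutoff is the equal-posterior point between the means.

    If the fitted components barely separate (no posterior crossing between
    the means, e.g. on unimodal input) the midpoint of the means is returned
    with ``separation_ok=False`` and a warning — such a cutoff is unstable
    and should not be trusted.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError(f"need >= 50 finite values, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    s_var = float(np.var(x))
    var_floor = 1e-4 * s_var
    sd0 = np.sqrt(s_var)

    best = None
    n_converged = 0
    for r in range(n_restarts):
        q_lo, q_hi = np.quantile(x, [0.25, 0.75])
        jitter = 0.0 if r == 0 else 0.25 * sd0
        mu = np.array([
            q_lo + jitter * rng.standard_normal(),
            q_hi + jitter * rng.standard_normal(),
        ])
        sd = np.full(2, sd0 / 2.0)
        w0 = 0.5 if r == 0 else float(rng.uniform(0.2, 0.8))
        w, mu_f, sd_f, ll, conv = _em_once(x, w0, mu, sd, tol, max_iter, var_floor)
        n_converged += conv
        if best is None or ll > best[3]:
            best = (w, mu_f, sd_f, ll, conv)
    if n_converged == 0:
        raise RuntimeError("EM failed to converge in any restart")
    w, mu, sd, ll, conv = best
    order = np.argsort(mu)  # normalize labels: abnormal = lower mean
    mu, sd = mu[order], sd[order]
    w_a = w if order[0] == 0 else 1.0 - w
    try:
        cutoff = equal_posterior_point(w_a, mu[0], sd[0], 1 - w_a, mu[1], sd[1])
        separation_ok = True
    except ValueError:
        cutoff = float(0.5 * (mu[0] + mu[1]))
        separation_ok = False
        logger.warning(
            "mixture components barely separated (means %.1f / %.1f); "
            "cutoff is unstable", mu[0], mu[1],
        )
    return MixtureCutoffModel(
        weight_abnormal=float(w_a),
        mean_abnormal=float(mu[0]),
        sd_abnormal=float(sd[0]),
        mean_normal=float(mu[1]),
        sd_normal=float(sd[1]),
        cutoff=cutoff,
        loglik=ll,
        n_restarts=n_restarts,
        converged=bool(conv),
        separation_ok=separation_ok,
    )


def classify_abeta(value: float, cutoff: float = DEFAULT_ABETA_CUTOFF) -> str:
    """Amyloid status: value <= cutoff -> "positive" (low Abeta42)."""
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"invalid Abeta42 value: {value}")
    return "positive" if value <= cutoff else "negative"


def classify_ptau(value: float, cutoff: float = DEFAULT_PTAU_CUTOFF) -> str:
    """Tau status: value > cutoff -> "elevated", else "normal"."""
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"invalid P-tau value: {value}")
    return "elevated" if value > cutoff else "normal"


def bin_memory_errors(errors: int) -> str:
    """Map a delayed-recall error count (0..10) to its analysis bin."""
    e = int(errors)
    if e != errors or not (0 <= e <= MAX_MEMORY_ERRORS):
        raise ValueError(
            f"memory errors must be an integer in 0..{MAX_MEMORY_ERRORS}, "
            f"got {errors!r}"
        )
    for label, hi in zip(MEMORY_BINS, _MEMORY_BIN_EDGES):
        if e <= hi:
            return label
    raise AssertionError("unreachable")
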