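"""Pixel-wise mono-exponential T2 estimation from multi-echo magnitude images.

Two estimators are provided for the decay model ``nu_i = A * exp(-TE_i / T2)``:

* a log-linear least-squares fit (``fit_loglinear``) — fast, but biased upward
  at low SNR because the Rician noise floor lifts the late-echo magnitudes;
* a Rician maximum-likelihood fit (``fit_rician_mle``) — jointly estimates
  (A, T2, sigma) per pixel under the Rician magnitude-noise model, which is
  the appropriate likelihood for magnitude MR data.

``fit_map`` applies either estimator to every masked pixel of an
:class:`EchoSeries` and returns a :class:`T2Map`. A statsmodels-flavoured
front end (:class:`MonoExpDecayModel` / :class:`MonoExpDecayResults`) wraps
the single-curve case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e

__all__ = [
    "EchoSeries",
    "T2Map",
    "fit_loglinear",
    "rician_loglik",
    "fit_rician_mle",
    "fit_map",
    "MonoExpDecayModel",
    "MonoExpDecayResults",
]

#: default physiological T2 search window in ms (flagged when hit)
DEFAULT_T2_BOUNDS = (1.0, 500.0)


def _check_echo_times(echo_times: np.ndarray, min_n: int = 3) -> np.ndarray:
    te = np.asarray(echo_times, dtype=float)
    if te.ndim != 1 or te.size < min_n:
        raise ValueError(f"need at least {min_n} echo times")
    if not np.all(np.diff(te) > 0):
        raise ValueError("echo times must be strictly increasing")
    return te


@dataclass
class EchoSeries:
    """A multi-echo magnitude image stack.

    ``magnitudes`` has the echo dimension last (e.g. ``(nx, ny, nz, n_echo)``
    for an image volume, or ``(n_pixel, n_echo)`` for a flat pixel list).
    """

    magnitudes: np.ndarray
    echo_times_ms: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.echo_times_ms = _check_echo_times(self.echo_times_ms)
        if self.magnitudes.shape[-1] != self.echo_times_ms.size:
            raise ValueError("last magnitude axis must match echo_times_ms")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.magnitudes.shape[:-1]:
                raise ValueError("mask shape must match the image grid")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times_ms.size)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.magnitudes.shape[:-1]


@dataclass
class T2Map:
    """Per-pixel fit results on the image grid (NaN outside the mask)."""

    T2_ms: np.ndarray
    A: np.ndarray
    sigma: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    method: str
    mask: np.ndarray

    @property
    def n_fitted(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# log-linear baseline
# ---------------------------------------------------------------------------

def fit_loglinear(magnitudes, echo_times):
    """Ordinary least squares of log(M) on -TE.

    T2 = -1/slope, A = exp(intercept). Pixels with any non-positive magnitude
    or a non-negative slope (non-decaying signal) are flagged by returning
    NaN for that pixel rather than raising.

    Parameters
    ----------
    magnitudes : array, echoes on the last axis
    echo_times : 1-d array of strictly increasing echo times (ms)

    Returns
    -------
    (T2_ms, A) arrays with the leading shape of ``magnitudes``.
    """
    te = _check_echo_times(echo_times, min_n=2)
    m = np.asarray(magnitudes, dtype=float)
    if m.shape[-1] != te.size:
        raise ValueError("last magnitude axis must match echo_times")
    valid = np.all(m > 0, axis=-1)
    logm = np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), 0.0)

    te_c = te - te.mean()
    sxx = float(np.sum(te_c**2))
    slope = (logm * te_c).sum(axis=-1) / sxx
    intercept = logm.mean(axis=-1) - slope * te.mean()

    # slope must be clearly negative: a flat series (slope ~ 0 up to float
    # noise) means infinite T2 and is flagged rather than fitted
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(slope < -1e-12, -1.0 / slope, np.nan)
    t2 = np.where(valid, t2, np.nan)
    a = np.where(np.isfinite(t2), np.exp(intercept), np.nan)
    if m.ndim == 1:
        return float(t2), float(a)
    return t2, a


# ---------------------------------------------------------------------------
# Rician log-likelihood
# ---------------------------------------------------------------------------

def _log_i0(z: np.ndarray) -> np.ndarray:
    # log I0(z) via the exponentially scaled Bessel function: stable for huge z
    return np.log(i0e(z)) + z


def _batch_loglik(theta: np.ndarray, m: np.ndarray, te: np.ndarray) -> np.ndarray:
    """Rician log-likelihood for a batch. theta = (logA, logT2, logsigma), (N, 3).

    Uses the cancellation-free identity
    ``-(M^2 + nu^2)/(2 sigma^2) + z = -(M - nu)^2 / (2 sigma^2)`` with
    ``z = M nu / sigma^2``, so the value stays accurate when sigma is tiny
    relative to the signal (near-noiseless data)."""
    a = np.exp(theta[:, 0:1])
    t2 = np.exp(theta[:, 1:2])
    sig2 = np.exp(2.0 * theta[:, 2:3])
    nu = a * np.exp(-te[None, :] / t2)
    z = m * nu / sig2
    with np.errstate(divide="ignore"):
        logm = np.log(m)
    ll = logm - np.log(sig2) - (m - nu) ** 2 / (2.0 * sig2) + np.log(i0e(z))
    return ll.sum(axis=1)


def _batch_grad(theta: np.ndarray, m: np.ndarray, te: np.ndarray) -> np.ndarray:
    """Analytic gradient of the batch log-likelihood wrt (logA, logT2, logsigma).

    Formulated through ``1 - R`` with ``R = I1(z)/I0(z)`` to avoid the
    large-z cancellation in ``M R - nu`` and ``(M^2+nu^2)/sigma^2 - 2 z R``."""
    a = np.exp(theta[:, 0:1])
    t2 = np.exp(theta[:, 1:2])
    sig2 = np.exp(2.0 * theta[:, 2:3])
    nu = a * np.exp(-te[None, :] / t2)
    z = m * nu / sig2
    b0 = i0e(z)
    one_minus_r = (b0 - i1e(z)) / b0  # 1 - I1/I0, ~ 1/(2z) for large z
    dl_dnu = ((m - nu) - m * one_minus_r) / sig2
    g_a = (dl_dnu * nu).sum(axis=1)                      # d nu/d logA = nu
    g_t = (dl_dnu * nu * te[None, :] / t2).sum(axis=1)   # d nu/d logT2 = nu*TE/T2
    g_s = (-2.0 + (m - nu) ** 2 / sig2 + 2.0 * z * one_minus_r).sum(axis=1)
    return np.stack([g_a, g_t, g_s], axis=1)


def rician_loglik(params, magnitudes, echo_times) -> float:
    """Rician log-likelihood of a single decay curve.

    ``sum_i [log M_i - 2 log sigma - (M_i^2 + nu_i^2)/(2 sigma^2)
    + log I0(M_i nu_i / sigma^2)]`` with ``nu_i = A exp(-TE_i/T2)``.
    Uses the exponentially scaled Bessel I0, so large arguments do not
    overflow.
    """
    a, t2, sigma = (float(v) for v in params)
    if a <= 0 or t2 <= 0 or sigma <= 0:
        raise ValueError("A, T2 and sigma must all be positive")
    te = _check_echo_times(echo_times)
    m = np.asarray(magnitudes, dtype=float)
    if m.shape != te.shape:
        raise ValueError("magnitudes and echo_times must have the same length")
    theta = np.log([[a, t2, sigma]])
    return float(_batch_loglik(theta, m[None, :], te)[0])


# ---------------------------------------------------------------------------
# Rician maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class RicianFit:
    T2_ms: np.ndarray
    A: np.ndarray
    sigma: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    n_iter: int


def _initial_theta(m, te, bounds, sigma_floor):
    t2_ll, a_ll = fit_loglinear(m, te)
    t2_ll = np.atleast_1d(np.asarray(t2_ll, dtype=float))
    a_ll = np.atleast_1d(np.asarray(a_ll, dtype=float))
    bad = ~np.isfinite(t2_ll)
    if np.any(bad):
        # degenerate pixels: start mid-range from the observed scale
        t2_ll = np.where(bad, te.mean(), t2_ll)
        a_ll = np.where(bad, np.maximum(m.max(axis=-1), sigma_floor), a_ll)
    t2_ll = np.clip(t2_ll, bounds[0] * 1.01, bounds[1] * 0.99)
    a_ll = np.maximum(a_ll, sigma_floor)
    nu = a_ll[:, None] * np.exp(-te[None, :] / t2_ll[:, None])
    resid = m - nu
    sig0 = np.sqrt(np.mean(resid**2, axis=-1))
    sig0 = np.maximum(sig0, np.maximum(1e-3 * a_ll, sigma_floor))
    return np.log(np.stack([a_ll, t2_ll, sig0], axis=1))


def _fit_rician_batch(
    m: np.ndarray,
    te: np.ndarray,
    init: np.ndarray | None = None,
    bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
    tol: float = 1e-8,
    max_iter: int = 200,
    sigma_floor: float = 1e-6,
) -> RicianFit:
    """Damped-Newton (Levenberg) ascent of the Rician likelihood, vectorised
    over pixels. Parameters live on the log scale, so positivity holds by
    construction; T2 is clipped to ``bounds`` and bound-hitting pixels are
    flagged non-converged."""
    n = m.shape[0]
    theta = _initial_theta(m, te, bounds, sigma_floor) if init is None else init.copy()
    lo = np.array([np.log(sigma_floor), np.log(bounds[0]), np.log(sigma_floor)])
    hi = np.array([np.log(1e12), np.log(bounds[1]), np.log(1e12)])
    theta = np.clip(theta, lo, hi)

    ll = _batch_loglik(theta, m, te)
    lam = np.full(n, 1e-2)
    done = np.zeros(n, dtype=bool)
    stuck = np.zeros(n, dtype=bool)
    # near-exact initial fit: the likelihood is unbounded as sigma -> 0, so
    # the MLE degenerates to the exact curve with sigma at its floor
    nu0 = np.exp(theta[:, 0:1]) * np.exp(-te[None, :] / np.exp(theta[:, 1:2]))
    rel_resid = np.sqrt(np.mean((m - nu0) ** 2, axis=1)) / np.maximum(m.max(axis=1), 1e-300)
    exact = rel_resid < 1e-8
    if np.any(exact):
        theta[exact, 2] = lo[2]
        ll[exact] = _batch_loglik(theta[exact], m[exact], te)
        done[exact] = True
    h = 1e-5
    eye = np.eye(3)
    it = 0
    for it in range(1, max_iter + 1):
        active = np.flatnonzero(~done & ~stuck)
        if active.size == 0:
            break
        th = theta[active]
        ma = m[active]
        g = _batch_grad(th, ma, te)
        # finite-difference Hessian of the gradient (3 extra gradient calls)
        hess = np.empty((active.size, 3, 3))
        for j in range(3):
            hess[:, :, j] = (_batch_grad(th + h * eye[j], ma, te) - g) / h
        hess = 0.5 * (hess + np.transpose(hess, (0, 2, 1)))
        # Newton on the *negative* log-likelihood with Levenberg damping
        damped = -hess + (lam[active] + 1e-10)[:, None, None] * eye
        try:
            step = np.linalg.solve(damped, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(damped + 1e-6 * eye, g[..., None])[..., 0]
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step = np.where(norm > 2.0, step * (2.0 / norm), step)
        th_new = np.clip(th + step, lo, hi)
        ll_new = _batch_loglik(th_new, ma, te)
        improved = np.isfinite(ll_new) & (ll_new >= ll[active])
        rel = np.abs(ll_new - ll[active]) / (np.abs(ll[active]) + 1.0)
        stalled = np.max(np.abs(th_new - th), axis=1) < 1e-10
        conv_now = improved & ((rel < tol) | stalled)
        upd = active[improved]
        theta[upd] = th_new[improved]
        ll[upd] = ll_new[improved]
        lam[upd] = np.maximum(lam[upd] / 3.0, 1e-10)
        rej = active[~improved]
        lam[rej] *= 10.0
        done[active[conv_now]] = True
        stuck[rej[lam[rej] > 1e10]] = True

    at_t2_bound = (np.abs(theta[:, 1] - lo[1]) < 1e-9) | (np.abs(theta[:, 1] - hi[1]) < 1e-9)
    converged = done & ~at_t2_bound & np.isfinite(ll)
    return RicianFit(
        T2_ms=np.exp(theta[:, 1]),
        A=np.exp(theta[:, 0]),
        sigma=np.exp(theta[:, 2]),
        loglik=ll,
        converged=converged,
        n_iter=it,
    )


def fit_rician_mle(
    magnitudes,
    echo_times,
    init=None,
    bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
    tol: float = 1e-8,
    max_iter: int = 200,
    sigma_floor: float = 1e-6,
):
    """Maximum-likelihood (A, T2, sigma) under Rician noise.

    Accepts a single curve (1-d) or a batch with echoes on the last axis.
    Initialised from the log-linear fit unless ``init=(A0, T2_0, sigma0)`` is
    given; the achieved log-likelihood is never below the initialiser's.

    Returns a :class:`RicianFit` with arrays shaped like the input batch
    (scalars for a single curve).
    """
    te = _check_echo_times(echo_times)
    m = np.asarray(magnitudes, dtype=float)
    single = m.ndim == 1
    m2 = m[None, :] if single else m.reshape(-1, m.shape[-1])
    if np.any(m2 < 0):
        raise ValueError("magnitudes must be non-negative")
    if np.all(m2 == 0):
        raise ValueError("all-zero magnitudes cannot be fitted")
    theta0 = None
    if init is not None:
        a0, t20, s0 = (float(v) for v in init)
        if min(a0, t20, s0) <= 0:
            raise ValueError("init values must be positive")
        theta0 = np.tile(np.log([a0, t20, s0]), (m2.shape[0], 1))
    fit = _fit_rician_batch(m2, te, init=theta0, bounds=bounds, tol=tol,
                            max_iter=max_iter, sigma_floor=sigma_floor)
    if single:
        return RicianFit(
            T2_ms=float(fit.T2_ms[0]), A=float(fit.A[0]), sigma=float(fit.sigma[0]),
            loglik=float(fit.loglik[0]), converged=bool(fit.converged[0]),
            n_iter=fit.n_iter,
        )
    lead = m.shape[:-1]
    return RicianFit(
        T2_ms=fit.T2_ms.reshape(lead), A=fit.A.reshape(lead),
        sigma=fit.sigma.reshape(lead), loglik=fit.loglik.reshape(lead),
        converged=fit.converged.reshape(lead), n_iter=fit.n_iter,
    )


def fit_map(series: EchoSeries, method: str = "rician_mle", mask=None, **kwargs) -> T2Map:
    """Fit every masked pixel of an :class:`EchoSeries` and return a :class:`T2Map`.

    ``method`` is ``"loglinear"`` or ``"rician_mle"``. The mask defaults to
    the series' own mask, else all pixels. Unmasked pixels are NaN.
    """
    if method not in ("loglinear", "rician_mle", "rician"):
        raise ValueError(f"unknown fit method: {method!r}")
    mask = series.mask if mask is None else np.asarray(mask, dtype=bool)
    if mask is None:
        mask = np.ones(series.grid_shape, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError("mask shape must match the image grid")
    if not mask.any():
        raise ValueError("empty mask: nothing to fit")
    te = series.echo_times_ms
    m = series.magnitudes[mask]

    grid = series.grid_shape
    out = {k: np.full(grid, np.nan) for k in ("T2_ms", "A", "sigma", "loglik")}
    conv = np.zeros(grid, dtype=bool)

    if method == "loglinear":
        t2, a = fit_loglinear(m, te)
        ok = np.isfinite(t2)
        nu = np.where(ok[:, None], a[:, None], 0.0) * np.exp(
            -te[None, :] / np.where(ok, t2, 1.0)[:, None])
        sig = np.sqrt(np.mean((m - nu) ** 2, axis=-1))
        out["T2_ms"][mask] = t2
        out["A"][mask] = a
        out["sigma"][mask] = np.where(ok, sig, np.nan)
        conv[mask] = ok
        method_tag = "loglinear"
    else:
        fit = _fit_rician_batch(m, te, **kwargs)
        out["T2_ms"][mask] = fit.T2_ms
        out["A"][mask] = fit.A
        out["sigma"][mask] = fit.sigma
        out["loglik"][mask] = fit.loglik
        conv[mask] = fit.converged
        method_tag = "rician_mle"
    return T2Map(T2_ms=out["T2_ms"], A=out["A"], sigma=out["sigma"],
                 loglik=out["loglik"], converged=conv, method=method_tag, mask=mask)


# ---------------------------------------------------------------------------
# statsmodels-flavoured front end for a single decay curve
# ---------------------------------------------------------------------------

class MonoExpDecayModel:
    """Mono-exponential T2 decay model for one magnitude curve.

    Parameters
    ----------
    magnitudes : 1-d array of echo magnitudes
    echo_times_ms : 1-d array of strictly increasing echo times (ms)

    Examples
    --------
    >>> res = MonoExpDecayModel(mags, te).fit(method="rician_mle")
    >>> res.params  # {'A': ..., 'T2_ms': ..., 'sigma': ...}
    """

    def __init__(self, magnitudes, echo_times_ms):
        self.echo_times_ms = _check_echo_times(echo_times_ms)
        self.magnitudes = np.asarray(magnitudes, dtype=float)
        if self.magnitudes.shape != self.echo_times_ms.shape:
            raise ValueError("magnitudes and echo_times_ms must match in length")

    def fit(self, method: str = "rician_mle", **kwargs) -> "MonoExpDecayResults":
        if method == "loglinear":
            t2, a = fit_loglinear(self.magnitudes, self.echo_times_ms)
            conv = np.isfinite(t2)
            ll = np.nan
            sigma = np.nan
        else:
            f = fit_rician_mle(self.magnitudes, self.echo_times_ms, **kwargs)
            t2, a, sigma, ll, conv = f.T2_ms, f.A, f.sigma, f.loglik, f.converged
        return MonoExpDecayResults(self, method, t2, a, sigma, ll, conv)


@dataclass
class MonoExpDecayResults:
    model: MonoExpDecayModel
    method: str
    T2_ms: float
    A: float
    sigma: float
    loglik: float
    converged: bool
    params: dict = field(init=False)

    def __post_init__(self):
        self.params = {"A": self.A, "T2_ms": self.T2_ms, "sigma": self.sigma}

    def predict(self, echo_times_ms=None) -> np.ndarray:
        te = self.model.echo_times_ms if echo_times_ms is None else np.asarray(echo_times_ms)
        return self.A * np.exp(-te / self.T2_ms)

    def summary(self) -> str:
        lines = [
            "Mono-exponential T2 decay fit",
            f"  method:    {self.method}",
            f"  n echoes:  {self.model.echo_times_ms.size}",
            f"  T2 [ms]:   {self.T2_ms:.3f}",
            f"  A:         {self.A:.3f}",
            f"  sigma:     {self.sigma:.4g}" if np.isfinite(self.sigma) else "  sigma:     n/a",
            f"  loglik:    {self.loglik:.4f}" if np.isfinite(self.loglik) else "  loglik:    n/a",
            f"  converged: {self.converged}",
        ]
        return "\n".join(lines)
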