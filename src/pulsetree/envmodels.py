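"""Environmental covariates for rate models.

An :class:`EnvCurve` is a smooth function of age (Ma before present) with an
analytic derivative, evaluable on a finite support; outside the support it
clamps to the boundary value (and its derivative to zero).  Three kinds are
provided:

* smooths of gridded (age, value) series — penalized cubic B-splines
  (P-splines) with the penalty weight chosen by generalized cross-validation,
  emulating a many-knot cubic-spline GAM fit to a paleotemperature record;
* Gaussian *pulse* covariates — the Normal probability density with a given
  peak age and width, used as an artificial environmental perturbation
  confined to a narrow time window (raw PDF values, not renormalized after
  truncation to the support, so the peak value for sd 0.5 is
  1/(0.5*sqrt(2*pi)) ~ 0.798);
* derived rate-of-change curves.

Sign convention for rate of change: change per Myr moving *toward the
present* (forward in time), i.e. ``-d(value)/d(age)``; a temperature drop at
the Eocene-Oligocene boundary is therefore negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import norm

from .errors import DomainError, ValidationError

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


class EnvCurve:
    """A covariate as a function of age, with derivative access.

    Evaluations outside ``support`` clamp to the boundary value; the
    ``n_clamped`` counter records how often that happened.
    """

    def __init__(self, fn, dfn, support):
        lo, hi = float(support[0]), float(support[1])
        if not lo < hi:
            raise ValidationError("support must be a non-degenerate interval")
        self.support = (lo, hi)
        self._fn = fn
        self._dfn = dfn
        self.n_clamped = 0

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        lo, hi = self.support
        clipped = np.clip(age, lo, hi)
        n_out = int(np.sum((age < lo) | (age > hi)))
        if n_out:
            self.n_clamped += n_out
        out = self._fn(clipped)
        if not np.all(np.isfinite(out)):
            bad = np.asarray(clipped)[~np.isfinite(np.atleast_1d(out))]
            raise DomainError(f"covariate is non-finite at age {np.atleast_1d(bad)[0]:g}")
        return out if out.ndim else float(out)

    def derivative(self, age):
        """d(value)/d(age); zero outside the support (value is clamped)."""
        age = np.asarray(age, dtype=float)
        lo, hi = self.support
        inside = (age >= lo) & (age <= hi)
        out = np.where(inside, self._dfn(np.clip(age, lo, hi)), 0.0)
        return out if out.ndim else float(out)

    def rate_of_change(self) -> "EnvCurve":
        """Change per Myr moving toward the present: ``-d(value)/d(age)``."""
        return EnvCurve(
            fn=lambda a: -self._dfn(a),
            dfn=lambda a: _numeric_second(self, a),
            support=self.support,
        )

    def to_grid(self, step: float = 0.1) -> np.ndarray:
        """Dense (age, value) grid over the support."""
        lo, hi = self.support
        ages = np.arange(lo, hi + step / 2, step)
        return np.column_stack([ages, np.asarray(self(ages))])


def _numeric_second(curve: EnvCurve, a, h: float = 1e-4):
    a = np.asarray(a, dtype=float)
    return -(curve._dfn(a + h) - curve._dfn(a - h)) / (2 * h)


class PulseCurve(EnvCurve):
    """Normal-PDF pulse covariate centred at ``peak_age`` (Ma)."""

    def __init__(self, peak_age: float, sd: float = 0.5, support=(0.0, 50.0)):
        if sd <= 0:
            raise DomainError("pulse sd must be positive")
        if not support[0] <= peak_age <= support[1]:
            raise DomainError("pulse peak must lie inside the support")
        self.peak_age = float(peak_age)
        self.sd = float(sd)
        dist = norm(loc=peak_age, scale=sd)
        super().__init__(
            fn=dist.pdf,
            dfn=lambda a: dist.pdf(a) * (peak_age - a) / sd**2,
            support=support,
        )


def make_pulse(peak_age: float, sd: float = 0.5, support=(0.0, 50.0)) -> PulseCurve:
    """Gaussian pulse covariate: Normal PDF values over the support,
    truncated without renormalization."""
    return PulseCurve(peak_age, sd, support)


# ---------------------------------------------------------------------------
# P-spline smoothing
# ---------------------------------------------------------------------------


def _pspline_fit(x: np.ndarray, y: np.ndarray, n_knots: int):
    """Penalized cubic B-spline regression; GCV chooses the penalty.

    Returns a fitted :class:`scipy.interpolate.BSpline`.
    """
    k = 3
    lo, hi = x.min(), x.max()
    inner = np.linspace(lo, hi, n_knots)
    t = np.r_[[lo] * k, inner, [hi] * k]
    B = BSpline.design_matrix(x, t, k).toarray()
    nb = B.shape[1]
    # second-order difference penalty on coefficients
    D = np.diff(np.eye(nb), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    n = len(x)
    best = None
    for lam in np.logspace(-8, 8, 33):
        A = BtB + lam * P
        try:
            c = np.linalg.solve(A, Bty)
            Ainv_BtB = np.linalg.solve(A, BtB)
        except np.linalg.LinAlgError:
            continue
        edf = np.trace(Ainv_BtB)
        resid = y - B @ c
        rss = float(resid @ resid)
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, c)
    if best is None:
        raise ValidationError("spline smoothing failed for all penalty values")
    return BSpline(t, best[1], k)


def smooth_series(raw, knots: int = 300) -> EnvCurve:
    """Smooth a two-column (age, value) series into an :class:`EnvCurve`.

    ``raw`` is an (n, 2) array-like or a pandas DataFrame whose first two
    columns are age (Ma) and value.  Duplicate ages are averaged (with a
    warning); the knot count is capped at the number of unique ages minus 1.
    """
    arr = np.asarray(raw, dtype=float) if not hasattr(raw, "to_numpy") else raw.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError("raw series must have two columns (age, value)")
    ages, values = arr[:, 0], arr[:, 1]
    order = np.argsort(ages)
    ages, values = ages[order], values[order]
    uniq, inv, counts = np.unique(ages, return_inverse=True, return_counts=True)
    if len(uniq) < len(ages):
        warnings.warn("duplicate ages in series; averaging their values")
        sums = np.zeros_like(uniq)
        np.add.at(sums, inv, values)
        values = sums / counts
        ages = uniq
    if len(ages) < 4:
        raise ValidationError("need at least 4 points to smooth a series")
    if knots < 4:
        raise ValidationError("need at least 4 knots")
    n_knots = min(knots, len(ages) - 1)
    spl = _pspline_fit(ages, values, n_knots)
    dspl = spl.derivative()
    return EnvCurve(fn=spl, dfn=dspl, support=(float(ages[0]), float(ages[-1])))


# ---------------------------------------------------------------------------
# Coupling covariates into rates
# ---------------------------------------------------------------------------


@dataclass
class RateFunction:
    """A per-lineage rate as a function of age, built from a base rate, a
    sensitivity and a covariate through an exponential or linear link.

    ``clamp_count`` records how often the linear link was clamped at zero.
    """

    base: float
    alpha: float
    link: str
    curve: EnvCurve | None
    clamp_count: int = 0

    def __call__(self, age):
        if self.curve is None or self.alpha == 0.0:
            return np.broadcast_to(self.base, np.shape(age)).copy() if np.ndim(age) else self.base
        e = np.asarray(self.curve(age), dtype=float)
        if self.link == "exponential":
            out = self.base * np.exp(self.alpha * e)
        else:
            out = self.base + self.alpha * e
            n_neg = int(np.sum(np.atleast_1d(out) < 0))
            if n_neg:
                self.clamp_count += n_neg
            out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)


def couple_rate(base: float, alpha: float, link: str, curve: EnvCurve | None) -> RateFunction:
    """Rate(t) = base*exp(alpha*E(t)) (exponential link) or
    max(0, base + alpha*E(t)) (linear link, clamped with a counter)."""
    if link not in ("exponential", "linear"):
        raise DomainError(f"unknown link {link!r}")
    if link == "exponential" and base <= 0:
        raise DomainError("exponential link requires base > 0")
    return RateFunction(base=float(base), alpha=float(alpha), link=link, curve=curve)
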