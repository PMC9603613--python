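"""Grey-system tools: GM(1,1) forecasting and Deng relational analysis.

GM(1,1) models a short positive series x(0) through its first-order
accumulation x(1) (1-AGO).  The grey difference equation

    x(0)(k) + a·z(1)(k) = b,   z(1)(k) = (x(1)(k) + x(1)(k−1)) / 2

is solved for the development coefficient ``a`` and grey input ``b`` by
ordinary least squares; the whitening equation dx(1)/dt + a·x(1) = b then
yields the time response

    x̂(1)(k+1) = (x(0)(1) − b/a)·e^(−a·k) + b/a

and restored values by inverse accumulation (first differences), with
x̂(0)(1) = x(0)(1) by construction.  Model adequacy uses the posterior-error
test: C = S2/S1 (residual std over data std, population form) and the
small-error probability p = P(|ε(k) − ε̄| < 0.6745·S1), graded on the
standard four-level table.

Deng grey relational analysis scores how closely each comparison series
tracks a reference after mean-value normalization:

    ξ(k) = (Δmin + ρ·Δmax) / (Δ(k) + ρ·Δmax),   degree = mean_k ξ(k)

with Δ the absolute normalized deviation, extremes taken over all
comparison series, and resolution coefficient ρ (default 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: (C_max, p_min) per grade 1..3; anything worse is grade 4.
DEFAULT_GM11_THRESHOLDS: tuple[tuple[float, float], ...] = (
    (0.35, 0.95),
    (0.50, 0.80),
    (0.65, 0.70),
)

GM11_GRADE_LABELS = {1: "good", 2: "qualified", 3: "barely qualified", 4: "unqualified"}

# treat |a| below this as the degenerate constant-dynamics branch
_A_TOL = 1e-12


@dataclass(frozen=True)
class GreySeries:
    """An ordered, strictly positive series (e.g. an annual index)."""

    label: str
    values: np.ndarray
    index: tuple[int, ...] | None = None  # e.g. years; consecutive integers

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) < 2:
            raise ValueError(f"{self.label!r}: need a 1-d series of length >= 2")
        if (vals <= 0).any() or not np.isfinite(vals).all():
            raise ValueError(f"{self.label!r}: all values must be finite and > 0")
        if self.index is not None and len(self.index) != len(vals):
            raise ValueError(f"{self.label!r}: index length mismatch")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GM11Fit:
    label: str
    a: float  # development coefficient
    b: float  # grey input
    x0: np.ndarray  # original series
    x1: np.ndarray  # 1-AGO
    z1: np.ndarray  # background (mean) series, length n-1
    fitted_x0: np.ndarray  # restored series x̂(0), fitted_x0[0] == x0[0]
    residuals: np.ndarray  # ε(0)(k) = x0 − x̂(0)
    rel_errors: np.ndarray  # |ε|/x0
    C: float  # posterior error ratio S2/S1
    p: float  # small-error probability
    grade: int  # 1 (best) .. 4
    index: tuple[int, ...] | None = None
    thresholds: tuple[tuple[float, float], ...] = DEFAULT_GM11_THRESHOLDS


@dataclass(frozen=True)
class GreyRelationResult:
    reference: str
    degrees: dict[str, float]
    rho: float
    normalization: str = "mean"


def _posterior_error(x0: np.ndarray, residuals: np.ndarray) -> tuple[float, float]:
    """Posterior error ratio C and small-error probability p (population stds)."""
    s1 = float(np.std(x0))  # population (1/n) form
    if s1 == 0.0:
        return 0.0, 1.0
    s2 = float(np.std(residuals))
    dev = np.abs(residuals - residuals.mean())
    p = float(np.mean(dev < 0.6745 * s1))
    return s2 / s1, p


def gm11_accuracy(
    C: float, p: float, thresholds: tuple[tuple[float, float], ...] = DEFAULT_GM11_THRESHOLDS
) -> int:
    """Grade 1..4 from the posterior-error pair on the standard table."""
    for grade, (c_max, p_min) in enumerate(thresholds, start=1):
        if C <= c_max and p >= p_min:
            return grade
    return len(thresholds) + 1


def _restore(a: float, b: float, x0_first: float, n: int) -> np.ndarray:
    """Restored series x̂(0)(1..n) from the time-response function."""
    k = np.arange(n, dtype=float)
    if abs(a) < _A_TOL:
        # whitening equation degenerates to dx1/dt = b: constant increments
        x1_hat = x0_first + b * k
    else:
        x1_hat = (x0_first - b / a) * np.exp(-a * k) + b / a
    x0_hat = np.empty(n)
    x0_hat[0] = x0_first
    x0_hat[1:] = np.diff(x1_hat)
    return x0_hat


def gm11_fit(
    series: GreySeries,
    thresholds: tuple[tuple[float, float], ...] = DEFAULT_GM11_THRESHOLDS,
) -> GM11Fit:
    """Least-squares GM(1,1) fit with posterior-error diagnostics.

    Requires n ≥ 4 strictly positive values.  ``(a, b)`` is the exact LS
    solution of the grey difference equation; for a constant series this is
    (0, x(0)) and the fit is exact.
    """
    x0 = np.asarray(series.values, dtype=float)
    n = len(x0)
    if n < 4:
        raise ValueError(f"{series.label!r}: GM(1,1) needs n >= 4, got {n}")
    x1 = np.cumsum(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z1, np.ones(n - 1)])
    Yn = x0[1:]
    (a, b), *_ = np.linalg.lstsq(B, Yn, rcond=None)
    if not np.isfinite(a) or not np.isfinite(b):
        raise ValueError(f"{series.label!r}: singular normal equations")
    fitted = _restore(a, b, x0[0], n)
    residuals = x0 - fitted
    rel_errors = np.abs(residuals) / x0
    C, p = _posterior_error(x0, residuals)
    return GM11Fit(
        label=series.label,
        a=float(a),
        b=float(b),
        x0=x0,
        x1=x1,
        z1=z1,
        fitted_x0=fitted,
        residuals=residuals,
        rel_errors=rel_errors,
        C=C,
        p=p,
        grade=gm11_accuracy(C, p, thresholds),
        index=series.index,
        thresholds=thresholds,
    )


def gm11_forecast(
    fit: GM11Fit, horizon: int, method: str = "difference"
) -> tuple[np.ndarray, tuple[int, ...] | None]:
    """Restored forecasts for the ``horizon`` steps after the sample.

    ``method="difference"`` differences the accumulated time response;
    ``method="closed_form"`` uses the equivalent closed form
    x̂(0)(k+1) = (1 − e^a)(x(0)(1) − b/a)e^(−a·k).  The two agree to
    rounding.  Forecast labels continue the fitted series' index
    (..., 2020 → 2021, 2022, ...).
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    n = len(fit.x0)
    a, b, x0_first = fit.a, fit.b, fit.x0[0]
    if abs(a) < _A_TOL:
        values = np.full(horizon, b)
    elif method == "difference":
        full = _restore(a, b, x0_first, n + horizon)
        values = full[n:]
    elif method == "closed_form":
        k = np.arange(n, n + horizon, dtype=float)
        values = (1.0 - math.exp(a)) * (x0_first - b / a) * np.exp(-a * k)
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = None
    if fit.index is not None:
        last = fit.index[-1]
        labels = tuple(last + i for i in range(1, horizon + 1))
    return values, labels


def _mean_normalize(values: np.ndarray) -> np.ndarray:
    return values / values.mean()


def grey_relation(
    reference: GreySeries,
    comparisons: list[GreySeries],
    rho: float = 0.5,
    normalization: str = "mean",
) -> GreyRelationResult:
    """Deng grey relational degree of each comparison series to the reference.

    Degrees lie in (0, 1]; a comparison identical (or, under mean-value
    normalization, proportional) to the reference scores exactly 1.
    """
    if not 0 < rho <= 1:
        raise ValueError(f"resolution coefficient rho must be in (0, 1], got {rho}")
    if normalization != "mean":
        raise ValueError(f"unknown normalization {normalization!r}")
    if not comparisons:
        raise ValueError("need at least one comparison series")
    n = len(reference)
    for s in comparisons:
        if len(s) != n:
            raise ValueError(f"{s.label!r}: length {len(s)} != reference length {n}")
    ref = _mean_normalize(reference.values)
    deltas = {s.label: np.abs(ref - _mean_normalize(s.values)) for s in comparisons}
    all_d = np.concatenate(list(deltas.values()))
    d_min, d_max = float(all_d.min()), float(all_d.max())
    degrees: dict[str, float] = {}
    for label, d in deltas.items():
        if d_max == 0.0:  # every comparison coincides with the reference
            degrees[label] = 1.0
            continue
        xi = (d_min + rho * d_max) / (d + rho * d_max)
        degrees[label] = float(xi.mean())
    return GreyRelationResult(
        reference=reference.label, degrees=degrees, rho=rho, normalization=normalization
    )
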