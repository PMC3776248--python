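"""Bi-Gaussian decomposition of Fp-ratio histograms.

Heterogeneity of the Fp redox ratio within a section is quantified by
fitting the sum of two Gaussian functions to the section's pixel histogram::

    f(x) = a1 * exp(-(x - b1)^2 / (2 c1^2)) + a2 * exp(-(x - b2)^2 / (2 c2^2))

where ``a_i`` is the peak height, ``b_i`` the peak center and ``c_i`` the
width parameter of component ``i``; FWHM_i = 2 sqrt(2 ln 2) c_i.  Wider
components (larger c, FWHM) mean a more heterogeneous redox state; the two
centers locate redox subpopulations (e.g. a more-oxidized subpopulation at
the higher center).

The fit is nonlinear least squares against the binned histogram (bin
centers vs counts), unweighted by default with an optional Poisson
weighting, started from several deterministic quantile-based initial
guesses so results are reproducible without a seed.  Components are
reported ordered by center (``b1 <= b2``, ties broken by width).

``mixture_moments`` is the closed-form bridge between fitted coefficients
and ordinary per-section statistics: interpreting the fitted curve as a
two-component Gaussian mixture with component weights proportional to the
component areas ``a_i * c_i``, it returns the mixture mean and SD of the
underlying pixel distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .indices import Histogram

__all__ = [
    "FWHM_FACTOR",
    "FitError",
    "bi_gaussian",
    "fwhm",
    "mixture_moments",
    "sample_mixture",
    "BiGaussianResults",
    "BiGaussianModel",
    "fit_bi_gaussian",
    "fits_to_frame",
]

#: FWHM of a Gaussian with width parameter c is FWHM_FACTOR * c.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Default box bounds for the optimizer: heights >= 0, centers in the ratio
#: support [0, 1], widths in [1e-4, 0.5].
DEFAULT_BOUNDS = {"a": (0.0, np.inf), "b": (0.0, 1.0), "c": (1e-4, 0.5)}


class FitError(RuntimeError):
    """Raised when the histogram cannot be fitted."""


def bi_gaussian(
    x: np.ndarray | float,
    a1: float, a2: float, b1: float, b2: float, c1: float, c2: float,
) -> np.ndarray | float:
    """Sum of two Gaussian functions evaluated at ``x``."""
    if c1 <= 0 or c2 <= 0:
        raise ValueError("width parameters c1, c2 must be positive")
    x = np.asarray(x, dtype=np.float64)
    val = a1 * np.exp(-((x - b1) ** 2) / (2.0 * c1 ** 2)) + a2 * np.exp(
        -((x - b2) ** 2) / (2.0 * c2 ** 2)
    )
    return float(val) if val.ndim == 0 else val


def fwhm(c: float) -> float:
    """Full width at half maximum of a Gaussian with width parameter ``c``."""
    if c <= 0:
        raise ValueError(f"width parameter must be positive, got {c}")
    return FWHM_FACTOR * c


def mixture_moments(
    a1: float, a2: float, b1: float, b2: float, c1: float, c2: float,
) -> tuple[float, float]:
    """Mean and SD of the two-component Gaussian mixture behind a fitted curve.

    Component weights are the normalized component areas, w_i = a_i c_i /
    (a1 c1 + a2 c2).  Then

        mean = w1 b1 + w2 b2
        sd   = sqrt( w1 (c1^2 + b1^2) + w2 (c2^2 + b2^2) - mean^2 )
    """
    if c1 < 0 or c2 < 0 or a1 < 0 or a2 < 0:
        raise ValueError("heights and widths must be non-negative")
    area1, area2 = a1 * c1, a2 * c2
    total = area1 + area2
    if total <= 0:
        raise ValueError("total component area a1*c1 + a2*c2 must be positive")
    w1, w2 = area1 / total, area2 / total
    mean = w1 * b1 + w2 * b2
    second = w1 * (c1 ** 2 + b1 ** 2) + w2 * (c2 ** 2 + b2 ** 2)
    var = max(second - mean ** 2, 0.0)
    return mean, math.sqrt(var)


def sample_mixture(
    rng: np.random.Generator,
    n: int,
    a1: float, a2: float, b1: float, b2: float, c1: float, c2: float,
) -> np.ndarray:
    """Draw ``n`` values from the mixture implied by bi-Gaussian coefficients.

    Monte-Carlo companion of :func:`mixture_moments`; used as an independent
    cross-check of the closed-form moments and by the phantom generator.
    """
    area1, area2 = a1 * c1, a2 * c2
    total = area1 + area2
    if total <= 0:
        raise ValueError("total component area must be positive")
    n2 = rng.binomial(n, area2 / total)
    out = np.empty(n)
    out[: n - n2] = rng.normal(b1, c1, size=n - n2)
    out[n - n2:] = rng.normal(b2, c2, size=n2)
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass
class BiGaussianResults:
    """Fitted bi-Gaussian coefficients and derived quantities.

    ``height_ratio`` is a2/a1 (the ratio of peak heights, the quantity
    conventionally tabulated under the name a2/a1); ``area_ratio`` is
    (a2 c2)/(a1 c1), the ratio of component areas.  Both are reported
    because tabulations are ambiguous between the two.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    sse: float
    converged: bool
    n_pixels: int
    n_bins: int
    degenerate: bool = False
    n_starts_converged: int = 0

    def __post_init__(self) -> None:
        # ordering convention: component 1 is the lower-center component
        if (self.b1, self.c1) > (self.b2, self.c2):
            self.a1, self.a2 = self.a2, self.a1
            self.b1, self.b2 = self.b2, self.b1
            self.c1, self.c2 = self.c2, self.c1

    @property
    def params(self) -> tuple[float, float, float, float, float, float]:
        return (self.a1, self.a2, self.b1, self.b2, self.c1, self.c2)

    @property
    def fwhm1(self) -> float:
        return fwhm(self.c1)

    @property
    def fwhm2(self) -> float:
        return fwhm(self.c2)

    @property
    def height_ratio(self) -> float:
        return self.a2 / self.a1 if self.a1 > 0 else float("inf")

    @property
    def area_ratio(self) -> float:
        return (self.a2 * self.c2) / (self.a1 * self.c1) if self.a1 * self.c1 > 0 else float("inf")

    def mixture_moments(self) -> tuple[float, float]:
        return mixture_moments(*self.params)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return bi_gaussian(x, *self.params)

    def to_record(self) -> dict:
        mean, sd = self.mixture_moments()
        return {
            "a1": self.a1, "a2": self.a2,
            "b1": self.b1, "b2": self.b2,
            "c1": self.c1, "c2": self.c2,
            "fwhm1": self.fwhm1, "fwhm2": self.fwhm2,
            "a2_over_a1": self.height_ratio,
            "area_ratio": self.area_ratio,
            "mixture_mean": mean, "mixture_sd": sd,
            "sse": self.sse, "converged": self.converged,
            "degenerate": self.degenerate, "n_pixels": self.n_pixels,
        }

    def summary(self) -> str:
        mean, sd = self.mixture_moments()
        lines = [
            "Bi-Gaussian histogram fit",
            "=" * 41,
            f"{'component':<12}{'center b':>9}{'width c':>9}{'height a':>10}",
            f"{'1 (lower)':<12}{self.b1:>9.4f}{self.c1:>9.4f}{self.a1:>10.2f}",
            f"{'2 (upper)':<12}{self.b2:>9.4f}{self.c2:>9.4f}{self.a2:>10.2f}",
            "-" * 41,
            f"FWHM1 = {self.fwhm1:.4f}   FWHM2 = {self.fwhm2:.4f}",
            f"a2/a1 (heights) = {self.height_ratio:.3f}   area ratio = {self.area_ratio:.3f}",
            f"mixture mean = {mean:.4f}   mixture SD = {sd:.4f}",
            f"SSE = {self.sse:.4g}   converged = {self.converged}"
            + ("   [degenerate components]" if self.degenerate else ""),
        ]
        return "\n".join(lines)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, x)


class BiGaussianModel:
    """Least-squares bi-Gaussian model for one histogram.

    Parameters
    ----------
    histogram
        A :class:`~redoxscan.indices.Histogram` (or any object with
        ``bin_centers``, ``counts`` and ``n_pixels``).
    weighting
        ``"none"`` (default, unweighted least squares) or ``"poisson"``
        (weights 1/sqrt(max(count, 1))).
    """

    def __init__(self, histogram: Histogram, weighting: str = "none"):
        if weighting not in ("none", "poisson"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.histogram = histogram
        self.weighting = weighting
        self.x = np.asarray(histogram.bin_centers, dtype=np.float64)
        self.y = np.asarray(histogram.counts, dtype=np.float64)

    def _starts(self, n_starts: int) -> list[np.ndarray]:
        """Deterministic quantile-based initial guesses."""
        occupied = self.y > 0
        x, y = self.x[occupied], self.y[occupied]
        mu = float(np.average(x, weights=y))
        sd = float(np.sqrt(np.average((x - mu) ** 2, weights=y)))
        sd = min(max(sd, 2e-4), 0.49)
        peak = float(y.max())
        qpairs = [(0.25, 0.75), (0.15, 0.85), (0.35, 0.65), (0.10, 0.60), (0.40, 0.90),
                  (0.30, 0.80), (0.20, 0.50)]
        starts = []
        for qlo, qhi in qpairs[: max(n_starts - 1, 1)]:
            blo, bhi = _weighted_quantile(x, y, np.array([qlo, qhi]))
            starts.append(np.array([peak, 0.6 * peak, blo, bhi,
                                    max(sd / 2, 2e-4), min(max(sd, 2e-4), 0.49)]))
        # narrow/wide pair sharing the bulk center: catches heavily
        # overlapped components that quantile splitting misses
        starts.append(np.array([peak, 0.5 * peak, mu, min(mu + sd / 2, 1.0),
                                max(sd / 3, 2e-4), min(max(1.5 * sd, 2e-4), 0.49)]))
        return starts[:n_starts] if n_starts <= len(starts) else starts

    def fit(self, n_starts: int = 5, maxfev: int = 20000) -> BiGaussianResults:
        """Fit from ``n_starts`` deterministic starts; return the best-SSE solution."""
        occupied = int((self.y > 0).sum())
        if occupied < 6:
            raise FitError(
                f"{occupied} occupied bins < 6 free parameters; cannot fit"
            )
        sigma = None
        if self.weighting == "poisson":
            sigma = np.sqrt(np.maximum(self.y, 1.0))

        def f(x, a1, a2, b1, b2, c1, c2):
            return bi_gaussian(x, a1, a2, b1, b2, c1, c2)

        lo = [DEFAULT_BOUNDS["a"][0]] * 2 + [DEFAULT_BOUNDS["b"][0]] * 2 + [DEFAULT_BOUNDS["c"][0]] * 2
        hi = [DEFAULT_BOUNDS["a"][1]] * 2 + [DEFAULT_BOUNDS["b"][1]] * 2 + [DEFAULT_BOUNDS["c"][1]] * 2

        best: tuple[float, np.ndarray] | None = None
        n_ok = 0
        failures: list[str] = []
        for p0 in self._starts(n_starts):
            p0 = np.clip(p0, lo, hi)
            try:
                popt, _ = curve_fit(
                    f, self.x, self.y, p0=p0, sigma=sigma,
                    bounds=(lo, hi), maxfev=maxfev, method="trf",
                )
            except (RuntimeError, ValueError) as exc:  # no convergence from this start
                failures.append(str(exc))
                continue
            resid = self.y - f(self.x, *popt)
            sse = float(resid @ resid)
            n_ok += 1
            if best is None or sse < best[0]:
                best = (sse, popt)
        if best is None:
            raise FitError(
                f"no start converged ({len(failures)} failures); first: {failures[0]}"
            )
        sse, popt = best
        a1, a2, b1, b2, c1, c2 = (float(v) for v in popt)
        # degenerate when one component is negligible or the two coincide
        area1, area2 = a1 * c1, a2 * c2
        tot = area1 + area2
        degenerate = tot <= 0 or min(area1, area2) / tot < 0.01 or abs(b1 - b2) < 1e-3
        return BiGaussianResults(
            a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2,
            sse=sse, converged=True,
            n_pixels=int(self.histogram.n_pixels),
            n_bins=int(self.x.size),
            degenerate=bool(degenerate),
            n_starts_converged=n_ok,
        )


def fit_bi_gaussian(
    hist: Histogram,
    *,
    weighting: str = "none",
    n_starts: int = 5,
) -> BiGaussianResults:
    """Convenience wrapper: build a :class:`BiGaussianModel` and fit it."""
    return BiGaussianModel(hist, weighting=weighting).fit(n_starts=n_starts)


_FIT_COLUMNS = [
    "animal_id", "group", "depth_um",
    "a1", "a2", "b1", "b2", "c1", "c2",
    "fwhm1", "fwhm2", "a2_over_a1", "area_ratio",
    "mixture_mean", "mixture_sd", "sse", "converged", "degenerate", "n_pixels",
]


def fits_to_frame(
    fits: Sequence[BiGaussianResults],
    meta: Sequence[dict] | None = None,
) -> pd.DataFrame:
    """Flatten per-section fits (plus section metadata) to a DataFrame."""
    rows = []
    for i, fit in enumerate(fits):
        rec = dict(meta[i]) if meta is not None else {}
        rec.update(fit.to_record())
        rows.append(rec)
    frame = pd.DataFrame(rows)
    cols = [c for c in _FIT_COLUMNS if c in frame.columns]
    return frame[cols]
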