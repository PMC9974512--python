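"""Bayes factor functions: curves over standardized effect size.

A Bayes factor function (BFF) maps each standardized effect size omega to
the Bayes factor obtained when the alternative prior is centered (by mode
matching) on that effect.  Reading a BFF answers, in one curve, "how much
support do the data give to alternatives of each plausible magnitude?":
its maximum is the strongest support any prior in the family can claim,
and its crossings of 1 delimit the effect sizes the data speak for or
against.

The public surface follows the model/results convention: build a
:class:`BayesFactorFunction` from a :class:`~bff.bayes_factors.TestReport`,
call :meth:`~BayesFactorFunction.fit`, and read the returned
:class:`BFFResults` (``max_bf10``, ``argmax_omega``, ``crossings``,
``summary()``, ``plot()``).  The module-level functions :func:`build_bff`,
:func:`summarize`, and :func:`bf_at_omega` expose the same computations
functionally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .bayes_factors import TestReport, log_bf10
from .effect_size import _tau2, categorize_effect

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_THRESHOLDS",
    "BFFPoint",
    "BFFCurve",
    "BFFSummary",
    "build_bff",
    "summarize",
    "bf_at_omega",
    "BayesFactorFunction",
    "BFFResults",
]

#: omega in [0.01, 1.0] with step 0.005.  Standardized effects above 1 are
#: rare on the Cohen scale; omega = 0 is excluded because the prior
#: degenerates there (the Bayes factor tends to 1 in the limit).
DEFAULT_GRID = (0.01, 1.0, 0.005)

DEFAULT_THRESHOLDS = (1.0, 2.0, 5.0, 10.0)

_XTOL = 1e-6  # refinement tolerance on omega for argmax and roots


@dataclass(frozen=True)
class BFFPoint:
    """A single (omega, tau2, BF10) evaluation of a Bayes factor function."""

    omega: float
    tau2: float
    bf10: float
    log_bf10: float


def _grid_array(grid: tuple[float, float, float]) -> np.ndarray:
    omega_min, omega_max, step = grid
    if not (0 < omega_min < omega_max and step > 0):
        raise ValueError(f"invalid grid {grid}: need 0 < omega_min < omega_max, step > 0")
    n = int(round((omega_max - omega_min) / step))
    omegas = omega_min + step * np.arange(n + 1)
    return omegas[omegas <= omega_max + 1e-12]


@dataclass
class BFFCurve:
    """An ordered sequence of BFF points plus the callable that generated it.

    ``omega`` is strictly increasing; ``logbf_fn`` evaluates log BF10 at any
    omega (used for off-grid refinement of the maximum and of threshold
    crossings), so curve values are a pointwise function of omega and do not
    depend on the grid step.
    """

    omega: np.ndarray
    tau2: np.ndarray
    log_bf10: np.ndarray
    source: object = None
    grid: tuple[float, float, float] | None = None
    logbf_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.omega) == 0:
            raise ValueError("curve must contain at least one point")
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega grid must be strictly increasing")

    @property
    def bf10(self) -> np.ndarray:
        return np.exp(self.log_bf10)

    @property
    def points(self) -> list[BFFPoint]:
        return [
            BFFPoint(float(w), float(t), float(math.exp(lb)), float(lb))
            for w, t, lb in zip(self.omega, self.tau2, self.log_bf10)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "omega": self.omega,
                "tau2": self.tau2,
                "bf10": self.bf10,
                "log_bf10": self.log_bf10,
            }
        )

    def to_csv(self, path) -> None:
        """Write ``omega,tau2,bf10,log_bf10`` with 17 significant digits.

        17 digits round-trip IEEE doubles exactly, so a re-imported curve
        reproduces the Bayes factors bit for bit.
        """
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "BFFCurve":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            omega=df["omega"].to_numpy(),
            tau2=df["tau2"].to_numpy(),
            log_bf10=df["log_bf10"].to_numpy(),
        )


@dataclass(frozen=True)
class BFFSummary:
    """Maximum, argmax, and threshold crossings of a Bayes factor function."""

    max_bf10: float
    argmax_omega: float
    tau2_at_argmax: float
    crossings: dict[float, tuple[float, ...]]

    def support_interval(self, threshold: float) -> list[tuple[float, float]]:
        """Omega intervals over which BF10 >= threshold, within the grid range.

        Assembled from the recorded roots of ``BF10 = threshold``; a curve
        that rises above the threshold and falls back yields one interval.
        """
        if threshold not in self.crossings:
            raise KeyError(f"threshold {threshold} was not summarized")
        roots = self.crossings[threshold]
        if self.max_bf10 < threshold:
            return []
        if not roots:
            return []
        # pair roots into [up, down] intervals around the maximum
        edges = list(roots)
        intervals = []
        if self.argmax_omega < edges[0]:
            intervals.append((-math.inf, edges.pop(0)))
        while len(edges) >= 2:
            intervals.append((edges.pop(0), edges.pop(0)))
        if edges:
            intervals.append((edges.pop(0), math.inf))
        return intervals


def build_bff(report: TestReport, grid: tuple[float, float, float] = DEFAULT_GRID) -> BFFCurve:
    """Evaluate the BFF of one reported statistic over an effect-size grid.

    At each omega, tau2 follows the report design's mode-matching rule and
    the Bayes factor uses the family's closed form.
    """
    omegas = _grid_array(grid)
    tau2 = _tau2(report.design, omegas, report.n, report.df1)

    def logbf_fn(w):
        return log_bf10(report, _tau2(report.design, w, report.n, report.df1))

    return BFFCurve(
        omega=omegas,
        tau2=np.atleast_1d(tau2),
        log_bf10=np.atleast_1d(logbf_fn(omegas)),
        source=report,
        grid=grid,
        logbf_fn=logbf_fn,
    )


def bf_at_omega(report: TestReport, omega: float) -> BFFPoint:
    """Single-point BFF evaluation: tau2 mapping composed with the closed form."""
    if not omega > 0:
        raise ValueError("omega must be positive")
    tau2 = float(_tau2(report.design, omega, report.n, report.df1))
    lb = float(log_bf10(report, tau2))
    return BFFPoint(float(omega), tau2, math.exp(lb), lb)


def _refine_argmax(curve: BFFCurve) -> tuple[float, float]:
    """Off-grid maximum of log BF10 within the bracketing grid cell."""
    lb = curve.log_bf10
    i = int(np.argmax(lb))
    if curve.logbf_fn is None or len(curve.omega) < 3:
        return float(curve.omega[i]), float(lb[i])
    lo = float(curve.omega[max(i - 1, 0)])
    hi = float(curve.omega[min(i + 1, len(curve.omega) - 1)])
    res = optimize.minimize_scalar(
        lambda w: -float(curve.logbf_fn(w)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _XTOL},
    )
    # never report worse than the best grid point
    if -res.fun >= lb[i]:
        return float(res.x), float(-res.fun)
    return float(curve.omega[i]), float(lb[i])


def _find_crossings(curve: BFFCurve, threshold: float) -> tuple[float, ...]:
    """All roots of BF10(omega) = threshold, in increasing omega."""
    target = math.log(threshold)
    g = curve.log_bf10 - target
    roots: list[float] = []
    for i in range(len(g) - 1):
        if g[i] == 0.0:
            roots.append(float(curve.omega[i]))
        elif g[i] * g[i + 1] < 0:
            if curve.logbf_fn is None:
                # linear interpolation fallback for imported curves
                w = curve.omega[i] + (curve.omega[i + 1] - curve.omega[i]) * (
                    -g[i] / (g[i + 1] - g[i])
                )
                roots.append(float(w))
            else:
                roots.append(
                    float(
                        optimize.brentq(
                            lambda w: float(curve.logbf_fn(w)) - target,
                            float(curve.omega[i]),
                            float(curve.omega[i + 1]),
                            xtol=_XTOL,
                        )
                    )
                )
    if g[-1] == 0.0:
        roots.append(float(curve.omega[-1]))
    return tuple(roots)


def summarize(
    curve: BFFCurve, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> BFFSummary:
    """Maximum (refined off-grid) and threshold crossings of a BFF curve.

    The argmax is refined within its bracketing grid cell by bounded
    derivative-free minimization of -log BF10; each threshold's roots are
    located by bracketed root finding on log BF10 minus the log threshold.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    argmax_omega, log_max = _refine_argmax(curve)
    tau2_at = (
        float(np.interp(argmax_omega, curve.omega, curve.tau2))
        if np.all(np.isfinite(curve.tau2))
        else float("nan")
    )
    if curve.source is not None and hasattr(curve.source, "design"):
        tau2_at = float(
            _tau2(curve.source.design, argmax_omega, curve.source.n, curve.source.df1)
        )
    crossings = {t: _find_crossings(curve, t) for t in thresholds}
    return BFFSummary(
        max_bf10=math.exp(log_max),
        argmax_omega=argmax_omega,
        tau2_at_argmax=tau2_at,
        crossings=crossings,
    )


# ---------------------------------------------------------------------------
# model / results surface


class BayesFactorFunction:
    """Model object for the BFF of a single reported test statistic.

    Parameters
    ----------
    report : TestReport
        The observed statistic with its degrees of freedom, design, and
        sample size(s).
    grid : (omega_min, omega_max, step)
        Effect-size grid over which the curve is evaluated.

    Examples
    --------
    >>> from bff import BayesFactorFunction, TestReport
    >>> model = BayesFactorFunction(TestReport("z", 2.0, n=100))
    >>> res = model.fit()
    >>> round(res.max_bf10, 2)
    2.9
    """

    def __init__(self, report: TestReport, grid: tuple[float, float, float] = DEFAULT_GRID):
        self.report = report
        self.grid = grid

    @classmethod
    def from_statistic(
        cls,
        family: str,
        statistic: float,
        *,
        n,
        df1: int = 1,
        df2: int | None = None,
        design: str | None = None,
        label: str = "",
        grid: tuple[float, float, float] = DEFAULT_GRID,
    ) -> "BayesFactorFunction":
        report = TestReport(
            family=family, statistic=statistic, n=n, df1=df1, df2=df2,
            design=design, label=label,
        )
        return cls(report, grid=grid)

    def fit(self, thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> "BFFResults":
        """Evaluate the curve and summarize it."""
        curve = build_bff(self.report, self.grid)
        return BFFResults(self, curve, summarize(curve, thresholds))

    def bf_at(self, omega: float) -> BFFPoint:
        return bf_at_omega(self.report, omega)


class BFFResults:
    """Fitted Bayes factor function: curve data plus its summary."""

    def __init__(self, model, curve: BFFCurve, summary: BFFSummary):
        self.model = model
        self.curve = curve
        self._summary = summary

    # -- headline quantities -------------------------------------------------
    @property
    def max_bf10(self) -> float:
        """Largest Bayes factor attainable within the prior family."""
        return self._summary.max_bf10

    @property
    def argmax_omega(self) -> float:
        """Standardized effect size whose matched prior attains the maximum."""
        return self._summary.argmax_omega

    @property
    def tau2_at_argmax(self) -> float:
        return self._summary.tau2_at_argmax

    @property
    def crossings(self) -> dict[float, tuple[float, ...]]:
        """Roots of BF10 = threshold for each summarized threshold."""
        return self._summary.crossings

    def support_interval(self, threshold: float) -> list[tuple[float, float]]:
        return self._summary.support_interval(threshold)

    # -- reporting -----------------------------------------------------------
    def _describe_source(self) -> list[tuple[str, str]]:
        rep = getattr(self.model, "report", None)
        rows: list[tuple[str, str]] = []
        if rep is not None:
            df = {"z": "", "t": f", df={rep.df2}", "chisq": f", df={rep.df1}",
                  "f": f", df=({rep.df1}, {rep.df2})"}[rep.family]
            rows.append(("Statistic:", f"{rep.family} = {rep.statistic:g}{df}"))
            rows.append(("Design:", f"{rep.design}, n = {rep.n}"))
            if rep.label:
                rows.append(("Label:", rep.label))
        return rows

    def summary(self) -> str:
        """Human-readable summary table of the fitted curve."""
        g = self.curve.grid or (self.curve.omega[0], self.curve.omega[-1], float("nan"))
        cat = categorize_effect(self.argmax_omega).name
        lines = ["Bayes Factor Function Results", "=" * 46]
        rows = self._describe_source()
        rows += [
            ("Grid:", f"omega in [{g[0]:g}, {g[1]:g}], step {g[2]:g}"),
            ("Max BF10:", f"{self.max_bf10:.2f}  ({self.max_bf10:.2f}:1 odds for H1)"),
            ("At omega:", f"{self.argmax_omega:.3f}  ({cat} effect)"),
            ("Implied tau^2:", f"{self.tau2_at_argmax:.3f}"),
        ]
        for key, val in rows:
            lines.append(f"{key:<16}{val}")
        lines.append("-" * 46)
        for t, roots in self.crossings.items():
            if roots:
                where = ", ".join(f"{r:.3f}" for r in roots)
                lines.append(f"BF10 = {t:g} at omega = {where}")
            else:
                lines.append(f"BF10 = {t:g} is never crossed on the grid")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.curve.to_csv(path)

    def to_json(self, path=None):
        """Curve plus summary as JSON (string if ``path`` is None)."""
        payload = {
            "curve": {
                "omega": [repr(x) for x in map(float, self.curve.omega)],
                "tau2": [repr(x) for x in map(float, self.curve.tau2)],
                "bf10": [repr(x) for x in map(float, self.curve.bf10)],
                "log_bf10": [repr(x) for x in map(float, self.curve.log_bf10)],
            },
            "max_bf10": self.max_bf10,
            "argmax_omega": self.argmax_omega,
            "tau2_at_argmax": self.tau2_at_argmax,
            "crossings": {f"{t:g}": list(r) for t, r in self.crossings.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def plot(self, ax=None, log_scale: bool = True):
        """Plot BF10 against omega (vertical axis on the log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.omega, self.curve.bf10, lw=1.5)
        ax.axhline(1.0, color="gray", lw=0.8, ls="--")
        ax.axvline(self.argmax_omega, color="gray", lw=0.8, ls=":")
        if log_scale:
            ax.set_yscale("log")
        ax.set_xlabel("standardized effect size $\\omega$")
        ax.set_ylabel("$BF_{10}$")
        return ax

    def __repr__(self) -> str:
        return (
            f"<BFFResults max_bf10={self.max_bf10:.4g} "
            f"argmax_omega={self.argmax_omega:.4g}>"
        )
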