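"""Nonlocal alternative priors on noncentrality parameters.

Two prior families are used to define alternative hypotheses for standard
test statistics.  For signed noncentrality parameters (z and t tests) the
alternative prior is the *normal-moment* distribution J(mu0, tau2), a
quadratically tilted normal whose density vanishes at its center mu0 and
peaks at mu0 +/- sqrt(2)*tau.  For nonnegative noncentrality parameters
(chi-squared and F tests) it is a gamma distribution with shape k/2 + 1 and
rate 1/(2*tau2), where k is the numerator degrees of freedom; the shape
exceeds 1, so the density vanishes at the origin.

Both families are therefore *nonlocal*: they place zero density exactly at
the null value of the noncentrality parameter.  This is the property that
lets Bayes factors built on them accumulate evidence in favor of true null
hypotheses, not only true alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NormalMomentPrior",
    "GammaNCPrior",
    "nmoment_pdf",
    "nmoment_logpdf",
    "nmoment_modes",
    "gammanc_pdf",
    "gammanc_logpdf",
    "gammanc_cv",
]


@dataclass(frozen=True)
class NormalMomentPrior:
    """Normal-moment distribution J(mu0, tau2).

    Density ``(x - mu0)^2 / (sqrt(2*pi) * tau^3) * exp(-(x - mu0)^2 / (2*tau2))``.

    Parameters
    ----------
    mu0 : float
        Location; the density is exactly zero here.
    tau2 : float
        Rate hyperparameter, strictly positive.  ``tau = sqrt(tau2)``.
    """

    mu0: float
    tau2: float

    def __post_init__(self) -> None:
        if not (self.tau2 > 0 and math.isfinite(self.tau2)):
            raise ValueError(f"tau2 must be a positive finite number, got {self.tau2}")

    @property
    def tau(self) -> float:
        return math.sqrt(self.tau2)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def logpdf(self, x):
        # log of the tilted-normal density; -inf at x == mu0.
        x = np.asarray(x, dtype=float)
        d2 = np.square(x - self.mu0)
        with np.errstate(divide="ignore"):
            out = (
                np.log(d2)
                - 0.5 * math.log(2.0 * math.pi)
                - 1.5 * math.log(self.tau2)
                - d2 / (2.0 * self.tau2)
            )
        return out if out.ndim else float(out)

    def modes(self) -> tuple[float, float]:
        """The two maxima, at ``mu0 -/+ sqrt(2)*tau``."""
        d = math.sqrt(2.0) * self.tau
        return (self.mu0 - d, self.mu0 + d)

    @property
    def var(self) -> float:
        # second central moment of J(mu0, tau2) is 3*tau2
        return 3.0 * self.tau2

    def rvs(self, size: int, rng: np.random.Generator):
        """Draws via mu0 + tau*s*sqrt(W), W ~ chi2(3), s a random sign.

        |X - mu0|/tau has density 2*y^2*phi(y) on y > 0, the square root of a
        chi-squared(3) variate; symmetrizing the sign gives the J density.
        """
        w = rng.chisquare(3, size=size)
        s = rng.choice([-1.0, 1.0], size=size)
        return self.mu0 + self.tau * s * np.sqrt(w)


@dataclass(frozen=True)
class GammaNCPrior:
    """Gamma prior on a nonnegative noncentrality parameter.

    Shape ``k/2 + 1`` and rate ``1/(2*tau2)``; equivalently a scaled
    chi-squared variable on k + 2 degrees of freedom.  Because the shape
    exceeds 1 the density is zero at the origin (nonlocal).  Its mode is
    ``k*tau2`` and its coefficient of variation ``sqrt(2/(k+2))`` does not
    depend on tau2.
    """

    k: int
    tau2: float

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if not (self.tau2 > 0 and math.isfinite(self.tau2)):
            raise ValueError(f"tau2 must be a positive finite number, got {self.tau2}")

    @property
    def shape(self) -> float:
        return self.k / 2.0 + 1.0

    @property
    def rate(self) -> float:
        return 1.0 / (2.0 * self.tau2)

    @property
    def scale(self) -> float:
        return 2.0 * self.tau2

    @property
    def mode(self) -> float:
        # (shape - 1) / rate = (k/2) * 2*tau2
        return self.k * self.tau2

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale

    def pdf(self, lam):
        lam = np.asarray(lam, dtype=float)
        out = np.where(lam < 0, 0.0, stats.gamma.pdf(np.maximum(lam, 0.0), a=self.shape, scale=self.scale))
        return out if out.ndim else float(out)

    def logpdf(self, lam):
        lam = np.asarray(lam, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(
                lam < 0,
                -np.inf,
                stats.gamma.logpdf(np.maximum(lam, 0.0), a=self.shape, scale=self.scale),
            )
        return out if out.ndim else float(out)

    def cv(self) -> float:
        return gammanc_cv(self.k)

    def rvs(self, size: int, rng: np.random.Generator):
        return rng.gamma(self.shape, scale=self.scale, size=size)


def nmoment_pdf(x, prior: NormalMomentPrior):
    """Normal-moment density at ``x``; zero iff ``x == prior.mu0``."""
    return prior.pdf(x)


def nmoment_logpdf(x, prior: NormalMomentPrior):
    return prior.logpdf(x)


def nmoment_modes(prior: NormalMomentPrior) -> tuple[float, float]:
    """The two modes ``mu0 -/+ sqrt(2)*tau`` of the normal-moment prior."""
    return prior.modes()


def gammanc_pdf(lam, prior: GammaNCPrior):
    """Gamma prior density at ``lam``; zero for ``lam <= 0``."""
    return prior.pdf(lam)


def gammanc_logpdf(lam, prior: GammaNCPrior):
    return prior.logpdf(lam)


def gammanc_cv(k: int) -> float:
    """Coefficient of variation sqrt(2/(k+2)) of the gamma noncentrality prior.

    Depends only on the numerator degrees of freedom k, never on tau2.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be a positive integer, got {k}")
    return math.sqrt(2.0 / (k + 2.0))
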