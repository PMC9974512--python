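"""Mapping standardized effect sizes to prior hyperparameters.

A Bayes factor function varies the alternative prior over a grid of
standardized effect sizes omega.  Each test design relates omega to the
noncentrality parameter lambda of its statistic; the prior hyperparameter
tau2 is then chosen by *mode matching*: tau2 is the value that puts the
mode(s) of the noncentrality prior exactly at the lambda implied by omega.

Default mappings by design (n is the total sample size, k the dimension of
the tested constraint, omega-tilde the root mean square effect size):

====================  =======================  ==========================
design                tau2                     noncentrality lambda
====================  =======================  ==========================
one_sample (z/t)      n*omega^2/2              sqrt(n)*omega
two_sample (z/t)      n1*n2*omega^2/            sqrt(n1*n2/(n1+n2))*omega
                      (2*(n1+n2))
multinomial_poisson   n*omega_t^2              n*k*omega_t^2
likelihood_ratio      n*omega_t^2              n*k*omega_t^2
linear_model (F)      n*omega_t^2/2            n*k*omega_t^2/2
====================  =======================  ==========================

The chi-squared designs (multinomial/Poisson and likelihood-ratio) use
tau2 = n*omega_t^2 while the linear-model F design uses n*omega_t^2/2, even
though the statistics are asymptotically related; the mappings are applied
exactly as tabulated, and users mixing the two designs on one omega axis
should be aware of the factor-of-two difference.

For multi-degree-of-freedom tests the effect is a vector; tau2 depends on
it only through the inner product omega'omega, so vectors are collapsed to
the scalar root mean square effect size (RMSES) before mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DESIGNS",
    "ZT_DESIGNS",
    "CHISQ_DESIGNS",
    "F_DESIGNS",
    "EffectSpec",
    "EffectCategory",
    "EFFECT_CATEGORIES",
    "tau2_from_omega",
    "noncentrality_from_omega",
    "rmses",
    "categorize_effect",
]

ZT_DESIGNS = ("one_sample", "two_sample")
CHISQ_DESIGNS = ("multinomial_poisson", "likelihood_ratio")
F_DESIGNS = ("linear_model",)
DESIGNS = ZT_DESIGNS + CHISQ_DESIGNS + F_DESIGNS


def rmses(omega_vector: Sequence[float]) -> float:
    """Root mean square effect size, sqrt(mean(omega_i^2)).

    Invariant under permutation and sign flips of the components; equals the
    common value when all components are equal in magnitude.
    """
    v = np.asarray(omega_vector, dtype=float)
    if v.size == 0:
        raise ValueError("omega_vector must be nonempty")
    return float(np.sqrt(np.mean(np.square(v))))


@dataclass(frozen=True)
class EffectSpec:
    """A design plus a standardized effect size (scalar or vector).

    Parameters
    ----------
    design : str
        One of ``DESIGNS``.
    n : int or (int, int)
        Total sample size; two-sample designs take the ``(n1, n2)`` pair.
    k : int
        Dimension of the tested constraint (numerator degrees of freedom);
        1 for z/t designs.
    omega : float, optional
        Scalar standardized effect (or RMSES for multi-df designs).
    omega_vector : sequence of float, optional
        Per-component standardized effects; collapsed to RMSES.
    """

    design: str
    n: int | tuple[int, int]
    k: int = 1
    omega: float | None = None
    omega_vector: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if self.design == "two_sample":
            if not (isinstance(self.n, tuple) and len(self.n) == 2):
                raise ValueError("two_sample design requires n=(n1, n2)")
            if not all(ni > 0 for ni in self.n):
                raise ValueError("sample sizes must be positive")
        else:
            if isinstance(self.n, tuple):
                raise ValueError(f"{self.design} design takes a single total sample size")
            if not self.n > 0:
                raise ValueError("sample size must be positive")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.design in ZT_DESIGNS and self.k != 1:
            raise ValueError("z/t designs have k=1")
        if self.omega is None and self.omega_vector is None:
            raise ValueError("provide omega or omega_vector")
        if self.omega is not None and self.omega_vector is not None:
            raise ValueError("provide omega or omega_vector, not both")

    @property
    def omega_tilde(self) -> float:
        """The scalar effect used for mapping: omega, or the RMSES of the vector."""
        if self.omega is not None:
            return float(self.omega)
        return rmses(self.omega_vector)


def _tau2(design: str, omega, n, k: int):
    """Vectorized tau2 mapping; ``omega`` may be an array."""
    w2 = np.square(np.asarray(omega, dtype=float))
    if design == "one_sample":
        out = n * w2 / 2.0
    elif design == "two_sample":
        n1, n2 = n
        out = n1 * n2 * w2 / (2.0 * (n1 + n2))
    elif design in CHISQ_DESIGNS:
        out = n * w2
    elif design in F_DESIGNS:
        out = n * w2 / 2.0
    else:  # pragma: no cover - guarded by EffectSpec
        raise ValueError(f"unknown design {design!r}")
    return out if np.ndim(out) else float(out)


def _noncentrality(design: str, omega, n, k: int):
    """Vectorized lambda mapping; the mode of the implied noncentrality prior."""
    omega = np.asarray(omega, dtype=float)
    if design == "one_sample":
        out = math.sqrt(n) * omega
    elif design == "two_sample":
        n1, n2 = n
        out = math.sqrt(n1 * n2 / (n1 + n2)) * omega
    elif design in CHISQ_DESIGNS:
        out = n * k * np.square(omega)
    elif design in F_DESIGNS:
        out = n * k * np.square(omega) / 2.0
    else:  # pragma: no cover
        raise ValueError(f"unknown design {design!r}")
    return out if np.ndim(out) else float(out)


def tau2_from_omega(spec: EffectSpec) -> float:
    """Prior hyperparameter tau2 implied by the spec's design and effect size.

    Chosen so the mode of the noncentrality prior (normal-moment for z/t
    designs, gamma for chi-squared/F designs) falls exactly at
    ``noncentrality_from_omega(spec)``.
    """
    w = spec.omega_tilde
    if not w > 0:
        raise ValueError("omega must be positive for the tau2 mapping")
    return _tau2(spec.design, w, spec.n, spec.k)


def noncentrality_from_omega(spec: EffectSpec) -> float:
    """Noncentrality parameter lambda implied by the standardized effect size."""
    return _noncentrality(spec.design, spec.omega_tilde, spec.n, spec.k)


@dataclass(frozen=True)
class EffectCategory:
    """A named interval of standardized effect sizes on the Cohen-style scale."""

    name: str
    lower: float
    upper: float

    def __contains__(self, omega: float) -> bool:
        # boundary values belong to the right-hand (larger) category
        return self.lower <= omega < self.upper and omega > 0


# Half-open intervals partitioning (0, inf); the shared boundary belongs to
# the larger category (0.1 -> small, 0.35 -> medium, 0.65 -> large).
EFFECT_CATEGORIES = (
    EffectCategory("very_small", 0.0, 0.1),
    EffectCategory("small", 0.1, 0.35),
    EffectCategory("medium", 0.35, 0.65),
    EffectCategory("large", 0.65, math.inf),
)


def categorize_effect(omega: float) -> EffectCategory:
    """Classify a positive standardized effect size.

    Very small (0, 0.1), small (0.1, 0.35], medium (0.35, 0.65], large above;
    a boundary value is assigned to the category on its right.
    """
    if not omega > 0:
        raise ValueError("omega must be positive")
    for cat in EFFECT_CATEGORIES:
        if omega in cat:
            return cat
    return EFFECT_CATEGORIES[-1]  # pragma: no cover
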