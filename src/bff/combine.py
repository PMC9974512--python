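"""Combining evidence across replicated studies.

For S independent studies of the same phenomenon, the marginal densities
factor across studies, so the Bayes factor of the combined data at a shared
root mean square effect size omega-tilde is the *product* of the per-study
Bayes factors, each evaluated with its own tau2 derived from that study's
sample size at the shared omega-tilde.  The common omega-tilde axis encodes
the belief that the intervention has a similar standardized effect in every
study; study independence is assumed, not checked.

Mixed statistic families are allowed (the factorization only needs
independence), but combining chi-squared-design studies (tau2 = n*w^2) with
F-design studies (tau2 = n*w^2/2) on one axis mixes two different
effect-size conventions; a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes_factors import TestReport
from .curve import (
    DEFAULT_GRID,
    DEFAULT_THRESHOLDS,
    BFFCurve,
    BFFResults,
    BFFSummary,
    _grid_array,
    build_bff,
    summarize,
)

__all__ = [
    "StudySet",
    "combine_bff",
    "combined_summary",
    "CombinedBayesFactorFunction",
    "CombinedBFFResults",
]

_STUDY_COLUMNS = ["label", "family", "statistic", "df1", "df2", "design", "n1", "n2"]


@dataclass(frozen=True)
class StudySet:
    """Independent studies sharing a common standardized-effect scale."""

    studies: tuple[TestReport, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.studies) < 1:
            raise ValueError("a study set needs at least one study")
        designs = {s.design for s in self.studies}
        if designs & {"multinomial_poisson", "likelihood_ratio"} and designs & {"linear_model"}:
            warnings.warn(
                "mixing chi-squared-design (tau2 = n*w^2) and F-design "
                "(tau2 = n*w^2/2) studies on one omega axis; the shared "
                "effect-size interpretation is your responsibility",
                UserWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.studies)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "StudySet":
        """Build from a table with columns label, family, statistic, df1,
        df2, design, n1, n2 (df2/n2 blank where not applicable)."""
        studies = []
        for i, row in df.iterrows():
            try:
                n2 = row.get("n2")
                has_n2 = n2 is not None and not pd.isna(n2)
                n = (int(row["n1"]), int(n2)) if has_n2 else int(row["n1"])
                df2 = row.get("df2")
                df2 = None if df2 is None or pd.isna(df2) else int(df2)
                design = row.get("design")
                design = None if design is None or pd.isna(design) or design == "" else str(design)
                studies.append(
                    TestReport(
                        family=str(row["family"]),
                        statistic=float(row["statistic"]),
                        n=n,
                        df1=int(row.get("df1", 1) if not pd.isna(row.get("df1", 1)) else 1),
                        df2=df2,
                        design=design,
                        label=str(row.get("label", "") or ""),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"study row {i}: {exc}") from exc
        return cls(tuple(studies), label=label)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "StudySet":
        return cls.from_dataframe(pd.read_csv(path), label=label)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.studies:
            n1, n2 = (s.n if isinstance(s.n, tuple) else (s.n, None))
            rows.append(
                {
                    "label": s.label,
                    "family": s.family,
                    "statistic": s.statistic,
                    "df1": s.df1,
                    "df2": s.df2,
                    "design": s.design,
                    "n1": n1,
                    "n2": n2,
                }
            )
        return pd.DataFrame(rows, columns=_STUDY_COLUMNS)


def combine_bff(studies: StudySet, grid: tuple[float, float, float] = DEFAULT_GRID) -> BFFCurve:
    """Combined BFF: at each omega-tilde, the product of per-study BF10s.

    The log Bayes factor of the combined curve is the sum of the per-study
    log Bayes factors, each study using tau2 from its own sample size at
    the shared omega-tilde.  Per-study tau2 values differ, so the combined
    curve's tau2 column is NaN.
    """
    per_study = [build_bff(s, grid) for s in studies.studies]
    omegas = _grid_array(grid)
    fns = [c.logbf_fn for c in per_study]

    def logbf_fn(w):
        return sum(fn(w) for fn in fns)

    return BFFCurve(
        omega=omegas,
        tau2=np.full_like(omegas, np.nan),
        log_bf10=np.sum([c.log_bf10 for c in per_study], axis=0),
        source=studies,
        grid=grid,
        logbf_fn=logbf_fn,
    )


def combined_summary(
    studies: StudySet,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> BFFSummary:
    """Summary (maximum and crossings) of the combined curve."""
    return summarize(combine_bff(studies, grid), thresholds)


class CombinedBayesFactorFunction:
    """Model object for the product-combined BFF of several studies.

    Examples
    --------
    >>> from bff import CombinedBayesFactorFunction
    >>> from bff.examples import fixture_confirmatory_studies
    >>> res = CombinedBayesFactorFunction(fixture_confirmatory_studies()).fit()
    >>> round(res.max_bf10, 2)
    5.75
    """

    def __init__(self, studies: StudySet, grid: tuple[float, float, float] = DEFAULT_GRID):
        self.studies = studies
        self.grid = grid

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid=DEFAULT_GRID, label: str = ""):
        return cls(StudySet.from_dataframe(df, label=label), grid=grid)

    @classmethod
    def from_csv(cls, path, grid=DEFAULT_GRID, label: str = ""):
        return cls(StudySet.from_csv(path, label=label), grid=grid)

    def fit(self, thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> "CombinedBFFResults":
        curve = combine_bff(self.studies, self.grid)
        per_study = [
            BFFResults(self, c, summarize(c, thresholds))
            for c in (build_bff(s, self.grid) for s in self.studies.studies)
        ]
        return CombinedBFFResults(self, curve, summarize(curve, thresholds), per_study)


class CombinedBFFResults(BFFResults):
    """Combined-curve results carrying the per-study curves alongside."""

    def __init__(self, model, curve, summary, per_study: list[BFFResults]):
        super().__init__(model, curve, summary)
        self.per_study = per_study

    def _describe_source(self):
        rows = []
        for i, s in enumerate(self.model.studies.studies, start=1):
            name = s.label or f"study {i}"
            df = {"z": "", "t": f", df={s.df2}", "chisq": f", df={s.df1}",
                  "f": f", df=({s.df1}, {s.df2})"}[s.family]
            rows.append((f"Study {i}:", f"{name}: {s.family} = {s.statistic:g}{df}, n = {s.n}"))
        return rows

    def plot(self, ax=None, log_scale: bool = True):
        """Combined curve (solid) with per-study curves (dotted)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for res in self.per_study:
            lbl = getattr(res.curve.source, "label", "") or None
            ax.plot(res.curve.omega, res.curve.bf10, ls=":", lw=1.0, label=lbl)
        ax.plot(self.curve.omega, self.curve.bf10, lw=1.8, color="black", label="combined")
        ax.axhline(1.0, color="gray", lw=0.8, ls="--")
        if log_scale:
            ax.set_yscale("log")
        ax.set_xlabel("root mean square effect size $\\tilde\\omega$")
        ax.set_ylabel("$BF_{10}$")
        ax.legend(loc="best", fontsize="small")
        return ax
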