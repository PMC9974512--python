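"""Worked-example data, the Pearson chi-squared test, and a statistic simulator.

This module carries two small published data sets used throughout the
documentation and tests: a 4x3 contingency table classifying 707 stomach
cancer patients by tumor site and blood group (a chi-squared test of
independence), and a pair of one-way ANOVA F statistics from an original
and a replication study of confirmatory information processing.  It also
provides a seeded simulator of z/t/chi-squared/F statistics under the
central (null) and noncentral (alternative) sampling models, used by the
distributional property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes_factors import TestReport
from .combine import StudySet
from .priors import GammaNCPrior, NormalMomentPrior

__all__ = [
    "ContingencyTable",
    "pearson_chisq_independence",
    "report_from_table",
    "fixture_table2",
    "fixture_confirmatory_studies",
    "simulate_statistic",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c matrix of nonnegative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.sum() <= 0:
            raise ValueError("table must contain at least one observation")
        object.__setattr__(self, "counts", counts)
        for labels, m, what in (
            (self.row_labels, counts.shape[0], "row"),
            (self.col_labels, counts.shape[1], "column"),
        ):
            if labels is not None and len(labels) != m:
                raise ValueError(f"{what} labels do not match the table shape")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def df(self) -> int:
        r, c = self.counts.shape
        return (r - 1) * (c - 1)

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        """Read counts from CSV; a header row / first label column are
        detected by non-numeric content and used as labels."""
        raw = pd.read_csv(path, header=None, dtype=str).fillna("")
        first_row_numeric = all(_is_number(v) for v in raw.iloc[0, :])
        first_col_numeric = all(_is_number(v) for v in raw.iloc[:, 0])
        row_labels = col_labels = None
        body = raw
        if not first_row_numeric:
            col_labels = tuple(str(v) for v in raw.iloc[0, :])
            body = body.iloc[1:, :]
        if not first_col_numeric:
            row_labels = tuple(str(v) for v in body.iloc[:, 0])
            if col_labels is not None:
                col_labels = col_labels[1:]
            body = body.iloc[:, 1:]
        counts = body.astype(float).to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("contingency table entries must be integer counts")
        return cls(np.round(counts).astype(int), row_labels, col_labels)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def pearson_chisq_independence(table: ContingencyTable) -> tuple[float, int, int]:
    """Pearson chi-squared statistic for independence of rows and columns.

    Expected counts are ``row_total * col_total / n``; no continuity
    correction is applied.  Returns ``(statistic, df, n)`` with
    ``df = (r - 1) * (c - 1)``.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column marginal is zero")
    statistic, _, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(statistic), int(df), table.n


def report_from_table(table: ContingencyTable, label: str = "") -> TestReport:
    """TestReport of the independence test: chi-squared statistic, df, and n."""
    statistic, df, n = pearson_chisq_independence(table)
    return TestReport(
        family="chisq", statistic=statistic, df1=df, n=n,
        design="multinomial_poisson", label=label,
    )


def fixture_table2() -> ContingencyTable:
    """707 stomach-cancer patients cross-classified by site and blood group."""
    return ContingencyTable(
        counts=np.array(
            [
                [104, 140, 52],
                [116, 117, 52],
                [28, 39, 11],
                [28, 12, 8],
            ]
        ),
        row_labels=("Pylorus and antrum", "Body and fundus", "Cardia", "Extensive"),
        col_labels=("O", "A", "B or AB"),
    )


def fixture_confirmatory_studies() -> StudySet:
    """Original and replication one-way ANOVA studies of confirmatory
    information processing (three groups, so k = 2 and m = n - 3)."""
    return StudySet(
        studies=(
            TestReport(family="f", statistic=4.05, df1=2, df2=82, n=85,
                       design="linear_model", label="original"),
            TestReport(family="f", statistic=1.99, df1=2, df2=137, n=140,
                       design="linear_model", label="replication"),
        ),
        label="confirmatory information processing",
    )


def simulate_statistic(
    family: str,
    lam_source,
    n_reps: int,
    seed: int,
    df1: int = 1,
    df2: int | None = None,
) -> np.ndarray:
    """Seeded draws of a test statistic under its null or alternative model.

    ``lam_source`` fixes the noncentrality parameter (a float; 0 gives the
    central null model) or draws it per replicate from a
    :class:`~bff.priors.NormalMomentPrior` (z/t) or
    :class:`~bff.priors.GammaNCPrior` (chisq/f), matching the hierarchical
    alternative.  Statistics are composed from primitive normal and
    chi-squared draws where the generator lacks a direct noncentral
    sampler (the t family); two same-seed calls return identical arrays.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    if isinstance(lam_source, (int, float, np.floating, np.integer)):
        lam = np.full(n_reps, float(lam_source))
    elif isinstance(lam_source, NormalMomentPrior):
        if family not in ("z", "t"):
            raise ValueError("normal-moment priors pair with z or t statistics")
        lam = lam_source.rvs(n_reps, rng)
    elif isinstance(lam_source, GammaNCPrior):
        if family not in ("chisq", "f"):
            raise ValueError("gamma priors pair with chisq or f statistics")
        if lam_source.k != df1:
            raise ValueError("prior k must equal df1")
        lam = lam_source.rvs(n_reps, rng)
    else:
        raise TypeError(f"unsupported lam_source {lam_source!r}")

    if family == "z":
        return rng.normal(loc=lam, scale=1.0)
    if family == "t":
        if df2 is None or df2 < 1:
            raise ValueError("t statistics require df2 >= 1")
        num = rng.normal(loc=lam, scale=1.0)
        den = np.sqrt(rng.chisquare(df2, size=n_reps) / df2)
        return num / den
    if family == "chisq":
        if df1 < 1:
            raise ValueError("chisq statistics require df1 >= 1")
        return _noncentral_chisquare(rng, df1, lam)
    if family == "f":
        if df1 < 1 or df2 is None or df2 < 1:
            raise ValueError("f statistics require df1 >= 1 and df2 >= 1")
        num = _noncentral_chisquare(rng, df1, lam) / df1
        den = rng.chisquare(df2, size=len(lam)) / df2
        return num / den
    raise ValueError(f"unknown family {family!r}")


def _noncentral_chisquare(rng: np.random.Generator, k: int, lam: np.ndarray) -> np.ndarray:
    # Generator.noncentral_chisquare rejects nc == 0; route central draws
    # through chisquare so a fixed lambda of 0 (the null model) works.
    out = np.empty(len(lam))
    central = lam == 0.0
    if central.any():
        out[central] = rng.chisquare(k, size=int(central.sum()))
    if (~central).any():
        out[~central] = rng.noncentral_chisquare(k, lam[~central])
    return out
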