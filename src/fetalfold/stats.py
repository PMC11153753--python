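"""PAD statistics: central-tendency estimation, regression, and FDR.

The core model is PAD = b0 + b1*GW + b2*X for each cortical measure X,
i.e. the brain-age gap regressed on a measure while adjusting for
gestational age; the coefficient of interest is b2.  Predictors are
z-scored by default so b2 values are comparable across measures with
different units.  Sex moderation is tested by adding sex and X-by-sex
terms, and multiple comparisons are controlled per measure family with
Benjamini-Hochberg FDR at q = 0.05.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortTable",
    "RegressionResult",
    "mode_continuous",
    "fit_pad_regression",
    "interaction_test",
    "bh_fdr",
    "run_association_suite",
]

RESERVED_COLUMNS = {"id", "gw", "sex", "pad"}


def mode_continuous(values) -> float:
    """Half-sample mode: robust mode estimator for a continuous sample.

    Recursively keep the shortest interval containing ceil(n/2) of the
    sorted values until at most three remain; terminal rule: one value ->
    itself, two -> their mean, three -> midpoint of the closer pair.
    Length ties are broken toward the lower interval.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("mode of empty sample")
    while x.size > 3:
        h = int(np.ceil(x.size / 2))
        widths = x[h - 1 :] - x[: x.size - h + 1]
        lo = int(np.argmin(widths))  # argmin takes the first = lower interval
        x = x[lo : lo + h]
    if x.size == 1:
        return float(x[0])
    if x.size == 2:
        return float(x.mean())
    # three values: mean of the closer adjacent pair
    if x[1] - x[0] <= x[2] - x[1]:
        return float(0.5 * (x[0] + x[1]))
    return float(0.5 * (x[1] + x[2]))


@dataclasses.dataclass
class RegressionResult:
    measure: str
    beta2: float
    se: float
    pvalue: float
    n: int
    beta0: float
    beta1: float
    term: str = "measure"  # which coefficient beta2 refers to

    def summary(self) -> str:
        return (
            f"{self.measure}: {self.beta2:+.3f} ± {self.se:.3f} "
            f"(p = {self.pvalue:.3g}, n = {self.n})"
        )


class CohortTable:
    """Subject-level table: id, gw, sex, pad, plus one column per measure.

    Thin validation wrapper around a DataFrame; measure columns are
    everything not in the reserved set.
    """

    def __init__(self, df: pd.DataFrame, gw_range: tuple[float, float] = (15.0, 42.0)):
        missing = RESERVED_COLUMNS - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if df["pad"].isna().any():
            raise ValueError("missing PAD values")
        gw = df["gw"].to_numpy(float)
        if np.any(gw < gw_range[0]) or np.any(gw > gw_range[1]):
            raise ValueError(f"gestational ages outside {gw_range}")
        meas = self.measure_columns(df)
        if not np.all(np.isfinite(df[meas].to_numpy(float))):
            raise ValueError("non-finite measure values")
        self.df = df.reset_index(drop=True)

    @staticmethod
    def measure_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c not in RESERVED_COLUMNS]

    @property
    def measures(self) -> list[str]:
        return self.measure_columns(self.df)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (collinear columns among {names})"
        )


def fit_pad_regression(
    cohort: CohortTable, measure: str, standardize: bool = True
) -> RegressionResult:
    """OLS of PAD on [1, GW, X]; returns the X coefficient with its SE and
    two-sided p (t distribution, n - 3 df)."""
    df = cohort.df
    if measure not in df.columns:
        raise KeyError(measure)
    n = len(df)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    gw = df["gw"].to_numpy(float)
    x = df[measure].to_numpy(float)
    if standardize:
        gw, x = _z(gw), _z(x)
    X = np.column_stack([np.ones(n), gw, x])
    _check_rank(X, ["const", "gw", measure])
    fit = sm.OLS(df["pad"].to_numpy(float), X).fit()
    return RegressionResult(
        measure=measure,
        beta2=float(fit.params[2]),
        se=float(fit.bse[2]),
        pvalue=float(fit.pvalues[2]),
        n=n,
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
    )


def interaction_test(
    cohort: CohortTable, measure: str, standardize: bool = True
) -> RegressionResult:
    """Measure-by-sex interaction: OLS of PAD on [1, GW, X, sex, X*sex].

    Unknown-sex subjects are dropped; returns the X*sex coefficient test.
    """
    df = cohort.df[cohort.df["sex"].isin(["M", "F"])]
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes required for the interaction test")
    n = len(df)
    gw = df["gw"].to_numpy(float)
    x = df[measure].to_numpy(float)
    if standardize:
        gw, x = _z(gw), _z(x)
    sex = (df["sex"] == "F").to_numpy(float)
    X = np.column_stack([np.ones(n), gw, x, sex, x * sex])
    _check_rank(X, ["const", "gw", measure, "sex", f"{measure}:sex"])
    fit = sm.OLS(df["pad"].to_numpy(float), X).fit()
    return RegressionResult(
        measure=measure,
        beta2=float(fit.params[4]),
        se=float(fit.bse[4]),
        pvalue=float(fit.pvalues[4]),
        n=n,
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        term="measure:sex",
    )


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def run_association_suite(
    cohort: CohortTable,
    measure_groups: dict[str, list[str]] | None = None,
    q: float = 0.05,
    standardize: bool = True,
) -> dict:
    """Fit every measure column and FDR-correct within each family.

    ``measure_groups`` maps family name -> list of measure columns (FDR is
    applied within a family); by default all measures form one family.
    Returns a JSON-serialisable dict with per-measure results, rejection
    flags, and a Table-2-style text report.
    """
    if measure_groups is None:
        measure_groups = {"all": cohort.measures}
    out: dict = {"q": q, "families": {}}
    lines = []
    for family, cols in measure_groups.items():
        results = [fit_pad_regression(cohort, c, standardize) for c in cols]
        reject, p_adj = bh_fdr([r.pvalue for r in results], q)
        fam = []
        for r, rej, pa in zip(results, reject, p_adj):
            fam.append(
                {
                    "measure": r.measure,
                    "beta2": r.beta2,
                    "se": r.se,
                    "p": r.pvalue,
                    "p_fdr": float(pa),
                    "significant_fdr": bool(rej),
                    "n": r.n,
                    "beta0": r.beta0,
                    "beta1": r.beta1,
                }
            )
            star = " *" if rej else ""
            lines.append(
                f"[{family}] {r.measure}: {r.beta2:+.3f} ± {r.se:.3f} "
                f"(p = {r.pvalue:.3g}){star}"
            )
        out["families"][family] = fam
    out["report"] = "\n".join(lines)
    return out
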