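"""Country-level association of accessibility metrics with health outcomes.

Spearman rank correlations (mid-ranks for ties, two-sided t-approximation
p-values, exact permutation available for small n) plus an ordinary
least-squares adjustment model controlling for potential accessibility and
log GDP. Countries with missing values are dropped listwise — associations
here are descriptive, not causal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["AssociationResult", "spearman", "adjusted_association", "OutcomeTable", "load_outcomes"]

OUTCOME_COLUMNS = ["country", "life_expectancy", "infant_mortality", "gdp"]


@dataclass
class AssociationResult:
    metric_name: str
    outcome_name: str
    rho: float
    p_value: float
    n: int
    adjusted_coefficients: dict | None = None
    estimate: float = float("nan")
    stderr: float = float("nan")

    def __post_init__(self):
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")


def spearman(x, y, exact: bool = False, names: tuple[str, str] = ("x", "y")) -> AssociationResult:
    """Spearman rank correlation across countries with listwise deletion.

    Mid-ranks are used for ties, the two-sided p-value comes from the
    t-distribution approximation, and for n <= 10 an exact permutation
    p-value can be requested (full enumeration; O(n!) — intended for small
    fixtures).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rho, p = stats.spearmanr(x, y)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p-value is only supported for n <= 10")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(np.corrcoef(rx[list(perm)], ry)[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return AssociationResult(names[0], names[1], float(rho), float(p), int(n))


def adjusted_association(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    controls: tuple = ("potential_weighted", "gdp"),
    log_gdp: bool = True,
) -> AssociationResult:
    """OLS of an outcome on a revealed-accessibility exposure plus controls.

    GDP enters log-transformed by default. Reports the exposure estimate,
    its standard error and two-sided p, along with every coefficient. Raises
    on a rank-deficient design, naming the collinear terms.
    """
    cols = [outcome, exposure, *controls]
    df = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(df)
    if n < len(controls) + 3:
        raise ValueError(f"need at least {len(controls) + 3} complete countries, got {n}")
    X = df[[exposure, *controls]].copy()
    if log_gdp and "gdp" in X.columns:
        if (X["gdp"] <= 0).any():
            raise ValueError("gdp must be positive for the log transform")
        X["gdp"] = np.log(X["gdp"])
        X = X.rename(columns={"gdp": "log_gdp"})
    Xmat = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xmat.to_numpy())
    if rank < Xmat.shape[1]:
        bad = _collinear_terms(Xmat)
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    fit = sm.OLS(df[outcome].to_numpy(), Xmat).fit()
    coefs = {
        term: (float(fit.params[term]), float(fit.pvalues[term]))
        for term in Xmat.columns
    }
    return AssociationResult(
        metric_name=exposure,
        outcome_name=outcome,
        rho=float("nan"),
        p_value=float(fit.pvalues[exposure]),
        n=n,
        adjusted_coefficients=coefs,
        estimate=float(fit.params[exposure]),
        stderr=float(fit.bse[exposure]),
    )


def _collinear_terms(Xmat: pd.DataFrame) -> list[str]:
    """Name columns involved in exact linear dependence (via QR diagnostics)."""
    arr = Xmat.to_numpy(dtype=float)
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = max(arr.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    return [c for c, d in zip(Xmat.columns, diag) if d < tol]


@dataclass
class OutcomeTable:
    """Validated country-level outcome table."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in OUTCOME_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"outcome table missing columns: {missing}")
        le = self.data["life_expectancy"].dropna()
        if ((le <= 30) | (le >= 100)).any():
            raise ValueError("life_expectancy values must lie in (30, 100) years")
        if (self.data["infant_mortality"].dropna() < 0).any():
            raise ValueError("infant_mortality must be >= 0")


def load_outcomes(path) -> pd.DataFrame:
    """Read a country,life_expectancy,infant_mortality,gdp CSV with validation."""
    df = pd.read_csv(path)
    return OutcomeTable(df).data
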