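"""Logistic-regression sensitivity analysis of DAD incidence.

Population studies relate per-cell parameter scale factors to a binary
outcome (did the cell produce a delayed afterdepolarization during the
pacing–pause provocation).  Features are the z-scored natural logarithms
of the scale factors, so a positive coefficient means that increasing the
parameter promotes DADs and a negative one that it protects.

The fit maximizes the Bernoulli log-likelihood under a logit link by
iteratively reweighted least squares (IRLS) with a small ridge penalty on
the slopes (not the intercept) to tame quasi-separation in small
populations.  ``DadLogit(dataset).fit()`` returns a results object with
coefficients, optional bootstrap confidence intervals and a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RegressionDataset:
    """Standardized design matrix plus binary labels.

    ``X`` holds z-scored log scale factors (one column per parameter),
    ``y`` the 0/1 DAD labels, ``feature_names`` the column names.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one row per label")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("one name per feature column required")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("labels must be binary 0/1")


def build_design_matrix(
    scale_factors: pd.DataFrame, labels=None
) -> RegressionDataset:
    """Z-scored natural-log features from a per-cell scale-factor table.

    Columns with zero variance (after the log) are dropped with a warning.
    Non-positive factors are rejected naming the offending cell and
    parameter.
    """
    bad = scale_factors <= 0
    if bad.any().any():
        cell = bad.any(axis=1).idxmax()
        param = bad.loc[cell][bad.loc[cell]].index[0]
        raise ValueError(
            f"non-positive scale factor for cell {cell!r}, parameter {param!r}"
        )
    logs = np.log(scale_factors.to_numpy(dtype=float))
    sd = logs.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        dropped = [c for c, k in zip(scale_factors.columns, keep) if not k]
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    logs = logs[:, keep]
    names = [c for c, k in zip(scale_factors.columns, keep) if k]
    z = (logs - logs.mean(axis=0)) / logs.std(axis=0, ddof=0)
    y = np.zeros(len(z)) if labels is None else np.asarray(labels, dtype=float)
    return RegressionDataset(z, y, names)


@dataclass
class DadLogitResults:
    """Fitted coefficients and diagnostics of the DAD logistic regression."""

    params: pd.Series              # slope per feature
    intercept: float
    converged: bool
    n_iter: int
    ridge: float
    model: "DadLogit"
    conf_int: pd.DataFrame | None = None   # columns lo, hi
    quasi_separation: bool = False

    def bootstrap(self, n_boot: int = 200, seed: int = 0, alpha: float = 0.05):
        """Nonparametric bootstrap percentile confidence intervals."""
        rng = np.random.default_rng(seed)
        n = len(self.model.data.y)
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            ys = self.model.data.y[idx]
            if ys.min() == ys.max():
                continue
            sub = RegressionDataset(
                self.model.data.X[idx], ys, self.model.data.feature_names
            )
            try:
                res = DadLogit(sub).fit(ridge=self.ridge)
            except Exception:
                continue
            draws.append(res.params.to_numpy())
        draws = np.array(draws)
        lo = np.quantile(draws, alpha / 2, axis=0)
        hi = np.quantile(draws, 1 - alpha / 2, axis=0)
        self.conf_int = pd.DataFrame(
            {"lo": lo, "hi": hi}, index=self.params.index
        )
        return self.conf_int

    def summary(self) -> pd.DataFrame:
        """Coefficient table ranked by influence, with sign annotation."""
        df = pd.DataFrame({"coefficient": self.params})
        if self.conf_int is not None:
            df["ci_lo"] = self.conf_int["lo"]
            df["ci_hi"] = self.conf_int["hi"]
        df["effect"] = np.where(
            df["coefficient"] > 0, "promotes DADs", "protects against DADs"
        )
        df["rank"] = (-df["coefficient"].abs()).rank(method="first").astype(int)
        return df.sort_values("rank")


class DadLogit:
    """Penalized logistic regression model for binary DAD labels."""

    def __init__(self, data: RegressionDataset):
        if data.y.min() == data.y.max():
            raise ValueError(
                "labels are single-class; logistic regression requires both "
                "outcomes to be present"
            )
        self.data = data

    @classmethod
    def from_tables(cls, scale_factors: pd.DataFrame, labels) -> "DadLogit":
        return cls(build_design_matrix(scale_factors, labels))

    def fit(
        self, ridge: float = 1e-4, max_iter: int = 200, tol: float = 1e-10
    ) -> DadLogitResults:
        """IRLS maximization of the penalized Bernoulli log-likelihood.

        The ridge penalty applies to the slopes only.  Non-convergence is
        reported in the results, never silently ignored.
        """
        X = np.column_stack([np.ones(len(self.data.y)), self.data.X])
        y = self.data.y
        n, p = X.shape
        pen = np.full(p, ridge)
        pen[0] = 0.0
        beta = np.zeros(p)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            XtW = X.T * w
            A = XtW @ X + np.diag(pen)
            b = XtW @ z
            new = np.linalg.solve(A, b)
            step = np.max(np.abs(new - beta))
            beta = new
            if step < tol:
                converged = True
                break
        quasi = bool(np.max(np.abs(beta[1:])) > 20.0) or not converged
        return DadLogitResults(
            params=pd.Series(beta[1:], index=self.data.feature_names),
            intercept=float(beta[0]),
            converged=converged,
            n_iter=it,
            ridge=ridge,
            model=self,
            quasi_separation=quasi,
        )


def fit_logistic(dataset: RegressionDataset, ridge: float = 1e-4) -> DadLogitResults:
    """Functional wrapper: fit the DAD logistic regression on a dataset."""
    return DadLogit(dataset).fit(ridge=ridge)


def interpret(result: DadLogitResults) -> pd.DataFrame:
    """Ranked influence report for a converged fit."""
    if not result.converged:
        raise ValueError("cannot interpret a non-converged fit")
    return result.summary()
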