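"""Principal component regression of a subject-level outcome on fPC scores.

Ordinary least squares with an intercept, the retained component scores
(Z-standardized by default so coefficients read as seconds per between-
subject SD), and optional covariates. Inference is classical: t statistics
and confidence intervals from the residual-degrees-of-freedom t
distribution; a heteroskedasticity-robust option is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class RegressionReport:
    """Per-term estimates plus model-level summary, Table-style."""

    terms: pd.DataFrame  # term, coefficient, std_error, t, p, ci_low, ci_high
    r_squared: float
    adj_r_squared: float
    n_obs: int
    df_resid: int
    dropped_subjects: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.attrs.update(
            r_squared=self.r_squared,
            adj_r_squared=self.adj_r_squared,
            n_obs=self.n_obs,
            df_resid=self.df_resid,
        )
        return out


class ScoreRegression(RegressorMixin, BaseEstimator):
    """OLS of an outcome on fPC scores (+ covariates), scikit-learn style.

    Parameters
    ----------
    covariates : sequence of str
        Covariate column names to pull from the subject table.
    standardized : bool
        Enter Z-standardized scores (default) or raw scores.
    outcome : str
        Outcome column name in the subject table.
    robust : bool
        Use HC1 robust standard errors instead of classical ones.

    Attributes
    ----------
    report_ : RegressionReport
    results_ : statsmodels RegressionResults
    """

    def __init__(
        self,
        covariates: Sequence[str] = (),
        standardized: bool = True,
        outcome: str = "transition_time",
        robust: bool = False,
    ):
        self.covariates = covariates
        self.standardized = standardized
        self.outcome = outcome
        self.robust = robust

    def _design(self, scores: pd.DataFrame, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, list[str]]:
        if "subject_id" not in table.columns:
            raise ValueError("subject table must have a subject_id column")
        table = table.set_index("subject_id")
        missing = [sid for sid in scores.index if sid not in table.index]
        extra = [sid for sid in table.index if sid not in scores.index]
        if missing:
            raise ValueError(
                f"subjects with scores but no outcome row: {missing[:5]}"
                + (" ..." if len(missing) > 5 else "")
            )
        cov = list(self.covariates)
        unknown = [c for c in cov if c not in table.columns]
        if unknown:
            raise ValueError(f"covariates not in subject table: {unknown}")
        table = table.loc[scores.index]
        design = pd.concat([scores, table[cov]], axis=1)
        y = table[self.outcome]
        # complete-case analysis; per-subject drops are reported
        keep = design.notna().all(axis=1) & y.notna()
        dropped = list(design.index[~keep])
        return design[keep], y[keep], dropped + extra

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """Fit on a score DataFrame (indexed by subject_id) and subject table."""
        scores = X.copy()
        if self.standardized:
            sd = scores.std(ddof=1)
            if (sd == 0).any():
                bad = list(scores.columns[sd == 0])
                raise ValueError(f"zero-variance score columns: {bad}")
            scores = (scores - scores.mean()) / sd
        design, out, dropped = self._design(scores, y)
        exog = sm.add_constant(design, prepend=False)
        rank = np.linalg.matrix_rank(exog.to_numpy())
        if rank < exog.shape[1]:
            # name the offending column for the user
            cols = list(exog.columns)
            for j in range(exog.shape[1]):
                sub = exog.drop(columns=cols[j]).to_numpy()
                if np.linalg.matrix_rank(sub) == rank:
                    raise ValueError(f"design is rank deficient; column '{cols[j]}' is redundant")
            raise ValueError("design is rank deficient")
        res = sm.OLS(out.to_numpy(dtype=float), exog).fit(
            cov_type="HC1" if self.robust else "nonrobust"
        )
        ci = res.conf_int(alpha=0.05)
        terms = pd.DataFrame(
            {
                "term": ["intercept" if c == "const" else c for c in exog.columns],
                "coefficient": res.params.to_numpy(),
                "std_error": res.bse.to_numpy(),
                "t": res.tvalues.to_numpy(),
                "p": res.pvalues.to_numpy(),
                "ci_low": ci.iloc[:, 0].to_numpy(),
                "ci_high": ci.iloc[:, 1].to_numpy(),
            }
        )
        self.results_ = res
        self.report_ = RegressionReport(
            terms=terms,
            r_squared=float(res.rsquared),
            adj_r_squared=float(res.rsquared_adj),
            n_obs=int(res.nobs),
            df_resid=int(res.df_resid),
            dropped_subjects=dropped,
        )
        self._score_means = X.mean()
        self._score_sds = X.std(ddof=1)
        self._columns = list(design.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "results_")
        scores = X.copy()
        if self.standardized:
            scores = (scores - self._score_means[scores.columns]) / self._score_sds[
                scores.columns
            ]
        exog = sm.add_constant(scores[self._columns[: scores.shape[1]]], prepend=False)
        return np.asarray(self.results_.predict(exog))


def fit_score_regression(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    covariates: Sequence[str] = (),
    outcome: str = "transition_time",
    standardized: bool = True,
    robust: bool = False,
) -> RegressionReport:
    """Fit the score regression and return its report."""
    model = ScoreRegression(
        covariates=covariates, standardized=standardized, outcome=outcome, robust=robust
    ).fit(scores, table)
    return model.report_


def regression_provenance(report: RegressionReport, pipeline_config: dict) -> dict:
    """Serializable run record: config, software version, model summary."""
    from . import __version__

    record = {
        "software": {"package": "nirsfda", "version": __version__},
        "config": json.loads(json.dumps(pipeline_config, sort_keys=True, default=str)),
        "model": {
            "n_obs": report.n_obs,
            "df_resid": report.df_resid,
            "r_squared": report.r_squared,
            "adj_r_squared": report.adj_r_squared,
            "terms": report.terms.to_dict(orient="records"),
            "dropped_subjects": report.dropped_subjects,
        },
    }
    return record
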