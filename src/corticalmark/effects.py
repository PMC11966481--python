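"""Covariate-adjusted case-control effect-size maps.

The deficit-pattern object at the heart of the analysis is a vector of
per-region Cohen's d values (case - control, so deficits are negative),
computed on measures residualized for age and sex.  Residualization fits
ordinary least squares of each region's measure on [1, age, sex] over the
pooled sample (diagnosis-blind by default) and re-centers the residuals at
the covariate means, preserving the measure's scale:

    x_adj = x - X b + x̄(mean age, mean sex).

Cohen's d uses the pooled standard deviation

    d_j = (mean_case - mean_ctrl) / s_pooled,
    s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)),

with the two-sample t statistic and a two-sided p from t_{n1+n2-2}.
Per-region significance is Bonferroni-corrected over the R regions tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RegionalMeasureTable

__all__ = [
    "CovariateModel",
    "DeficitPatternModel",
    "DeficitPatternResults",
    "residualize",
    "cohens_d_map",
    "summarize_map",
    "flag_significant",
]


@dataclass
class CovariateModel:
    """Per-region least-squares nuisance fit and the means used to re-center."""

    coefficients: pd.DataFrame  # rows: intercept + covariates; columns: regions
    covariate_means: pd.Series
    covariates: tuple

    def predict_at_means(self) -> pd.Series:
        """Fitted value at the covariate means, per region."""
        xrow = np.concatenate([[1.0], self.covariate_means.to_numpy(float)])
        return pd.Series(xrow @ self.coefficients.to_numpy(float), index=self.coefficients.columns)


def residualize(
    table: RegionalMeasureTable,
    covariates=("age", "sex"),
    adjustment: str = "pooled",
) -> tuple[RegionalMeasureTable, CovariateModel]:
    """Remove covariate contributions from every region's measure.

    ``adjustment='pooled'`` fits the nuisance model on all subjects,
    diagnosis-blind; ``'controls_only'`` estimates the coefficients on
    controls and applies them to everyone.  The adjusted value is the
    residual plus the fitted value at the (fitting-sample) covariate means,
    so the measure keeps its original scale.
    """
    if adjustment not in ("pooled", "controls_only"):
        raise ValueError(f"unknown adjustment mode {adjustment!r}")
    covariates = tuple(covariates)
    for c in covariates:
        if c not in table.subjects.columns:
            raise ValueError(f"covariate {c!r} not in subject table")

    fit_rows = (
        np.ones(table.n_subjects, bool)
        if adjustment == "pooled"
        else (table.subjects["dx"].to_numpy(int) == 0)
    )
    C_all = table.subjects[list(covariates)].to_numpy(float)
    X_all = np.column_stack([np.ones(len(C_all)), C_all])
    X_fit = X_all[fit_rows]
    if np.linalg.matrix_rank(X_fit) < X_fit.shape[1]:
        raise ValueError(
            f"singular covariate design for covariates {covariates} "
            "(a covariate is constant or collinear in the fitting sample)"
        )
    Y = table.measures.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X_fit, Y[fit_rows], rcond=None)
    means = X_fit[:, 1:].mean(axis=0)
    at_means = np.concatenate([[1.0], means]) @ beta
    adjusted = Y - X_all @ beta + at_means

    model = CovariateModel(
        coefficients=pd.DataFrame(
            beta, index=["intercept", *covariates], columns=table.measures.columns
        ),
        covariate_means=pd.Series(means, index=list(covariates)),
        covariates=covariates,
    )
    out = table.with_measures(pd.DataFrame(adjusted, columns=table.measures.columns))
    return out, model


def cohens_d_map(
    table: RegionalMeasureTable,
    measure_name: str | None = None,
    cohort_label: str = "",
    hedges: bool = False,
) -> pd.DataFrame:
    """Per-region case-control Cohen's d with t and two-sided p.

    Sign convention: d = case - control, so a case deficit is negative.
    Regions with pooled SD 0 yield NaN with a warning; regions where either
    group has fewer than 2 usable subjects are skipped with a warning.
    ``hedges`` applies the small-sample correction factor (off by default).
    """
    dx = table.subjects["dx"].to_numpy(int)
    rows = []
    for region in table.measures.columns:
        y = table.measures[region].to_numpy(float)
        ok = np.isfinite(y)
        a = y[ok & (dx == 1)]
        b = y[ok & (dx == 0)]
        n1, n2 = len(a), len(b)
        if n1 < 2 or n2 < 2:
            warnings.warn(
                f"region {region}: fewer than 2 usable subjects in a group "
                f"(n_case={n1}, n_control={n2}); skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        if s2 <= 0:
            warnings.warn(
                f"region {region}: pooled SD is zero; d undefined", RuntimeWarning, stacklevel=2
            )
            d = t = p = np.nan
        else:
            sp = np.sqrt(s2)
            d = (a.mean() - b.mean()) / sp
            if hedges:
                df = n1 + n2 - 2
                d *= 1.0 - 3.0 / (4.0 * df - 1.0)
            t = (a.mean() - b.mean()) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
            p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
        rows.append(dict(region=region, d=d, t=t, p=p, n_case=n1, n_control=n2))
    return pd.DataFrame(rows, columns=["region", "d", "t", "p", "n_case", "n_control"])


def flag_significant(es_map: pd.DataFrame, alpha: float = 0.05, method: str = "bonferroni") -> pd.DataFrame:
    """Add a ``sig_bonferroni`` flag: p < alpha / R over the R regions tested.

    R is taken from the map itself, never hard-coded.  ``method='fdr_bh'``
    switches to Benjamini-Hochberg (flag column name unchanged for schema
    stability).
    """
    out = es_map.copy()
    R = len(out)
    if R < 1:
        raise ValueError("empty effect-size map")
    p = out["p"].to_numpy(float)
    if method == "bonferroni":
        out["sig_bonferroni"] = p < alpha / R
    elif method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] <= alpha * (np.arange(1, R + 1) / R)
        k = np.max(np.nonzero(ranked)[0]) + 1 if ranked.any() else 0
        flags = np.zeros(R, bool)
        flags[order[:k]] = True
        out["sig_bonferroni"] = flags
    else:
        raise ValueError(f"unknown correction method {method!r}")
    out.loc[~np.isfinite(p), "sig_bonferroni"] = False
    return out


def summarize_map(es_map: pd.DataFrame) -> dict:
    """Mean and sample SD of d across regions, plus |d|-ranked extremes."""
    d = es_map["d"].to_numpy(float)
    finite = np.isfinite(d)
    if finite.sum() < 2:
        raise ValueError("need at least 2 regions with finite d to summarize")
    vals = d[finite]
    ranked = es_map.loc[finite].reindex(
        es_map.loc[finite, "d"].abs().sort_values(ascending=False).index
    )
    return {
        "mean_d": float(vals.mean()),
        "sd_d": float(vals.std(ddof=1)),
        "n_regions": int(finite.sum()),
        "ranking": list(zip(ranked["region"], ranked["d"].astype(float))),
    }


class DeficitPatternModel:
    """Case-control deficit-pattern model over a regional measure table.

    Fitting residualizes each region's measure on the covariates and
    computes the per-region pooled-SD Cohen's d map with Bonferroni flags.

    Parameters
    ----------
    table : RegionalMeasureTable
    covariates : sequence of str
        Subject columns to adjust for (default age and sex).
    adjustment : {'pooled', 'controls_only'}
        Sample on which the nuisance coefficients are estimated.
    hedges : bool
        Apply the small-sample (Hedges) correction to d.
    """

    def __init__(self, table, covariates=("age", "sex"), adjustment="pooled", hedges=False):
        self.table = table
        self.covariates = tuple(covariates)
        self.adjustment = adjustment
        self.hedges = hedges

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, measure_name: str = "measure", **kw):
        return cls(RegionalMeasureTable.from_frame(frame, measure_name=measure_name), **kw)

    def fit(self, alpha: float = 0.05, correction: str = "bonferroni") -> "DeficitPatternResults":
        adjusted, cov_model = residualize(self.table, self.covariates, self.adjustment)
        es = cohens_d_map(adjusted, hedges=self.hedges)
        es = flag_significant(es, alpha=alpha, method=correction)
        return DeficitPatternResults(
            model=self,
            effect_sizes=es,
            covariate_model=cov_model,
            adjusted_table=adjusted,
            alpha=alpha,
        )


@dataclass
class DeficitPatternResults:
    """Fitted effect-size map plus the nuisance model behind it."""

    model: DeficitPatternModel
    effect_sizes: pd.DataFrame
    covariate_model: CovariateModel
    adjusted_table: RegionalMeasureTable
    alpha: float

    def summarize(self) -> dict:
        return summarize_map(self.effect_sizes)

    @property
    def d(self) -> pd.Series:
        return pd.Series(
            self.effect_sizes["d"].to_numpy(float), index=self.effect_sizes["region"]
        )

    def summary(self) -> str:
        s = self.summarize()
        lines = [
            "Deficit-pattern effect-size map",
            f"  measure:    {self.model.table.measure_name}",
            f"  adjustment: {self.model.adjustment} ({', '.join(self.model.covariates)})",
            f"  regions:    {s['n_regions']}   mean d = {s['mean_d']:+.3f}  SD = {s['sd_d']:.3f}",
            f"  alpha:      {self.alpha} (Bonferroni over {len(self.effect_sizes)} regions)",
            "",
            self.effect_sizes.to_string(
                index=False, float_format=lambda v: f"{v: .4f}", justify="right"
            ),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Horizontal bar chart of d per region, significant bars highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.25 * len(self.effect_sizes) + 1))
        es = self.effect_sizes.sort_values("d")
        colors = ["#b2182b" if s else "#888888" for s in es["sig_bonferroni"]]
        ax.barh(es["region"], es["d"], color=colors)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("Cohen's d (case $-$ control)")
        return ax

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        write_tsv(self.effect_sizes, path)
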