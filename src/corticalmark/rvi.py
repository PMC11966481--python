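"""Regional Vulnerability Index (RVI): individual agreement with a template
deficit pattern.

Each subject's adjusted regional measures are z-scored against a healthy
reference (control means and SDs), and the RVI is the Pearson correlation,
across regions, between the subject's z-deviation vector and a template
effect-size vector (case - control d, deficits negative).  A subject whose
deviations follow the illness pattern — low values exactly where the
template is negative — therefore scores positively.  Group contrasts use
pooled-SD Cohen's d; symptom associations are Pearson correlations over
subjects with non-missing severity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RegionalMeasureTable, TemplateVector, canonical_region_name
from .effects import residualize

__all__ = [
    "ControlReference",
    "RVIModel",
    "RVIResults",
    "build_control_reference",
    "zscore_subjects",
    "rvi_scores",
    "rvi_group_contrast",
    "rvi_symptom_association",
]


@dataclass
class ControlReference:
    """Per-region control mean and sample SD used for z-scoring."""

    mean: pd.Series
    sd: pd.Series
    excluded: list

    @property
    def regions(self) -> list:
        return list(self.mean.index)


def build_control_reference(table: RegionalMeasureTable) -> ControlReference:
    """Control-only per-region mean and sample SD.

    Regions with zero control SD are excluded (and listed) — they carry no
    deviation scale.  Requires at least 2 controls.
    """
    ctrl = table.measures[table.subjects["dx"].to_numpy(int) == 0]
    if len(ctrl) < 2:
        raise ValueError(f"need >= 2 controls to build a reference, have {len(ctrl)}")
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    excluded = [r for r in sd.index if not np.isfinite(sd[r]) or sd[r] == 0]
    if excluded:
        warnings.warn(
            f"regions excluded from reference (zero/undefined control SD): {excluded}",
            RuntimeWarning,
            stacklevel=2,
        )
    keep = [r for r in sd.index if r not in set(excluded)]
    return ControlReference(mean=mu[keep], sd=sd[keep], excluded=excluded)


def zscore_subjects(table: RegionalMeasureTable, reference: ControlReference) -> pd.DataFrame:
    """Subjects x regions z matrix: (x - mu_j) / sigma_j against the reference."""
    missing = [r for r in reference.regions if r not in table.measures.columns]
    if missing:
        raise ValueError(f"table lacks reference regions: {missing}")
    x = table.measures[reference.regions]
    z = (x - reference.mean) / reference.sd
    z.index = table.subjects["subject_id"].to_numpy()
    return z


def rvi_scores(z: pd.DataFrame, template: TemplateVector, method: str = "pearson") -> pd.Series:
    """Per-subject RVI: correlation of the z-deviation row with the template.

    Region matching is by canonicalized name; a mismatch raises with the set
    difference.  Subjects with zero z-variance across regions get NaN with a
    warning.  ``method`` may be 'pearson' (default), 'spearman' or 'cosine'.
    """
    cols = {canonical_region_name(c): c for c in z.columns}
    t_regions = set(template.regions)
    z_regions = set(cols)
    shared = sorted(t_regions & z_regions)
    if len(shared) < 3:
        raise ValueError(
            "region mismatch between z matrix and template (fewer than 3 shared): "
            f"only-in-template={sorted(t_regions - z_regions)}, "
            f"only-in-table={sorted(z_regions - t_regions)}"
        )
    if t_regions != z_regions:
        warnings.warn(
            f"scoring on {len(shared)} shared regions; "
            f"unmatched: template-only={sorted(t_regions - z_regions)}, "
            f"table-only={sorted(z_regions - t_regions)}",
            RuntimeWarning,
            stacklevel=2,
        )
    zz = z[[cols[r] for r in shared]].to_numpy(float)
    tt = template.values[shared].to_numpy(float)

    if method == "spearman":
        zz = stats.rankdata(zz, axis=1)
        tt = stats.rankdata(tt)
    if method in ("pearson", "spearman"):
        zc = zz - zz.mean(axis=1, keepdims=True)
        tc = tt - tt.mean()
    elif method == "cosine":
        zc, tc = zz, tt
    else:
        raise ValueError(f"unknown similarity method {method!r}")

    znorm = np.sqrt((zc**2).sum(axis=1))
    degenerate = znorm == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} subjects with zero deviation variance scored NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (zc @ tc) / (znorm * np.sqrt((tc**2).sum()))
    scores[degenerate] = np.nan
    return pd.Series(scores, index=z.index, name="rvi")


def rvi_group_contrast(scores: pd.Series, dx) -> dict:
    """Pooled-SD Cohen's d (case - control) with two-sample t and p."""
    s = np.asarray(scores, dtype=float)
    g = np.asarray(dx, dtype=int)
    ok = np.isfinite(s)
    a, b = s[ok & (g == 1)], s[ok & (g == 0)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 scored subjects per group (case={len(a)}, control={len(b)})")
    n1, n2 = len(a), len(b)
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("degenerate groups: zero pooled variance of RVI scores")
    sp = np.sqrt(s2)
    d = (a.mean() - b.mean()) / sp
    t = (a.mean() - b.mean()) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return {"cohen_d": float(d), "t": float(t), "p": float(p), "n_case": n1, "n_control": n2}


def rvi_symptom_association(scores: pd.Series, severity) -> dict:
    """Pearson r between RVI and symptom severity over non-missing pairs."""
    s = np.asarray(scores, dtype=float)
    sev = np.asarray(severity, dtype=float)
    ok = np.isfinite(s) & np.isfinite(sev)
    n = int(ok.sum())
    if n < 4:
        raise ValueError(f"need >= 4 subjects with both RVI and severity, have {n}")
    if s[ok].std() == 0 or sev[ok].std() == 0:
        raise ValueError("zero variance in RVI or severity over complete pairs")
    r, p = stats.pearsonr(s[ok], sev[ok])
    return {"pearson_r": float(r), "p": float(p), "n": n}


class RVIModel:
    """Regional Vulnerability Index of a cohort against a template pattern.

    Fitting (1) residualizes the measures for the covariates (same
    adjustment as the effect maps), (2) builds the control-only reference,
    (3) z-scores every subject and correlates the deviation rows with the
    template, and (4) summarizes the case-control contrast and the
    severity association.

    Parameters
    ----------
    table : RegionalMeasureTable
    template : TemplateVector
        Case-control d template (deficits negative).
    covariates : sequence of str
    adjustment : {'pooled', 'controls_only'}
    method : {'pearson', 'spearman', 'cosine'}
        Similarity kernel between deviations and template.
    """

    def __init__(
        self,
        table,
        template,
        covariates=("age", "sex"),
        adjustment="pooled",
        method="pearson",
    ):
        self.table = table
        self.template = template
        self.covariates = tuple(covariates)
        self.adjustment = adjustment
        self.method = method

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, template, **kw):
        return cls(RegionalMeasureTable.from_frame(frame), template, **kw)

    def fit(self) -> "RVIResults":
        adjusted, _ = residualize(self.table, self.covariates, self.adjustment)
        reference = build_control_reference(adjusted)
        z = zscore_subjects(adjusted, reference)
        scores = rvi_scores(z, self.template, method=self.method)
        dx = self.table.subjects["dx"].to_numpy(int)
        contrast = rvi_group_contrast(scores, dx)
        sev = self.table.subjects["severity"].to_numpy(float)
        try:
            association = rvi_symptom_association(scores, sev)
        except ValueError:
            association = None
        return RVIResults(
            model=self, scores=scores, reference=reference, group_contrast=contrast,
            symptom_association=association,
        )


@dataclass
class RVIResults:
    model: RVIModel
    scores: pd.Series
    reference: ControlReference
    group_contrast: dict
    symptom_association: dict | None

    def summary(self) -> str:
        c = self.group_contrast
        lines = [
            "Regional Vulnerability Index",
            f"  template:  {self.model.template.source_label} "
            f"({len(self.model.template.regions)} regions, {self.model.method})",
            f"  subjects:  {len(self.scores)} scored "
            f"({c['n_case']} cases, {c['n_control']} controls)",
            f"  contrast:  Cohen's d = {c['cohen_d']:+.3f}, t = {c['t']:+.2f}, p = {c['p']:.3g}",
        ]
        if self.symptom_association is not None:
            a = self.symptom_association
            lines.append(
                f"  severity:  Pearson r = {a['pearson_r']:+.3f}, p = {a['p']:.3g} (n = {a['n']})"
            )
        else:
            lines.append("  severity:  not available (too few severity ratings)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """RVI distributions by group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        dx = self.model.table.subjects["dx"].to_numpy(int)
        s = self.scores.to_numpy(float)
        ax.hist([s[dx == 0], s[dx == 1]], bins=20, label=["control", "case"], density=True)
        ax.set_xlabel("RVI")
        ax.legend()
        return ax

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        write_tsv(
            pd.DataFrame({"subject_id": self.scores.index, "rvi": self.scores.to_numpy()}), path
        )
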