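"""Statistics for the in vitro bud-disc sprouting assay.

Bud discs are scored on the first principal BBCH growth stages
(00/01/02/03/05; stage 00 is dormancy, 05 the beginning of root formation).
Reporting mirrors the bench convention — the sum of all final stages per
treatment x repetition, then the average over repetitions — while inference
runs on the disc-level stages: a one-way linear model (optionally with
variety as an additive factor), ANOVA, and estimated-marginal-mean (EMM)
contrasts of every treatment against the medium control with a Dunnett-style
many-to-one multiplicity adjustment (multivariate-t critical values).
Treatments with a significantly negative contrast are flagged as sprouting
inhibitors.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

ALLOWED_STAGES = {0, 1, 2, 3, 5}


class AssayError(ValueError):
    pass


@dataclasses.dataclass
class ContrastResult:
    treatment: str
    estimate: float  # EMM(treatment) - EMM(control)
    se: float
    t: float
    p_adjusted: float
    p_unadjusted: float
    inhibitor: bool
    alpha: float = 0.05


def _validate(assay: pd.DataFrame) -> pd.DataFrame:
    for col in ("treatment", "repetition", "stage"):
        if col not in assay.columns:
            raise AssayError(f"assay table missing column {col!r}")
    bad = set(assay["stage"].astype(int)) - ALLOWED_STAGES
    if bad:
        raise AssayError(f"stages outside the BBCH set {sorted(ALLOWED_STAGES)}: "
                         f"{sorted(bad)}")
    counts = assay.groupby("treatment").size()
    if (counts < 1).any():
        raise AssayError("every treatment needs >= 1 disc")
    return assay


def stage_sums(assay: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per (treatment, repetition) stage sums and per-treatment repetition
    averages."""
    assay = _validate(assay)
    sums = (assay.groupby(["treatment", "repetition"])["stage"]
            .sum().rename("stage_sum").reset_index())
    averages = sums.groupby("treatment")["stage_sum"].mean()
    return sums, averages


def _dunnett_adjust(t_stats: np.ndarray, corr: np.ndarray, df: int
                    ) -> np.ndarray:
    """Two-sided many-to-one adjusted p-values.

    p_adj(i) = P(max_j |T_j| >= |t_i|) under the joint multivariate-t of the
    contrast statistics with correlation ``corr`` and ``df`` degrees of
    freedom.
    """
    mvt = stats.multivariate_t(shape=corr, df=df, allow_singular=True)
    out = np.empty_like(t_stats, dtype=float)
    for i, t in enumerate(np.abs(t_stats)):
        lower = np.full(len(t_stats), -t)
        upper = np.full(len(t_stats), t)
        inside = mvt.cdf(upper, lower_limit=lower)
        out[i] = min(1.0, max(1 - inside, 0.0))
    return out


def estimated_marginal_means(model, assay: pd.DataFrame) -> pd.Series:
    """EMM per treatment: model predictions with the treatment forced to each
    level, averaged over the observed values of every other factor.  Equals
    the arithmetic group mean in a balanced one-factor design."""
    out = {}
    for t in sorted(assay["treatment"].unique()):
        frame = assay.copy()
        frame["treatment"] = t
        out[t] = float(model.predict(frame).mean())
    return pd.Series(out, name="emm")


def fit_and_contrast(assay: pd.DataFrame, control: str = "TSB10",
                     adjust: str = "dunnett", alpha: float = 0.05,
                     include_variety: bool = False
                     ) -> tuple[pd.DataFrame, list[ContrastResult]]:
    """One-way linear model, ANOVA and treatment-vs-control EMM contrasts.

    Returns the ANOVA table (statsmodels type-II) and one
    :class:`ContrastResult` per non-control treatment.  In the balanced
    one-factor case EMMs equal the arithmetic group means and the unadjusted
    t equals the textbook pooled two-sample statistic.
    """
    assay = _validate(assay).copy()
    assay["stage"] = assay["stage"].astype(float)
    treatments = sorted(assay["treatment"].unique())
    if control not in treatments:
        raise AssayError(f"control treatment {control!r} absent "
                         f"(present: {treatments})")
    if len(treatments) < 2:
        raise AssayError("need >= 2 treatments")
    if (assay.groupby("treatment").size() < 2).any():
        raise AssayError("need >= 2 discs per treatment for inference")
    formula = "stage ~ C(treatment)"
    if include_variety and assay["variety"].nunique() > 1:
        formula += " + C(variety)"
    model = smf.ols(formula, data=assay).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    # a constant response has no variance to partition: report F = 0, p = 1
    if np.allclose(assay["stage"].var(ddof=0), 0.0):
        anova.loc[anova.index != "Residual", "F"] = 0.0
        anova.loc[anova.index != "Residual", "PR(>F)"] = 1.0

    # contrast vectors in design space for SEs and their joint correlation
    contrast_rows = []
    names = [t for t in treatments if t != control]
    import patsy
    design_info = model.model.data.design_info
    for t in names:
        frame_t = assay.copy()
        frame_t["treatment"] = t
        frame_c = assay.copy()
        frame_c["treatment"] = control
        dt = np.asarray(patsy.dmatrix(design_info, frame_t)).mean(axis=0)
        dc = np.asarray(patsy.dmatrix(design_info, frame_c)).mean(axis=0)
        contrast_rows.append(dt - dc)
    cmat = np.vstack(contrast_rows)
    cov = cmat @ model.cov_params().to_numpy() @ cmat.T
    est = cmat @ model.params.to_numpy()
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    df = int(model.df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    p_un = np.where(se > 0, 2 * stats.t.sf(np.abs(tstat), df), 1.0)
    if adjust == "dunnett":
        safe = np.where(se > 0, se, 1.0)
        corr = cov / np.outer(safe, safe)
        np.fill_diagonal(corr, 1.0)
        p_adj = _dunnett_adjust(tstat, corr, df)
    elif adjust == "bonferroni":
        p_adj = np.minimum(p_un * len(names), 1.0)
    elif adjust == "none":
        p_adj = p_un.copy()
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    p_adj = np.maximum(p_adj, p_un)  # adjusted p can never undercut raw p

    results = [ContrastResult(
        treatment=t, estimate=float(est[i]), se=float(se[i]),
        t=float(tstat[i]), p_adjusted=float(p_adj[i]),
        p_unadjusted=float(p_un[i]),
        inhibitor=bool(est[i] < 0 and p_adj[i] < alpha), alpha=alpha)
        for i, t in enumerate(names)]
    return anova, results
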