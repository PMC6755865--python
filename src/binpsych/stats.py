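"""Group-level statistics: correlations with FDR control, partial
correlations, power, ANCOVA with backward elimination, and the
Baron-Kenny mediation path model.

All analyses operate on per-participant values (repeated measurements
averaged first) with the study's transform set: Trail Making times and
the JNDs are log-transformed; age, PTA_LF, MoCA and the IPD frequency
limit enter untransformed.  Multiple testing uses the
Benjamini-Yekutieli step-up procedure, which controls the false
discovery rate under arbitrary dependence via the harmonic factor
c(m) = sum_{i<=m} 1/i; the corrected values are reported as q values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable, TRAITS

__all__ = [
    "StatsReport",
    "analysis_frame",
    "correlation_matrix",
    "by_adjust",
    "partial_correlation",
    "power_pearson",
    "ancova_backward",
    "mediation",
    "moca_education_adjust",
]

# analysis-scale variables: name -> (source column, log?)
ANALYSIS_VARIABLES = {
    "age": ("age", False),
    "pta_lf": ("pta_lf", False),
    "moca": ("moca", False),
    "tma_time": ("tma_time", True),
    "tmb_time": ("tmb_time", True),
    "tmb_minus_tma": ("tmb_minus_tma", False),
    "ipd_fl": ("ipd_fl", False),
    "ipd_jnd": ("ipd_jnd", True),
    "ild_jnd_level_rove": ("ild_jnd_level_rove", True),
    "int_jnd": ("int_jnd", True),
}


def analysis_frame(table: CohortTable) -> pd.DataFrame:
    """Per-participant analysis-scale frame.

    Repeated measurements are averaged per participant before the log
    transforms are applied to the times and JNDs.
    """
    avg = table.averaged_estimates()
    df = table.participants.set_index("participant").copy()
    for col in avg.columns:
        df[col] = avg[col]
    out = pd.DataFrame(index=df.index)
    for name, (src, log) in ANALYSIS_VARIABLES.items():
        if src not in df:
            continue
        out[name] = np.log(df[src]) if log else df[src]
    return out


def by_adjust(pvals) -> np.ndarray:
    """Benjamini-Yekutieli q values (step-up with c(m), capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


@dataclass
class StatsReport:
    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    flags: list = field(default_factory=list)
    partial_r: pd.DataFrame | None = None
    partial_p: pd.DataFrame | None = None
    partial_q: pd.DataFrame | None = None

    def to_json(self) -> str:
        import json

        payload = {"r": self.r.to_dict(), "p": self.p.to_dict(),
                   "q": self.q.to_dict(), "flags": self.flags}
        if self.partial_r is not None:
            payload["partial_r"] = self.partial_r.to_dict()
        return json.dumps(payload)


def _pairwise(df: pd.DataFrame, func):
    cols = list(df.columns)
    n = len(cols)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    flags = []
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            sub = df[[cols[i], cols[j]]].dropna()
            if sub[cols[i]].std() == 0 or sub[cols[j]].std() == 0:
                flags.append(f"constant column in pair ({cols[i]}, {cols[j]})")
                continue
            r[i, j], p[i, j] = func(sub[cols[i]].values, sub[cols[j]].values)
            r[j, i], p[j, i] = r[i, j], p[i, j]
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols), flags)


def _q_matrix(p: pd.DataFrame) -> pd.DataFrame:
    cols = list(p.columns)
    iu = np.triu_indices(len(cols), k=1)
    pvec = p.values[iu]
    mask = np.isfinite(pvec)
    qvec = np.full_like(pvec, np.nan)
    if mask.any():
        qvec[mask] = by_adjust(pvec[mask])
    q = np.full(p.shape, np.nan)
    q[iu] = qvec
    q.T[iu] = qvec
    np.fill_diagonal(q, 0.0)
    return pd.DataFrame(q, index=cols, columns=cols)


def correlation_matrix(table: CohortTable | pd.DataFrame,
                       variables=None) -> StatsReport:
    """Pearson correlations with two-sided p and Benjamini-Yekutieli q.

    Accepts either a cohort table (averaged and transformed here) or a
    ready analysis-scale frame.
    """
    df = table if isinstance(table, pd.DataFrame) else analysis_frame(table)
    if variables is not None:
        df = df[list(variables)]
    if len(df.dropna()) < 3:
        raise ValueError("need at least 3 complete rows")
    r, p, flags = _pairwise(df, sps.pearsonr)
    return StatsReport(r, p, _q_matrix(p), flags)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation(table, pair, controls=("age", "pta_lf")):
    """Pearson correlation of ``pair`` after regressing both variables
    on the controls; p via t with n - 2 - #controls df."""
    df = table if isinstance(table, pd.DataFrame) else analysis_frame(table)
    cols = list(pair) + list(controls)
    sub = df[cols].dropna()
    n, k = len(sub), len(controls)
    if n <= k + 2:
        raise ValueError("need n > #controls + 2 complete rows")
    x = sub[list(controls)].values
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < k + 1:
        raise ValueError("rank-deficient control set")
    res_a = _residualize(sub[pair[0]].values, x)
    res_b = _residualize(sub[pair[1]].values, x)
    tol_a = 1e-10 * max(sub[pair[0]].std(), 1.0)
    tol_b = 1e-10 * max(sub[pair[1]].std(), 1.0)
    if res_a.std() <= tol_a or res_b.std() <= tol_b:
        # a variable is (numerically) explained by the controls
        return float("nan"), float("nan")
    r = float(np.corrcoef(res_a, res_b)[0, 1])
    dfree = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dfree / (1.0 - r**2))
    p = float(2 * sps.t.sf(abs(t), dfree))
    return r, p


def partial_correlation_matrix(table, controls=("age", "pta_lf"),
                               variables=None) -> StatsReport:
    df = table if isinstance(table, pd.DataFrame) else analysis_frame(table)
    if variables is None:
        variables = [c for c in df.columns if c not in controls]
    cols = list(variables)
    n = len(cols)
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j], p[i, j] = partial_correlation(df, (cols[i], cols[j]),
                                                   controls)
            r[j, i], p[j, i] = r[i, j], p[i, j]
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return StatsReport(rdf, pdf, _q_matrix(pdf))


def power_pearson(r: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power to detect a correlation of size ``r`` at sample
    size ``n`` via the Fisher z approximation."""
    if not 0 < abs(r) < 1:
        raise ValueError("need 0 < |r| < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    z = abs(np.arctanh(r)) * np.sqrt(n - 3)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    return float(sps.norm.cdf(z - zcrit) + sps.norm.cdf(-z - zcrit))


@dataclass
class AncovaResult:
    retained: list
    eliminated: list            # (name, p at elimination), in drop order
    model: object               # statsmodels results (final fit)
    anova: pd.DataFrame | None
    r_squared: float
    collinear: bool = False


def ancova_backward(table, response: str, candidates,
                    alpha: float = 0.05) -> AncovaResult:
    """OLS backward elimination: iteratively drop the least-significant
    candidate (largest p > alpha) until all remaining are significant."""
    df = table if isinstance(table, pd.DataFrame) else analysis_frame(table)
    cols = [response] + list(candidates)
    sub = df[cols].dropna()

    collinear = False
    design = sub[list(candidates)].values
    if len(candidates) >= 1:
        full = np.column_stack([np.ones(len(sub)), design])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            collinear = True
        # a candidate that is (nearly) the response itself is aliasing,
        # not a predictor
        for cand in candidates:
            if sub[cand].std() > 0 and sub[response].std() > 0:
                if abs(np.corrcoef(sub[cand], sub[response])[0, 1]) > 0.9999:
                    collinear = True

    remaining = list(candidates)
    eliminated = []
    model = smf.ols(f"{response} ~ 1", data=sub).fit()
    while remaining:
        formula = f"{response} ~ " + " + ".join(remaining)
        model = smf.ols(formula, data=sub).fit()
        pvals = model.pvalues.drop("Intercept")
        worst = pvals.idxmax()
        if pvals[worst] > alpha:
            eliminated.append((worst, float(pvals[worst])))
            remaining.remove(worst)
        else:
            break
    if not remaining:
        model = smf.ols(f"{response} ~ 1", data=sub).fit()
        anova = None
    else:
        anova = sm.stats.anova_lm(model, typ=2)
    return AncovaResult(remaining, eliminated, model, anova,
                        float(model.rsquared), collinear)


@dataclass
class MediationResult:
    path_c: tuple      # total effect x -> y: (coef, p)
    path_a: tuple      # x -> m
    path_b: tuple      # m -> y | x
    path_c_prime: tuple  # x -> y | m
    classification: str  # none | partial | perfect


def mediation(table, x: str = "age", m: str = "tmb_time",
              y: str = "ipd_fl", alpha: float = 0.05) -> MediationResult:
    """Baron-Kenny causal-steps mediation.

    Perfect mediation: the total effect c and paths a, b are
    significant while the direct effect c' is not once the mediator is
    controlled; partial: c' remains significant but smaller than c.
    """
    df = table if isinstance(table, pd.DataFrame) else analysis_frame(table)
    sub = df[[x, m, y]].dropna()
    if len(sub) <= 5:
        raise ValueError("need more than 5 complete rows")
    if sub[x].std() == 0 or sub[m].std() == 0 or sub[y].std() == 0:
        raise ValueError("degenerate variance")

    fit_c = smf.ols(f"{y} ~ {x}", data=sub).fit()
    fit_a = smf.ols(f"{m} ~ {x}", data=sub).fit()
    fit_by = smf.ols(f"{y} ~ {x} + {m}", data=sub).fit()

    c = (float(fit_c.params[x]), float(fit_c.pvalues[x]))
    a = (float(fit_a.params[x]), float(fit_a.pvalues[x]))
    b = (float(fit_by.params[m]), float(fit_by.pvalues[m]))
    cp = (float(fit_by.params[x]), float(fit_by.pvalues[x]))

    if c[1] < alpha and a[1] < alpha and b[1] < alpha:
        if cp[1] >= alpha:
            cls = "perfect"
        elif abs(cp[0]) < abs(c[0]):
            cls = "partial"
        else:
            cls = "none"
    else:
        cls = "none"
    return MediationResult(c, a, b, cp, cls)


def moca_education_adjust(scores, low_education) -> np.ndarray:
    """Education-corrected MoCA: +1 point (max 30) for participants with
    12 or fewer years of formal education."""
    scores = np.asarray(scores, dtype=float)
    low = np.asarray(low_education, dtype=bool)
    return np.minimum(scores + low.astype(float), 30.0)
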