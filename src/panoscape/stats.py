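"""Exposure-response models and the mixed-type correlation matrix.

Two model families relate a scene's visual-pattern covariates (five per
layer: three PLANDs, DIVISION, SHDI) plus street-scale and gender controls
to the perception indicators:

* multiple linear regression for the nine continuous physiological
  indicators (six EEG performance metrics, SCR.n, SCR.Amp, HR.Avg), with
  standardized outcome and continuous covariates (dummies enter raw), a
  two-sided t-test per coefficient and an overall F-test;
* multinomial logistic regression for the three ordinal subjective ratings
  (levels 1-3, level 1 as reference: ``log[P_n/P_1] = X beta_n`` for
  n = 2, 3), Wald tests per coefficient and a likelihood-ratio test against
  the intercept-only model.

Correlations between the twelve indicators use Pearson for pairs of
continuous indicators and Spearman whenever an ordinal rating is involved,
with pairwise deletion and the three-level star convention
(* p<0.1, ** p<0.05, *** p<0.01).  No multiple-testing correction is
applied, and repeated scenes per participant are pooled, not clustered; see
the methods note for the caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .metrics import COLOR_COVARIATES, ELEMENT_COVARIATES  # noqa: F401 (re-export)

EEG_INDICATORS = ["EEG.En", "EEG.Ex", "EEG.St", "EEG.Re", "EEG.In", "EEG.Fo"]
SCR_INDICATORS = ["SCR.n", "SCR.Amp"]
PHYSIOLOGICAL = EEG_INDICATORS + SCR_INDICATORS + ["HR.Avg"]
SUBJECTIVE = ["EVA.In", "EVA.Co", "EVA.Vi"]
INDICATORS = PHYSIOLOGICAL + SUBJECTIVE

CONTROLS = ["large_street", "small_street", "gender"]

STAR_THRESHOLDS = (0.1, 0.05, 0.01)


def stars(p: float, thresholds=STAR_THRESHOLDS) -> str:
    """Significance stars: * < 0.1, ** < 0.05, *** < 0.01 (descending)."""
    if not np.isfinite(p):
        return ""
    out = ""
    for t in sorted(thresholds, reverse=True):
        if p < t:
            out += "*"
    return out


def standardize(x) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant (zero-variance) vector")
    return (x - x.mean()) / sd


def add_controls(df: pd.DataFrame) -> pd.DataFrame:
    """Expand ``street_scale`` into large/small dummies (medium = reference).

    Gender is already coded male = 1, female = 0.
    """
    out = df.copy()
    if "street_scale" in out:
        out["large_street"] = (out["street_scale"] == "large").astype(int)
        out["small_street"] = (out["street_scale"] == "small").astype(int)
    return out


def _prepare(df, covariates, outcome, include_controls):
    df = add_controls(df)
    if include_controls == "auto":
        include_controls = all(c in df.columns for c in CONTROLS)
    controls = CONTROLS if include_controls else []
    cols = list(covariates) + list(controls) + [outcome]
    data = df[cols].apply(pd.to_numeric, errors="coerce").dropna()
    return data, list(covariates), controls


def _check_rank(X: pd.DataFrame, drop_collinear: bool = False) -> pd.DataFrame:
    """Verify the design has full column rank.

    With ``drop_collinear`` the dependent columns (greedy, keeping earlier
    columns — covariates take precedence over controls) are removed with a
    warning instead of raising; small scene sets cannot identify all eight
    predictors.
    """
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return X
    if not drop_collinear:
        culprits = []
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                culprits.append(col)
        raise ValueError(f"design is rank deficient; collinear set involves {culprits}")
    keep: list[int] = []
    for j in range(arr.shape[1]):
        if np.linalg.matrix_rank(arr[:, keep + [j]]) > len(keep):
            keep.append(j)
    dropped = [c for i, c in enumerate(X.columns) if i not in keep]
    warnings.warn(f"dropping collinear design columns: {dropped}", RuntimeWarning, stacklevel=3)
    return X.iloc[:, keep]


@dataclass
class LinearFit:
    """Fitted linear exposure-response model (one outcome column of the
    physiological tables)."""

    outcome: str
    params: pd.Series
    pvalues: pd.Series
    model_p: float
    n: int
    r_squared: float
    bse: pd.Series = None
    residuals: np.ndarray = field(repr=False, default=None)


def fit_linear(
    df: pd.DataFrame,
    covariates,
    outcome: str,
    standardize_y: bool = True,
    standardize_x: bool = True,
    include_controls="auto",
    drop_collinear: bool = False,
) -> LinearFit:
    """OLS fit of one continuous indicator on the visual-pattern covariates.

    By default both the outcome and the continuous covariates are z-scored
    (so slopes are standardized coefficients, comparable across covariates)
    while dummy controls enter raw.  Records missing the outcome are dropped
    for this model only.
    """
    data, covs, controls = _prepare(df, covariates, outcome, include_controls)
    if data.shape[0] <= len(covs) + len(controls) + 1:
        raise ValueError(f"too few rows ({data.shape[0]}) for the design")
    X = pd.DataFrame(index=data.index)
    for c in covs:
        X[c] = standardize(data[c]) if standardize_x else data[c]
    for c in controls:
        X[c] = data[c].astype(float)
    X = _check_rank(X, drop_collinear)
    y = standardize(data[outcome]) if standardize_y else data[outcome].to_numpy(float)
    Xc = sm.add_constant(X, prepend=True)
    res = sm.OLS(y, Xc).fit()
    model_p = float(res.f_pvalue)
    if not np.isfinite(model_p) and res.rsquared > 1 - 1e-12:
        model_p = 0.0  # exact fit: zero residual variance
    return LinearFit(
        outcome=outcome,
        params=res.params,
        pvalues=res.pvalues,
        model_p=model_p,
        n=int(res.nobs),
        r_squared=float(res.rsquared),
        bse=res.bse,
        residuals=np.asarray(res.resid),
    )


@dataclass
class MultinomialFit:
    """Fitted multinomial logit (levels 2 and 3 vs reference level 1)."""

    outcome: str
    params: pd.DataFrame  # index: terms, columns: non-reference levels
    pvalues: pd.DataFrame
    model_p: float
    n: int
    converged: bool
    levels: list = field(default_factory=list)
    bse: pd.DataFrame = None


def fit_multinomial(
    df: pd.DataFrame,
    covariates,
    outcome: str,
    standardize_x: bool = False,
    include_controls="auto",
    maxiter: int = 200,
    drop_collinear: bool = False,
) -> MultinomialFit:
    """Maximum-likelihood multinomial logit of an ordinal 1-3 rating.

    Coefficients are reported on the raw covariate scale by default (set
    ``standardize_x=True`` to z-score continuous covariates).  The overall
    model p-value is the likelihood-ratio test against intercept-only;
    per-coefficient p-values are Wald tests.  Newton iterations start from
    zero coefficients.
    """
    data, covs, controls = _prepare(df, covariates, outcome, include_controls)
    levels = sorted(data[outcome].unique())
    if len(levels) < 2:
        raise ValueError(f"outcome {outcome} has fewer than two observed levels")
    X = pd.DataFrame(index=data.index)
    for c in covs:
        X[c] = standardize(data[c]) if standardize_x else data[c]
    for c in controls:
        X[c] = data[c].astype(float)
    X = _check_rank(X, drop_collinear)
    Xc = sm.add_constant(X, prepend=True)
    y = data[outcome].map({lvl: i for i, lvl in enumerate(levels)}).to_numpy()
    model = sm.MNLogit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=maxiter, disp=0)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        warnings.warn(
            f"multinomial fit for {outcome} did not converge in {maxiter} "
            "iterations (possible separation: check for diverging coefficients)",
            RuntimeWarning,
            stacklevel=2,
        )
    params = pd.DataFrame(
        np.asarray(res.params), index=Xc.columns, columns=levels[1:]
    )
    pvalues = pd.DataFrame(
        np.asarray(res.pvalues), index=Xc.columns, columns=levels[1:]
    )
    return MultinomialFit(
        outcome=outcome,
        params=params,
        pvalues=pvalues,
        model_p=float(res.llr_pvalue),
        n=int(res.nobs),
        converged=converged,
        levels=levels,
        bse=pd.DataFrame(np.asarray(res.bse), index=Xc.columns, columns=levels[1:]),
    )


def predicted_level_frequencies(fit: MultinomialFit, df: pd.DataFrame) -> dict:
    """Observed level frequencies implied by an intercept-only fit.

    With only an intercept, maximum likelihood reproduces the sample level
    frequencies exactly: ``P_n = exp(b0_n) / sum exp(b0_k)`` with the
    reference logit fixed at zero.
    """
    b0 = fit.params.loc["const"]
    logits = np.concatenate([[0.0], b0.to_numpy(float)])
    p = np.exp(logits) / np.exp(logits).sum()
    return {lvl: float(pi) for lvl, pi in zip(fit.levels, p)}


# ---------------------------------------------------------------------------
# Correlation matrix


@dataclass
class CorrelationTable:
    """12x12 mixed Pearson/Spearman correlation matrix with per-cell p."""

    r: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame
    n: pd.DataFrame


def correlate(
    df: pd.DataFrame,
    indicators=None,
    ordinal=None,
    min_pairs: int = 3,
) -> CorrelationTable:
    """Mixed-type correlation matrix over the perception indicators.

    Pearson for continuous x continuous pairs, Spearman whenever an ordinal
    subjective rating is involved; pairwise deletion; cells with fewer than
    ``min_pairs`` complete pairs are marked missing (NaN).
    """
    indicators = list(indicators) if indicators is not None else list(INDICATORS)
    ordinal = set(ordinal) if ordinal is not None else set(SUBJECTIVE)
    k = len(indicators)
    r = pd.DataFrame(np.eye(k), index=indicators, columns=indicators)
    p = pd.DataFrame(np.zeros((k, k)), index=indicators, columns=indicators)
    meth = pd.DataFrame("", index=indicators, columns=indicators)
    n = pd.DataFrame(0, index=indicators, columns=indicators)
    for i, a in enumerate(indicators):
        n.loc[a, a] = int(df[a].notna().sum())
        for b in indicators[i + 1:]:
            pair = df[[a, b]].apply(pd.to_numeric, errors="coerce").dropna()
            use_spearman = a in ordinal or b in ordinal
            meth.loc[a, b] = meth.loc[b, a] = "spearman" if use_spearman else "pearson"
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < min_pairs:
                rv, pv = np.nan, np.nan
            elif use_spearman:
                rv, pv = sps.spearmanr(pair[a], pair[b])
            else:
                rv, pv = sps.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return CorrelationTable(r=r, p=p, method=meth, n=n)


# ---------------------------------------------------------------------------
# Table rendering


def tidy_linear(fits: list[LinearFit]) -> pd.DataFrame:
    """Long-format summary of linear fits (one row per term per outcome)."""
    rows = []
    for f in fits:
        for term in f.params.index:
            rows.append(
                {
                    "outcome": f.outcome,
                    "term": term,
                    "beta": f.params[term],
                    "p": f.pvalues[term],
                    "stars": stars(f.pvalues[term]),
                    "model_p": f.model_p,
                    "n": f.n,
                }
            )
    return pd.DataFrame(rows)


def tidy_multinomial(fits: list[MultinomialFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        for level in f.params.columns:
            for term in f.params.index:
                rows.append(
                    {
                        "outcome": f.outcome,
                        "level": level,
                        "term": term,
                        "beta": f.params.loc[term, level],
                        "p": f.pvalues.loc[term, level],
                        "stars": stars(f.pvalues.loc[term, level]),
                        "model_p": f.model_p,
                        "n": f.n,
                    }
                )
    return pd.DataFrame(rows)


def render_linear(fits: list[LinearFit]) -> str:
    """Human-readable table: predictors as rows, outcomes as columns, cells
    ``beta stars``, with a final overall-significance row."""
    terms = [t for t in fits[0].params.index if t != "const"]
    header = ["Indicator"] + [f.outcome for f in fits]
    lines = ["\t".join(header)]
    for term in terms:
        cells = [f"{f.params[term]:.3f} {stars(f.pvalues[term])}".strip() for f in fits]
        lines.append("\t".join([term] + cells))
    sig = [f"{f.model_p:.3f} {stars(f.model_p)}".strip() for f in fits]
    lines.append("\t".join(["Model Sig."] + sig))
    return "\n".join(lines) + "\n"


def render_multinomial(fits: list[MultinomialFit]) -> str:
    terms = [t for t in fits[0].params.index if t != "const"]
    header = ["Indicator"]
    for f in fits:
        header += [f"{f.outcome} = {lvl}" for lvl in f.params.columns]
    lines = ["\t".join(header)]
    for term in terms:
        cells = []
        for f in fits:
            for lvl in f.params.columns:
                b, pv = f.params.loc[term, lvl], f.pvalues.loc[term, lvl]
                cells.append(f"{b:.3f} {stars(pv)}".strip())
        lines.append("\t".join([term] + cells))
    sig = []
    for f in fits:
        sig.append(f"{f.model_p:.3f} {stars(f.model_p)}".strip())
        sig += [""] * (len(f.params.columns) - 1)
    lines.append("\t".join(["Model Sig."] + sig))
    lines.append("(reference category of the dependent variable is 1)")
    return "\n".join(lines) + "\n"


def render_correlation(table: CorrelationTable) -> str:
    """Lower-triangle rendering with stars, unit diagonal."""
    names = list(table.r.index)
    lines = ["\t".join(["Indicators"] + names)]
    for i, a in enumerate(names):
        cells = []
        for j, b in enumerate(names):
            if j > i:
                cells.append("")
            elif i == j:
                cells.append("1")
            else:
                rv, pv = table.r.loc[a, b], table.p.loc[a, b]
                cells.append("NA" if not np.isfinite(rv) else f"{rv:.3f} {stars(pv)}".strip())
        lines.append("\t".join([a] + cells))
    return "\n".join(lines) + "\n"
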