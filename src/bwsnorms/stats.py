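"""Correlation, collinearity and regression battery for norm tables.

The battery reproduces the standard analysis chain for a new norm variable:

* a Spearman correlation matrix over all variables, reordered by
  average-linkage hierarchical clustering on ``1 - |rho|`` (cluster-map
  order);
* iterative variance-inflation-factor (VIF) pruning of predictors, removing
  the worst offender until all VIFs sit below a cutoff (default 4);
* per-variable regressions of specificity on each covariate, fitting both a
  linear and a quadratic form and selecting by BIC — a quadratic win
  signals an extremum at mid-scale, the signature of basic-level effects;
* reaction-time models: specificity alone, concreteness alone, the
  specificity x concreteness interaction, the full post-VIF predictor set,
  and abstract/concrete subset refits;
* an ablation over the significant predictors of the full model, reporting
  each variable's increment ``r2(full) - r2(full minus variable)`` on a
  fixed row set (deltas are non-negative for nested least squares).

All fits are ordinary least squares (the identity-covariance special case
of generalized least squares); no correlation or heteroscedasticity
structure is imposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionReport",
    "VifReport",
    "AblationReport",
    "correlation_matrix",
    "vif",
    "vif_prune",
    "fit_and_select",
    "rt_regressions",
    "ablation",
]


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------


def correlation_matrix(
    norms: pd.DataFrame,
    method: str = "spearman",
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise correlations with a clustering order.

    Returns ``(matrix, order)`` where the matrix rows/columns are reordered
    by average-linkage hierarchical clustering on distance ``1 - |rho|``.
    Constant columns yield undefined correlations; they are logged and
    excluded from the clustering (and from the returned matrix).
    """
    if len(norms) < 3:
        raise ValueError("need at least 3 rows to correlate")
    constant = [c for c in norms.columns if norms[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("constant columns excluded from correlation: %s", constant)
    use = norms.drop(columns=constant)
    corr = use.corr(method=method)
    if corr.shape[0] <= 2:
        return corr, list(corr.columns)
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # guard tiny asymmetries
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [corr.columns[i] for i in hierarchy.leaves_list(link)]
    return corr.loc[order, order], order


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------


@dataclass
class VifReport:
    """Iterative VIF pruning trace."""

    initial: pd.Series
    removal_sequence: list[tuple[str, float]]
    final: pd.Series
    retained: list[str]
    cutoff: float

    @property
    def max_final(self) -> float:
        return float(self.final.max())

    @property
    def mean_final(self) -> float:
        return float(self.final.mean())


def vif(norms: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """VIF_j = 1 / (1 - R^2_j) from regressing j on the other predictors.

    A perfectly collinear predictor gets ``inf``.
    """
    predictors = list(predictors)
    data = norms[predictors].dropna()
    out = {}
    for j in predictors:
        others = [c for c in predictors if c != j]
        if not others:
            out[j] = 1.0
            continue
        X = sm.add_constant(data[others].to_numpy(dtype=float))
        r2 = sm.OLS(data[j].to_numpy(dtype=float), X).fit().rsquared
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_prune(
    norms: pd.DataFrame,
    predictors: Sequence[str],
    cutoff: float = 4.0,
) -> VifReport:
    """Remove the max-VIF predictor until every VIF is at or below ``cutoff``.

    Exact collinearity (VIF = inf) is removed first, deterministically
    (alphabetical tie-break on equal VIFs).
    """
    retained = list(predictors)
    data = norms[retained].dropna()
    if len(data) < len(retained) + 2:
        raise ValueError(
            f"need at least p + 2 = {len(retained) + 2} complete rows, have {len(data)}"
        )
    initial = vif(norms, retained)
    removal: list[tuple[str, float]] = []
    current = initial
    while len(retained) > 1 and float(current.max()) > cutoff:
        worst_val = current.max()
        worst = sorted(current[current == worst_val].index)[0]
        removal.append((worst, float(worst_val)))
        retained.remove(worst)
        current = vif(norms, retained)
    return VifReport(
        initial=initial,
        removal_sequence=removal,
        final=current,
        retained=retained,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------


@dataclass
class RegressionReport:
    """Fitted-model summary: selected form plus both candidate fits."""

    response: str
    predictors: list[str]
    form: str  # "linear" | "quadratic"
    coef: pd.Series
    pvalues: pd.Series
    r2: float
    bic: float
    n: int
    fits: dict[str, dict] = field(default_factory=dict)  # per-form r2/bic/coef/pvalues

    def stars(self) -> pd.Series:
        """Significance markers: ``*`` p < 0.05, ``**`` p < 0.01."""
        return self.pvalues.map(lambda p: "**" if p < 0.01 else ("*" if p < 0.05 else ""))


def _design(
    df: pd.DataFrame, predictors: Sequence[str], quadratic: Sequence[str] = ()
) -> pd.DataFrame:
    X = df[list(predictors)].astype(float).copy()
    for q in quadratic:
        X[f"{q}^2"] = X[q] ** 2
    X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(
            f"singular design matrix (rank {rank} < {X.shape[1]}); "
            f"most collinear columns: {worst}"
        )


def _fit(df: pd.DataFrame, response: str, X: pd.DataFrame):
    model = sm.OLS(df[response].astype(float), X)
    return model.fit()


def fit_and_select(
    df: pd.DataFrame,
    response: str,
    predictors: Sequence[str] | str,
    quadratic: Sequence[str] | None = None,
    forms: Sequence[str] = ("linear", "quadratic"),
) -> RegressionReport:
    """Fit linear and quadratic forms, select the one with lower BIC.

    The quadratic form adds a squared term for every predictor named in
    ``quadratic`` (default: all predictors). Both fits are retained in
    ``fits``; coefficients carry two-sided p-values.
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    predictors = list(predictors)
    if quadratic is None:
        quadratic = predictors
    rows = df[[response, *predictors]].dropna()
    if len(rows) <= len(predictors) + 2:
        raise ValueError(f"n = {len(rows)} too small for p = {len(predictors)} predictors")

    fits: dict[str, dict] = {}
    results = {}
    for form in forms:
        quad = quadratic if form == "quadratic" else ()
        X = _design(rows, predictors, quad)
        _check_rank(X)
        res = _fit(rows, response, X)
        results[form] = res
        fits[form] = {
            "r2": float(res.rsquared),
            "bic": float(res.bic),
            "coef": res.params,
            "pvalues": res.pvalues,
        }
    chosen = min(fits, key=lambda f: fits[f]["bic"])
    res = results[chosen]
    return RegressionReport(
        response=response,
        predictors=predictors,
        form=chosen,
        coef=res.params,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        bic=float(res.bic),
        n=int(res.nobs),
        fits=fits,
    )


def _linear_report(
    rows: pd.DataFrame, response: str, columns: Sequence[str], check_rank: bool = True
) -> RegressionReport:
    X = _design(rows, columns)
    if check_rank:
        _check_rank(X)
    res = _fit(rows, response, X)
    return RegressionReport(
        response=response,
        predictors=list(columns),
        form="linear",
        coef=res.params,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        bic=float(res.bic),
        n=int(res.nobs),
        fits={"linear": {"r2": float(res.rsquared), "bic": float(res.bic),
                         "coef": res.params, "pvalues": res.pvalues}},
    )


def rt_regressions(
    rt: pd.DataFrame,
    norms: pd.DataFrame,
    model: str,
    rt_col: str = "rt_ms",
    specificity: str = "specificity",
    concreteness: str = "concreteness",
    predictors: Sequence[str] | None = None,
    class_col: str = "class",
    vif_cutoff: float = 4.0,
    min_coverage: int = 30,
):
    """Reaction-time models against the norm table.

    ``rt`` needs columns ``word`` and ``rt_col``; it is inner-joined to
    ``norms`` (indexed by word) with listwise deletion per model. Models:

    - ``spec_only`` / ``conc_only``: one predictor, linear-vs-quadratic by
      BIC;
    - ``interaction``: ``rt ~ spec + conc + spec:conc``;
    - ``full``: the post-VIF predictor set (``predictors`` if given,
      otherwise all norm columns pruned at ``vif_cutoff``);
    - ``subset``: the full model minus concreteness refitted separately on
      rows whose ``class_col`` is ``abstract`` or ``concrete`` (predictors
      re-checked for VIF within each subset); returns a dict of reports.
    """
    joined = rt.set_index("word").join(norms, how="inner")
    if len(joined) < min_coverage:
        logger.warning("rt/norms join covers only %d words", len(joined))

    if model == "spec_only":
        return fit_and_select(joined.dropna(subset=[rt_col, specificity]), rt_col, [specificity])
    if model == "conc_only":
        return fit_and_select(joined.dropna(subset=[rt_col, concreteness]), rt_col, [concreteness])
    if model == "interaction":
        rows = joined.dropna(subset=[rt_col, specificity, concreteness]).copy()
        inter = f"{specificity}:{concreteness}"
        rows[inter] = rows[specificity] * rows[concreteness]
        return _linear_report(rows, rt_col, [specificity, concreteness, inter])
    if model in ("full", "subset"):
        if predictors is None:
            candidates = [c for c in norms.columns if c != class_col]
            rows_all = joined.dropna(subset=[rt_col, *candidates])
            predictors = vif_prune(rows_all, candidates, cutoff=vif_cutoff).retained
        predictors = list(predictors)
        if model == "full":
            rows = joined.dropna(subset=[rt_col, *predictors])
            return _linear_report(rows, rt_col, predictors)
        # subset: drop concreteness (the stimuli are pre-labelled by it)
        sub_preds = [p for p in predictors if p != concreteness]
        out: dict[str, RegressionReport] = {}
        rows = joined.dropna(subset=[rt_col, *sub_preds])
        out["all"] = _linear_report(rows, rt_col, sub_preds)
        if class_col not in joined.columns:
            raise ValueError(f"subset model requires a {class_col!r} column")
        for label in ("abstract", "concrete"):
            part = rows[rows[class_col] == label] if class_col in rows.columns else rows.iloc[0:0]
            keep = vif_prune(part, sub_preds, cutoff=vif_cutoff).retained
            out[label] = _linear_report(part, rt_col, keep)
        return out
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------


@dataclass
class AblationReport:
    """Per-variable increment of the full model over its leave-one-out fits."""

    full_r2: float
    deltas: pd.Series  # sorted descending
    sub_r2: pd.Series
    n: int


def ablation(
    rt: pd.DataFrame,
    norms: pd.DataFrame,
    predictors: Sequence[str],
    rt_col: str = "rt_ms",
) -> AblationReport:
    """``delta_j = r2(all) - r2(all minus j)`` on one fixed row set.

    The full model's listwise-complete rows are reused for every sub-model,
    so the deltas are guaranteed non-negative (nested least squares).
    """
    predictors = list(predictors)
    joined = rt.set_index("word").join(norms, how="inner")
    rows = joined.dropna(subset=[rt_col, *predictors])
    # rank is not enforced here: an exactly redundant predictor is a valid
    # ablation input (its delta is zero) and pinv-based OLS handles it
    full = _linear_report(rows, rt_col, predictors, check_rank=False)
    sub_r2 = {}
    for j in predictors:
        others = [p for p in predictors if p != j]
        sub_rows = rows.dropna(subset=[rt_col, *others])
        if len(sub_rows) != len(rows):
            raise ValueError(
                f"sub-model for {j!r} would use {len(sub_rows)} rows vs "
                f"{len(rows)} in the full model"
            )
        sub_r2[j] = (
            _linear_report(sub_rows, rt_col, others, check_rank=False).r2 if others else 0.0
        )
    sub = pd.Series(sub_r2, name="r2_without")
    deltas = (full.r2 - sub).clip(lower=0.0).sort_values(ascending=False).rename("delta")
    return AblationReport(full_r2=full.r2, deltas=deltas, sub_r2=sub, n=full.n)
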