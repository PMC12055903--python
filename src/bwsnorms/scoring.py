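"""Validation and scoring of best-worst judgments.

The scoring chain mirrors the standard counting approach for best-worst
scaling: sessions failing an attention check are excluded, check trials are
stripped, and each word's raw score is::

    raw(w) = (#times chosen best - #times chosen worst) / #appearances

which lies in [-1, 1]. Published scores are the min-max rescaling of the
raw scores over the scored vocabulary, so the most generic word maps to 0
and the most specific to 1 (the convention under which the extreme items
attain the bounds exactly). Reliability is quantified by the split-half
procedure: the sessions of every tuple are repeatedly partitioned into two
halves, each half is scored, and the two half-scores are correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CheckTuple

logger = logging.getLogger(__name__)

__all__ = [
    "JudgmentSet",
    "ReliabilityResult",
    "validate_session",
    "validate_sessions",
    "exclusion_rate",
    "minmax_scale",
    "bws_scores",
    "split_half_reliability",
    "read_judgments",
    "write_judgments",
]

RECORD_COLUMNS = ["session_id", "rater_id", "list_id", "tuple_id", "is_check", "best", "worst"]


@dataclass
class JudgmentSet:
    """Per-session best/worst records plus an optional validity flag.

    ``records`` columns: ``session_id rater_id list_id tuple_id is_check
    best worst``. ``valid`` (if set) is a boolean Series indexed by
    session_id, produced by :func:`validate_sessions`.
    """

    records: pd.DataFrame
    valid: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"judgment records missing columns: {missing}")
        same = self.records["best"] == self.records["worst"]
        if bool(same.any()):
            bad = self.records.loc[same, "tuple_id"].head(3).tolist()
            raise ValueError(f"best == worst in records for tuples {bad}")

    @property
    def sessions(self) -> list[str]:
        return list(pd.unique(self.records["session_id"]))

    def valid_records(self, include_checks: bool = False) -> pd.DataFrame:
        """Records of valid sessions (all sessions if never validated)."""
        df = self.records
        if self.valid is not None:
            keep = df["session_id"].map(self.valid).fillna(False).astype(bool)
            df = df[keep]
        if not include_checks:
            df = df[df["is_check"] == 0]
        return df


@dataclass
class ReliabilityResult:
    """Split-half reliability summary over ``n_iterations`` random splits."""

    n_iterations: int
    pearson_mean: float
    pearson_sd: float
    spearman_mean: float
    spearman_sd: float
    per_pool: pd.DataFrame  # index pool; columns pearson_mean/sd, spearman_mean/sd
    iterations: pd.DataFrame  # per-iteration pearson/spearman, overall

    def round_table(self, decimals: int = 2) -> pd.DataFrame:
        """Report-style table with correlations rounded to ``decimals``."""
        rows = self.per_pool.copy()
        overall = pd.DataFrame(
            {
                "pearson_mean": [self.pearson_mean],
                "pearson_sd": [self.pearson_sd],
                "spearman_mean": [self.spearman_mean],
                "spearman_sd": [self.spearman_sd],
            },
            index=["all"],
        )
        return pd.concat([rows, overall]).round(decimals)


def validate_session(
    answers: Mapping[str, tuple[str, str]],
    checks: Mapping[str, CheckTuple],
    assigned: Iterable[str] | None = None,
) -> bool:
    """Check one session's answers on its attention-check trials.

    ``answers`` maps check tuple_id -> (best form, worst form). The session
    passes iff for *every* assigned check the picked best outranks the
    picked worst on the check's generic-to-specific scale — a non-strict
    criterion: the picks need not be the extremes. A missing answer counts
    as a failure (logged).
    """
    assigned = list(assigned) if assigned is not None else list(answers)
    for tuple_id in assigned:
        if tuple_id not in answers:
            logger.warning("missing answer for check %s: treated as fail", tuple_id)
            return False
        check = checks[tuple_id]
        best, worst = answers[tuple_id]
        if check.rank_of(best) <= check.rank_of(worst):
            return False
    return True


def validate_sessions(
    judgments: JudgmentSet,
    checks: Mapping[str, CheckTuple],
    assigned_by_list: Mapping[str, Sequence[str]] | None = None,
) -> pd.Series:
    """Validate every session; returns a bool Series indexed by session_id.

    ``assigned_by_list`` (list_id -> check tuple_ids) lets missing check
    answers be detected; without it only answered checks are verified.
    The result is also stored on ``judgments.valid``.
    """
    df = judgments.records
    answers_by_session: dict[str, dict[str, tuple[str, str]]] = {}
    list_of_session: dict[str, str] = {}
    for r in df.itertuples(index=False):
        list_of_session.setdefault(r.session_id, r.list_id)
        if r.is_check:
            answers_by_session.setdefault(r.session_id, {})[r.tuple_id] = (r.best, r.worst)
    result = {}
    for session_id in pd.unique(df["session_id"]):
        answers = answers_by_session.get(session_id, {})
        if assigned_by_list is not None:
            assigned = assigned_by_list.get(list_of_session[session_id], [])
        else:
            assigned = list(answers)
        result[session_id] = validate_session(answers, checks, assigned)
    valid = pd.Series(result, name="valid")
    judgments.valid = valid
    n_fail = int((~valid).sum())
    logger.info(
        "validated %d sessions: %d excluded (%.2f%%)",
        len(valid),
        n_fail,
        100.0 * n_fail / max(len(valid), 1),
    )
    return valid


def exclusion_rate(n_excluded: int, n_sessions: int) -> float:
    """Percentage of excluded sessions, reported to two decimals."""
    if n_sessions <= 0:
        raise ValueError("n_sessions must be > 0")
    if not 0 <= n_excluded <= n_sessions:
        raise ValueError("n_excluded must lie in [0, n_sessions]")
    return round(100.0 * n_excluded / n_sessions, 2)


def minmax_scale(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Affine rescale to [0, 1]; rejects constant input (scaling undefined)."""
    arr = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        raise ValueError("cannot min-max scale a constant vector")
    return (arr - lo) / (hi - lo)


def bws_scores(
    judgments: JudgmentSet,
    tuple_items: Mapping[str, Sequence[str]],
    rescale: bool = True,
) -> pd.DataFrame:
    """Aggregate valid non-check judgments into per-word scores.

    ``tuple_items`` maps tuple_id -> the words shown in that tuple; every
    judgment on a tuple counts one appearance for each of its words.
    Returns a DataFrame indexed by word with ``raw`` in [-1, 1] and (when
    ``rescale``) ``score`` = min-max over the scored vocabulary. Words
    with zero appearances are absent from the output.
    """
    df = judgments.valid_records(include_checks=False)
    if df.empty:
        raise ValueError("no valid non-check judgments to score")
    best = df["best"].value_counts()
    worst = df["worst"].value_counts()
    appearances: dict[str, int] = {}
    tuple_counts = df["tuple_id"].value_counts()
    for tuple_id, n in tuple_counts.items():
        items = tuple_items.get(tuple_id)
        if items is None:
            raise KeyError(f"tuple {tuple_id!r} missing from tuple_items")
        for w in items:
            appearances[w] = appearances.get(w, 0) + int(n)
    app = pd.Series(appearances, name="appearances").sort_index()
    raw = (
        best.reindex(app.index, fill_value=0) - worst.reindex(app.index, fill_value=0)
    ) / app
    out = pd.DataFrame({"appearances": app, "raw": raw})
    out.index.name = "word"
    if rescale:
        out["score"] = minmax_scale(out["raw"])
    return out


def _split_halves(
    df: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly split each tuple's judgments into two near-equal halves.

    With an odd per-tuple count the extra record lands in either half with
    equal probability.
    """
    key = rng.random(len(df))
    order = df.assign(_key=key).sort_values(["tuple_id", "_key"], kind="stable")
    pos = order.groupby("tuple_id", sort=False).cumcount()
    size = order.groupby("tuple_id", sort=False)["tuple_id"].transform("size")
    cut = size // 2 + (size % 2) * (rng.random(len(order)) < 0.5).astype(int)
    in_a = pos < cut
    return order[in_a].drop(columns="_key"), order[~in_a].drop(columns="_key")


def split_half_reliability(
    judgments: JudgmentSet,
    tuple_items: Mapping[str, Sequence[str]],
    n_iter: int = 100,
    seed: int = 0,
    tuple_pools: Mapping[str, str] | None = None,
) -> ReliabilityResult:
    """Average split-half reliability (SHR) over ``n_iter`` random splits.

    Each iteration partitions the sessions of every tuple into two halves,
    scores each half, and records the Pearson and Spearman correlation of
    the two half-scores over the common vocabulary. Requires at least two
    valid judgments per tuple. With ``tuple_pools`` (tuple_id -> pool) the
    correlations are additionally computed within each pool, scoring that
    pool's judgments alone.
    """
    df = judgments.valid_records(include_checks=False)
    counts = df["tuple_id"].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"{len(thin)} tuples have fewer than 2 valid sessions "
            f"(e.g. {thin.index[:3].tolist()}); split-half reliability undefined"
        )
    rng = np.random.default_rng(seed)
    pools = sorted(set(tuple_pools.values())) if tuple_pools else []
    rows = []
    for it in range(n_iter):
        half_a, half_b = _split_halves(df, rng)
        rec = {"iteration": it}
        scopes: list[tuple[str, pd.DataFrame, pd.DataFrame]] = [("all", half_a, half_b)]
        for pool in pools:
            ids = {t for t, p in tuple_pools.items() if p == pool}
            scopes.append(
                (pool, half_a[half_a["tuple_id"].isin(ids)], half_b[half_b["tuple_id"].isin(ids)])
            )
        for label, a, b in scopes:
            sa = bws_scores(JudgmentSet(records=a), tuple_items, rescale=False)["raw"]
            sb = bws_scores(JudgmentSet(records=b), tuple_items, rescale=False)["raw"]
            common = sa.index.intersection(sb.index)
            pr = sps.pearsonr(sa.loc[common], sb.loc[common]).statistic
            sr = sps.spearmanr(sa.loc[common], sb.loc[common]).statistic
            rec[f"pearson_{label}"] = pr
            rec[f"spearman_{label}"] = sr
        rows.append(rec)
    iters = pd.DataFrame(rows).set_index("iteration")
    per_pool = pd.DataFrame(
        {
            "pearson_mean": [iters[f"pearson_{p}"].mean() for p in pools],
            "pearson_sd": [iters[f"pearson_{p}"].std(ddof=0) for p in pools],
            "spearman_mean": [iters[f"spearman_{p}"].mean() for p in pools],
            "spearman_sd": [iters[f"spearman_{p}"].std(ddof=0) for p in pools],
        },
        index=pools,
    )
    return ReliabilityResult(
        n_iterations=n_iter,
        pearson_mean=float(iters["pearson_all"].mean()),
        pearson_sd=float(iters["pearson_all"].std(ddof=0)),
        spearman_mean=float(iters["spearman_all"].mean()),
        spearman_sd=float(iters["spearman_all"].std(ddof=0)),
        per_pool=per_pool,
        iterations=iters,
    )


def read_judgments(path: str | Path) -> JudgmentSet:
    """Read a judgments CSV (``session_id,rater_id,list_id,tuple_id,is_check,best,worst``)."""
    df = pd.read_csv(path, dtype={"session_id": str, "rater_id": str, "list_id": str, "tuple_id": str})
    if "is_check" not in df.columns:
        df["is_check"] = 0
    return JudgmentSet(records=df[RECORD_COLUMNS])


def write_judgments(judgments: JudgmentSet, path: str | Path) -> None:
    judgments.records.to_csv(path, index=False)
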