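"""Synthetic ground truth for end-to-end testing of the norming pipeline.

Real specificity norms come from crowdsourced best-worst judgments; this
module generates a *latent world* — a true specificity scale plus correlated
psycholinguistic covariates — and simulates the observable data the pipeline
consumes: rater choices and per-word reaction times. Because the latent
scale is known, downstream stages (scoring, reliability, regressions) can be
checked for recovery rather than merely for not crashing.

Covariates are drawn from a Gaussian copula whose correlation targets are
specified on the Spearman scale (the scale used throughout the analyses) and
converted to the Gaussian scale via ``r = 2 sin(pi * rho / 6)``; marginals
are mapped to [0, 1] by the empirical rank transform, which preserves ranks
exactly and attains both bounds.

Rater choices follow a Thurstonian model: each trial the rater perceives a
utility ``u(w) = specificity(w) + Normal(0, noise_sd)`` per word and picks
the argmax as "most specific" and the argmin as "most generic". In the
noiseless limit the picks equal the latent extremes. A *careless* rater
ignores the words entirely and picks an ordered (best, worst) pair uniformly
among the ``k * (k - 1)`` possibilities — which makes the power of the
attention-check exclusion rule measurable (pass probability of one 4-word
check is exactly 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .design import BwsTuple, CheckTuple, Questionnaire, TupleSet
from .scoring import JudgmentSet

__all__ = [
    "DEFAULT_VARIABLES",
    "DEFAULT_TARGET_SPEARMAN",
    "DEFAULT_RT_COEFFICIENTS",
    "DEFAULT_RT_INTERCEPT",
    "DEFAULT_RT_NOISE_SD",
    "LatentWorld",
    "RaterProfile",
    "InfeasibleCorrelationError",
    "sample_world",
    "make_raters",
    "simulate_judgments",
    "simulate_latencies",
    "sample_taxonomy_files",
    "perturb_norms",
]

#: Variables of the norming study: the latent specificity scale plus the
#: eight psycholinguistic covariates it is compared against.
DEFAULT_VARIABLES = (
    "specificity",
    "concreteness",
    "valence",
    "arousal",
    "dominance",
    "imageability",
    "familiarity",
    "aoa",
    "frequency",
)

# Target Spearman correlations. The specificity row and the strong
# covariate-covariate pairs (valence-dominance, concreteness-imageability)
# follow the correlation structure reported for the ANEW-based norms; the
# remaining entries are modest values consistent with published norm sets.
_S = {
    ("specificity", "concreteness"): 0.552,
    ("specificity", "valence"): -0.173,
    ("specificity", "arousal"): -0.049,
    ("specificity", "dominance"): -0.216,
    ("specificity", "imageability"): 0.50,
    ("specificity", "familiarity"): -0.228,
    ("specificity", "aoa"): 0.0,
    ("specificity", "frequency"): -0.475,
    ("concreteness", "valence"): -0.10,
    ("concreteness", "arousal"): -0.15,
    ("concreteness", "dominance"): -0.05,
    ("concreteness", "imageability"): 0.88,
    ("concreteness", "familiarity"): -0.05,
    ("concreteness", "aoa"): -0.10,
    ("concreteness", "frequency"): -0.15,
    ("valence", "arousal"): -0.15,
    ("valence", "dominance"): 0.833,
    ("valence", "imageability"): -0.05,
    ("valence", "familiarity"): 0.15,
    ("valence", "aoa"): -0.10,
    ("valence", "frequency"): 0.10,
    ("arousal", "dominance"): -0.20,
    ("arousal", "imageability"): -0.05,
    ("arousal", "familiarity"): -0.05,
    ("arousal", "aoa"): 0.05,
    ("arousal", "frequency"): -0.05,
    ("dominance", "imageability"): -0.05,
    ("dominance", "familiarity"): 0.20,
    ("dominance", "aoa"): -0.10,
    ("dominance", "frequency"): 0.15,
    ("imageability", "familiarity"): 0.10,
    ("imageability", "aoa"): -0.35,
    ("imageability", "frequency"): 0.05,
    ("familiarity", "aoa"): -0.40,
    ("familiarity", "frequency"): 0.60,
    ("aoa", "frequency"): -0.45,
}


def _default_spearman() -> pd.DataFrame:
    p = len(DEFAULT_VARIABLES)
    mat = pd.DataFrame(
        np.eye(p), index=list(DEFAULT_VARIABLES), columns=list(DEFAULT_VARIABLES)
    )
    for (a, b), rho in _S.items():
        mat.loc[a, b] = rho
        mat.loc[b, a] = rho
    return mat


DEFAULT_TARGET_SPEARMAN = _default_spearman()

#: Default RT generating model (ms per unit of each [0,1]-scaled predictor),
#: patterned on the full lexical-decision regression for the large
#: university-lab megastudy: strong positive age-of-acquisition effect,
#: strong negative frequency/familiarity effects, small specificity and
#: concreteness effects.
DEFAULT_RT_COEFFICIENTS: dict[str, float] = {
    "specificity": 33.583,
    "concreteness": -18.973,
    "valence": -8.031,
    "arousal": -28.647,
    "dominance": -10.073,
    "familiarity": -60.070,
    "aoa": 119.139,
    "frequency": -122.684,
}
DEFAULT_RT_INTERCEPT = 650.0
DEFAULT_RT_NOISE_SD = 50.0


class InfeasibleCorrelationError(ValueError):
    """Raised when the target correlation matrix admits no Gaussian copula."""


@dataclass
class LatentWorld:
    """Ground truth behind a simulated norming study.

    ``specificity`` holds the true latent scale on [0, 1]; ``covariates``
    the correlated psycholinguistic variables, also on [0, 1].
    """

    specificity: pd.Series
    covariates: pd.DataFrame
    target_spearman: pd.DataFrame
    rt_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RT_COEFFICIENTS)
    )
    rt_intercept: float = DEFAULT_RT_INTERCEPT
    rt_noise_sd: float = DEFAULT_RT_NOISE_SD

    @property
    def words(self) -> list[str]:
        return list(self.specificity.index)

    @property
    def table(self) -> pd.DataFrame:
        """All latent variables, specificity first, one row per word."""
        return pd.concat([self.specificity.rename("specificity"), self.covariates], axis=1)

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.rename_axis("word").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LatentWorld":
        """Read a world table TSV (``word specificity var1 ... varM``)."""
        df = pd.read_csv(path, sep="\t", dtype={"word": str}).set_index("word")
        if "specificity" not in df.columns:
            raise ValueError("world table must have a 'specificity' column")
        variables = list(df.columns)
        return cls(
            specificity=df["specificity"],
            covariates=df.drop(columns=["specificity"]),
            target_spearman=pd.DataFrame(
                np.eye(len(variables)), index=variables, columns=variables
            ),
        )


@dataclass(frozen=True)
class RaterProfile:
    """One simulated annotator: utility noise level and carelessness flag."""

    rater_id: str
    noise_sd: float = 0.1
    careless: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def spearman_to_pearson(rho: np.ndarray) -> np.ndarray:
    """Gaussian-copula correlation reproducing a target Spearman matrix."""
    return 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)


def _rank_to_unit(x: np.ndarray) -> np.ndarray:
    """Empirical rank transform to [0, 1] (attains both bounds)."""
    n = len(x)
    if n == 0:
        return x
    if n == 1:
        return np.array([0.5])
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(n)
    return ranks / (n - 1)


def sample_world(
    n_words: int,
    variables: Sequence[str] | None = None,
    target_spearman: pd.DataFrame | None = None,
    seed: int = 0,
    words: Sequence[str] | None = None,
) -> LatentWorld:
    """Draw a latent world of ``n_words`` with the requested rank structure.

    The realized pairwise Spearman correlations land within about ±0.1 of
    the targets for ``n_words >= 500``. Raises
    :class:`InfeasibleCorrelationError` when the target matrix is not
    positive semi-definite after conversion to the Gaussian scale.
    """
    if target_spearman is None:
        target_spearman = DEFAULT_TARGET_SPEARMAN
    if variables is None:
        variables = list(target_spearman.columns)
    target_spearman = target_spearman.loc[list(variables), list(variables)]
    mat = target_spearman.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise InfeasibleCorrelationError("target Spearman matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise InfeasibleCorrelationError("target Spearman matrix must have unit diagonal")

    pearson = spearman_to_pearson(mat)
    np.fill_diagonal(pearson, 1.0)
    eigval, eigvec = np.linalg.eigh(pearson)
    if eigval.min() < -1e-8:
        raise InfeasibleCorrelationError(
            "target correlation matrix is not positive semi-definite after "
            f"rank-to-Gaussian conversion (min eigenvalue {eigval.min():.4g})"
        )
    factor = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))

    if words is None:
        words = [f"w{i:04d}" for i in range(n_words)]
    elif len(words) != n_words:
        raise ValueError("len(words) must equal n_words")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_words, len(variables))) @ factor.T
    unit = np.column_stack([_rank_to_unit(z[:, j]) for j in range(z.shape[1])]) if n_words else z
    table = pd.DataFrame(unit, index=pd.Index(list(words), name="word"),
                         columns=list(variables))

    spec_name = variables[0]
    return LatentWorld(
        specificity=table[spec_name].rename("specificity"),
        covariates=table.drop(columns=[spec_name]),
        target_spearman=target_spearman,
    )


def make_raters(
    n: int,
    noise_sd: float = 0.1,
    careless_rate: float = 0.0,
    seed: int = 0,
) -> list[RaterProfile]:
    """Build ``n`` rater profiles; each is careless with prob ``careless_rate``."""
    rng = np.random.default_rng(seed)
    flags = rng.random(n) < careless_rate
    return [
        RaterProfile(rater_id=f"r{i:04d}", noise_sd=noise_sd, careless=bool(flags[i]))
        for i in range(n)
    ]


def _as_questionnaires(
    design: Union[TupleSet, Sequence[Questionnaire]],
) -> list[Questionnaire]:
    if isinstance(design, TupleSet):
        return [Questionnaire(list_id="l001", trials=list(design.tuples))]
    return list(design)


def simulate_judgments(
    design: Union[TupleSet, Sequence[Questionnaire]],
    world: LatentWorld,
    raters: Sequence[RaterProfile],
    per_tuple: int = 10,
    seed: int = 0,
) -> JudgmentSet:
    """Simulate ``per_tuple`` complete sessions for every questionnaire.

    Every trial of a questionnaire — experimental tuples and attention
    checks alike — is answered in each of its sessions, so each tuple
    receives exactly ``per_tuple`` judgments. Raters are assigned to
    sessions round-robin in a seeded random order.
    """
    if per_tuple < 1:
        raise ValueError("per_tuple must be >= 1")
    if not raters:
        raise ValueError("need at least one rater profile")
    questionnaires = _as_questionnaires(design)
    spec = world.specificity
    for q in questionnaires:
        for trial in q.trials:
            for item in trial.items:
                if item.form not in spec.index:
                    raise ValueError(
                        f"word {item.form!r} (trial {trial.tuple_id}) not in world"
                    )

    rng = np.random.default_rng(seed)
    rater_order = rng.permutation(len(raters))
    rows = []
    session_no = 0
    cursor = 0
    for q in questionnaires:
        for _ in range(per_tuple):
            session_no += 1
            rater = raters[rater_order[cursor % len(raters)]]
            cursor += 1
            session_id = f"s{session_no:05d}"
            for trial in q.trials:
                k = len(trial.items)
                forms = [it.form for it in trial.items]
                if rater.careless:
                    b = int(rng.integers(0, k))
                    w = int(rng.integers(0, k - 1))
                    if w >= b:
                        w += 1
                else:
                    u = spec.loc[forms].to_numpy(dtype=float)
                    if rater.noise_sd > 0:
                        u = u + rng.normal(0.0, rater.noise_sd, size=k)
                    # ties broken by a seeded random preference order
                    pref = rng.permutation(k)
                    b = int(max(range(k), key=lambda i: (u[i], pref[i])))
                    w = int(min(range(k), key=lambda i: (u[i], pref[i])))
                rows.append(
                    {
                        "session_id": session_id,
                        "rater_id": rater.rater_id,
                        "list_id": q.list_id,
                        "tuple_id": trial.tuple_id,
                        "is_check": int(isinstance(trial, CheckTuple)),
                        "best": forms[b],
                        "worst": forms[w],
                    }
                )
    return JudgmentSet(records=pd.DataFrame(rows))


def simulate_latencies(
    world: LatentWorld,
    coefficients: Mapping[str, float] | None = None,
    intercept: float | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-word reaction times from a linear model on the latents.

    ``RT(w) = intercept + sum_v coeff_v * value_v(w) + Normal(0, noise_sd)``.
    Returns a DataFrame with columns ``word`` and ``rt_ms``.
    """
    coefficients = dict(world.rt_coefficients if coefficients is None else coefficients)
    intercept = world.rt_intercept if intercept is None else intercept
    noise_sd = world.rt_noise_sd if noise_sd is None else noise_sd
    table = world.table
    missing = [v for v in coefficients if v not in table.columns]
    if missing:
        raise ValueError(f"rt coefficients refer to unknown variables: {missing}")
    rng = np.random.default_rng(seed)
    rt = np.full(len(table), float(intercept))
    for var, coeff in coefficients.items():
        rt += coeff * table[var].to_numpy(dtype=float)
    if noise_sd > 0:
        rt += rng.normal(0.0, noise_sd, size=len(table))
    return pd.DataFrame({"word": table.index, "rt_ms": rt}).reset_index(drop=True)


def sample_taxonomy_files(
    world: LatentWorld,
    seed: int = 0,
    max_depth: int = 20,
    depth_noise: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a synthetic hypernym taxonomy consistent with the latent scale.

    Emits (edges, senses) DataFrames in the edge-list / sense-list layout
    the taxonomy module reads. Nodes form a single root-to-leaf chain
    ``n00 -> n01 -> ... `` (child -> parent edges point rootward); each word
    gets one sense at a depth increasing with its latent specificity plus
    integer noise, so taxonomy-derived specificity correlates with — but
    does not equal — the latent scale. The map is convex (depth grows with
    the square of specificity), mimicking the left-skew of expert-taxonomy
    depths relative to behavioural scales.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"n{d:02d}" for d in range(max_depth)]
    edges = pd.DataFrame(
        {"child": nodes[1:], "parent": nodes[:-1]}
    )
    spec = world.specificity
    depth = np.rint(spec.to_numpy() ** 2 * (max_depth - 2)).astype(int)
    if depth_noise > 0:
        depth = depth + rng.integers(-depth_noise, depth_noise + 1, size=len(depth))
    depth = np.clip(depth, 0, max_depth - 1)
    senses = pd.DataFrame(
        {"word": spec.index, "sense_rank": 1, "node": [nodes[d] for d in depth]}
    )
    return edges, senses


def perturb_norms(
    table: pd.DataFrame,
    shifts: Mapping[str, float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a second population rating the same items on the same scales.

    Adds a per-variable systematic shift plus independent Gaussian noise,
    then clips to [0, 1] — a simple model of cross-language scale-use
    differences between populations norming translation equivalents.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    shifts = shifts or {}
    for col in out.columns:
        vals = out[col].to_numpy(dtype=float)
        vals = vals + float(shifts.get(col, 0.0)) + rng.normal(0.0, noise_sd, size=len(vals))
        out[col] = np.clip(vals, 0.0, 1.0)
    return out
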