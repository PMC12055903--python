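"""End-to-end orchestration: design -> simulate -> score -> analyse -> report.

``run_pipeline`` wires every stage together under a single seed and writes a
deterministic artifact tree (TSV/CSV/JSON) plus a manifest with versions,
the seed, and per-stage row counts. ``make_fixtures`` emits the small
hand-checkable toy study used throughout the test suite.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import design as dz
from . import scoring, stats, synthetic_world as sw, taxonomy as tx
from . import crosslingual as xl

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "make_fixtures",
           "DEFAULT_SCALE_SHIFTS", "read_norms", "write_norms"]

#: Per-variable systematic shifts applied to the simulated second-language
#: population (language b minus language a), patterned on the mean rating
#: differences observed between the Italian and English ANEW norm sets:
#: the second population rates arousal much higher and specificity,
#: concreteness and familiarity lower.
DEFAULT_SCALE_SHIFTS: dict[str, float] = {
    "valence": 0.001,
    "dominance": -0.014,
    "frequency": 0.026,
    "aoa": -0.041,
    "imageability": 0.042,
    "concreteness": -0.051,
    "familiarity": -0.057,
    "specificity": -0.068,
    "arousal": 0.154,
}


@dataclass
class RunConfig:
    """Parameters of one full synthetic norming run."""

    seed: int = 0
    n_words: int = 100
    k: int = 4
    factor: int = 2
    max_per_list: int = 40
    n_checks: int = 2
    per_tuple: int = 10
    n_raters: int = 0  # 0 -> one rater per session
    noise_sd: float = 0.05
    careless_rate: float = 0.0
    shr_iterations: int = 100
    vif_cutoff: float = 4.0
    max_depth: int = 20
    language_a: str = "en"
    language_b: str = "it"
    pos_shares: tuple[float, float, float] = (0.6, 0.2, 0.2)  # noun, verb, adjective
    out_dir: str | None = None

    def validate(self) -> None:
        positive = ["n_words", "k", "factor", "max_per_list", "per_tuple",
                    "shr_iterations", "max_depth"]
        for name in positive:
            if getattr(self, name) < 1:
                raise ValueError(f"config field {name!r} must be >= 1")
        for name in ["n_checks", "n_raters"]:
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name!r} must be >= 0")
        if not 0 <= self.careless_rate <= 1:
            raise ValueError("config field 'careless_rate' must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("config field 'noise_sd' must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` config file (one pair per line)."""
        kwargs: dict = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("out_dir", "language_a", "language_b"):
                kwargs[key] = value
            elif key == "pos_shares":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("noise_sd", "careless_rate", "vif_cutoff"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory handles on everything one run produced."""

    config: RunConfig
    world: sw.LatentWorld
    tuple_set: dz.TupleSet
    questionnaires: list
    judgments: scoring.JudgmentSet
    exclusion_pct: float
    norms: pd.DataFrame
    reliability: scoring.ReliabilityResult | None
    taxonomy_comparison: tx.DistributionComparison
    correlations: pd.DataFrame
    vif_report: stats.VifReport
    covariate_regressions: dict[str, stats.RegressionReport]
    rt: pd.DataFrame
    rt_models: dict
    ablation_report: stats.AblationReport
    pairing: xl.BilingualPairing
    deltas: pd.DataFrame
    scale_use: xl.ScaleUseReport
    manifest: dict


def _assign_pos(words: list[str], shares, k: int) -> dict[str, str]:
    n = len(words)
    n_noun = int(round(shares[0] * n))
    n_verb = int(round(shares[1] * n))
    counts = {"noun": n_noun, "verb": n_verb, "adjective": n - n_noun - n_verb}
    if min(counts.values()) < k:  # tiny lexicons stay single-pool
        return {w: "noun" for w in words}
    pos_map = {}
    i = 0
    for pos in ("noun", "verb", "adjective"):
        for w in words[i : i + counts[pos]]:
            pos_map[w] = pos
        i += counts[pos]
    return pos_map


def _make_checks(world: sw.LatentWorld, lexicon: list[dz.WordItem], k: int,
                 n_chains: int, seed: int) -> list[dz.CheckTuple]:
    """Attention-check chains from words spread along the latent scale.

    Words are picked at well-separated specificity quantiles within the
    largest pool so the generic-to-specific ordering is unambiguous to an
    attentive (low-noise) simulated rater.
    """
    by_form = {w.form: w for w in lexicon}
    spec = world.specificity.loc[[w.form for w in lexicon]].sort_values()
    n = len(spec)
    if n < k:
        raise ValueError(f"world has {n} words; cannot build {k}-word checks")
    checks = []
    for c in range(n_chains):
        pos = np.linspace(0.05 * (n - 1), 0.95 * (n - 1), k) + c
        idx = np.clip(np.round(pos).astype(int), 0, n - 1)
        for j in range(1, k):  # enforce strictly increasing latent positions
            if idx[j] <= idx[j - 1]:
                idx[j] = idx[j - 1] + 1
        if idx[-1] > n - 1:  # tiny worlds: fall back to the top-k band
            idx = np.arange(n - k, n)
        chain = [by_form[spec.index[i]] for i in idx]
        checks.append(dz.make_attention_check(chain, tuple_id=f"c{c + 1:03d}", seed=seed + c))
    return checks


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage of the synthetic study described by ``config``.

    Stages run in order with seeds derived from ``config.seed``; any stage
    failure propagates with its diagnostic. When ``config.out_dir`` is set
    the artifact tree is written there.
    """
    config.validate()
    seed = config.seed

    # 1. latent world and lexicon
    world = sw.sample_world(config.n_words, seed=seed)
    pos_map = _assign_pos(world.words, config.pos_shares, config.k)
    lexicon = [dz.WordItem(w, pos_map[w], config.language_a) for w in world.words]

    # 2. design
    tuple_set = dz.generate_tuples(lexicon, k=config.k, factor=config.factor, seed=seed + 1)
    checks = _make_checks(world, lexicon, config.k, max(config.n_checks * 2, 4), seed + 2)
    questionnaires = dz.build_questionnaires(
        tuple_set, config.max_per_list, checks, config.n_checks, seed=seed + 3
    )

    # 3. simulated annotation
    n_sessions = len(questionnaires) * config.per_tuple
    n_raters = config.n_raters or n_sessions
    raters = sw.make_raters(n_raters, config.noise_sd, config.careless_rate, seed + 4)
    judgments = sw.simulate_judgments(questionnaires, world, raters, config.per_tuple, seed + 5)

    # 4. validation and scoring
    check_map = {c.tuple_id: c for c in checks}
    assigned = {q.list_id: [c.tuple_id for c in q.checks] for q in questionnaires}
    valid = scoring.validate_sessions(judgments, check_map, assigned)
    excl = scoring.exclusion_rate(int((~valid).sum()), len(valid))
    items_map = tuple_set.items_map()
    scores = scoring.bws_scores(judgments, items_map)
    tuple_pools = {t.tuple_id: t.pool for t in tuple_set.tuples}
    try:
        reliability = scoring.split_half_reliability(
            judgments, items_map, n_iter=config.shr_iterations, seed=seed + 6,
            tuple_pools=tuple_pools,
        )
    except ValueError as err:
        logger.warning("split-half reliability skipped: %s", err)
        reliability = None

    # 5. norm table
    norms = pd.DataFrame(
        {
            "pos": pd.Series({w.form: w.pos for w in lexicon}),
            "language": config.language_a,
            "specificity_raw": scores["raw"],
            "specificity": scores["score"],
        }
    ).join(world.covariates)
    norms.index.name = "word"

    # 6. taxonomy comparison (nouns only, shared vocabulary, both rescaled)
    edges, senses = sw.sample_taxonomy_files(world, seed=seed + 7, max_depth=config.max_depth)
    taxonomy = tx.Taxonomy.from_edges(edges, senses, max_depth=config.max_depth)
    nouns = [w for w, p in pos_map.items() if p == "noun"]
    wn = tx.specificity_table(nouns, taxonomy)["wn_specificity"]
    shared = norms.loc[norms.index.intersection(wn.index)]
    bws_col = pd.Series(
        scoring.minmax_scale(shared["specificity_raw"]), index=shared.index
    )
    wn_col = pd.Series(scoring.minmax_scale(wn.loc[shared.index]), index=shared.index)
    taxonomy_comparison = tx.compare_specificity_sources(bws_col, wn_col)

    # 7. correlation / collinearity / covariate regressions
    variable_cols = ["specificity", *world.covariates.columns]
    corr, _ = stats.correlation_matrix(norms[variable_cols])
    vif_report = stats.vif_prune(norms, variable_cols, cutoff=config.vif_cutoff)
    covariate_regressions = {
        var: stats.fit_and_select(norms, var, ["specificity"])
        for var in world.covariates.columns
    }

    # 8. reaction-time battery
    rt = sw.simulate_latencies(world, seed=seed + 8)
    predictors = [p for p in vif_report.retained]
    norms_rt = norms.copy()
    norms_rt["class"] = np.where(
        norms_rt["concreteness"] >= norms_rt["concreteness"].median(), "concrete", "abstract"
    )
    rt_models = {
        "spec_only": stats.rt_regressions(rt, norms_rt, "spec_only"),
        "conc_only": stats.rt_regressions(rt, norms_rt, "conc_only"),
        "interaction": stats.rt_regressions(rt, norms_rt, "interaction"),
        "full": stats.rt_regressions(rt, norms_rt, "full", predictors=predictors),
        "subset": stats.rt_regressions(rt, norms_rt, "subset", predictors=predictors,
                                       vif_cutoff=config.vif_cutoff),
    }
    full_report = rt_models["full"]
    significant = [
        p for p in full_report.predictors if full_report.pvalues.get(p, 1.0) < 0.05
    ] or full_report.predictors
    ablation_report = stats.ablation(rt, norms_rt, significant)

    # 9. cross-lingual comparison against a simulated second population
    table_a = norms[variable_cols]
    table_b = sw.perturb_norms(table_a, shifts=DEFAULT_SCALE_SHIFTS, noise_sd=0.05,
                               seed=seed + 9)
    table_b.index = [f"{w}_{config.language_b}" for w in table_b.index]
    mapping = pd.DataFrame({"word_a": table_a.index, "word_b": table_b.index})
    pairing = xl.pair_norms(table_a, table_b, mapping,
                            language_a=config.language_a, language_b=config.language_b)
    deltas = xl.specificity_deltas(pairing)
    scale_use = xl.scale_use_comparison(pairing)

    manifest = {
        "seed": seed,
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "words": len(world.words),
            "tuples": len(tuple_set),
            "questionnaires": len(questionnaires),
            "sessions": int(len(valid)),
            "sessions_excluded": int((~valid).sum()),
            "judgments": int(len(judgments.records)),
            "scored_words": int(len(scores)),
            "taxonomy_shared_words": taxonomy_comparison.n,
            "translation_pairs": len(pairing),
        },
        "exclusion_pct": excl,
    }

    result = PipelineResult(
        config=config, world=world, tuple_set=tuple_set, questionnaires=questionnaires,
        judgments=judgments, exclusion_pct=excl, norms=norms, reliability=reliability,
        taxonomy_comparison=taxonomy_comparison, correlations=corr,
        vif_report=vif_report, covariate_regressions=covariate_regressions,
        rt=rt, rt_models=rt_models, ablation_report=ablation_report,
        pairing=pairing, deltas=deltas, scale_use=scale_use, manifest=manifest,
    )
    if config.out_dir:
        write_artifacts(result, Path(config.out_dir))
    return result


def _report_json(report: stats.RegressionReport) -> dict:
    return {
        "response": report.response,
        "predictors": report.predictors,
        "form": report.form,
        "coef": {k: round(float(v), 6) for k, v in report.coef.items()},
        "pvalues": {k: round(float(v), 6) for k, v in report.pvalues.items()},
        "r2": round(report.r2, 6),
        "bic": round(report.bic, 3),
        "n": report.n,
    }


def write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    """Write the deterministic artifact tree for one run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    dz.write_design(result.questionnaires, out_dir / "design.tsv", k=result.config.k)
    scoring.write_judgments(result.judgments, out_dir / "judgments.csv")
    write_norms(result.norms, out_dir / "norms.tsv")
    if result.reliability is not None:
        result.reliability.round_table().to_csv(out_dir / "reliability.tsv", sep="\t")
        result.reliability.iterations.round(6).to_json(
            out_dir / "reliability_iterations.jsonl", orient="records", lines=True
        )
    result.taxonomy_comparison.table().round(6).to_csv(out_dir / "taxonomy_comparison.tsv", sep="\t")
    result.correlations.round(6).to_csv(out_dir / "correlations.tsv", sep="\t")
    result.deltas.round(6).to_csv(out_dir / "crosslingual_deltas.tsv", sep="\t", index=False)
    result.scale_use.table.round(6).to_csv(out_dir / "scale_use.tsv", sep="\t", index=False)
    with open(out_dir / "vif.json", "w") as fh:
        json.dump(
            {
                "initial": result.vif_report.initial.round(6).to_dict(),
                "removed": result.vif_report.removal_sequence,
                "final": result.vif_report.final.round(6).to_dict(),
                "retained": result.vif_report.retained,
            },
            fh, indent=2,
        )
    models = {name: (_report_json(rep) if isinstance(rep, stats.RegressionReport)
                     else {k: _report_json(r) for k, r in rep.items()})
              for name, rep in result.rt_models.items()}
    models["covariate_regressions"] = {
        k: _report_json(r) for k, r in result.covariate_regressions.items()
    }
    with open(out_dir / "regressions.json", "w") as fh:
        json.dump(models, fh, indent=2)
    result.ablation_report.deltas.round(6).to_csv(out_dir / "ablation.tsv", sep="\t")
    result.rt.round(3).to_csv(out_dir / "rt.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def read_norms(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="word")


def write_norms(norms: pd.DataFrame, path: str | Path) -> None:
    norms.round(6).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """A packaged toy study, small enough to verify by hand.

    Returns (and optionally writes) a bilingual lexicon, a four-level toy
    taxonomy, a two-judgment scoring example with a known closed-form
    answer, and a translation pairing with known per-word deltas.
    """
    en = [("object", "noun"), ("food", "noun"), ("fruit", "noun"), ("banana", "noun"),
          ("animal", "noun"), ("dog", "noun"), ("run", "verb"), ("eat", "verb"),
          ("think", "verb"), ("jump", "verb"), ("red", "adjective"), ("big", "adjective"),
          ("loud", "adjective"), ("soft", "adjective")]
    it = [("oggetto", "noun"), ("cibo", "noun"), ("frutta", "noun"), ("banana", "noun"),
          ("animale", "noun"), ("cane", "noun"), ("correre", "verb"), ("mangiare", "verb"),
          ("pensare", "verb"), ("saltare", "verb"), ("rosso", "adjective"),
          ("grande", "adjective"), ("forte", "adjective"), ("morbido", "adjective")]
    lexicon = [dz.WordItem(f, p, "en") for f, p in en] + [
        dz.WordItem(f, p, "it") for f, p in it
    ]

    # four-level chain: root -> food -> fruit -> banana (banana depth 3)
    edges = pd.DataFrame(
        {"child": ["food", "fruit", "banana", "animal", "dog"],
         "parent": ["object", "food", "fruit", "object", "animal"]}
    )
    senses = pd.DataFrame(
        {"word": ["object", "food", "fruit", "banana", "animal", "dog"],
         "sense_rank": 1,
         "node": ["object", "food", "fruit", "banana", "animal", "dog"]}
    )

    # two judgments over one tuple {A, B, C, D}: raw A=1, B=0, C=D=-0.5
    judgments = scoring.JudgmentSet(records=pd.DataFrame(
        {
            "session_id": ["s1", "s2"],
            "rater_id": ["r1", "r2"],
            "list_id": ["l1", "l1"],
            "tuple_id": ["t1", "t1"],
            "is_check": [0, 0],
            "best": ["A", "A"],
            "worst": ["D", "C"],
        }
    ))
    tuple_items = {"t1": ("A", "B", "C", "D")}

    # translation pairing with known specificity deltas: four high-delta
    # pairs plus two near-identical ones
    pairs = pd.DataFrame(
        {
            "word_a": ["mushroom", "absurd", "rabies", "pasta", "victim", "loyal"],
            "word_b": ["fungo", "assurdo", "rabbia", "pasta", "vittima", "leale"],
            "spec_a": [0.781, 0.672, 0.839, 0.808, 0.4452, 0.5103],
            "spec_b": [0.235, 0.152, 0.345, 0.325, 0.4447, 0.5110],
        }
    )
    norms_a = pd.DataFrame({"specificity": pairs["spec_a"].values}, index=pairs["word_a"])
    norms_b = pd.DataFrame({"specificity": pairs["spec_b"].values}, index=pairs["word_b"])
    mapping = pairs[["word_a", "word_b"]]

    fixtures = {
        "lexicon": lexicon,
        "taxonomy_edges": edges,
        "taxonomy_senses": senses,
        "judgments": judgments,
        "tuple_items": tuple_items,
        "norms_a": norms_a,
        "norms_b": norms_b,
        "mapping": mapping,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [{"form": w.form, "pos": w.pos, "language": w.language} for w in lexicon]
        ).to_csv(out_dir / "lexicon.tsv", sep="\t", index=False)
        edges.to_csv(out_dir / "taxonomy_edges.tsv", sep="\t", index=False)
        senses.to_csv(out_dir / "taxonomy_senses.tsv", sep="\t", index=False)
        scoring.write_judgments(judgments, out_dir / "judgments.csv")
        norms_a.rename_axis("word").to_csv(out_dir / "norms_a.tsv", sep="\t")
        norms_b.rename_axis("word").to_csv(out_dir / "norms_b.tsv", sep="\t")
        mapping.to_csv(out_dir / "mapping.tsv", sep="\t", index=False)
    return fixtures
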