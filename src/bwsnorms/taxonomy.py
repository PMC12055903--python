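"""Taxonomy-derived specificity and its comparison with crowdsourced scores.

A hypernym taxonomy (WordNet-like: nodes are senses, edges point from a
child sense to its hypernym) assigns each word a depth ``d`` — the shortest
hypernym-path distance from the word's *first listed sense* to the root.
The taxonomy specificity metric is::

    wn_specificity = (1 + d) / max_depth

with ``max_depth`` defaulting to 20, the conventional maximum depth of the
WordNet noun hierarchy. The score is strictly increasing in depth: a node
one edge deeper scores exactly ``1 / max_depth`` higher.

The comparison against behaviourally collected (best-worst) specificity
reports per-source descriptives, a two-sided Mann-Whitney U test of
distributional divergence, and the paired Spearman correlation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Taxonomy",
    "DistributionComparison",
    "wn_specificity",
    "specificity_table",
    "mann_whitney",
    "compare_specificity_sources",
]


@dataclass
class Taxonomy:
    """Rooted hypernym graph plus per-word ordered sense lists.

    ``graph`` holds child -> parent edges; roots are the nodes with no
    parent. ``senses[word]`` lists node ids most-salient first; only the
    first is used for specificity.
    """

    graph: nx.DiGraph
    senses: dict[str, list[str]]
    max_depth: int = 20
    _depths: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("taxonomy graph must be acyclic")
        roots = self.roots
        if not roots:
            raise ValueError("taxonomy has no root (a node with no parent)")
        for word, nodes in self.senses.items():
            if not nodes:
                raise ValueError(f"word {word!r} has an empty sense list")

    @property
    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def depth(self, node: str) -> int:
        """Shortest hypernym-path length from ``node`` to any root."""
        if node not in self.graph:
            raise KeyError(f"node {node!r} not in taxonomy")
        if not self._depths:
            # BFS rootward distances computed once on the reversed graph
            rev = self.graph.reverse(copy=False)
            dist: dict[str, int] = {}
            for root in self.roots:
                for n, d in nx.single_source_shortest_path_length(rev, root).items():
                    if n not in dist or d < dist[n]:
                        dist[n] = d
            self._depths.update(dist)
        if node not in self._depths:
            raise ValueError(f"node {node!r} does not reach a root")
        return self._depths[node]

    @classmethod
    def from_edges(
        cls,
        edges: pd.DataFrame,
        senses: pd.DataFrame,
        max_depth: int = 20,
    ) -> "Taxonomy":
        """Build from an edge list (``child parent``) and a sense table
        (``word sense_rank node``); sense lists are ordered by rank."""
        g = nx.DiGraph()
        for r in edges.itertuples(index=False):
            g.add_edge(str(r.child), str(r.parent))
        sense_map: dict[str, list[str]] = {}
        ordered = senses.sort_values(["word", "sense_rank"], kind="stable")
        for r in ordered.itertuples(index=False):
            sense_map.setdefault(str(r.word), []).append(str(r.node))
        return cls(graph=g, senses=sense_map, max_depth=max_depth)

    @classmethod
    def from_files(
        cls, edges_path: str | Path, senses_path: str | Path, max_depth: int = 20
    ) -> "Taxonomy":
        edges = pd.read_csv(edges_path, sep="\t", dtype=str)
        senses = pd.read_csv(senses_path, sep="\t", dtype={"word": str, "node": str})
        return cls.from_edges(edges, senses, max_depth=max_depth)


def wn_specificity(word: str, taxonomy: Taxonomy) -> float:
    """Taxonomy specificity ``(1 + d) / max_depth`` of the first listed sense."""
    if word not in taxonomy.senses:
        raise KeyError(f"word {word!r} has no sense in the taxonomy")
    first = taxonomy.senses[word][0]
    d = taxonomy.depth(first)
    return (1 + d) / taxonomy.max_depth


def specificity_table(
    words: Iterable[str],
    taxonomy: Taxonomy,
) -> pd.DataFrame:
    """Per-word taxonomy specificity; words absent from the taxonomy are
    skipped and logged (the comparison uses the shared vocabulary only)."""
    rows = []
    skipped = []
    for w in words:
        try:
            rows.append({"word": w, "wn_specificity": wn_specificity(w, taxonomy)})
        except KeyError:
            skipped.append(w)
    if skipped:
        logger.info("skipped %d words absent from taxonomy (e.g. %s)", len(skipped), skipped[:3])
    return pd.DataFrame(rows, columns=["word", "wn_specificity"]).set_index("word")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample ``x``: #{x_i > y_j} + 0.5 * #{x_i == y_j}."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_mw_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided p by full enumeration of group assignments of the pooled
    sample (permutation-exact, valid with ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))
    mean_u = len(x) * len(y) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    exact_threshold: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)`` with U for ``x``.

    Pooled sample sizes up to ``exact_threshold`` use exact enumeration
    (valid under ties); larger samples use the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    if n1 + n2 <= exact_threshold:
        p = _exact_mw_p(x, y, u)
    else:
        pooled = np.concatenate([x, y])
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            return u, 1.0
        z = (abs(u - n1 * n2 / 2.0) - 0.5) / math.sqrt(var_u)
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return u, min(p, 1.0)


@dataclass
class DistributionComparison:
    """Descriptives plus divergence and association of two score sources."""

    n: int
    stats_a: pd.Series  # mean, sd, q1, q2, q3
    stats_b: pd.Series
    mannwhitney_u: float
    mannwhitney_p: float
    spearman_rho: float
    spearman_p: float
    label_a: str = "bws"
    label_b: str = "taxonomy"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({self.label_a: self.stats_a, self.label_b: self.stats_b})


def _descriptives(x: pd.Series) -> pd.Series:
    return pd.Series(
        {
            "mean": x.mean(),
            "sd": x.std(ddof=0),
            "q1": x.quantile(0.25),
            "q2": x.quantile(0.50),
            "q3": x.quantile(0.75),
        }
    )


def compare_specificity_sources(
    bws: pd.Series,
    wn: pd.Series,
    label_a: str = "bws",
    label_b: str = "taxonomy",
) -> DistributionComparison:
    """Compare two specificity columns over their shared vocabulary.

    Both columns should already be min-max scaled to [0, 1]. Reports
    per-source descriptive statistics, a two-sided Mann-Whitney U test of
    the two distributions, and the paired Spearman correlation.
    """
    common = bws.index.intersection(wn.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} shared words; need at least 3")
    a = bws.loc[common].astype(float)
    b = wn.loc[common].astype(float)
    u, p_u = mann_whitney(a.to_numpy(), b.to_numpy())
    rho_res = sps.spearmanr(a, b)
    return DistributionComparison(
        n=len(common),
        stats_a=_descriptives(a),
        stats_b=_descriptives(b),
        mannwhitney_u=u,
        mannwhitney_p=p_u,
        spearman_rho=float(rho_res.statistic),
        spearman_p=float(rho_res.pvalue),
        label_a=label_a,
        label_b=label_b,
    )
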