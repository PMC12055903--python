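"""Balanced best-worst-scaling (BWS) experiment design.

A BWS study presents raters with small tuples of words (typically four) and
asks for the *most* and *least* specific item in each. This module turns a
lexicon into a balanced set of such tuples and packs them into
questionnaires with embedded attention checks.

Balance means two things, enforced per part-of-speech pool:

* every word appears in (almost) the same number of tuples — with the
  slot-multiset construction used here the appearance counts are exactly
  ``factor * k`` for every word;
* every unordered pair of words co-occurs in (almost) the same number of
  tuples — the max-min spread of pair co-occurrence counts is driven below a
  configurable tolerance (default 2) by seeded local search.

Attention checks are tuples of words chained by hyponym/hypernym relations
(e.g. *object > food > baked goods > muffin*); their unambiguous generic-to-
specific ordering is stored so scoring can later verify that a rater's
"most specific" pick outranks their "most generic" pick.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

POS_LABELS = ("noun", "verb", "adjective", "mixed")

__all__ = [
    "POS_LABELS",
    "WordItem",
    "BwsTuple",
    "CheckTuple",
    "Questionnaire",
    "TupleSet",
    "generate_tuples",
    "build_questionnaires",
    "make_attention_check",
    "read_lexicon",
    "write_design",
    "read_design",
]


@dataclass(frozen=True, order=True)
class WordItem:
    """A lexical stimulus: surface form, part-of-speech, language."""

    form: str
    pos: str = "noun"
    language: str = "en"

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError("WordItem.form must be non-empty")
        if self.pos not in POS_LABELS:
            raise ValueError(f"unknown pos {self.pos!r}; expected one of {POS_LABELS}")


@dataclass(frozen=True)
class BwsTuple:
    """One experimental trial: ``k`` distinct words drawn from one pool."""

    tuple_id: str
    items: tuple[WordItem, ...]
    pool: str

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"tuple {self.tuple_id}: repeated item")

    @property
    def forms(self) -> tuple[str, ...]:
        return tuple(w.form for w in self.items)


@dataclass(frozen=True)
class CheckTuple:
    """An attention-check trial: items plus their generic-to-specific ranks.

    ``ranks[i]`` is the rank of ``items[i]``: 1 = most generic,
    ``k`` = most specific. Ranks form a permutation of ``1..k``.
    """

    tuple_id: str
    items: tuple[WordItem, ...]
    ranks: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.items)
        if len(set(self.items)) != k:
            raise ValueError(f"check {self.tuple_id}: repeated item")
        if sorted(self.ranks) != list(range(1, k + 1)):
            raise ValueError(f"check {self.tuple_id}: ranks must be a permutation of 1..{k}")

    @property
    def forms(self) -> tuple[str, ...]:
        return tuple(w.form for w in self.items)

    def rank_of(self, form: str) -> int:
        for item, rank in zip(self.items, self.ranks):
            if item.form == form:
                return rank
        raise KeyError(f"{form!r} not in check {self.tuple_id}")


@dataclass
class Questionnaire:
    """One annotation list: experimental tuples with checks interleaved.

    ``trials`` is the presentation order; checks are distinguishable by type
    so scoring can strip them.
    """

    list_id: str
    trials: list[Union[BwsTuple, CheckTuple]] = field(default_factory=list)

    @property
    def tuples(self) -> list[BwsTuple]:
        return [t for t in self.trials if isinstance(t, BwsTuple)]

    @property
    def checks(self) -> list[CheckTuple]:
        return [t for t in self.trials if isinstance(t, CheckTuple)]

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class TupleSet:
    """The designed experiment: all generated tuples plus design parameters."""

    tuples: list[BwsTuple]
    k: int
    factor: int

    def __len__(self) -> int:
        return len(self.tuples)

    @property
    def pools(self) -> list[str]:
        return sorted({t.pool for t in self.tuples})

    def by_pool(self, pool: str) -> list[BwsTuple]:
        return [t for t in self.tuples if t.pool == pool]

    def appearance_counts(self, pool: str | None = None) -> Counter:
        """Number of tuples each word appears in (optionally one pool)."""
        tuples = self.tuples if pool is None else self.by_pool(pool)
        return Counter(w for t in tuples for w in t.items)

    def pair_counts(self, pool: str) -> Counter:
        """Co-occurrence count for every pair that appears in ``pool``."""
        counts: Counter = Counter()
        for t in self.by_pool(pool):
            for a, b in itertools.combinations(sorted(t.items), 2):
                counts[(a, b)] += 1
        return counts

    def items_map(self) -> dict[str, tuple[str, ...]]:
        return {t.tuple_id: t.forms for t in self.tuples}


# ---------------------------------------------------------------------------
# tuple generation
# ---------------------------------------------------------------------------


def _fix_duplicates(rows: np.ndarray, rng: np.random.Generator) -> None:
    """Swap items across rows until no row contains a repeated item.

    Swapping occurrences of two different items between rows preserves every
    item's total appearance count, so exact balance survives the repair.
    """
    m, k = rows.shape

    def bad_rows() -> list[int]:
        return [i for i in range(m) if len(set(rows[i].tolist())) != k]

    def try_swap(i: int) -> bool:
        row = rows[i]
        seen: set[int] = set()
        dup_positions = []
        for p, v in enumerate(row.tolist()):
            if v in seen:
                dup_positions.append(p)
            seen.add(v)
        for p in dup_positions:
            x = row[p]
            for j in rng.permutation(m):
                if j == i or x in rows[j]:
                    continue
                other = rows[j]
                candidates = [q for q in range(k) if other[q] not in row]
                if candidates:
                    q = int(rng.choice(candidates))
                    rows[i, p], rows[j, q] = other[q], x
                    return True
        return False

    for _ in range(100 * m + 1000):
        bad = bad_rows()
        if not bad:
            return
        progress = False
        for i in rng.permutation(bad):
            if try_swap(int(i)):
                progress = True
                break
        if not progress:
            # no single swap helps: pool a bad row with a random partner and
            # redeal their items (count-preserving), then keep going
            i = int(rng.choice(bad))
            j = int(rng.choice([r for r in range(m) if r != i]))
            pool = np.concatenate([rows[i], rows[j]])
            rng.shuffle(pool)
            rows[i], rows[j] = pool[:k], pool[k:]
    if bad_rows():  # pragma: no cover
        raise RuntimeError("duplicate repair failed to converge")


def _pair_counter(rows: np.ndarray) -> Counter:
    counts: Counter = Counter()
    for row in rows:
        s = sorted(row.tolist())
        for a, b in itertools.combinations(s, 2):
            counts[(a, b)] += 1
    return counts


def _spread(counts: Counter, n_words: int) -> int:
    total_pairs = n_words * (n_words - 1) // 2
    hi = max(counts.values())
    lo = 0 if len(counts) < total_pairs else min(counts.values())
    return hi - lo


def _balance_pairs(
    rows: np.ndarray,
    n_words: int,
    tol: int,
    rng: np.random.Generator,
) -> None:
    """Seeded local search driving pair co-occurrence spread down to ``tol``.

    Two phases, both count-preserving (moves swap one item between two rows):

    1. targeted repair — while some pair co-occurs more than ``lo + tol``
       times, evict one of its members from a row holding the pair; this is
       what large sparse pools need, where the minimum count is 0 and only a
       handful of pairs exceed the tolerance;
    2. random hill-climbing on the sum of squared pair counts (total fixed,
       so lowering it flattens the distribution) — needed only for small
       dense pools where the *minimum* count must also be raised.
    """
    m, k = rows.shape
    counts = _pair_counter(rows)
    total_pairs = n_words * (n_words - 1) // 2

    def pairs_with(row: np.ndarray, skip_pos: int, item: int):
        for p in range(k):
            if p == skip_pos:
                continue
            a, b = (item, int(row[p])) if item < row[p] else (int(row[p]), item)
            yield (a, b)

    def apply_swap(i: int, p: int, j: int, q: int) -> None:
        x, y = int(rows[i, p]), int(rows[j, q])
        for pr in pairs_with(rows[i], p, x):
            counts[pr] -= 1
            if counts[pr] == 0:
                del counts[pr]
        for pr in pairs_with(rows[j], q, y):
            counts[pr] -= 1
            if counts[pr] == 0:
                del counts[pr]
        rows[i, p], rows[j, q] = y, x
        for pr in pairs_with(rows[i], p, y):
            counts[pr] += 1
        for pr in pairs_with(rows[j], q, x):
            counts[pr] += 1

    def swap_delta(i: int, p: int, j: int, q: int) -> int:
        x, y = int(rows[i, p]), int(rows[j, q])
        delta = 0
        for pr in pairs_with(rows[i], p, x):
            delta += -2 * counts[pr] + 1
        for pr in pairs_with(rows[j], q, y):
            delta += -2 * counts[pr] + 1
        # simulate removals before counting additions to keep delta exact
        removed = Counter()
        for pr in pairs_with(rows[i], p, x):
            removed[pr] += 1
        for pr in pairs_with(rows[j], q, y):
            removed[pr] += 1
        for pr in pairs_with(rows[i], p, y):
            c = counts[pr] - removed[pr]
            delta += 2 * c + 1
            removed[pr] -= 1  # reuse as net-change tracker
        for pr in pairs_with(rows[j], q, x):
            c = counts[pr] - removed[pr]
            delta += 2 * c + 1
            removed[pr] -= 1
        return delta

    # phase 1: targeted eviction of over-represented pairs
    for _ in range(20 * m + 200):
        lo = 0 if len(counts) < total_pairs else min(counts.values())
        offenders = [pr for pr, c in counts.items() if c > lo + tol]
        if not offenders:
            break
        a, b = offenders[int(rng.integers(0, len(offenders)))]
        holders = [i for i in range(m) if a in rows[i] and b in rows[i]]
        i = holders[int(rng.integers(0, len(holders)))]
        x = a if rng.random() < 0.5 else b
        p = int(np.where(rows[i] == x)[0][0])
        done = False
        for j in rng.permutation(m):
            if j == i or x in rows[j]:
                continue
            for q in rng.permutation(k):
                y = int(rows[j, q])
                if y in rows[i]:
                    continue
                if swap_delta(i, p, j, q) < 0:
                    apply_swap(i, p, j, q)
                    done = True
                    break
            if done:
                break

    # phase 2: random hill-climbing (small dense pools)
    if _spread(counts, n_words) > tol:
        budget = 5000 * m
        for it in range(budget):
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            p, q = rng.integers(0, k, size=2)
            x, y = int(rows[i, p]), int(rows[j, q])
            if x == y or x in rows[j] or y in rows[i]:
                continue
            delta = swap_delta(i, p, j, q)
            if delta < 0 or (delta == 0 and rng.random() < 0.25):
                apply_swap(i, p, j, q)
            if it % 200 == 0 and _spread(counts, n_words) <= tol:
                return
    if _spread(counts, n_words) > tol:  # pragma: no cover
        raise RuntimeError(
            f"pair balancing did not reach spread <= {tol} within budget "
            f"(current spread {_spread(counts, n_words)})"
        )


def _pool_rows(n: int, k: int, factor: int, tol: int, rng: np.random.Generator) -> np.ndarray:
    """Generate ``factor * n`` rows of ``k`` distinct item indices, balanced."""
    m = factor * n
    slots = np.repeat(np.arange(n), factor * k)
    rng.shuffle(slots)
    rows = slots.reshape(m, k)
    _fix_duplicates(rows, rng)
    _balance_pairs(rows, n, tol, rng)
    return rows


def generate_tuples(
    lexicon: Sequence[WordItem],
    k: int = 4,
    factor: int = 2,
    seed: int = 0,
    pair_tolerance: int = 2,
) -> TupleSet:
    """Generate ``factor`` tuples per word, balanced within each POS pool.

    Parameters
    ----------
    lexicon
        Unique word items; words sharing a part-of-speech form one pool.
        Mixed-POS words (``pos="mixed"``) form their own pool.
    k
        Tuple size (the study default is 4).
    factor
        Tuples generated per pool equal ``factor`` times the pool size, so
        each word appears exactly ``factor * k`` times.
    seed
        Seeds the shuffle and the balancing search; identical inputs and
        seed give identical output.
    pair_tolerance
        Maximum allowed max-min spread of pair co-occurrence counts within
        a pool.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if len(set(lexicon)) != len(lexicon):
        dupes = [w for w, c in Counter(lexicon).items() if c > 1]
        raise ValueError(f"duplicate lexicon entries: {dupes[:5]}")

    pools: dict[str, list[WordItem]] = {}
    for w in lexicon:
        pools.setdefault(w.pos, []).append(w)
    for label, words in pools.items():
        if len(words) < k:
            raise ValueError(f"pool {label!r} has {len(words)} words, fewer than k={k}")

    rng = np.random.default_rng(seed)
    tuples: list[BwsTuple] = []
    counter = 0
    for label in sorted(pools):
        words = sorted(pools[label])
        rows = _pool_rows(len(words), k, factor, pair_tolerance, rng)
        for row in rows:
            counter += 1
            tuples.append(
                BwsTuple(
                    tuple_id=f"t{counter:05d}",
                    items=tuple(words[i] for i in row),
                    pool=label,
                )
            )
    return TupleSet(tuples=tuples, k=k, factor=factor)


# ---------------------------------------------------------------------------
# attention checks and questionnaire assembly
# ---------------------------------------------------------------------------


def make_attention_check(
    chain: Sequence[WordItem],
    tuple_id: str = "chk001",
    seed: int = 0,
) -> CheckTuple:
    """Build a check from a hypernym chain ordered generic -> specific.

    ``chain[i]`` receives rank ``i + 1``; the presented item order is a
    seeded shuffle of the chain so the answer is not positional.
    """
    if len(set(chain)) != len(chain):
        raise ValueError("attention-check chain contains duplicates")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chain))
    items = tuple(chain[i] for i in order)
    ranks = tuple(int(i) + 1 for i in order)
    return CheckTuple(tuple_id=tuple_id, items=items, ranks=ranks)


def _check_positions(n_trials: int, n_checks: int, rng: np.random.Generator) -> list[int]:
    """Seeded random non-adjacent slots for checks within ``n_trials`` trials."""
    if n_checks == 0:
        return []
    for _ in range(1000):
        pos = sorted(rng.choice(n_trials, size=min(n_checks, n_trials), replace=False).tolist())
        if all(b - a > 1 for a, b in zip(pos, pos[1:])):
            return [int(p) for p in pos]
    # tiny lists may admit no non-adjacent placement; fall back to spaced slots
    return sorted(set(range(0, n_trials, max(1, n_trials // max(n_checks, 1))))[:n_checks])


def build_questionnaires(
    tuple_set: TupleSet,
    max_per_list: int = 40,
    checks: Sequence[CheckTuple] = (),
    n_checks: int = 2,
    seed: int = 0,
    allow_check_reuse: bool = True,
) -> list[Questionnaire]:
    """Partition tuples into lists of at most ``max_per_list``, adding checks.

    Lists never mix pools; the list count is the sum over pools of
    ``ceil(pool_tuples / max_per_list)``. Each tuple lands in exactly one
    list. ``n_checks`` checks are injected per list at seeded random
    non-adjacent positions.
    """
    if max_per_list < 1:
        raise ValueError("max_per_list must be >= 1")
    n_lists = sum(
        math.ceil(len(tuple_set.by_pool(p)) / max_per_list) for p in tuple_set.pools
    )
    if n_checks > 0:
        if not checks:
            raise ValueError("n_checks > 0 but no CheckTuples supplied")
        if len(set(c.tuple_id for c in checks)) < n_checks:
            raise ValueError(f"need {n_checks} distinct checks per list, got {len(checks)}")
        if not allow_check_reuse and len(checks) < n_lists * n_checks:
            raise ValueError(
                f"check reuse disabled: need {n_lists * n_checks} checks, got {len(checks)}"
            )

    rng = np.random.default_rng(seed)
    questionnaires: list[Questionnaire] = []
    list_no = 0
    check_cursor = 0
    for pool in tuple_set.pools:
        pool_tuples = tuple_set.by_pool(pool)
        order = rng.permutation(len(pool_tuples))
        for start in range(0, len(pool_tuples), max_per_list):
            list_no += 1
            chunk = [pool_tuples[i] for i in order[start : start + max_per_list]]
            if allow_check_reuse:
                chosen = [checks[i] for i in rng.choice(len(checks), size=n_checks, replace=False)] if n_checks else []
            else:
                chosen = list(checks[check_cursor : check_cursor + n_checks])
                check_cursor += n_checks
            total = len(chunk) + len(chosen)
            positions = _check_positions(total, len(chosen), rng)
            trials: list[Union[BwsTuple, CheckTuple]] = []
            it = iter(chunk)
            ci = 0
            for slot in range(total):
                if ci < len(positions) and slot == positions[ci]:
                    trials.append(chosen[ci])
                    ci += 1
                else:
                    trials.append(next(it))
            questionnaires.append(Questionnaire(list_id=f"l{list_no:03d}", trials=trials))
    return questionnaires


# ---------------------------------------------------------------------------
# external interfaces (TSV)
# ---------------------------------------------------------------------------


def read_lexicon(path: str | Path) -> list[WordItem]:
    """Read a lexicon TSV with header ``form  pos  language``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"form", "pos", "language"}
    if not required.issubset(df.columns):
        raise ValueError(f"lexicon file must have columns {sorted(required)}")
    return [WordItem(r.form, r.pos, r.language) for r in df.itertuples(index=False)]


def write_design(
    questionnaires: Sequence[Questionnaire],
    path: str | Path,
    k: int,
    language: str = "en",
) -> pd.DataFrame:
    """Write the designed experiment as a trial table TSV.

    Columns: ``list_id position tuple_id pool language is_check item1..itemk
    rank1..rankk`` (rank columns empty for non-checks). Row order is the
    presentation order within each list.
    """
    rows = []
    for q in questionnaires:
        for pos_idx, trial in enumerate(q.trials):
            row: dict[str, object] = {
                "list_id": q.list_id,
                "position": pos_idx,
                "tuple_id": trial.tuple_id,
                "pool": trial.pool if isinstance(trial, BwsTuple) else "check",
                "language": trial.items[0].language,
                "is_check": int(isinstance(trial, CheckTuple)),
            }
            for i, item in enumerate(trial.items, start=1):
                row[f"item{i}"] = item.form
            if isinstance(trial, CheckTuple):
                for i, r in enumerate(trial.ranks, start=1):
                    row[f"rank{i}"] = r
            else:
                for i in range(1, k + 1):
                    row[f"rank{i}"] = ""
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_design(path: str | Path) -> list[Questionnaire]:
    """Read a trial table written by :func:`write_design`."""
    df = pd.read_csv(path, sep="\t", dtype={"list_id": str, "tuple_id": str})
    k = max(int(c[4:]) for c in df.columns if c.startswith("item"))
    questionnaires: list[Questionnaire] = []
    for list_id, grp in df.groupby("list_id", sort=True):
        grp = grp.sort_values("position")
        trials: list[Union[BwsTuple, CheckTuple]] = []
        for r in grp.itertuples(index=False):
            forms = [getattr(r, f"item{i}") for i in range(1, k + 1)]
            language = getattr(r, "language", "en")
            if int(r.is_check):
                items = tuple(WordItem(f, "noun", language) for f in forms)
                ranks = tuple(int(getattr(r, f"rank{i}")) for i in range(1, k + 1))
                trials.append(CheckTuple(tuple_id=r.tuple_id, items=items, ranks=ranks))
            else:
                pos = r.pool if r.pool in POS_LABELS else "noun"
                items = tuple(WordItem(f, pos, language) for f in forms)
                trials.append(BwsTuple(tuple_id=r.tuple_id, items=items, pool=r.pool))
        questionnaires.append(Questionnaire(list_id=str(list_id), trials=trials))
    return questionnaires
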