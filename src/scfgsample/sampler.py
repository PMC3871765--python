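"""Recursive statistical sampling of secondary structures from inside charts.

A structure is drawn top-down: the exterior loop is decomposed left to
right, every paired substructure is completed recursively, and each
decision (which alternative rule of the current nonterminal, and where to
split the fragment) is drawn from the conditional distribution obtained by
normalizing option weights

    w(rule, splits) = Pr_tr(rule) * prod(inside values of child spans)
                      * prod(emissions of terminals the rule emits here)

by their sum (``norm_alpha``).  Outside values cancel out of these
conditional distributions — for a reachable context the outside value is a
common positive factor of every option — so sampling needs only the inside
chart; :func:`build_choice_set` can optionally multiply the outside factor
back in to demonstrate the equivalence.

When the chart has been disturbed, a drawn option may be structurally
impossible (e.g. a "pair here" choice on a fragment too short to close a
hairpin).  The modified strategy never backtracks: it settles for the
partially formed substructure — the fragment is left unpaired, or a
multiloop that managed only one helix degrades to a bulge/interior-like
loop — and records a fallback event.  The output is therefore always a
valid structure.  With an exact chart, every drawn option is feasible and
no fallback can occur.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .disturbance import DisturbedInsideTable
from .grammar import (
    BULGE,
    EXTERIOR,
    HAIRPIN,
    HELIX,
    MULTI,
    GrammarSpec,
    ParamSet,
)
from .inside_outside import InsideTable, OutsideTable

__all__ = [
    "ChoiceSet",
    "SampledStructure",
    "SampleSet",
    "StructureSampler",
    "build_choice_set",
    "sample_structure",
    "sample_set",
    "option_children",
    "reachable_contexts",
]

Table = Union[InsideTable, DisturbedInsideTable]

#: symbols at which the recursive strategy takes a decision (Z only emits)
DECISION_SYMBOLS = ("S", "T", "C", "A", "P", "L", "F", "H", "G", "B", "M", "O", "N", "U")


@dataclass
class ChoiceSet:
    """The weighted, mutually exclusive options for symbol X on span (i, j)."""

    symbol: str
    i: int
    j: int
    rule_ids: list[str]
    splits: list[tuple[int, ...]]
    weights: np.ndarray
    norm: float
    cum: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cum is None and self.norm > 0.0:
            self.cum = np.cumsum(self.weights) / self.norm

    def __len__(self) -> int:
        return len(self.rule_ids)

    @property
    def probabilities(self) -> np.ndarray:
        """Normalized sampling probabilities (weights / norm_alpha)."""
        return self.weights / self.norm

    def draw(self, rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
        idx = int(np.searchsorted(self.cum, rng.random(), side="right"))
        idx = min(idx, len(self.rule_ids) - 1)
        return self.rule_ids[idx], self.splits[idx]


def build_choice_set(
    symbol: str,
    i: int,
    j: int,
    table: Table,
    params: ParamSet,
    grammar: GrammarSpec,
    outside: OutsideTable | None = None,
) -> ChoiceSet:
    """Enumerate all options of ``symbol`` on fragment (i, j) with weights.

    Options with weight zero are excluded.  An empty option list signals a
    dead end to the caller (it is not an error: disturbed charts can lead
    the sampler into contexts with no feasible continuation).

    If ``outside`` is given, every weight is additionally multiplied by
    ``beta_symbol(i, j)``; this scales all options by a common factor and
    leaves the normalized distribution unchanged.
    """
    a = table.alpha
    seq = table.sequence
    mh, ms = grammar.min_hairpin, grammar.min_helix
    L = j - i + 1
    tr = params.tr

    rules: list[str] = []
    splits: list[tuple[int, ...]] = []
    weights: list[float] = []

    def add(rule: str, split: tuple[int, ...], w: float) -> None:
        if w > 0.0:
            rules.append(rule)
            splits.append(split)
            weights.append(w)

    def add_vec(rule: str, ks: range, w: np.ndarray) -> None:
        for k, wk in zip(ks, w):
            if wk > 0.0:
                rules.append(rule)
                splits.append((k,))
                weights.append(float(wk))

    A, B, C, T, U, N, O = a["A"], a["B"], a["C"], a["T"], a["U"], a["N"], a["O"]

    if symbol == "S":
        add("p1", (), tr("p1", L) * T[i, j])
    elif symbol == "T":
        add("p2", (), tr("p2", L) * C[i, j])
        add("p3", (), tr("p3", L) * A[i, j])
        if L >= 2:
            add_vec("p4", range(i, j), tr("p4", L) * C[i, i:j] * A[i + 1 : j + 1, j])
            add_vec("p5", range(i, j), tr("p5", L) * A[i, i:j] * T[i + 1 : j + 1, j])
        if L >= 3:
            t6 = tr("p6", L)
            if t6 > 0.0:
                for k1 in range(i, j - 1):
                    # k2 runs k1+1 .. j-1: A[k1+1, k2] * T[k2+1, j]
                    w = t6 * C[i, k1] * A[k1 + 1, k1 + 1 : j] * T[k1 + 2 : j + 1, j]
                    for off, wk in enumerate(w):
                        if wk > 0.0:
                            rules.append("p6")
                            splits.append((k1, k1 + 1 + off))
                            weights.append(float(wk))
    elif symbol == "C":
        if L == 1:
            add("p8", (), tr("p8", 1) * a["Z"][i, i])
        else:
            add("p7", (), tr("p7", L) * a["Z"][i, i] * C[i + 1, j])
    elif symbol == "H":
        if L == 1:
            add("p17", (), tr("p17", 1) * a["Z"][i, i])
        else:
            add("p16", (), tr("p16", L) * a["Z"][i, i] * a["H"][i + 1, j])
    elif symbol == "B":
        if L == 1:
            add("p22", (), tr("p22", 1) * a["Z"][i, i])
        else:
            add("p21", (), tr("p21", L) * a["Z"][i, i] * B[i + 1, j])
    elif symbol == "U":
        if L <= 0:
            add("p28", (), tr("p28", 0))
        else:
            add("p27", (), tr("p27", L) * a["Z"][i, i] * U[i + 1, j])
    elif symbol == "Z":
        add("p29", (), tr("p29", 1) * params.em1(seq[i - 1]))
    elif symbol == "A":
        if L >= 2 * ms + 1:
            emp = 1.0
            for t in range(ms):
                emp *= params.em2(seq[i + t - 1], seq[j - t - 1])
            add("p9", (), tr("p9", L) * emp * a["L"][i + ms, j - ms])
    elif symbol == "P":
        if L >= 3:
            em = params.em2(seq[i - 1], seq[j - 1])
            add("p10", (), tr("p10", L) * em * a["L"][i + 1, j - 1])
    elif symbol == "L":
        add("p11", (), tr("p11", L) * a["F"][i, j])
        add("p12", (), tr("p12", L) * a["P"][i, j])
        add("p13", (), tr("p13", L) * a["G"][i, j])
        add("p14", (), tr("p14", L) * a["M"][i, j])
    elif symbol == "F":
        if L >= mh:
            zprod = 1.0
            for t in range(i, i + mh - 1):
                zprod *= a["Z"][t, t]
            add("p15", (), tr("p15", L) * zprod * a["H"][i + mh - 1, j])
    elif symbol == "G":
        if L >= 2:
            add_vec("p18", range(i, j), tr("p18", L) * B[i, i:j] * A[i + 1 : j + 1, j])
            add_vec("p19", range(i, j), tr("p19", L) * A[i, i:j] * B[i + 1 : j + 1, j])
        if L >= 3:
            t20 = tr("p20", L)
            if t20 > 0.0:
                for k1 in range(i, j - 1):
                    w = t20 * B[i, k1] * A[k1 + 1, k1 + 1 : j] * B[k1 + 2 : j + 1, j]
                    for off, wk in enumerate(w):
                        if wk > 0.0:
                            rules.append("p20")
                            splits.append((k1, k1 + 1 + off))
                            weights.append(float(wk))
    elif symbol == "M":
        t23 = tr("p23", L)
        if t23 > 0.0:
            for k1 in range(i - 1, j - 1):
                uk = U[i, k1]
                if uk <= 0.0:
                    continue
                w = t23 * uk * A[k1 + 1, k1 + 1 : j] * O[k1 + 2 : j + 1, j]
                for off, wk in enumerate(w):
                    if wk > 0.0:
                        rules.append("p23")
                        splits.append((k1, k1 + 1 + off))
                        weights.append(float(wk))
    elif symbol in ("O", "N"):
        rule3 = "p24" if symbol == "O" else "p25"
        if L >= 1:
            t3 = tr(rule3, L)
            if t3 > 0.0:
                for k1 in range(i - 1, j):
                    uk = U[i, k1]
                    if uk <= 0.0:
                        continue
                    # k2 runs k1+1 .. j; N child may be empty (k2 == j)
                    w = t3 * uk * A[k1 + 1, k1 + 1 : j + 1] * N[k1 + 2 : j + 2, j]
                    for off, wk in enumerate(w):
                        if wk > 0.0:
                            rules.append(rule3)
                            splits.append((k1, k1 + 1 + off))
                            weights.append(float(wk))
        if symbol == "N":
            if L <= 0:
                add("p26", (), tr("p26", 0) * U[i, i - 1])
            else:
                add("p26", (), tr("p26", L) * U[i, j])
    else:
        raise ValueError(f"no sampling decision for symbol {symbol!r}")

    w = np.asarray(weights, dtype=float)
    if outside is not None and len(w):
        w = w * outside.beta[symbol][i, j]
    norm = float(w.sum())
    return ChoiceSet(
        symbol=symbol, i=i, j=j, rule_ids=rules, splits=splits, weights=w, norm=norm
    )


def option_children(
    rule_id: str,
    i: int,
    j: int,
    splits: tuple[int, ...],
    grammar: GrammarSpec,
) -> list[tuple[str, int, int]]:
    """Nonterminal child contexts implied by applying ``rule_id`` on (i, j)."""
    mh, ms = grammar.min_hairpin, grammar.min_helix
    if rule_id == "p1":
        return [("T", i, j)]
    if rule_id == "p2":
        return [("C", i, j)]
    if rule_id == "p3":
        return [("A", i, j)]
    if rule_id == "p4":
        (k,) = splits
        return [("C", i, k), ("A", k + 1, j)]
    if rule_id == "p5":
        (k,) = splits
        return [("A", i, k), ("T", k + 1, j)]
    if rule_id == "p6":
        k1, k2 = splits
        return [("C", i, k1), ("A", k1 + 1, k2), ("T", k2 + 1, j)]
    if rule_id in ("p7", "p16", "p21"):
        child = {"p7": "C", "p16": "H", "p21": "B"}[rule_id]
        return [("Z", i, i), (child, i + 1, j)]
    if rule_id in ("p8", "p17", "p22"):
        return [("Z", i, i)]
    if rule_id == "p9":
        return [("L", i + ms, j - ms)]
    if rule_id == "p10":
        return [("L", i + 1, j - 1)]
    if rule_id in ("p11", "p12", "p13", "p14"):
        child = {"p11": "F", "p12": "P", "p13": "G", "p14": "M"}[rule_id]
        return [(child, i, j)]
    if rule_id == "p15":
        return [("Z", t, t) for t in range(i, i + mh - 1)] + [("H", i + mh - 1, j)]
    if rule_id == "p18":
        (k,) = splits
        return [("B", i, k), ("A", k + 1, j)]
    if rule_id == "p19":
        (k,) = splits
        return [("A", i, k), ("B", k + 1, j)]
    if rule_id == "p20":
        k1, k2 = splits
        return [("B", i, k1), ("A", k1 + 1, k2), ("B", k2 + 1, j)]
    if rule_id in ("p23", "p24", "p25"):
        k1, k2 = splits
        last = {"p23": "O", "p24": "N", "p25": "N"}[rule_id]
        return [("U", i, k1), ("A", k1 + 1, k2), (last, k2 + 1, j)]
    if rule_id == "p26":
        return [("U", i, j)]
    if rule_id == "p27":
        return [("Z", i, i), ("U", i + 1, j)]
    if rule_id in ("p28", "p29"):
        return []
    raise ValueError(f"unknown rule {rule_id!r}")


@dataclass
class SampledStructure:
    """One draw: dot-bracket string plus per-position loop annotation.

    ``fallback_events`` lists (span, intended, realized) triples recorded
    when a drawn substructure type could not be completed and the strategy
    settled for a degraded one; it is empty for draws from an exact chart.
    """

    structure: str
    loop_annotation: list[str]
    fallback_events: list[tuple[tuple[int, int], str, str]] = field(default_factory=list)
    trace: list[tuple[str, tuple[int, int], str, tuple[int, ...]]] | None = None

    def __len__(self) -> int:
        return len(self.structure)


@dataclass
class SampleSet:
    """N independent draws for one sequence."""

    sequence: str
    structures: list[SampledStructure]

    @property
    def size(self) -> int:
        return len(self.structures)

    @property
    def counts(self) -> Counter:
        """Multiset view keyed by dot-bracket string."""
        return Counter(s.structure for s in self.structures)


class StructureSampler:
    """Draws structures from one (possibly disturbed) inside chart.

    Choice sets are cached per (symbol, i, j), so repeated draws from the
    same chart cost only the random decisions.
    """

    def __init__(
        self,
        table: Table,
        params: ParamSet | None = None,
        grammar: GrammarSpec | None = None,
        record_trace: bool = False,
    ) -> None:
        self.table = table
        self.params = params if params is not None else table.params
        self.grammar = grammar if grammar is not None else table.grammar
        self.record_trace = record_trace
        self._cache: dict[tuple[str, int, int], ChoiceSet] = {}

    @property
    def n(self) -> int:
        return len(self.table.sequence)

    def choice_set(self, symbol: str, i: int, j: int) -> ChoiceSet:
        key = (symbol, i, j)
        cs = self._cache.get(key)
        if cs is None:
            cs = build_choice_set(symbol, i, j, self.table, self.params, self.grammar)
            self._cache[key] = cs
        return cs

    # -- one draw -----------------------------------------------------------

    def sample(self, rng: np.random.Generator) -> SampledStructure:
        n = self.n
        chars = ["."] * (n + 1)
        labels = [EXTERIOR] * (n + 1)
        events: list[tuple[tuple[int, int], str, str]] = []
        trace: list | None = [] if self.record_trace else None
        mh, ms = self.grammar.min_hairpin, self.grammar.min_helix

        def draw(symbol: str, i: int, j: int):
            cs = self.choice_set(symbol, i, j)
            if cs.norm <= 0.0:
                return None
            rule, splits = cs.draw(rng)
            if trace is not None:
                trace.append((symbol, (i, j), rule, splits))
            return rule, splits

        def dots(i: int, j: int, label: str) -> None:
            for k in range(i, j + 1):
                chars[k] = "."
                labels[k] = label

        def do_T(i: int, j: int) -> None:
            choice = draw("T", i, j)
            if choice is None:
                dots(i, j, EXTERIOR)
                events.append(((i, j), "exterior decomposition", "unpaired"))
                return
            rule, sp = choice
            if rule == "p2":
                dots(i, j, EXTERIOR)
            elif rule == "p3":
                if not do_A(i, j):
                    dots(i, j, EXTERIOR)
                    events.append(((i, j), "helix", "unpaired"))
            elif rule == "p4":
                (k,) = sp
                dots(i, k, EXTERIOR)
                if not do_A(k + 1, j):
                    dots(k + 1, j, EXTERIOR)
                    events.append(((k + 1, j), "helix", "unpaired"))
            elif rule == "p5":
                (k,) = sp
                if not do_A(i, k):
                    dots(i, k, EXTERIOR)
                    events.append(((i, k), "helix", "unpaired"))
                do_T(k + 1, j)
            else:  # p6
                k1, k2 = sp
                dots(i, k1, EXTERIOR)
                if not do_A(k1 + 1, k2):
                    dots(k1 + 1, k2, EXTERIOR)
                    events.append(((k1 + 1, k2), "helix", "unpaired"))
                do_T(k2 + 1, j)

        def do_A(i: int, j: int) -> bool:
            if j - i + 1 < 2 * ms + 1:
                return False
            choice = draw("A", i, j)
            if choice is None:
                return False
            # p9: the chart value of L is never disturbed, so a positive
            # option weight guarantees the interior can be completed validly
            for t in range(ms):
                chars[i + t] = "("
                chars[j - t] = ")"
                labels[i + t] = labels[j - t] = HELIX
            do_L(i + ms, j - ms)
            return True

        def do_P(i: int, j: int) -> bool:
            if j - i + 1 < 3:
                return False
            choice = draw("P", i, j)
            if choice is None:
                return False
            chars[i], chars[j] = "(", ")"
            labels[i] = labels[j] = HELIX
            do_L(i + 1, j - 1)
            return True

        def do_L(i: int, j: int) -> None:
            choice = draw("L", i, j)
            if choice is None:
                dots(i, j, HAIRPIN)
                events.append(((i, j), "loop", "hairpin"))
                return
            rule, _ = choice
            if rule == "p11":
                dots(i, j, HAIRPIN)
            elif rule == "p12":
                if not do_P(i, j):
                    dots(i, j, HAIRPIN)
                    events.append(((i, j), "helix extension", "hairpin"))
            elif rule == "p13":
                if not do_G(i, j):
                    dots(i, j, HAIRPIN)
                    events.append(((i, j), "bulge/interior loop", "hairpin"))
            else:  # p14
                if not do_M(i, j):
                    dots(i, j, HAIRPIN)
                    events.append(((i, j), "multiloop", "hairpin"))

        def do_G(i: int, j: int) -> bool:
            choice = draw("G", i, j)
            if choice is None:
                return False
            rule, sp = choice
            if rule == "p18":
                (k,) = sp
                dots(i, k, BULGE)
                if not do_A(k + 1, j):
                    dots(k + 1, j, BULGE)
                    events.append(((k + 1, j), "bulge/interior helix", "unpaired"))
            elif rule == "p19":
                (k,) = sp
                if not do_A(i, k):
                    dots(i, k, BULGE)
                    events.append(((i, k), "bulge/interior helix", "unpaired"))
                dots(k + 1, j, BULGE)
            else:  # p20
                k1, k2 = sp
                dots(i, k1, BULGE)
                if not do_A(k1 + 1, k2):
                    dots(k1 + 1, k2, BULGE)
                    events.append(((k1 + 1, k2), "bulge/interior helix", "unpaired"))
                dots(k2 + 1, j, BULGE)
            return True

        def do_M(i: int, j: int) -> bool:
            choice = draw("M", i, j)
            if choice is None:
                return False
            _, (k1, k2) = choice
            if k1 >= i:
                dots(i, k1, MULTI)
            if not do_A(k1 + 1, k2):
                dots(k1 + 1, k2, MULTI)
                events.append(((k1 + 1, k2), "multiloop helix", "unpaired"))
            do_O(k2 + 1, j)
            return True

        def do_O(i: int, j: int) -> None:
            choice = draw("O", i, j)
            if choice is None:
                dots(i, j, MULTI)
                events.append(((i, j), "multiloop continuation", "unpaired"))
                return
            _, (k1, k2) = choice
            if k1 >= i:
                dots(i, k1, MULTI)
            if not do_A(k1 + 1, k2):
                dots(k1 + 1, k2, MULTI)
                events.append(((k1 + 1, k2), "multiloop helix", "unpaired"))
            do_N(k2 + 1, j)

        def do_N(i: int, j: int) -> None:
            if j < i:
                return
            choice = draw("N", i, j)
            if choice is None:
                dots(i, j, MULTI)
                events.append(((i, j), "multiloop continuation", "unpaired"))
                return
            rule, sp = choice
            if rule == "p26":
                dots(i, j, MULTI)
                return
            k1, k2 = sp
            if k1 >= i:
                dots(i, k1, MULTI)
            if not do_A(k1 + 1, k2):
                dots(k1 + 1, k2, MULTI)
                events.append(((k1 + 1, k2), "multiloop helix", "unpaired"))
            do_N(k2 + 1, j)

        start = draw("S", 1, n)
        if start is None:
            dots(1, n, EXTERIOR)
            events.append(((1, n), "any structure", "unpaired"))
        else:
            do_T(1, n)

        return SampledStructure(
            structure="".join(chars[1:]),
            loop_annotation=labels[1:],
            fallback_events=events,
            trace=trace,
        )

    def sample_set(self, size: int, rng: np.random.Generator) -> SampleSet:
        if size < 1:
            raise ValueError(f"sample size must be >= 1, got {size}")
        return SampleSet(
            sequence=self.table.sequence,
            structures=[self.sample(rng) for _ in range(size)],
        )


def sample_structure(
    table: Table,
    params: ParamSet,
    grammar: GrammarSpec,
    rng: np.random.Generator,
) -> SampledStructure:
    """Draw one structure (convenience wrapper; see :class:`StructureSampler`)."""
    return StructureSampler(table, params, grammar).sample(rng)


def sample_set(
    table: Table,
    params: ParamSet,
    grammar: GrammarSpec,
    size: int,
    rng: np.random.Generator,
) -> SampleSet:
    """Draw ``size`` independent structures with a shared choice-set cache."""
    return StructureSampler(table, params, grammar).sample_set(size, rng)


def reachable_contexts(
    table: Table,
    params: ParamSet,
    grammar: GrammarSpec,
    symbols: tuple[str, ...] = DECISION_SYMBOLS,
) -> list[tuple[str, int, int]]:
    """All decision contexts (symbol, i, j) the strategy can reach.

    Breadth-first closure from (S, 1, n) over every positive-weight option.
    """
    n = len(table.sequence)
    seen: set[tuple[str, int, int]] = set()
    queue: list[tuple[str, int, int]] = [("S", 1, n)]
    out: list[tuple[str, int, int]] = []
    while queue:
        ctx = queue.pop()
        if ctx in seen:
            continue
        seen.add(ctx)
        sym, i, j = ctx
        if sym == "Z":
            continue
        cs = build_choice_set(sym, i, j, table, params, grammar)
        if cs.norm <= 0.0:
            continue
        if sym in symbols:
            out.append(ctx)
        for rule, sp in zip(cs.rule_ids, cs.splits):
            for child in option_children(rule, i, j, sp, grammar):
                if child not in seen:
                    queue.append(child)
    return sorted(out)
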