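"""Secondary-structure grammar, unique parsing and maximum-likelihood training.

The grammar models pseudoknot-free RNA secondary structures as dot-bracket
words over ``{ ( , ) , . }``.  Fifteen nonterminals decompose a structure the
way a biologist reads it: the exterior loop (``T``/``C``), helices (``A``
starts one with ``min_helix`` stacked pairs, ``P`` extends it pair by pair),
and the loop closed by a helix (``L`` chooses hairpin ``F``/``H``,
bulge/interior ``G``/``B`` or multiloop ``M``/``O``/``N``/``U``).  ``Z``
emits a single unpaired base.  Two structural knobs parameterize the rule
set: ``min_hairpin`` (minimum number of unpaired bases enclosed by a hairpin)
and ``min_helix`` (minimum number of stacked pairs per helix).

The grammar is unambiguous: every valid structure string has exactly one
leftmost derivation, which :func:`parse_structure` computes in linear time by
structural recursion (no chart needed for parsing).  Transition probabilities
attach to rules, emission probabilities to the terminals (unpaired bases at
``p29``, base pairs at ``p9``/``p10``), giving a joint generative model of
(sequence, structure).  In the length-dependent variant a rule's probability
is conditioned on the length of the terminal subword the application derives.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "BASES",
    "SAMPLING_SYMBOLS",
    "ProductionRule",
    "GrammarSpec",
    "ParamSet",
    "StructureRecord",
    "Derivation",
    "ParseError",
    "build_grammar",
    "parse_structure",
    "replay",
    "annotate_loops",
    "pair_table",
    "train",
    "structure_probability",
]

BASES = ("A", "C", "G", "U")

#: Intermediate symbols whose inside values feed the conditional sampling
#: distributions (and which are therefore eligible for disturbance).
SAMPLING_SYMBOLS = ("T", "C", "A", "P", "F", "G", "B", "M", "O", "N", "U")

NONTERMINALS = ("S", "T", "C", "A", "P", "L", "F", "H", "G", "B", "M", "O", "N", "U", "Z")

#: Loop-type annotation labels.
EXTERIOR, HELIX, HAIRPIN, BULGE, MULTI = (
    "exterior",
    "helix",
    "hairpin",
    "bulge/interior",
    "multiloop",
)


class ParseError(ValueError):
    """A structure string violates the grammar's constraints."""


@dataclass(frozen=True)
class ProductionRule:
    """One labeled production.

    ``rhs`` lists symbols left to right; nonterminals by name, terminals as
    ``"("``, ``")"`` or ``"."``.  Pair-emitting rules additionally declare
    how many matched outermost bracket pairs they emit (``n_pairs``).
    """

    id: str
    premise: str
    rhs: tuple[str, ...]
    role: str = ""
    is_epsilon: bool = False
    n_pairs: int = 0
    is_helper: bool = False

    @property
    def nonterminal_children(self) -> tuple[str, ...]:
        return tuple(s for s in self.rhs if s in NONTERMINALS)


@dataclass(frozen=True)
class GrammarSpec:
    """The 29-rule structure grammar for a given (min_hairpin, min_helix)."""

    min_hairpin: int
    min_helix: int
    rules: tuple[ProductionRule, ...]

    nonterminals: tuple[str, ...] = NONTERMINALS
    terminals: tuple[str, ...] = ("(", ")", ".")
    sampling_symbols: tuple[str, ...] = SAMPLING_SYMBOLS

    def __post_init__(self) -> None:
        by_id = {r.id: r for r in self.rules}
        object.__setattr__(self, "_by_id", by_id)
        alts: dict[str, list[ProductionRule]] = defaultdict(list)
        for r in self.rules:
            if not r.is_helper:
                alts[r.premise].append(r)
        object.__setattr__(self, "_alternatives", dict(alts))

    def rule(self, rule_id: str) -> ProductionRule:
        return self._by_id[rule_id]

    def alternatives(self, premise: str) -> list[ProductionRule]:
        """Observable alternative rules sharing ``premise``."""
        return self._alternatives[premise]

    @property
    def observable_rules(self) -> tuple[ProductionRule, ...]:
        return tuple(r for r in self.rules if not r.is_helper)

    @property
    def min_span(self) -> dict[str, int]:
        """Minimum terminal-subword length derivable from each nonterminal."""
        mh, ms = self.min_hairpin, self.min_helix
        pair_min = 2 * ms + mh  # shortest helix closing a shortest hairpin
        return {
            "S": 1, "T": 1, "C": 1, "Z": 1, "H": 1, "B": 1, "U": 0,
            "F": mh, "L": mh, "A": pair_min, "P": mh + 2,
            "G": pair_min + 1, "M": 2 * pair_min, "O": pair_min, "N": 0,
        }


def build_grammar(min_hairpin: int, min_helix: int) -> GrammarSpec:
    """Construct the structure grammar for the given loop/helix minima.

    Parameters
    ----------
    min_hairpin
        Minimum number of unpaired bases enclosed by a hairpin loop
        (``m_h >= 1``).
    min_helix
        Minimum number of stacked base pairs per helix (``m_s >= 1``).
    """
    if min_hairpin < 1:
        raise ValueError(f"min_hairpin must be >= 1, got {min_hairpin}")
    if min_helix < 1:
        raise ValueError(f"min_helix must be >= 1, got {min_helix}")
    mh, ms = min_hairpin, min_helix
    R = ProductionRule
    rules = [
        R("p1", "S", ("T",), "initiate exterior loop"),
        R("p2", "T", ("C",), "shape of exterior loop"),
        R("p3", "T", ("A",), "shape of exterior loop"),
        R("p4", "T", ("C", "A"), "shape of exterior loop"),
        R("p5", "T", ("A", "T"), "shape of exterior loop"),
        R("p6", "T", ("C", "A", "T"), "shape of exterior loop"),
        R("p7", "C", ("Z", "C"), "strands in exterior loop"),
        R("p8", "C", ("Z",), "strands in exterior loop"),
        R("p9", "A", ("(",) * ms + ("L",) + (")",) * ms, "initiate helix", n_pairs=ms),
        R("p10", "P", ("(", "L", ")"), "extend helix", n_pairs=1),
        R("p11", "L", ("F",), "initiate any loop"),
        R("p12", "L", ("P",), "initiate any loop"),
        R("p13", "L", ("G",), "initiate any loop"),
        R("p14", "L", ("M",), "initiate any loop"),
        R("p15", "F", ("Z",) * (mh - 1) + ("H",), "start hairpin loop"),
        R("p16", "H", ("Z", "H"), "extend hairpin loop"),
        R("p17", "H", ("Z",), "extend hairpin loop"),
        R("p18", "G", ("B", "A"), "shape of bulge/interior loop"),
        R("p19", "G", ("A", "B"), "shape of bulge/interior loop"),
        R("p20", "G", ("B", "A", "B"), "shape of bulge/interior loop"),
        R("p21", "B", ("Z", "B"), "strands in bulge/interior loop"),
        R("p22", "B", ("Z",), "strands in bulge/interior loop"),
        R("p23", "M", ("U", "A", "O"), "first substructure of multiple loop"),
        R("p24", "O", ("U", "A", "N"), "second substructure of multiple loop"),
        R("p25", "N", ("U", "A", "N"), "kth substructure of multiple loop"),
        R("p26", "N", ("U",), "kth substructure of multiple loop"),
        R("p27", "U", ("Z", "U"), "strands in multiple loop"),
        R("p28", "U", (), "strands in multiple loop", is_epsilon=True),
        R("p29", "Z", (".",), "unpaired base"),
        # probability-1 binarization helpers for the three-nonterminal rules;
        # never observable in derivations, parameters or disturbance targets
        R("h_AT", "h_AT", ("A", "T"), "helper", is_helper=True),
        R("h_AB", "h_AB", ("A", "B"), "helper", is_helper=True),
        R("h_AO", "h_AO", ("A", "O"), "helper", is_helper=True),
        R("h_AN", "h_AN", ("A", "N"), "helper", is_helper=True),
    ]
    return GrammarSpec(min_hairpin=mh, min_helix=ms, rules=tuple(rules))


# ---------------------------------------------------------------------------
# structures


@dataclass
class StructureRecord:
    """A dot-bracket structure, optionally with its sequence.

    Coordinates are 1-based inclusive; ``pairs`` holds ``(i, j)`` with
    ``i < j``.
    """

    structure: str
    sequence: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("T", "U")
            if len(self.sequence) != len(self.structure):
                raise ValueError(
                    f"sequence length {len(self.sequence)} != structure length "
                    f"{len(self.structure)}"
                )
            bad = set(self.sequence) - set(BASES)
            if bad:
                raise ValueError(f"illegal bases {sorted(bad)} in sequence")

    def __len__(self) -> int:
        return len(self.structure)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        pt = pair_table(self.structure)
        return {(i, pt[i]) for i in range(1, len(self.structure) + 1) if pt[i] > i}


def pair_table(structure: str) -> list[int]:
    """1-based partner table; ``pt[i] == 0`` for unpaired, ``pt[0]`` unused.

    Raises :class:`ParseError` on unbalanced brackets or illegal characters.
    """
    n = len(structure)
    pt = [0] * (n + 1)
    stack: list[int] = []
    for idx, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unmatched ')' at position {idx}")
            i = stack.pop()
            pt[i], pt[idx] = idx, i
        elif ch != ".":
            raise ParseError(f"illegal character {ch!r} at position {idx}")
    if stack:
        raise ParseError(f"unmatched '(' at position {stack[-1]}")
    return pt


Derivation = list[tuple[str, tuple[int, int]]]
"""Leftmost derivation: ordered ``(rule_id, (i, j))`` applications."""


def parse_structure(record: StructureRecord | str, grammar: GrammarSpec) -> Derivation:
    """Compute the unique leftmost derivation of a dot-bracket word.

    Raises :class:`ParseError` if the structure is unbalanced, crossing, or
    violates the grammar's hairpin/helix minima, naming the offending
    position.
    """
    s = record.structure if isinstance(record, StructureRecord) else record
    if not s:
        raise ParseError("empty structure")
    pt = pair_table(s)
    n = len(s)
    mh, ms = grammar.min_hairpin, grammar.min_helix
    out: Derivation = []

    def components(i: int, j: int) -> list[tuple[int, int]]:
        """Maximal paired components and unpaired runs on [i, j] in order.

        Returns a list of (start, end) spans; a span is a component when
        ``pt[start] == end > start``, otherwise an unpaired run.
        """
        spans = []
        k = i
        while k <= j:
            if pt[k]:
                spans.append((k, pt[k]))
                k = pt[k] + 1
            else:
                start = k
                while k <= j and not pt[k]:
                    k += 1
                spans.append((start, k - 1))
        return spans

    def run(symbol: str, extend_id: str, end_id: str, i: int, j: int) -> None:
        # right-linear chains C/H/B over a known all-dot span
        for k in range(i, j):
            out.append((extend_id, (k, j)))
            out.append(("p29", (k, k)))
        out.append((end_id, (j, j)))
        out.append(("p29", (j, j)))

    def u_run(i: int, j: int) -> None:
        for k in range(i, j + 1):
            out.append(("p27", (k, j)))
            out.append(("p29", (k, k)))
        out.append(("p28", (j + 1, j)))

    def derive_A(i: int, j: int) -> None:
        for t in range(ms):
            if pt[i + t] != j - t:
                raise ParseError(
                    f"helix starting at position {i} has fewer than "
                    f"{ms} stacked pairs (position {i + t})"
                )
        out.append(("p9", (i, j)))
        derive_L(i + ms, j - ms)

    def derive_L(i: int, j: int) -> None:
        if j < i:
            raise ParseError(f"empty loop interior at position {i - 1}")
        spans = components(i, j)
        comps = [(a, b) for (a, b) in spans if pt[a] == b and pt[a] != 0]
        if not comps:
            if j - i + 1 < mh:
                raise ParseError(
                    f"hairpin loop at position {i} has {j - i + 1} unpaired "
                    f"bases (< min_hairpin={mh})"
                )
            out.append(("p11", (i, j)))
            out.append(("p15", (i, j)))
            for t in range(i, i + mh - 1):
                out.append(("p29", (t, t)))
            run("H", "p16", "p17", i + mh - 1, j)
        elif len(comps) == 1:
            (a, b) = comps[0]
            if (a, b) == (i, j):
                out.append(("p12", (i, j)))
                out.append(("p10", (i, j)))
                derive_L(i + 1, j - 1)
            else:
                out.append(("p13", (i, j)))
                if a == i:  # runs only on the right: G -> A B
                    out.append(("p19", (i, j)))
                    derive_A(a, b)
                    run("B", "p21", "p22", b + 1, j)
                elif b == j:  # runs only on the left: G -> B A
                    out.append(("p18", (i, j)))
                    run("B", "p21", "p22", i, a - 1)
                    derive_A(a, b)
                else:  # interior loop: G -> B A B
                    out.append(("p20", (i, j)))
                    run("B", "p21", "p22", i, a - 1)
                    derive_A(a, b)
                    run("B", "p21", "p22", b + 1, j)
        else:
            out.append(("p14", (i, j)))
            out.append(("p23", (i, j)))
            (a1, b1) = comps[0]
            u_run(i, a1 - 1) if a1 > i else out.append(("p28", (i, i - 1)))
            derive_A(a1, b1)
            pos = b1 + 1
            for idx, (a, b) in enumerate(comps[1:], start=1):
                rule = "p24" if idx == 1 else "p25"
                out.append((rule, (pos, j)))
                u_run(pos, a - 1) if a > pos else out.append(("p28", (pos, pos - 1)))
                derive_A(a, b)
                pos = b + 1
            out.append(("p26", (pos, j)))
            if pos <= j:
                u_run(pos, j)
            else:
                out.append(("p28", (pos, j)))

    def derive_T(i: int, j: int) -> None:
        spans = components(i, j)
        first = spans[0]
        is_comp = pt[first[0]] == first[1] and pt[first[0]] != 0
        if is_comp:
            if first[1] == j:
                out.append(("p3", (i, j)))
                derive_A(i, j)
            else:
                out.append(("p5", (i, j)))
                derive_A(first[0], first[1])
                derive_T(first[1] + 1, j)
        else:
            a, b = first  # leading unpaired run
            if b == j:
                out.append(("p2", (i, j)))
                run("C", "p7", "p8", i, j)
            else:
                comp = spans[1]  # a component follows the run
                if comp[1] == j:
                    out.append(("p4", (i, j)))
                    run("C", "p7", "p8", i, b)
                    derive_A(comp[0], comp[1])
                else:
                    out.append(("p6", (i, j)))
                    run("C", "p7", "p8", i, b)
                    derive_A(comp[0], comp[1])
                    derive_T(comp[1] + 1, j)

    out.append(("p1", (1, n)))
    derive_T(1, n)
    return out


def replay(derivation: Derivation, grammar: GrammarSpec) -> str:
    """Reconstruct the dot-bracket word from a derivation."""
    n = max(j for _, (_, j) in derivation)
    chars = [""] * (n + 1)
    ms = grammar.min_helix
    for rule_id, (i, j) in derivation:
        if rule_id == "p29":
            chars[i] = "."
        elif rule_id == "p9":
            for t in range(ms):
                chars[i + t] = "("
                chars[j - t] = ")"
        elif rule_id == "p10":
            chars[i], chars[j] = "(", ")"
    if any(c == "" for c in chars[1:]):
        raise ValueError("derivation does not cover every position")
    return "".join(chars[1:])


def annotate_loops(structure: str, grammar: GrammarSpec) -> list[str]:
    """Per-position loop-type labels implied by the unique derivation.

    Paired positions are labeled ``helix``; unpaired positions get the loop
    type of the rule chain that emitted them (exterior, hairpin,
    bulge/interior, multiloop).
    """
    derivation = parse_structure(structure, grammar)
    return annotate_from_derivation(derivation, len(structure))


_LOOP_OF_CHAIN = {"C": EXTERIOR, "H": HAIRPIN, "B": BULGE, "U": MULTI, "F": HAIRPIN}


def annotate_from_derivation(derivation: Derivation, n: int) -> list[str]:
    labels = [""] * (n + 1)
    context = EXTERIOR
    for rule_id, (i, j) in derivation:
        if rule_id in ("p9", "p10"):
            pass
        elif rule_id in ("p7", "p8"):
            context = EXTERIOR
        elif rule_id in ("p16", "p17", "p15"):
            context = HAIRPIN
        elif rule_id in ("p21", "p22"):
            context = BULGE
        elif rule_id in ("p27", "p28"):
            context = MULTI
        if rule_id == "p29":
            labels[i] = context
    return labels[1:]


def annotate_structure(structure: str, grammar: GrammarSpec) -> list[str]:
    """Loop labels for every position (paired positions -> ``helix``)."""
    labels = annotate_loops(structure, grammar)
    return [HELIX if structure[k] in "()" else labels[k] for k in range(len(structure))]


# ---------------------------------------------------------------------------
# parameters


@dataclass
class ParamSet:
    """Transition and emission probabilities of the grammar.

    ``transition`` maps rule id to probability.  In the length-dependent
    variant ``transition_len`` maps rule id to ``{subword length: prob}``
    and is consulted instead; lengths unseen in training have probability 0
    unless ``fallback_to_plain`` is set.
    """

    transition: dict[str, float]
    emission_unpaired: dict[str, float]
    emission_pair: dict[tuple[str, str], float]
    length_dependent: bool = False
    transition_len: dict[str, dict[int, float]] = field(default_factory=dict)
    fallback_to_plain: bool = False

    def tr(self, rule_id: str, length: int) -> float:
        if self.length_dependent:
            table = self.transition_len.get(rule_id)
            if table is not None:
                p = table.get(length)
                if p is not None:
                    return p
            if not self.fallback_to_plain:
                return 0.0
        return self.transition.get(rule_id, 0.0)

    def em1(self, base: str) -> float:
        return self.emission_unpaired.get(base, 0.0)

    def em2(self, b1: str, b2: str) -> float:
        return self.emission_pair.get((b1, b2), 0.0)

    def validate(self, grammar: GrammarSpec, atol: float = 1e-9) -> None:
        """Check simplex invariants; raise ``ValueError`` on violation."""
        groups: dict[str, list[str]] = defaultdict(list)
        for r in grammar.observable_rules:
            groups[r.premise].append(r.id)
        for premise, ids in groups.items():
            total = sum(self.transition.get(rid, 0.0) for rid in ids)
            if not math.isclose(total, 1.0, abs_tol=atol):
                raise ValueError(f"transitions of premise {premise} sum to {total}")
            for rid in ids:
                p = self.transition.get(rid, 0.0)
                if not 0.0 <= p <= 1.0 + atol:
                    raise ValueError(f"transition {rid} = {p} outside [0, 1]")
        if self.length_dependent:
            lengths: dict[str, set[int]] = defaultdict(set)
            for premise, ids in groups.items():
                for rid in ids:
                    lengths[premise] |= set(self.transition_len.get(rid, {}))
            for premise, lens in lengths.items():
                for ln in lens:
                    total = sum(
                        self.transition_len.get(rid, {}).get(ln, 0.0)
                        for rid in groups[premise]
                    )
                    if not math.isclose(total, 1.0, abs_tol=atol):
                        raise ValueError(
                            f"length-dependent transitions of {premise} at "
                            f"length {ln} sum to {total}"
                        )
        for name, table in (
            ("emission_unpaired", self.emission_unpaired),
            ("emission_pair", self.emission_pair),
        ):
            if table:
                total = sum(table.values())
                if not math.isclose(total, 1.0, abs_tol=atol):
                    raise ValueError(f"{name} sums to {total}")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "length_dependent": self.length_dependent,
            "fallback_to_plain": self.fallback_to_plain,
            "transition": self.transition,
            "transition_len": {
                rid: {str(k): v for k, v in tbl.items()}
                for rid, tbl in self.transition_len.items()
            },
            "emission_unpaired": self.emission_unpaired,
            "emission_pair": {f"{a}{b}": p for (a, b), p in self.emission_pair.items()},
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParamSet":
        doc = json.loads(text)
        return cls(
            transition=dict(doc["transition"]),
            emission_unpaired=dict(doc["emission_unpaired"]),
            emission_pair={(k[0], k[1]): v for k, v in doc["emission_pair"].items()},
            length_dependent=bool(doc.get("length_dependent", False)),
            transition_len={
                rid: {int(k): v for k, v in tbl.items()}
                for rid, tbl in doc.get("transition_len", {}).items()
            },
            fallback_to_plain=bool(doc.get("fallback_to_plain", False)),
        )


def train(
    corpus: Sequence[StructureRecord],
    grammar: GrammarSpec,
    length_dependent: bool = False,
    need_emissions: bool | None = None,
) -> ParamSet:
    """Maximum-likelihood parameters from a corpus of structures.

    Transition probabilities are relative frequencies of rule applications
    among the alternatives of the same premise (length-binned by the terminal
    subword length of each application in the length-dependent case).
    Emission probabilities are relative frequencies of bases at unpaired
    positions and of ordered base pairs at paired positions; they require
    sequences on the records.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    if need_emissions is None:
        need_emissions = all(r.sequence is not None for r in corpus)
    counts: dict[str, float] = defaultdict(float)
    counts_len: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    em1: dict[str, float] = defaultdict(float)
    em2: dict[tuple[str, str], float] = defaultdict(float)
    ms = grammar.min_helix
    for rec in corpus:
        if need_emissions and rec.sequence is None:
            raise ValueError("emission training requested but record lacks a sequence")
        derivation = parse_structure(rec, grammar)
        for rule_id, (i, j) in derivation:
            counts[rule_id] += 1
            if length_dependent:
                counts_len[rule_id][j - i + 1] += 1
            if need_emissions:
                seq = rec.sequence
                if rule_id == "p29":
                    em1[seq[i - 1]] += 1
                elif rule_id == "p9":
                    for t in range(ms):
                        em2[(seq[i + t - 1], seq[j - t - 1])] += 1
                elif rule_id == "p10":
                    em2[(seq[i - 1], seq[j - 1])] += 1

    groups: dict[str, list[str]] = defaultdict(list)
    for r in grammar.observable_rules:
        groups[r.premise].append(r.id)

    transition: dict[str, float] = {}
    for premise, ids in groups.items():
        total = sum(counts[rid] for rid in ids)
        if total == 0:
            # premise never used: uniform over alternatives keeps the simplex
            for rid in ids:
                transition[rid] = 1.0 / len(ids)
        else:
            for rid in ids:
                transition[rid] = counts[rid] / total

    transition_len: dict[str, dict[int, float]] = {}
    if length_dependent:
        for premise, ids in groups.items():
            lens: set[int] = set()
            for rid in ids:
                lens |= set(counts_len[rid])
            for ln in lens:
                total = sum(counts_len[rid].get(ln, 0.0) for rid in ids)
                for rid in ids:
                    c = counts_len[rid].get(ln, 0.0)
                    if total > 0:
                        transition_len.setdefault(rid, {})[ln] = c / total

    def normalized(d):
        total = sum(d.values())
        return {k: v / total for k, v in d.items()} if total else {}

    params = ParamSet(
        transition=transition,
        emission_unpaired=normalized(em1) if need_emissions else {},
        emission_pair=normalized(em2) if need_emissions else {},
        length_dependent=length_dependent,
        transition_len=transition_len,
    )
    params.validate(grammar)
    return params


def structure_probability(
    record: StructureRecord,
    params: ParamSet,
    grammar: GrammarSpec,
    with_emissions: bool | None = None,
) -> float:
    """Probability of the unique derivation of ``record`` under ``params``.

    With a sequence attached this is the joint probability of (sequence,
    structure); without one (or with ``with_emissions=False``) only the
    transition product, i.e. the structure-shape probability.
    """
    if with_emissions is None:
        with_emissions = record.sequence is not None and bool(params.emission_unpaired)
    derivation = parse_structure(record, grammar)
    return derivation_probability(
        derivation, record.sequence, params, grammar, with_emissions
    )


def derivation_probability(
    derivation: Derivation,
    sequence: str | None,
    params: ParamSet,
    grammar: GrammarSpec,
    with_emissions: bool = True,
) -> float:
    ms = grammar.min_helix
    p = 1.0
    for rule_id, (i, j) in derivation:
        p *= params.tr(rule_id, j - i + 1)
        if with_emissions and sequence is not None:
            if rule_id == "p29":
                p *= params.em1(sequence[i - 1])
            elif rule_id == "p9":
                for t in range(ms):
                    p *= params.em2(sequence[i + t - 1], sequence[j - t - 1])
            elif rule_id == "p10":
                p *= params.em2(sequence[i - 1], sequence[j - 1])
        if p == 0.0:
            return 0.0
    return p
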