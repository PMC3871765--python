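"""Seeded synthetic corpora drawn jointly from the grammar itself.

The grammar is a generative model: expanding a derivation from the axiom
using the transition probabilities and emitting bases at the terminal
slots from the emission probabilities yields a joint (structure, sequence)
draw.  Rejection sampling on the total length emulates the length windows
of curated structure databases (tRNA-like 64-93 nt, 5S-rRNA-like
102-135 nt) without requiring any download.

The default parameter set is hand-set to produce plausible RNA-like
ensembles — helices of a few stacked pairs, hairpin loops of a few bases,
occasional multiloops, Watson-Crick-dominated pairing — and is the fixed
generator behind all in-repo test corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grammar import (
    BASES,
    GrammarSpec,
    ParamSet,
    StructureRecord,
    build_grammar,
    pair_table,
)

__all__ = [
    "CorpusSpec",
    "default_paramset",
    "generate_record",
    "generate_corpus",
    "worked_fixture",
]


def default_paramset() -> ParamSet:
    """Hand-set generator parameters (length-independent).

    Transition masses favor moderately long helices (mean ~3.5 stacked
    pairs), short hairpin loops, and sparse multiloops; emissions favor
    Watson-Crick pairs with some GU wobble.
    """
    transition = {
        "p1": 1.0,
        # exterior loop shape
        "p2": 0.15, "p3": 0.10, "p4": 0.15, "p5": 0.25, "p6": 0.35,
        # exterior strands
        "p7": 0.70, "p8": 0.30,
        "p9": 1.0,
        "p10": 1.0,
        # loop choice: helix extension dominates
        "p11": 0.15, "p12": 0.72, "p13": 0.08, "p14": 0.05,
        "p15": 1.0,
        "p16": 0.75, "p17": 0.25,
        "p18": 0.40, "p19": 0.40, "p20": 0.20,
        "p21": 0.60, "p22": 0.40,
        "p23": 1.0, "p24": 1.0,
        "p25": 0.35, "p26": 0.65,
        "p27": 0.60, "p28": 0.40,
        "p29": 1.0,
    }
    emission_unpaired = {"A": 0.30, "C": 0.20, "G": 0.20, "U": 0.30}
    emission_pair = {}
    main = {("C", "G"): 0.23, ("G", "C"): 0.23, ("A", "U"): 0.16, ("U", "A"): 0.16,
            ("G", "U"): 0.08, ("U", "G"): 0.08}
    rest = [(a, b) for a in BASES for b in BASES if (a, b) not in main]
    for k in main:
        emission_pair[k] = main[k]
    for k in rest:
        emission_pair[k] = 0.06 / len(rest)
    return ParamSet(
        transition=transition,
        emission_unpaired=emission_unpaired,
        emission_pair=emission_pair,
    )


@dataclass
class CorpusSpec:
    """Generator configuration: model, corpus size, length window, seed."""

    size: int
    length_range: tuple[int, int] = (64, 93)
    seed: int = 0
    params: ParamSet = field(default_factory=default_paramset)
    grammar: GrammarSpec = field(default_factory=lambda: build_grammar(1, 1))
    max_attempts_per_record: int = 10_000

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("corpus size must be >= 1")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"bad length window {self.length_range}")


class _ExpansionOverflow(Exception):
    pass


def _expand_structure(
    params: ParamSet,
    grammar: GrammarSpec,
    rng: np.random.Generator,
    max_len: int,
) -> str:
    """Expand one derivation from S into a dot-bracket word.

    Aborts (for redraw) once the emitted word exceeds ``max_len``; this
    guards against rare runaway expansions under user-supplied parameters.
    """
    mh, ms = grammar.min_hairpin, grammar.min_helix
    alts = {
        premise: (
            [r.id for r in grammar.alternatives(premise)],
            np.array([params.transition[r.id] for r in grammar.alternatives(premise)]),
        )
        for premise in ("S", "T", "C", "A", "P", "L", "F", "H", "G", "B", "M", "O", "N", "U", "Z")
    }
    rhs = {r.id: r.rhs for r in grammar.observable_rules}
    out: list[str] = []
    stack: list[str] = ["S"]
    while stack:
        sym = stack.pop()
        if sym in ("(", ")", "."):
            out.append(sym)
            if len(out) > max_len:
                raise _ExpansionOverflow
            continue
        ids, probs = alts[sym]
        if len(ids) == 1:
            rule = ids[0]
        else:
            rule = ids[int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))]
        stack.extend(reversed(rhs[rule]))
    return "".join(out)


def generate_record(
    params: ParamSet,
    grammar: GrammarSpec,
    rng: np.random.Generator,
    max_len: int = 10_000,
) -> StructureRecord:
    """One joint (structure, sequence) draw from the model.

    Bases are emitted after the structure: unpaired positions i.i.d. from
    the unpaired emission distribution, paired positions jointly from the
    ordered-pair distribution — exactly the factorization of the model.
    """
    while True:
        try:
            structure = _expand_structure(params, grammar, rng, max_len)
            break
        except _ExpansionOverflow:
            continue
    n = len(structure)
    bases = [""] * (n + 1)
    pt = pair_table(structure)
    u_items = list(params.emission_unpaired.items())
    u_cum = np.cumsum([p for _, p in u_items])
    p_items = list(params.emission_pair.items())
    p_cum = np.cumsum([p for _, p in p_items])
    for i in range(1, n + 1):
        if pt[i] == 0:
            bases[i] = u_items[int(np.searchsorted(u_cum, rng.random(), side="right"))][0]
        elif pt[i] > i:
            b1, b2 = p_items[int(np.searchsorted(p_cum, rng.random(), side="right"))][0]
            bases[i], bases[pt[i]] = b1, b2
    return StructureRecord(structure=structure, sequence="".join(bases[1:]))


def generate_corpus(spec: CorpusSpec) -> list[StructureRecord]:
    """N records whose lengths fall in the window, by rejection sampling."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[StructureRecord] = []
    attempts = 0
    budget = spec.max_attempts_per_record * spec.size
    while len(records) < spec.size:
        if attempts >= budget:
            raise RuntimeError(
                f"length window {spec.length_range} unreachable: "
                f"{attempts} attempts yielded {len(records)}/{spec.size} records"
            )
        attempts += 1
        rec = generate_record(spec.params, spec.grammar, rng, max_len=10 * hi)
        if lo <= len(rec) <= hi:
            rec.id = f"synth_{len(records):05d}"
            records.append(rec)
    return records


def worked_fixture() -> dict:
    """Tiny fixed sequences with complete enumeration data.

    Regenerated deterministically on every call (fixed parameters, no
    randomness): for each sequence the full structure list with joint
    probabilities, the exact ensemble pair/unpaired probabilities, and the
    inside total.  This is the shared oracle bundle the test suite checks
    the dynamic programs and the sampler against.
    """
    from .inside_outside import compute_inside, enumerate_structures

    grammar = build_grammar(1, 1)
    params = default_paramset()
    bundle = {"grammar": grammar, "params": params, "entries": {}}
    for seq in ("ACG", "GCAU", "GGGAAACCC", "ACGUACGUAC"):
        structs = enumerate_structures(seq, grammar, params)
        total = sum(p for _, p in structs)
        n = len(seq)
        pmat = np.zeros((n + 1, n + 1))
        q = np.zeros(n + 1)
        for rec, p in structs:
            for (i, j) in rec.pairs:
                pmat[i, j] += p / total
            ptab = pair_table(rec.structure)
            for i in range(1, n + 1):
                if ptab[i] == 0:
                    q[i] += p / total
        inside = compute_inside(seq, params, grammar)
        bundle["entries"][seq] = {
            "structures": [(r.structure, p) for r, p in structs],
            "total": total,
            "pair_probs": pmat,
            "unpaired_probs": q,
            "inside_total": inside.total,
        }
    return bundle
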