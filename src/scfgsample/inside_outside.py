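"""Inside/outside probability charts and the brute-force enumeration oracle.

The inside probability ``alpha_X(i, j)`` is the probability that nonterminal
``X`` derives the sequence fragment ``r_i..r_j`` (1-based inclusive); the
outside probability ``beta_X(i, j)`` is the probability that the axiom
derives ``r_1..r_{i-1} X r_{j+1}..r_n``.  Both charts are filled by an
O(n^3)-time, O(n^2)-space span dynamic program over the binarized grammar
(the three-nonterminal rules go through probability-1 helper symbols
``h_AT``, ``h_AB``, ``h_AO``, ``h_AN``).

Probabilities are kept in linear space, not log space, because the
disturbance model adds raw errors to chart entries; underflow limits inputs
to a few hundred nucleotides, which covers the RNA families this package
targets (tRNA- and 5S-rRNA-scale molecules).

The empty span is encoded ``(i, i-1)`` and is populated only for the
epsilon-capable symbols ``U`` and ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .grammar import (
    BASES,
    GrammarSpec,
    ParamSet,
    StructureRecord,
    structure_probability,
)

__all__ = [
    "InsideTable",
    "OutsideTable",
    "compute_inside",
    "compute_outside",
    "enumerate_structures",
    "pair_probabilities",
    "ALL_SYMBOLS",
]

#: chart symbols in inside fill order (per span); helpers flagged by ``h_``
ALL_SYMBOLS = (
    "Z", "U", "C", "H", "B", "F", "A", "P", "h_AB", "G",
    "h_AN", "N", "O", "h_AO", "M", "L", "h_AT", "T", "S",
)

HELPERS = ("h_AT", "h_AB", "h_AO", "h_AN")


@dataclass
class InsideTable:
    """Inside chart ``alpha[sym][i, j]`` for one sequence.

    Arrays have shape ``(n + 2, n + 2)``; row index ``i`` runs 1..n+1 and
    column index ``j`` runs 0..n so that the empty span sits at
    ``[i, i - 1]``.
    """

    sequence: str
    grammar: GrammarSpec
    params: ParamSet
    alpha: dict[str, np.ndarray]

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> float:
        """Full-sequence probability ``alpha_S(1, n)``."""
        return float(self.alpha["S"][1, self.n])

    def value(self, symbol: str, i: int, j: int) -> float:
        return float(self.alpha[symbol][i, j])

    def to_tsv(self) -> str:
        """Chart dump (symbol, i, j, value) for nonzero entries."""
        lines = ["symbol\ti\tj\tvalue"]
        for sym in ALL_SYMBOLS:
            arr = self.alpha[sym]
            for i, j in zip(*np.nonzero(arr)):
                lines.append(f"{sym}\t{i}\t{j}\t{arr[i, j]:.12e}")
        return "\n".join(lines) + "\n"


@dataclass
class OutsideTable:
    sequence: str
    beta: dict[str, np.ndarray]

    def value(self, symbol: str, i: int, j: int) -> float:
        return float(self.beta[symbol][i, j])


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in sequence")
    if not seq:
        raise ValueError("empty sequence")
    return seq


def compute_inside(sequence: str, params: ParamSet, grammar: GrammarSpec) -> InsideTable:
    """Fill the inside chart bottom-up by span length."""
    seq = _validate_sequence(sequence)
    n = len(seq)
    mh, ms = grammar.min_hairpin, grammar.min_helix
    a = {sym: np.zeros((n + 2, n + 2)) for sym in ALL_SYMBOLS}
    Z, U, C, H, B, F, A, P = a["Z"], a["U"], a["C"], a["H"], a["B"], a["F"], a["A"], a["P"]
    G, N, O, M, Lh, T, S = a["G"], a["N"], a["O"], a["M"], a["L"], a["T"], a["S"]
    hAB, hAN, hAO, hAT = a["h_AB"], a["h_AN"], a["h_AO"], a["h_AT"]

    # empty spans (epsilon-capable symbols only)
    tr_p28_0 = params.tr("p28", 0)
    tr_p26_0 = params.tr("p26", 0)
    for i in range(1, n + 2):
        U[i, i - 1] = tr_p28_0
        N[i, i - 1] = tr_p26_0 * tr_p28_0

    em1 = np.array([params.em1(b) for b in seq])

    for L in range(1, n + 1):
        tr = {r.id: params.tr(r.id, L) for r in grammar.observable_rules}
        for i in range(1, n - L + 2):
            j = i + L - 1
            if L == 1:
                Z[i, i] = tr["p29"] * em1[i - 1]
                U[i, i] = tr["p27"] * Z[i, i] * U[i + 1, i]
                C[i, i] = tr["p8"] * Z[i, i]
                H[i, i] = tr["p16"] * 0.0 + tr["p17"] * Z[i, i]
                B[i, i] = tr["p22"] * Z[i, i]
            else:
                U[i, j] = tr["p27"] * Z[i, i] * U[i + 1, j]
                C[i, j] = tr["p7"] * Z[i, i] * C[i + 1, j]
                H[i, j] = tr["p16"] * Z[i, i] * H[i + 1, j]
                B[i, j] = tr["p21"] * Z[i, i] * B[i + 1, j]
            if L >= mh:
                zprod = 1.0
                for t in range(i, i + mh - 1):
                    zprod *= Z[t, t]
                F[i, j] = tr["p15"] * zprod * H[i + mh - 1, j]
            if L >= 2 * ms + 1:
                emp = 1.0
                for t in range(ms):
                    emp *= params.em2(seq[i + t - 1], seq[j - t - 1])
                A[i, j] = tr["p9"] * emp * Lh[i + ms, j - ms]
            if L >= 3:
                P[i, j] = (
                    tr["p10"] * params.em2(seq[i - 1], seq[j - 1]) * Lh[i + 1, j - 1]
                )
            if L >= 2:
                hAB[i, j] = np.dot(A[i, i:j], B[i + 1 : j + 1, j])
                G[i, j] = (
                    tr["p18"] * np.dot(B[i, i:j], A[i + 1 : j + 1, j])
                    + tr["p19"] * hAB[i, j]
                )
                if L >= 3:
                    G[i, j] += tr["p20"] * np.dot(B[i, i : j - 1], hAB[i + 1 : j, j])
            hAN[i, j] = np.dot(A[i, i : j + 1], N[i + 1 : j + 2, j])
            un_sum = U[i, i - 1] * hAN[i, j] + np.dot(U[i, i:j], hAN[i + 1 : j + 1, j])
            N[i, j] = tr["p25"] * un_sum + tr["p26"] * U[i, j]
            O[i, j] = tr["p24"] * un_sum
            hAO[i, j] = np.dot(A[i, i:j], O[i + 1 : j + 1, j])
            M[i, j] = tr["p23"] * (
                U[i, i - 1] * hAO[i, j] + np.dot(U[i, i : j - 1], hAO[i + 1 : j, j])
            )
            Lh[i, j] = (
                tr["p11"] * F[i, j]
                + tr["p12"] * P[i, j]
                + tr["p13"] * G[i, j]
                + tr["p14"] * M[i, j]
            )
            hAT[i, j] = np.dot(A[i, i:j], T[i + 1 : j + 1, j])
            T[i, j] = (
                tr["p2"] * C[i, j]
                + tr["p3"] * A[i, j]
                + tr["p5"] * hAT[i, j]
            )
            if L >= 2:
                T[i, j] += tr["p4"] * np.dot(C[i, i:j], A[i + 1 : j + 1, j])
            if L >= 3:
                T[i, j] += tr["p6"] * np.dot(C[i, i : j - 1], hAT[i + 1 : j, j])
            S[i, j] = tr["p1"] * T[i, j]

    return InsideTable(sequence=seq, grammar=grammar, params=params, alpha=a)


def compute_outside(
    sequence: str,
    params: ParamSet,
    grammar: GrammarSpec,
    inside: InsideTable,
) -> OutsideTable:
    """Fill the outside chart top-down, pushing mass from parents to children."""
    seq = _validate_sequence(sequence)
    if seq != inside.sequence:
        raise ValueError("inside table was computed for a different sequence")
    n = len(seq)
    mh, ms = grammar.min_hairpin, grammar.min_helix
    a = inside.alpha
    b = {sym: np.zeros((n + 2, n + 2)) for sym in ALL_SYMBOLS}
    b["S"][1, n] = 1.0
    aZ, aU, aC, aH, aB, aA, aO, aN, aT = (
        a["Z"], a["U"], a["C"], a["H"], a["B"], a["A"], a["O"], a["N"], a["T"],
    )
    ahAN, ahAO, ahAT, ahAB = a["h_AN"], a["h_AO"], a["h_AT"], a["h_AB"]

    order = (
        "S", "T", "L", "M", "O", "N", "h_AN", "h_AO", "h_AT",
        "A", "G", "h_AB", "P", "F", "C", "H", "B", "U", "Z",
    )

    for L in range(n, 0, -1):
        tr = {r.id: params.tr(r.id, L) for r in grammar.observable_rules}
        for i in range(1, n - L + 2):
            j = i + L - 1
            for sym in order:
                w = b[sym][i, j]
                if w == 0.0:
                    continue
                if sym == "S":
                    b["T"][i, j] += w * tr["p1"]
                elif sym == "T":
                    b["C"][i, j] += w * tr["p2"]
                    b["A"][i, j] += w * tr["p3"]
                    if L >= 2:
                        b["C"][i, i:j] += w * tr["p4"] * aA[i + 1 : j + 1, j]
                        b["A"][i + 1 : j + 1, j] += w * tr["p4"] * aC[i, i:j]
                    b["h_AT"][i, j] += w * tr["p5"]
                    if L >= 3:
                        b["C"][i, i : j - 1] += w * tr["p6"] * ahAT[i + 1 : j, j]
                        b["h_AT"][i + 1 : j, j] += w * tr["p6"] * aC[i, i : j - 1]
                elif sym == "h_AT":
                    b["A"][i, i:j] += w * aT[i + 1 : j + 1, j]
                    b["T"][i + 1 : j + 1, j] += w * aA[i, i:j]
                elif sym == "L":
                    b["F"][i, j] += w * tr["p11"]
                    b["P"][i, j] += w * tr["p12"]
                    b["G"][i, j] += w * tr["p13"]
                    b["M"][i, j] += w * tr["p14"]
                elif sym == "M":
                    wv = w * tr["p23"]
                    b["U"][i, i - 1] += wv * ahAO[i, j]
                    b["h_AO"][i, j] += wv * aU[i, i - 1]
                    if L >= 2:
                        b["U"][i, i : j - 1] += wv * ahAO[i + 1 : j, j]
                        b["h_AO"][i + 1 : j, j] += wv * aU[i, i : j - 1]
                elif sym == "h_AO":
                    b["A"][i, i:j] += w * aO[i + 1 : j + 1, j]
                    b["O"][i + 1 : j + 1, j] += w * aA[i, i:j]
                elif sym == "O" or sym == "N":
                    if sym == "O":
                        wv = w * tr["p24"]
                    else:
                        wv = w * tr["p25"]
                        b["U"][i, j] += w * tr["p26"]
                    b["U"][i, i - 1] += wv * ahAN[i, j]
                    b["h_AN"][i, j] += wv * aU[i, i - 1]
                    b["U"][i, i:j] += wv * ahAN[i + 1 : j + 1, j]
                    b["h_AN"][i + 1 : j + 1, j] += wv * aU[i, i:j]
                elif sym == "h_AN":
                    b["A"][i, i : j + 1] += w * aN[i + 1 : j + 2, j]
                    b["N"][i + 1 : j + 2, j] += w * aA[i, i : j + 1]
                elif sym == "A":
                    if L >= 2 * ms + 1:
                        emp = 1.0
                        for t in range(ms):
                            emp *= params.em2(seq[i + t - 1], seq[j - t - 1])
                        b["L"][i + ms, j - ms] += w * tr["p9"] * emp
                elif sym == "G":
                    if L >= 2:
                        b["B"][i, i:j] += w * tr["p18"] * aA[i + 1 : j + 1, j]
                        b["A"][i + 1 : j + 1, j] += w * tr["p18"] * aB[i, i:j]
                        b["h_AB"][i, j] += w * tr["p19"]
                    if L >= 3:
                        b["B"][i, i : j - 1] += w * tr["p20"] * ahAB[i + 1 : j, j]
                        b["h_AB"][i + 1 : j, j] += w * tr["p20"] * aB[i, i : j - 1]
                elif sym == "h_AB":
                    b["A"][i, i:j] += w * aB[i + 1 : j + 1, j]
                    b["B"][i + 1 : j + 1, j] += w * aA[i, i:j]
                elif sym == "P":
                    if L >= 3:
                        em = params.em2(seq[i - 1], seq[j - 1])
                        b["L"][i + 1, j - 1] += w * tr["p10"] * em
                elif sym == "F":
                    if L >= mh:
                        zprod = 1.0
                        for t in range(i, i + mh - 1):
                            zprod *= aZ[t, t]
                        b["H"][i + mh - 1, j] += w * tr["p15"] * zprod
                        for t in range(i, i + mh - 1):
                            other = tr["p15"] * aH[i + mh - 1, j]
                            for t2 in range(i, i + mh - 1):
                                if t2 != t:
                                    other *= aZ[t2, t2]
                            b["Z"][t, t] += w * other
                elif sym in ("C", "H", "B", "U"):
                    ext, end = {
                        "C": ("p7", "p8"),
                        "H": ("p16", "p17"),
                        "B": ("p21", "p22"),
                        "U": ("p27", None),
                    }[sym]
                    if sym == "U":
                        b["Z"][i, i] += w * tr[ext] * aU[i + 1, j]
                        b["U"][i + 1, j] += w * tr[ext] * aZ[i, i]
                    elif L == 1:
                        b["Z"][i, i] += w * tr[end]
                    else:
                        rest = a[sym][i + 1, j]
                        b["Z"][i, i] += w * tr[ext] * rest
                        b[sym][i + 1, j] += w * tr[ext] * aZ[i, i]
                # Z: terminal emission, nothing to push

    # empty spans: N(i, i-1) -> U(i, i-1) via p26
    tr_p26_0 = params.tr("p26", 0)
    for i in range(1, n + 2):
        b["U"][i, i - 1] += b["N"][i, i - 1] * tr_p26_0

    return OutsideTable(sequence=seq, beta=b)


def pair_probabilities(
    inside: InsideTable,
    outside: OutsideTable,
    params: ParamSet,
    grammar: GrammarSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact ensemble base-pair matrix ``p[i, j]`` and unpaired vector ``q[i]``.

    ``p[i, j]`` sums, over the pair-emitting rule applications that put
    ``(i, j)`` together, outside x transition x emission x inner inside,
    normalized by the full-sequence probability.  The identity
    ``q_i + sum_j p[i, j] == 1`` holds for every position.
    """
    seq = inside.sequence
    n = inside.n
    total = inside.total
    if total <= 0.0:
        raise ValueError("sequence has zero total probability under the model")
    mh, ms = grammar.min_hairpin, grammar.min_helix
    a, b = inside.alpha, outside.beta
    p = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            L = j - i + 1
            if L >= 2 * ms + 1 and b["A"][i, j] > 0.0:
                emp = 1.0
                for t in range(ms):
                    emp *= params.em2(seq[i + t - 1], seq[j - t - 1])
                w = b["A"][i, j] * params.tr("p9", L) * emp * a["L"][i + ms, j - ms]
                w /= total
                for t in range(ms):
                    p[i + t, j - t] += w
            if L >= 3 and b["P"][i, j] > 0.0:
                w = (
                    b["P"][i, j]
                    * params.tr("p10", L)
                    * params.em2(seq[i - 1], seq[j - 1])
                    * a["L"][i + 1, j - 1]
                    / total
                )
                p[i, j] += w
    q = np.zeros(n + 1)
    for i in range(1, n + 1):
        q[i] = b["Z"][i, i] * a["Z"][i, i] / total
    return p, q


# ---------------------------------------------------------------------------
# brute-force oracle


def _candidate_structures(n: int, min_hairpin: int) -> list[str]:
    """All balanced non-crossing dot-bracket words of length ``n`` whose
    loops each enclose >= ``min_hairpin`` unpaired-or-paired positions
    recursively satisfying the same constraint."""

    @lru_cache(maxsize=None)
    def gen(length: int) -> tuple[str, ...]:
        if length == 0:
            return ("",)
        out = ["." + rest for rest in gen(length - 1)]
        for inner_len in range(min_hairpin, length - 1):
            for inner in gen(inner_len):
                for rest in gen(length - 2 - inner_len):
                    out.append("(" + inner + ")" + rest)
        return tuple(out)

    return list(gen(n))


def enumerate_structures(
    sequence: str,
    grammar: GrammarSpec,
    params: ParamSet,
    cap: int = 14,
) -> list[tuple[StructureRecord, float]]:
    """Exhaustively enumerate all feasible structures with their joint
    probabilities, in lexicographic dot-bracket order.

    Exponential-time validation oracle; refuses sequences longer than
    ``cap``.
    """
    seq = _validate_sequence(sequence)
    n = len(seq)
    if n > cap:
        raise ValueError(f"sequence length {n} exceeds enumeration cap {cap}")
    from .grammar import ParseError, parse_structure

    results = []
    for s in sorted(_candidate_structures(n, grammar.min_hairpin)):
        rec = StructureRecord(structure=s, sequence=seq)
        if grammar.min_helix > 1:
            try:
                parse_structure(rec, grammar)
            except ParseError:
                continue
        results.append((rec, structure_probability(rec, params, grammar)))
    return results
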