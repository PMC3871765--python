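"""Controlled random errors on inside-probability charts.

Four error types skew a precomputed inside chart entry-by-entry:

``mep``  maximum error percentage — relative, uniform on
         ``[-prob * alpha, +prob * alpha]``
``fep``  fixed error percentage — relative, the two endpoints
         ``{-prob * alpha, +prob * alpha}`` with probability 1/2 each
``mev``  maximum error value — absolute, uniform on ``[-prob, +prob]``
``fev``  fixed error value — absolute, the endpoints ``{-prob, +prob}``

Each skewed entry is clamped back into [0, 1].  Errors are gated three
ways: by intermediate symbol (a subset of the sampling symbols
``T C A P F G B M O N U``; the forced-derivation symbols ``S L H Z`` and
the binarization helpers are never disturbed), by a span-length window
(``op='+'`` disturbs spans longer than ``win``, ``op='-'`` spans of length
at most ``win``), and implicitly by the error type: relative errors keep
zero entries at exactly zero, so the support of the ensemble distribution —
which structures are possible at all — is preserved; absolute errors may
create or destroy support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grammar import SAMPLING_SYMBOLS
from .inside_outside import ALL_SYMBOLS, InsideTable

__all__ = ["DisturbanceSpec", "DisturbedInsideTable", "draw_error", "disturb"]

FUNCS = ("mep", "fep", "mev", "fev")
EPSILON_SYMBOLS = ("U", "N")  # symbols with populated empty-span entries


@dataclass(frozen=True)
class DisturbanceSpec:
    """Which entries get disturbed, how strongly, and with which seed.

    ``win=0`` with ``op='+'`` (the default; equivalently ``win >= n`` with
    ``op='-'``) disturbs every span length — the ungated variant.
    """

    func: str
    prob: float
    win: int = 0
    op: str = "+"
    symbols: tuple[str, ...] = SAMPLING_SYMBOLS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.func not in FUNCS:
            raise ValueError(f"func must be one of {FUNCS}, got {self.func!r}")
        if not 0.0 < self.prob <= 1.0:
            raise ValueError(f"prob must be in (0, 1], got {self.prob}")
        if self.op not in ("+", "-"):
            raise ValueError(f"op must be '+' or '-', got {self.op!r}")
        object.__setattr__(self, "symbols", tuple(self.symbols))
        extra = set(self.symbols) - set(SAMPLING_SYMBOLS)
        if extra:
            raise ValueError(f"symbols {sorted(extra)} are not disturbable")

    @classmethod
    def all_lengths(cls, func: str, prob: float, symbols=SAMPLING_SYMBOLS, seed: int = 0):
        """The ungated variant: errors for every subword length."""
        return cls(func=func, prob=prob, win=0, op="+", symbols=symbols, seed=seed)

    def gate(self, span_length: int) -> bool:
        if self.op == "+":
            return span_length > self.win
        return span_length <= self.win

    def to_dict(self) -> dict:
        return {
            "func": self.func,
            "prob": self.prob,
            "win": self.win,
            "op": self.op,
            "symbols": list(self.symbols),
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, doc: dict) -> "DisturbanceSpec":
        return cls(
            func=doc["func"],
            prob=float(doc["prob"]),
            win=int(doc.get("win", -1)),
            op=doc.get("op", "-"),
            symbols=tuple(doc.get("symbols", SAMPLING_SYMBOLS)),
            seed=int(doc.get("seed", 0)),
        )


@dataclass
class DisturbedInsideTable:
    """A skewed copy of an inside chart.

    Arrays of undisturbed symbols are shared with the exact table;
    disturbed symbols get fresh arrays.  ``mask[sym]`` marks entries whose
    value actually changed.
    """

    exact: InsideTable
    spec: DisturbanceSpec
    alpha: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]

    @property
    def sequence(self) -> str:
        return self.exact.sequence

    @property
    def grammar(self):
        return self.exact.grammar

    @property
    def params(self):
        return self.exact.params

    @property
    def n(self) -> int:
        return self.exact.n

    def value(self, symbol: str, i: int, j: int) -> float:
        return float(self.alpha[symbol][i, j])


def draw_error(
    spec: DisturbanceSpec,
    alpha: float,
    span_length: int,
    symbol: str,
    rng: np.random.Generator,
) -> float:
    """One error draw for an entry that already passed the gating.

    Relative types scale with the exact value (so an exact zero stays
    zero); absolute types do not.
    """
    if spec.func == "mep":
        return float(spec.prob * alpha * rng.uniform(-1.0, 1.0))
    if spec.func == "fep":
        return float(spec.prob * alpha * (1.0 if rng.random() < 0.5 else -1.0))
    if spec.func == "mev":
        return float(rng.uniform(-spec.prob, spec.prob))
    return float(spec.prob * (1.0 if rng.random() < 0.5 else -1.0))


def _span_mask(n: int, symbol: str, spec: DisturbanceSpec) -> np.ndarray:
    """Boolean gate over the (n+2, n+2) chart for one symbol."""
    mask = np.zeros((n + 2, n + 2), dtype=bool)
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            mask[i, j] = spec.gate(j - i + 1)
    if symbol in EPSILON_SYMBOLS and spec.gate(0):
        for i in range(1, n + 2):
            mask[i, i - 1] = True
    return mask


def disturb(inside: InsideTable, spec: DisturbanceSpec) -> DisturbedInsideTable:
    """Apply one independent error draw to every gated chart entry.

    Iteration order is fixed (symbols in the order of the sampling-symbol
    list, then i, then j) so results are reproducible across platforms for
    a given seed.
    """
    n = inside.n
    rng = np.random.default_rng(spec.seed)
    alpha = {sym: inside.alpha[sym] for sym in ALL_SYMBOLS}  # shared views
    mask: dict[str, np.ndarray] = {}
    for sym in SAMPLING_SYMBOLS:
        if sym not in spec.symbols:
            continue
        gate = _span_mask(n, sym, spec)
        idx = np.nonzero(gate)  # row-major: i, then j
        count = idx[0].size
        if count == 0:
            continue
        vals = inside.alpha[sym][idx]
        if spec.func == "mep":
            err = vals * spec.prob * rng.uniform(-1.0, 1.0, size=count)
        elif spec.func == "fep":
            err = vals * spec.prob * np.where(rng.random(count) < 0.5, 1.0, -1.0)
        elif spec.func == "mev":
            err = rng.uniform(-spec.prob, spec.prob, size=count)
        else:  # fev
            err = spec.prob * np.where(rng.random(count) < 0.5, 1.0, -1.0)
        skewed = np.clip(vals + err, 0.0, 1.0)
        arr = inside.alpha[sym].copy()
        arr[idx] = skewed
        alpha[sym] = arr
        changed = np.zeros((n + 2, n + 2), dtype=bool)
        changed[idx] = skewed != vals
        mask[sym] = changed
    return DisturbedInsideTable(exact=inside, spec=spec, alpha=alpha, mask=mask)
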