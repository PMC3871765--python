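"""Extracting one predicted structure from a sample set.

Four principles:

* **MP** — most probable: the sampled candidate with the highest exact
  model probability (always scored with the undisturbed parameters, even
  when the sample came from a skewed chart: a derivation's probability
  depends only on the grammar parameters).
* **MF** — most frequent: the candidate sampled most often.
* **MEA** — maximum expected accuracy: a new structure maximizing
  ``sum_i(unpaired) q_i + 2*gamma*sum_(i,j)(paired) p_ij`` over all
  non-crossing structures, where p/q are the observed sample frequencies.
* **centroid** — the structure maximizing
  ``sum_(i,j)(paired) ((gamma+1)*p_ij - 1)``; at gamma=1 this is exactly
  the set of base pairs occurring in more than 50% of the sample.

``gamma`` trades sensitivity against positive predictive value; gamma=1 is
the neutral setting.  MEA/centroid structures are ensemble summaries, not
grammar derivations: only balance, non-crossing and a one-base minimum
hairpin are enforced on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grammar import (
    GrammarSpec,
    ParamSet,
    ParseError,
    StructureRecord,
    pair_table,
    structure_probability,
)
from .sampler import SampleSet

__all__ = [
    "FrequencyProfile",
    "Prediction",
    "frequency_profile",
    "mp_structure",
    "mf_structure",
    "gamma_mea",
    "gamma_centroid",
    "predict",
]


@dataclass
class FrequencyProfile:
    """Observed pair/unpaired frequencies of a sample.

    ``p[i, j]`` (1-based, i < j) is the fraction of sampled structures
    containing pair (i, j); ``q[i]`` the fraction leaving i unpaired.
    """

    p: np.ndarray
    q: np.ndarray
    size: int

    @property
    def n(self) -> int:
        return self.q.shape[0] - 1


@dataclass
class Prediction:
    principle: str
    structure: StructureRecord
    gamma: float | None = None


def frequency_profile(sample: SampleSet) -> FrequencyProfile:
    if sample.size < 1:
        raise ValueError("empty sample")
    n = len(sample.sequence)
    p = np.zeros((n + 1, n + 1))
    q = np.zeros(n + 1)
    for structure, count in sample.counts.items():
        pt = pair_table(structure)
        for i in range(1, n + 1):
            if pt[i] == 0:
                q[i] += count
            elif pt[i] > i:
                p[i, pt[i]] += count
    p /= sample.size
    q /= sample.size
    return FrequencyProfile(p=p, q=q, size=sample.size)


def mp_structure(
    sample: SampleSet, params: ParamSet, grammar: GrammarSpec
) -> Prediction:
    """Highest exact-probability candidate among the distinct sampled
    structures; ties broken toward the lexicographically smaller string."""
    best: tuple[float, str] | None = None
    for structure in sample.counts:
        try:
            prob = structure_probability(
                StructureRecord(structure=structure, sequence=sample.sequence),
                params,
                grammar,
            )
        except ParseError:
            warnings.warn(
                f"sampled structure {structure!r} is not derivable under the "
                "grammar; excluded from MP candidacy",
                stacklevel=2,
            )
            continue
        key = (-prob, structure)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no parsable candidate in sample")
    return Prediction(
        principle="MP",
        structure=StructureRecord(structure=best[1], sequence=sample.sequence),
    )


def mf_structure(
    sample: SampleSet,
    params: ParamSet | None = None,
    grammar: GrammarSpec | None = None,
) -> Prediction:
    """Most frequently sampled structure; ties broken by exact probability
    (when parameters are supplied), then lexicographically."""
    counts = sample.counts
    best = None
    for structure, count in counts.items():
        prob = 0.0
        if params is not None and grammar is not None:
            try:
                prob = structure_probability(
                    StructureRecord(structure=structure, sequence=sample.sequence),
                    params,
                    grammar,
                )
            except ParseError:
                prob = 0.0
        key = (-count, -prob, structure)
        if best is None or key < best:
            best = key
    return Prediction(
        principle="MF",
        structure=StructureRecord(structure=best[2], sequence=sample.sequence),
    )


def _accuracy_dp(
    pair_score: np.ndarray, unpaired_score: np.ndarray, n: int
) -> str:
    """Nussinov-style maximization over non-crossing structures.

    ``pair_score[i, j]`` is the credit for pairing (i, j) (pairs need
    j >= i + 2, i.e. hairpins enclose at least one base), and
    ``unpaired_score[i]`` for leaving i unpaired.  Ties prefer fewer pairs
    and, beyond that, leaving the leftmost position unpaired — the
    traceback is therefore deterministic.
    """
    NEG = -1e18
    val = np.zeros((n + 2, n + 2))
    npairs = np.zeros((n + 2, n + 2), dtype=int)
    choice = np.zeros((n + 2, n + 2), dtype=int)  # 0: i unpaired, k: pair (i, k)
    eps = 1e-12
    for i in range(n, 0, -1):
        for j in range(i, n + 1):
            bv = val[i + 1, j] + unpaired_score[i]
            bp = npairs[i + 1, j]
            bc = 0
            for k in range(i + 2, j + 1):
                v = pair_score[i, k] + val[i + 1, k - 1] + val[k + 1, j]
                c = 1 + npairs[i + 1, k - 1] + npairs[k + 1, j]
                if v > bv + eps or (v > bv - eps and c < bp):
                    bv, bp, bc = v, c, k
            val[i, j] = bv
            npairs[i, j] = bp
            choice[i, j] = bc
    chars = ["."] * (n + 1)
    stack = [(1, n)]
    while stack:
        i, j = stack.pop()
        if i > j:
            continue
        k = choice[i, j]
        if k == 0:
            stack.append((i + 1, j))
        else:
            chars[i], chars[k] = "(", ")"
            stack.append((i + 1, k - 1))
            stack.append((k + 1, j))
    return "".join(chars[1:])


def gamma_mea(profile: FrequencyProfile, gamma: float = 1.0) -> Prediction:
    """Maximum-expected-accuracy structure for trade-off ``gamma``."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    n = profile.n
    structure = _accuracy_dp(2.0 * gamma * profile.p, profile.q, n)
    return Prediction(
        principle="MEA", gamma=gamma, structure=StructureRecord(structure=structure)
    )


def gamma_centroid(profile: FrequencyProfile, gamma: float = 1.0) -> Prediction:
    """gamma-centroid structure; gamma=1 gives the >50%-pair consensus."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    n = profile.n
    structure = _accuracy_dp((gamma + 1.0) * profile.p - 1.0, np.zeros(n + 1), n)
    return Prediction(
        principle="centroid", gamma=gamma, structure=StructureRecord(structure=structure)
    )


def predict(
    sample: SampleSet,
    principle: str,
    params: ParamSet | None = None,
    grammar: GrammarSpec | None = None,
    gamma: float = 1.0,
    profile: FrequencyProfile | None = None,
) -> Prediction:
    """Dispatch on principle name (``mp``, ``mf``, ``mea``, ``centroid``)."""
    key = principle.lower()
    if key == "mp":
        if params is None or grammar is None:
            raise ValueError("MP prediction needs params and grammar")
        return mp_structure(sample, params, grammar)
    if key == "mf":
        return mf_structure(sample, params, grammar)
    if profile is None:
        profile = frequency_profile(sample)
    if key == "mea":
        return gamma_mea(profile, gamma)
    if key == "centroid":
        return gamma_centroid(profile, gamma)
    raise ValueError(f"unknown prediction principle {principle!r}")
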