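import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scfgsample import build_grammar, default_paramset
from scfgsample.grammar import BASES, GrammarSpec, ParamSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grammar() -> GrammarSpec:
    return build_grammar(1, 1)


@pytest.fixture(scope="session")
def params() -> ParamSet:
    return default_paramset()


def random_paramset(rng: np.random.Generator, grammar: GrammarSpec) -> ParamSet:
    """A random valid parameter set (Dirichlet over each simplex)."""
    transition: dict[str, float] = {}
    premises: dict[str, list[str]] = {}
    for rule in grammar.observable_rules:
        premises.setdefault(rule.premise, []).append(rule.id)
    for premise, ids in premises.items():
        probs = rng.dirichlet(np.ones(len(ids)))
        for rid, p in zip(ids, probs):
            transition[rid] = float(p)
    unp = rng.dirichlet(np.ones(4))
    pairs = rng.dirichlet(np.ones(16))
    return ParamSet(
        transition=transition,
        emission_unpaired={b: float(p) for b, p in zip(BASES, unp)},
        emission_pair={
            (a, c): float(p)
            for (a, c), p in zip(
                [(a, c) for a in BASES for c in BASES], pairs
            )
        },
    )


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))
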