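"""Choice-set construction and the dead-end-tolerant recursive sampler."""

from collections import Counter

import numpy as np
import pytest

from scfgsample import (
    DisturbanceSpec,
    StructureSampler,
    build_choice_set,
    compute_inside,
    compute_outside,
    disturb,
    enumerate_structures,
    parse_structure,
    reachable_contexts,
    sample_set,
    sample_structure,
)

from .conftest import random_paramset, random_sequence


@pytest.fixture(scope="module")
def inside8(grammar, params):
    return compute_inside("GGGAAACC", params, grammar)


class TestChoiceSets:
    def test_normalized_probabilities_sum_to_one(self, grammar, params):
        rng = np.random.default_rng(21)
        seq = random_sequence(rng, 25)
        inside = compute_inside(seq, params, grammar)
        contexts = reachable_contexts(inside, params, grammar)
        assert contexts
        for (sym, i, j) in contexts:
            cs = build_choice_set(sym, i, j, inside, params, grammar)
            assert cs.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_norm_equals_inside_value_on_exact_chart(self, inside8, grammar, params):
        for (sym, i, j) in reachable_contexts(inside8, params, grammar):
            cs = build_choice_set(sym, i, j, inside8, params, grammar)
            assert cs.norm == pytest.approx(inside8.alpha[sym][i, j], rel=1e-12)

    def test_positive_inside_value_gives_nonempty_choice_set(self, inside8, grammar, params):
        n = inside8.n
        for sym in ("T", "L", "A", "G", "M"):
            for i in range(1, n + 1):
                for j in range(i, n + 1):
                    if inside8.alpha[sym][i, j] > 0:
                        cs = build_choice_set(sym, i, j, inside8, params, grammar)
                        assert len(cs) > 0

    def test_option_weights_match_conditional_ensemble(self, grammar, params):
        # the normalized T-level decision at the top must equal the exact
        # conditional probabilities computed from exhaustive enumeration
        seq = "GGAAACCA"
        inside = compute_inside(seq, params, grammar)
        structs = enumerate_structures(seq, grammar, params)
        total = sum(p for _, p in structs)
        # conditional probability that the whole sequence is unpaired equals
        # the weight of the T -> C option at (1, n)
        p_unpaired = sum(p for r, p in structs if "(" not in r.structure) / total
        cs = build_choice_set("T", 1, len(seq), inside, params, grammar)
        w = {r: 0.0 for r in cs.rule_ids}
        for r, wt in zip(cs.rule_ids, cs.weights):
            w[r] += wt
        assert w["p2"] / cs.norm == pytest.approx(p_unpaired, rel=1e-10)

    def test_outside_factor_cancels(self, inside8, grammar, params):
        outside = compute_outside(inside8.sequence, params, grammar, inside8)
        for (sym, i, j) in reachable_contexts(inside8, params, grammar):
            plain = build_choice_set(sym, i, j, inside8, params, grammar)
            weighted = build_choice_set(
                sym, i, j, inside8, params, grammar, outside=outside
            )
            assert plain.rule_ids == weighted.rule_ids
            assert plain.splits == weighted.splits
            np.testing.assert_allclose(
                plain.probabilities, weighted.probabilities, rtol=1e-12
            )


class TestSampling:
    def test_two_bases_always_unpaired(self, grammar, params):
        inside = compute_inside("GC", params, grammar)
        rng = np.random.default_rng(0)
        for _ in range(25):
            assert sample_structure(inside, params, grammar, rng).structure == ".."

    def test_same_seed_reproduces_sample_set(self, inside8, grammar, params):
        s1 = sample_set(inside8, params, grammar, 100, np.random.default_rng(5))
        s2 = sample_set(inside8, params, grammar, 100, np.random.default_rng(5))
        assert [a.structure for a in s1.structures] == [
            b.structure for b in s2.structures
        ]

    def test_size_validation(self, inside8, grammar, params):
        with pytest.raises(ValueError):
            sample_set(inside8, params, grammar, 0, np.random.default_rng(0))

    def test_empirical_distribution_approaches_ensemble(self, inside8, grammar, params):
        structs = enumerate_structures(inside8.sequence, grammar, params)
        total = sum(p for _, p in structs)
        dist = {r.structure: p / total for r, p in structs}
        rng = np.random.default_rng(77)
        draws = StructureSampler(inside8, params, grammar).sample_set(20_000, rng)
        counts = draws.counts
        tv = 0.5 * sum(
            abs(counts.get(s, 0) / draws.size - p) for s, p in dist.items()
        ) + 0.5 * sum(c / draws.size for s, c in counts.items() if s not in dist)
        assert tv <= 0.02

    def test_exact_chart_never_falls_back(self, grammar, params):
        rng = np.random.default_rng(13)
        for _ in range(3):
            seq = random_sequence(rng, int(rng.integers(10, 30)))
            inside = compute_inside(seq, params, grammar)
            sampler = StructureSampler(inside, params, grammar)
            for _ in range(300):
                assert not sampler.sample(rng).fallback_events

    def test_relative_disturbance_keeps_exact_support(self, grammar, params):
        seq = "GGGAAACCCA"
        inside = compute_inside(seq, params, grammar)
        support = {
            r.structure for r, p in enumerate_structures(seq, grammar, params) if p > 0
        }
        rng = np.random.default_rng(4)
        for func in ("mep", "fep"):
            table = disturb(inside, DisturbanceSpec.all_lengths(func, 0.99, seed=8))
            sampler = StructureSampler(table, params, grammar)
            for _ in range(1500):
                s = sampler.sample(rng)
                assert s.structure in support
                assert not s.fallback_events

    def test_heavy_absolute_disturbance_triggers_fallback_but_stays_valid(
        self, grammar, params
    ):
        seq = "GGGAAACCCAUGCAU"
        inside = compute_inside(seq, params, grammar)
        table = disturb(inside, DisturbanceSpec.all_lengths("fev", 0.5, seed=8))
        rng = np.random.default_rng(4)
        sampler = StructureSampler(table, params, grammar)
        n_fallback = 0
        for _ in range(1000):
            s = sampler.sample(rng)
            parse_structure(s.structure, grammar)  # always a valid structure
            n_fallback += bool(s.fallback_events)
        assert n_fallback > 0

    def test_trace_records_decisions(self, inside8, grammar, params):
        sampler = StructureSampler(inside8, params, grammar, record_trace=True)
        s = sampler.sample(np.random.default_rng(0))
        assert s.trace
        assert s.trace[0][0] == "S"
        symbols, spans, rules, splits = zip(*s.trace)
        assert all(r.startswith("p") for r in rules)

    def test_loop_annotations_match_derivation(self, grammar, params):
        from scfgsample.grammar import annotate_structure

        rng = np.random.default_rng(2)
        seq = random_sequence(rng, 40)
        inside = compute_inside(seq, params, grammar)
        sampler = StructureSampler(inside, params, grammar)
        for _ in range(50):
            s = sampler.sample(rng)
            assert s.loop_annotation == annotate_structure(s.structure, grammar)

    def test_random_model_sampling_matches_oracle(self, grammar):
        # full pipeline at a random parameter set, distribution-level check
        rng = np.random.default_rng(31)
        pset = random_paramset(rng, grammar)
        seq = random_sequence(rng, 7)
        inside = compute_inside(seq, pset, grammar)
        structs = enumerate_structures(seq, grammar, pset)
        total = sum(p for _, p in structs)
        dist = {r.structure: p / total for r, p in structs}
        counts = Counter(
            s.structure
            for s in StructureSampler(inside, pset, grammar)
            .sample_set(10_000, rng)
            .structures
        )
        tv = 0.5 * sum(
            abs(counts.get(s, 0) / 10_000 - p) for s, p in dist.items()
        ) + 0.5 * sum(c / 10_000 for s, c in counts.items() if s not in dist)
        assert tv <= 0.03
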