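"""Prediction principles: MP, MF, MEA and centroid families."""

import numpy as np
import pytest

from scfgsample import (
    StructureRecord,
    compute_inside,
    enumerate_structures,
    frequency_profile,
    gamma_centroid,
    gamma_mea,
    mf_structure,
    mp_structure,
)
from scfgsample.grammar import pair_table
from scfgsample.inside_outside import _candidate_structures
from scfgsample.predictions import FrequencyProfile
from scfgsample.sampler import SampledStructure, SampleSet, StructureSampler

from .conftest import random_sequence


def make_sample(sequence: str, counted: dict[str, int]) -> SampleSet:
    structures = []
    for s, c in counted.items():
        structures.extend(
            SampledStructure(structure=s, loop_annotation=None) for _ in range(c)
        )
    return SampleSet(sequence=sequence, structures=structures)


def random_profile(rng: np.random.Generator, n: int) -> FrequencyProfile:
    """A frequency profile from a random small sample of real structures."""
    candidates = _candidate_structures(n, 1)
    picks = rng.choice(len(candidates), size=30)
    counts: dict[str, int] = {}
    for k in picks:
        counts[candidates[k]] = counts.get(candidates[k], 0) + 1
    return frequency_profile(make_sample("A" * n, counts))


class TestProfile:
    def test_row_sum_identity(self, grammar, params):
        seq = "GGGAAACC"
        inside = compute_inside(seq, params, grammar)
        sample = StructureSampler(inside, params, grammar).sample_set(
            500, np.random.default_rng(0)
        )
        prof = frequency_profile(sample)
        n = len(seq)
        rows = prof.q[1:] + prof.p.sum(axis=1)[1:] + prof.p.sum(axis=0)[1:]
        assert np.abs(rows - 1.0).max() < 1e-12

    def test_single_structure_gives_indicator_profile(self):
        prof = frequency_profile(make_sample("GGAAACC", {"((...))": 10}))
        assert prof.p[1, 7] == 1.0 and prof.p[2, 6] == 1.0
        assert list(prof.q[3:6]) == [1.0, 1.0, 1.0]
        assert prof.q[1] == 0.0

    def test_converges_to_exact_pair_probabilities(self, grammar, params):
        from scfgsample import compute_outside, pair_probabilities

        seq = "GGAAACCA"
        inside = compute_inside(seq, params, grammar)
        outside = compute_outside(seq, params, grammar, inside)
        pm, q = pair_probabilities(inside, outside, params, grammar)
        sample = StructureSampler(inside, params, grammar).sample_set(
            50_000, np.random.default_rng(1)
        )
        prof = frequency_profile(sample)
        assert np.abs(prof.p - pm).max() < 0.01
        assert np.abs(prof.q - q)[1:].max() < 0.01


class TestSelection:
    def test_mp_on_uniform_sample_is_that_structure(self, grammar, params):
        sample = make_sample("GGAAACC", {"((...))": 5})
        assert mp_structure(sample, params, grammar).structure.structure == "((...))"

    def test_mp_equals_enumeration_argmax_under_full_coverage(self, grammar, params):
        seq = "GGAAACC"
        structs = enumerate_structures(seq, grammar, params)
        best = max(structs, key=lambda t: (t[1], t[0].structure))[0].structure
        sample = make_sample(seq, {r.structure: 1 for r, _ in structs})
        assert mp_structure(sample, params, grammar).structure.structure == best

    def test_mp_tie_breaks_lexicographically(self, grammar):
        from .conftest import random_paramset

        pset = random_paramset(np.random.default_rng(0), grammar)
        # same shape, different position: identical transition product; force
        # equal emission products by a uniform emission model
        for b in pset.emission_unpaired:
            pset.emission_unpaired[b] = 0.25
        for k in pset.emission_pair:
            pset.emission_pair[k] = 1 / 16
        sample = make_sample("AAAAAAA", {"(...)..": 1, "..(...)": 1})
        assert mp_structure(sample, pset, grammar).structure.structure == "(...).."

    def test_mf_majority(self, grammar, params):
        sample = make_sample("GCAU", {"....": 700, "(..)": 300})
        assert mf_structure(sample).structure.structure == "...."

    def test_mf_tie_falls_back_to_probability(self, grammar, params):
        sample = make_sample("GGAAACC", {"((...))": 1, ".......": 1})
        pred = mf_structure(sample, params, grammar)
        from scfgsample import structure_probability

        pa = structure_probability(
            StructureRecord("((...))", "GGAAACC"), params, grammar
        )
        pb = structure_probability(
            StructureRecord(".......", "GGAAACC"), params, grammar
        )
        expected = "((...))" if pa > pb else "......."
        assert pred.structure.structure == expected

    def test_mf_agrees_with_mp_on_large_undisturbed_sample(self, grammar, params):
        rng = np.random.default_rng(15)
        agree = 0
        trials = 10
        for _ in range(trials):
            seq = random_sequence(rng, 8)
            inside = compute_inside(seq, params, grammar)
            sample = StructureSampler(inside, params, grammar).sample_set(4000, rng)
            mp = mp_structure(sample, params, grammar).structure.structure
            mf = mf_structure(sample, params, grammar).structure.structure
            agree += mp == mf
        assert agree >= trials - 2  # identical in the vast majority of cases


class TestMEA:
    def test_unpaired_profile_gives_open_chain(self):
        prof = frequency_profile(make_sample("ACGUA", {".....": 4}))
        for gamma in (0.0, 1.0, 16.0):
            assert gamma_mea(prof, gamma).structure.structure == "....."

    def test_gamma_zero_gives_open_chain(self):
        rng = np.random.default_rng(1)
        prof = random_profile(rng, 9)
        assert gamma_mea(prof, 0.0).structure.structure == "." * 9

    def test_dp_equals_exhaustive_maximum(self):
        rng = np.random.default_rng(2)
        for n in (6, 9, 12):
            prof = random_profile(rng, n)
            for gamma in (0.25, 1.0, 4.0):
                structure = gamma_mea(prof, gamma).structure.structure

                def objective(s: str) -> float:
                    pt = pair_table(s)
                    v = sum(prof.q[i] for i in range(1, n + 1) if pt[i] == 0)
                    v += sum(
                        2 * gamma * prof.p[i, pt[i]]
                        for i in range(1, n + 1)
                        if pt[i] > i
                    )
                    return v

                best = max(objective(s) for s in _candidate_structures(n, 1))
                assert objective(structure) == pytest.approx(best, abs=1e-9)


class TestCentroid:
    def test_gamma_one_is_majority_pair_set(self):
        rng = np.random.default_rng(3)
        for n in (6, 9, 12):
            prof = random_profile(rng, n)
            pred = gamma_centroid(prof, 1.0).structure
            majority = {
                (i, j)
                for i in range(1, n + 1)
                for j in range(i + 1, n + 1)
                if prof.p[i, j] > 0.5
            }
            assert pred.pairs == majority

    def test_gamma_zero_is_empty(self):
        prof = random_profile(np.random.default_rng(4), 10)
        assert gamma_centroid(prof, 0.0).structure.pairs == set()

    def test_pair_count_monotone_in_gamma(self):
        rng = np.random.default_rng(5)
        prof = random_profile(rng, 12)
        counts = [
            len(gamma_centroid(prof, g).structure.pairs)
            for g in (0.0, 0.5, 1.0, 2.0, 8.0, 64.0)
        ]
        assert counts == sorted(counts)

    def test_dp_equals_exhaustive_maximum(self):
        rng = np.random.default_rng(6)
        for n in (8, 11):
            prof = random_profile(rng, n)
            for gamma in (0.5, 1.0, 3.0):
                pred = gamma_centroid(prof, gamma).structure

                def objective(pairs) -> float:
                    return sum((gamma + 1) * prof.p[i, j] - 1 for (i, j) in pairs)

                best = max(
                    objective(StructureRecord(s).pairs)
                    for s in _candidate_structures(n, 1)
                )
                assert objective(pred.pairs) == pytest.approx(best, abs=1e-9)
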