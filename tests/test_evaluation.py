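"""Accuracy metrics, ROC/AUC, abstract shapes, quality statistics, CV."""

import numpy as np
import pytest

from scfgsample import (
    DisturbanceSpec,
    StructureRecord,
    compute_inside,
    count_relevant,
    cross_validate,
    disturb,
    loop_profile,
    quality_metrics,
    roc_auc,
    sens_ppv,
    shape,
)
from scfgsample.evaluation import (
    CVConfig,
    LOOP_TYPES,
    SHAPE_LEVELS,
    _auc_from_points,
    default_gamma_grid,
)
from scfgsample.sampler import SampledStructure, SampleSet, StructureSampler
from scfgsample.synthetic import CorpusSpec, generate_corpus

from .test_predictions import make_sample


class TestSensPPV:
    def test_printed_formula_arithmetic(self):
        s = sens_ppv({(1, 5), (3, 7)}, {(1, 5), (2, 4)})
        assert (s.tp, s.fn, s.fp) == (1, 1, 1)
        assert s.sens == 0.5 and s.ppv == 0.5

    def test_perfect_prediction(self):
        ref = {(1, 9), (2, 8)}
        s = sens_ppv(ref, ref)
        assert s.sens == 1.0 and s.ppv == 1.0

    def test_empty_prediction_convention(self):
        s = sens_ppv(set(), {(1, 5)})
        assert s.sens == 0.0
        assert s.ppv == 0.0 and not s.ppv_defined

    def test_both_empty_convention(self):
        s = sens_ppv(set(), set())
        assert s.sens == 1.0 and s.ppv == 1.0
        assert not s.sens_defined and not s.ppv_defined

    def test_out_of_range_pair_rejected(self):
        with pytest.raises(ValueError):
            sens_ppv({(1, 12)}, set(), n=10)


class TestROC:
    def _samples(self, grammar, params, n_records=4):
        rng = np.random.default_rng(8)
        samples, refs = [], []
        corpus = generate_corpus(
            CorpusSpec(size=n_records, length_range=(15, 25), seed=3)
        )
        for rec in corpus:
            inside = compute_inside(rec.sequence, params, grammar)
            samples.append(
                StructureSampler(inside, params, grammar).sample_set(200, rng)
            )
            refs.append(rec)
        return samples, refs

    def test_default_grid_has_25_points(self):
        grid = default_gamma_grid()
        assert len(grid) == 25
        assert grid[12] == 1.0 and grid[-1] == 4096.0

    def test_perfect_predictor_auc_one(self):
        # every gamma point at (ppv, sens) = (1, 1)
        assert _auc_from_points([(1.0, 1.0)] * 25) == pytest.approx(1.0)

    def test_all_empty_predictions_auc_zero(self):
        sample = make_sample("GGAAACC", {".......": 10})
        ref = StructureRecord("((...))", "GGAAACC")
        curve = roc_auc([sample], [ref], principle="centroid")
        assert curve.auc == pytest.approx(0.0)

    def test_hand_computed_trapezoid(self):
        pts = [(0.5, 0.4), (1.0, 0.2)]
        # continuation: (0,0.4) .. (0.5,0.4) .. (1,0.2): 0.2 + 0.15 = 0.35
        assert _auc_from_points(pts) == pytest.approx(0.2 + 0.15)

    def test_curve_on_sampled_data(self, grammar, params):
        samples, refs = self._samples(grammar, params)
        curve = roc_auc(samples, refs, principle="MEA")
        assert len(curve.points) == 25
        assert 0.0 <= curve.auc <= 1.0
        per_rec = roc_auc(samples, refs, principle="MEA", per_record=True)
        assert 0.0 <= per_rec.auc <= 1.0


class TestShapes:
    @pytest.mark.parametrize(
        "structure,level,expected",
        [
            ("((...))", 0, "((...))"),
            ("((...))", 1, "[_]"),
            ("((...))", 5, "[]"),
            ("((..((...))..((...))))", 5, "[[][]]"),
            ("..((...)).((..)).", 1, "_[_]_[_]_"),
            ("..((...)).((..)).", 3, "[][]"),
            ("((..((...))..))", 1, "[_[_]_]"),
            ("((..((...))..))", 2, "[_[]_]"),
            ("((..((...))..))", 3, "[[]]"),
            ("((..((...))..))", 4, "[[]]"),  # interior loop: no merge
            ("((..((...))..))", 5, "[]"),
            ("((..((...))))", 4, "[]"),  # bulge: merged
            ("....", 2, "_"),
        ],
    )
    def test_reference_abstractions(self, structure, level, expected):
        assert shape(structure, level) == expected

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            shape("(.)", 6)

    def test_level_equality_propagates_upward(self, grammar, params):
        # within the hierarchy, agreement at level l implies agreement at l+1
        rng = np.random.default_rng(4)
        from scfgsample.synthetic import generate_record

        structures = [
            generate_record(params, grammar, rng, 200).structure for _ in range(60)
        ]
        for a in structures[:20]:
            for b in structures[20:40]:
                for lv in (1, 2, 3, 4):
                    if shape(a, lv) == shape(b, lv):
                        assert shape(a, lv + 1) == shape(b, lv + 1)

    def test_abstraction_is_deterministic_function(self):
        s = "((..((...))..((.))))"
        for lv in SHAPE_LEVELS:
            assert shape(s, lv) == shape(s, lv)


class TestQuality:
    def test_reference_occurrences_counted(self):
        ref = "((...))"
        sample = make_sample("GGAAACC", {ref: 120, ".......": 880})
        report = quality_metrics([(sample, {"MF": "......."}, ref)])
        assert report.cs_num[0] == 120
        assert report.cso_freq[0] == 1.0
        assert report.csp_freq["MF"][0] == 0.0

    def test_exact_prediction_correct_at_all_levels(self):
        ref = "((...))"
        sample = make_sample("GGAAACC", {ref: 10})
        report = quality_metrics([(sample, {"MP": ref}, ref)])
        for lv in SHAPE_LEVELS:
            assert report.csp_freq["MP"][lv] == 1.0

    def test_distinct_shape_count_decreases_with_abstraction(self, grammar, params):
        rng = np.random.default_rng(9)
        seq = "GGGAAACCCAUGCAUGG"
        inside = compute_inside(seq, params, grammar)
        sample = StructureSampler(inside, params, grammar).sample_set(300, rng)
        report = quality_metrics([(sample, {}, sample.structures[0].structure)])
        assert report.ds_num[5] <= report.ds_num[1] <= report.ds_num[0]


class TestLoopProfile:
    def test_indicator_for_constant_sample(self, grammar):
        sample = SampleSet(
            sequence="GGAAACC",
            structures=[
                SampledStructure(structure="((...))", loop_annotation=None)
            ]
            * 5,
        )
        lp = loop_profile(sample, grammar)
        assert lp.freq["hairpin"][4] == 1.0
        assert lp.freq["exterior"][4] == 0.0

    def test_partition_of_unpaired_frequency(self, grammar, params):
        from scfgsample import frequency_profile

        seq = "GGGAAACCAU"
        inside = compute_inside(seq, params, grammar)
        sample = StructureSampler(inside, params, grammar).sample_set(
            800, np.random.default_rng(2)
        )
        lp = loop_profile(sample)
        q = frequency_profile(sample).q
        total = sum(lp.freq[lt] for lt in LOOP_TYPES)
        assert np.abs(total[1:] - q[1:]).max() < 1e-12

    def test_hairpin_profile_matches_exact_ensemble(self, grammar, params):
        from scfgsample import enumerate_structures
        from scfgsample.grammar import annotate_structure

        seq = "GGAAACCA"
        structs = enumerate_structures(seq, grammar, params)
        total = sum(p for _, p in structs)
        n = len(seq)
        exact = np.zeros(n + 1)
        for rec, p in structs:
            ann = annotate_structure(rec.structure, grammar)
            for i in range(1, n + 1):
                if ann[i - 1] == "hairpin":
                    exact[i] += p / total
        inside = compute_inside(seq, params, grammar)
        sample = StructureSampler(inside, params, grammar).sample_set(
            30_000, np.random.default_rng(3)
        )
        lp = loop_profile(sample)
        assert np.abs(lp.freq["hairpin"] - exact).max() < 0.01


class TestRelevantCounts:
    def test_relative_disturbance_leaves_support_identical(self, grammar, params):
        seq = "GGGAAACCCAU"
        inside = compute_inside(seq, params, grammar)
        table = disturb(inside, DisturbanceSpec.all_lengths("mep", 0.9, seed=1))
        rc = count_relevant(inside, table, params, grammar)
        for sym, c in rc.inside.items():
            assert c["exact_only"] == 0 and c["disturbed_only"] == 0
        for sym, c in rc.sampling.items():
            assert c["exact_only"] == 0 and c["disturbed_only"] == 0

    def test_absolute_disturbance_creates_relevant_entries(self, grammar, params):
        seq = "GGGAAACCCAU"
        inside = compute_inside(seq, params, grammar)
        table = disturb(inside, DisturbanceSpec.all_lengths("fev", 0.5, seed=1))
        rc = count_relevant(inside, table, params, grammar)
        assert sum(c["disturbed_only"] for c in rc.inside.values()) > 0

    def test_totals_identity(self, grammar, params):
        seq = "GGGAAACCC"
        inside = compute_inside(seq, params, grammar)
        table = disturb(inside, DisturbanceSpec.all_lengths("mev", 0.2, seed=2))
        rc = count_relevant(inside, table, params, grammar)
        for group in (rc.inside, rc.sampling):
            for c in group.values():
                assert c["both"] + c["exact_only"] == c["exact_total"]
                assert c["both"] + c["disturbed_only"] == c["disturbed_total"]


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(CorpusSpec(size=20, length_range=(15, 30), seed=6))


class TestCrossValidation:
    def test_fold_sizes_balanced(self, corpus):
        config = CVConfig(sample_size=20, seed=1)
        report, _ = cross_validate(corpus, folds=10, config=config)
        frame = report.to_frame()
        assert len(frame) == 20
        assert frame.groupby("fold").size().tolist() == [2] * 10

    def test_same_seed_reproduces(self, corpus):
        config = CVConfig(sample_size=20, seed=1)
        r1, _ = cross_validate(corpus, folds=5, config=config)
        r2, _ = cross_validate(corpus, folds=5, config=config)
        assert r1.to_frame().equals(r2.to_frame())

    def test_small_corpus_rejected(self, corpus):
        with pytest.raises(ValueError):
            cross_validate(corpus[:3], folds=10, config=CVConfig(sample_size=5))

    def test_heavy_relative_disturbance_degrades_sensitivity(self, corpus):
        base = CVConfig(sample_size=50, seed=2)
        heavy = CVConfig(
            sample_size=50,
            seed=2,
            disturbance=DisturbanceSpec.all_lengths("fep", 0.99, seed=5),
        )
        exact_rep, _ = cross_validate(corpus, folds=5, config=base)
        fep_rep, _ = cross_validate(corpus, folds=5, config=heavy)
        assert exact_rep.mean_sens >= fep_rep.mean_sens
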