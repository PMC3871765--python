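"""Scoring predictions and sample sets.

Covers base-pair sensitivity/PPV, ROC curves and AUC over a
gamma-trade-off grid, abstract shape levels 0-5, sample-quality statistics
(CSP_freq, CSO_freq, CS_num, DS_num), per-position loop-type probability
profiles, relevant-(nonzero)-probability bookkeeping between exact and
disturbed charts, and seeded k-fold cross-validation over a corpus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disturbance import DisturbanceSpec, DisturbedInsideTable, disturb
from .grammar import (
    BULGE,
    EXTERIOR,
    HAIRPIN,
    MULTI,
    GrammarSpec,
    ParamSet,
    ParseError,
    StructureRecord,
    annotate_loops,
    pair_table,
    train,
)
from .inside_outside import InsideTable, compute_inside
from .predictions import (
    FrequencyProfile,
    frequency_profile,
    gamma_centroid,
    gamma_mea,
    predict,
)
from .sampler import (
    SampleSet,
    StructureSampler,
    build_choice_set,
    reachable_contexts,
)

__all__ = [
    "PairScore",
    "EvalReport",
    "ROCCurve",
    "QualityReport",
    "LoopProfile",
    "RelevantCounts",
    "CVConfig",
    "default_gamma_grid",
    "sens_ppv",
    "roc_auc",
    "shape",
    "quality_metrics",
    "loop_profile",
    "count_relevant",
    "cross_validate",
]

LOOP_TYPES = (HAIRPIN, BULGE, MULTI, EXTERIOR)
SHAPE_LEVELS = (0, 1, 2, 3, 4, 5)


# ---------------------------------------------------------------------------
# sensitivity / PPV


@dataclass(frozen=True)
class PairScore:
    tp: int
    fn: int
    fp: int
    sens: float
    ppv: float
    ppv_defined: bool = True
    sens_defined: bool = True


def sens_ppv(
    predicted: set[tuple[int, int]],
    reference: set[tuple[int, int]],
    n: int | None = None,
) -> PairScore:
    """Base-pair sensitivity TP/(TP+FN) and PPV TP/(TP+FP).

    When a denominator is zero the measure is undefined; by convention it
    is reported as 1 when the other set is empty too (a perfect vacuous
    prediction) and 0 otherwise, with the ``*_defined`` flag cleared.
    """
    if n is not None:
        for (i, j) in predicted | reference:
            if not 1 <= i < j <= n:
                raise ValueError(f"pair {(i, j)} out of range for length {n}")
    tp = len(predicted & reference)
    fn = len(reference - predicted)
    fp = len(predicted - reference)
    sens_defined = (tp + fn) > 0
    ppv_defined = (tp + fp) > 0
    sens = tp / (tp + fn) if sens_defined else (1.0 if fp == 0 else 0.0)
    ppv = tp / (tp + fp) if ppv_defined else (1.0 if fn == 0 else 0.0)
    return PairScore(tp, fn, fp, sens, ppv, ppv_defined, sens_defined)


@dataclass
class EvalReport:
    """Per-record TP/FN/FP and sensitivity/PPV with aggregate means."""

    records: list[dict] = field(default_factory=list)

    def add(self, record_id: str, score: PairScore, **extra) -> None:
        row = {
            "id": record_id,
            "tp": score.tp,
            "fn": score.fn,
            "fp": score.fp,
            "sens": score.sens,
            "ppv": score.ppv,
        }
        row.update(extra)
        self.records.append(row)

    @property
    def mean_sens(self) -> float:
        return float(np.mean([r["sens"] for r in self.records]))

    @property
    def mean_ppv(self) -> float:
        return float(np.mean([r["ppv"] for r in self.records]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


# ---------------------------------------------------------------------------
# ROC / AUC


def default_gamma_grid() -> list[float]:
    """The 25-point trade-off grid {1.25^k : -12<=k<=-1} u {2^k : 0<=k<=12}."""
    return [1.25**k for k in range(-12, 0)] + [2.0**k for k in range(0, 13)]


@dataclass
class ROCCurve:
    gammas: list[float]
    points: list[tuple[float, float]]  # (mean ppv, mean sens) per gamma
    auc: float
    principle: str


def _auc_from_points(points: list[tuple[float, float]]) -> float:
    pts = sorted(points)
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    # constant continuation to the PPV endpoints 0 and 1
    xs = [0.0] + xs + [1.0]
    ys = [ys[0]] + ys + [ys[-1]]
    return float(np.trapezoid(ys, xs))


def roc_auc(
    samples: list[SampleSet],
    references: list[StructureRecord | str],
    principle: str = "MEA",
    gamma_grid: list[float] | None = None,
    per_record: bool = False,
) -> ROCCurve:
    """Sensitivity-vs-PPV curve over the gamma grid, with trapezoidal AUC.

    Default aggregation averages sensitivity and PPV across records at each
    gamma and integrates the mean curve; ``per_record=True`` instead
    averages per-record AUCs.
    """
    if not samples:
        raise ValueError("empty dataset")
    if len(samples) != len(references):
        raise ValueError("samples and references differ in length")
    if gamma_grid is None:
        gamma_grid = default_gamma_grid()
    key = principle.lower()
    if key not in ("mea", "centroid"):
        raise ValueError("ROC analysis applies to the MEA and centroid principles")
    fn = gamma_mea if key == "mea" else gamma_centroid
    profiles = [frequency_profile(s) for s in samples]
    ref_pairs = [
        (r if isinstance(r, StructureRecord) else StructureRecord(r)).pairs
        for r in references
    ]
    grid_scores: list[list[PairScore]] = []
    for gamma in gamma_grid:
        scores = []
        for prof, ref in zip(profiles, ref_pairs):
            pred = fn(prof, gamma).structure.pairs
            scores.append(sens_ppv(pred, ref))
        grid_scores.append(scores)
    points = [
        (float(np.mean([s.ppv for s in scores])), float(np.mean([s.sens for s in scores])))
        for scores in grid_scores
    ]
    if per_record:
        aucs = []
        for rec_idx in range(len(samples)):
            rec_points = [
                (grid_scores[gi][rec_idx].ppv, grid_scores[gi][rec_idx].sens)
                for gi in range(len(gamma_grid))
            ]
            aucs.append(_auc_from_points(rec_points))
        auc = float(np.mean(aucs))
    else:
        auc = _auc_from_points(points)
    return ROCCurve(gammas=list(gamma_grid), points=points, auc=auc, principle=key)


# ---------------------------------------------------------------------------
# abstract shapes


@dataclass
class _Helix:
    outer: tuple[int, int]
    inner: tuple[int, int]
    loop: list  # _Helix nodes and ("run", a, b) leaves


def _helix_tree(structure: str) -> list:
    pt = pair_table(structure)

    def scan(i: int, j: int) -> list:
        items: list = []
        k = i
        while k <= j:
            if pt[k] > k:
                o1, c1 = k, pt[k]
                o2, c2 = o1, c1
                while pt[o2 + 1] == c2 - 1 and c2 - 1 > o2 + 1:
                    o2, c2 = o2 + 1, c2 - 1
                items.append(_Helix((o1, c1), (o2, c2), scan(o2 + 1, c2 - 1)))
                k = c1 + 1
            else:
                a = k
                while k <= j and pt[k] == 0:
                    k += 1
                items.append(("run", a, k - 1))
        return items

    return scan(1, len(structure))


def _render(items: list, level: int, in_bulge_loop: bool) -> str:
    out = []
    helices = [x for x in items if isinstance(x, _Helix)]
    for item in items:
        if isinstance(item, _Helix):
            out.append(_render_helix(item, level))
        else:
            if level == 1 or (level == 2 and in_bulge_loop):
                out.append("_")
    return "".join(out)


def _render_helix(h: _Helix, level: int) -> str:
    if level >= 4:
        cur = h
        while True:
            children = [x for x in cur.loop if isinstance(x, _Helix)]
            runs = [x for x in cur.loop if not isinstance(x, _Helix)]
            if len(children) == 1 and (level == 5 or len(runs) <= 1):
                cur = children[0]  # merge across bulge (level 4) / any interruption (5)
            else:
                break
        return "[" + _render(cur.loop, level, in_bulge_loop=False) + "]"
    children = [x for x in h.loop if isinstance(x, _Helix)]
    return "[" + _render(h.loop, level, in_bulge_loop=len(children) == 1) + "]"


def shape(structure: StructureRecord | str, level: int) -> str:
    """Abstract shape of a structure at abstraction level 0-5.

    Level 0 is the dot-bracket string itself.  Level 1 writes one bracket
    pair per maximal helix and ``_`` for every maximal unpaired run; level
    2 keeps ``_`` only for helix-interrupting (bulge/interior) runs; level
    3 drops all ``_``; level 4 merges helices separated only by bulges
    (one-sided runs); level 5 merges every interrupted-helix chain, leaving
    the pure helix nesting/adjacency pattern.  A structure without pairs
    has shape ``_`` at every level >= 1.
    """
    s = structure.structure if isinstance(structure, StructureRecord) else structure
    if level not in SHAPE_LEVELS:
        raise ValueError(f"shape level must be in {SHAPE_LEVELS}, got {level}")
    if level == 0:
        return s
    tree = _helix_tree(s)
    if not any(isinstance(x, _Helix) for x in tree):
        return "_"
    return _render(tree, level, in_bulge_loop=False)


# ---------------------------------------------------------------------------
# sample-quality statistics


@dataclass
class QualityReport:
    """Shape-level quality statistics, per abstraction level 0-5.

    ``csp_freq[principle][level]``: fraction of records whose prediction
    has the reference shape.  ``cso_freq[level]``: fraction of records
    whose sample contains the reference shape.  ``cs_num[level]``: mean
    occurrences of the reference shape per sample.  ``ds_num[level]``:
    mean number of distinct shapes per sample.
    """

    csp_freq: dict[str, dict[int, float]]
    cso_freq: dict[int, float]
    cs_num: dict[int, float]
    ds_num: dict[int, float]
    n_records: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in SHAPE_LEVELS:
            row = {"level": level, "cso_freq": self.cso_freq[level],
                   "cs_num": self.cs_num[level], "ds_num": self.ds_num[level]}
            for principle, table in self.csp_freq.items():
                row[f"csp_freq_{principle}"] = table[level]
            rows.append(row)
        return pd.DataFrame(rows)


def quality_metrics(
    dataset: list[tuple[SampleSet, dict[str, StructureRecord | str], StructureRecord | str]],
) -> QualityReport:
    """Shape statistics over (sample, predictions, reference) triples."""
    if not dataset:
        raise ValueError("empty dataset")
    principles = sorted({p for _, preds, _ in dataset for p in preds})
    csp = {p: {lv: 0.0 for lv in SHAPE_LEVELS} for p in principles}
    cso = {lv: 0.0 for lv in SHAPE_LEVELS}
    cs = {lv: 0.0 for lv in SHAPE_LEVELS}
    ds = {lv: 0.0 for lv in SHAPE_LEVELS}
    for sample, predictions, reference in dataset:
        ref = reference.structure if isinstance(reference, StructureRecord) else reference
        counts = sample.counts
        for lv in SHAPE_LEVELS:
            ref_shape = shape(ref, lv)
            shape_counts: Counter = Counter()
            for structure, count in counts.items():
                shape_counts[shape(structure, lv)] += count
            cso[lv] += 1.0 if shape_counts.get(ref_shape, 0) > 0 else 0.0
            cs[lv] += shape_counts.get(ref_shape, 0)
            ds[lv] += len(shape_counts)
            for principle, pred in predictions.items():
                ps = pred.structure if isinstance(pred, StructureRecord) else pred
                if shape(ps, lv) == ref_shape:
                    csp[principle][lv] += 1.0
    m = len(dataset)
    return QualityReport(
        csp_freq={p: {lv: v / m for lv, v in tbl.items()} for p, tbl in csp.items()},
        cso_freq={lv: v / m for lv, v in cso.items()},
        cs_num={lv: v / m for lv, v in cs.items()},
        ds_num={lv: v / m for lv, v in ds.items()},
        n_records=m,
    )


# ---------------------------------------------------------------------------
# loop-type probability profiles


@dataclass
class LoopProfile:
    """Per-position frequency of being unpaired within each loop type."""

    sequence: str
    freq: dict[str, np.ndarray]  # loop type -> length-(n+1) array, 1-based

    def to_frame(self) -> pd.DataFrame:
        n = len(self.sequence)
        data = {"position": list(range(1, n + 1)),
                "base": list(self.sequence)}
        for lt in LOOP_TYPES:
            data[lt] = self.freq[lt][1:]
        return pd.DataFrame(data)


def loop_profile(sample: SampleSet, grammar: GrammarSpec | None = None) -> LoopProfile:
    """Observed unpaired-within-loop-type frequencies across a sample.

    Uses the loop annotations the sampler recorded; plain dot-bracket
    samples are re-annotated through the unique derivation (``grammar``
    required in that case).
    """
    n = len(sample.sequence)
    freq = {lt: np.zeros(n + 1) for lt in LOOP_TYPES}
    anns: dict[str, list[str]] = {}
    for s in sample.structures:
        ann = getattr(s, "loop_annotation", None)
        if ann is None:
            structure = s if isinstance(s, str) else s.structure
            if structure not in anns:
                if grammar is None:
                    raise ValueError("grammar needed to re-annotate plain structures")
                anns[structure] = annotate_loops(structure, grammar)
            ann = anns[structure]
            for i in range(1, n + 1):
                if structure[i - 1] == ".":
                    freq[ann[i - 1]][i] += 1
        else:
            structure = s.structure
            for i in range(1, n + 1):
                if structure[i - 1] == ".":
                    freq[ann[i - 1]][i] += 1
    for lt in LOOP_TYPES:
        freq[lt] /= sample.size
    return LoopProfile(sequence=sample.sequence, freq=freq)


# ---------------------------------------------------------------------------
# relevant (nonzero) probability bookkeeping


@dataclass
class RelevantCounts:
    """Cross-tabulation of nonzero entries, exact vs disturbed.

    ``inside[sym]`` and ``sampling[sym]`` each map to a dict with keys
    ``both``, ``exact_only``, ``disturbed_only``, ``exact_total``,
    ``disturbed_total``.
    """

    inside: dict[str, dict[str, int]]
    sampling: dict[str, dict[str, int]]


def count_relevant(
    exact: InsideTable,
    disturbed: DisturbedInsideTable,
    params: ParamSet,
    grammar: GrammarSpec,
    contexts: list[tuple[str, int, int]] | None = None,
) -> RelevantCounts:
    """Count relevant (greater-than-zero) inside values and sampling
    weights under the exact and the disturbed chart.

    ``contexts`` defaults to the union of decision contexts reachable
    under either chart.
    """
    n = exact.n
    inside_counts: dict[str, dict[str, int]] = {}
    from .grammar import SAMPLING_SYMBOLS
    from .disturbance import EPSILON_SYMBOLS

    for sym in SAMPLING_SYMBOLS:
        mask = np.zeros((n + 2, n + 2), dtype=bool)
        for i in range(1, n + 1):
            mask[i, i:] = True
        mask[:, n + 1 :] = False
        if sym in EPSILON_SYMBOLS:
            for i in range(1, n + 2):
                mask[i, i - 1] = True
        e = exact.alpha[sym][mask] > 0
        d = disturbed.alpha[sym][mask] > 0
        inside_counts[sym] = {
            "both": int((e & d).sum()),
            "exact_only": int((e & ~d).sum()),
            "disturbed_only": int((~e & d).sum()),
            "exact_total": int(e.sum()),
            "disturbed_total": int(d.sum()),
        }

    if contexts is None:
        ctx = set(reachable_contexts(exact, params, grammar))
        ctx |= set(reachable_contexts(disturbed, params, grammar))
        contexts = sorted(ctx)
    sampling_counts: dict[str, dict[str, int]] = {}
    for (sym, i, j) in contexts:
        cse = build_choice_set(sym, i, j, exact, params, grammar)
        csd = build_choice_set(sym, i, j, disturbed, params, grammar)
        eset = set(zip(cse.rule_ids, cse.splits))
        dset = set(zip(csd.rule_ids, csd.splits))
        c = sampling_counts.setdefault(
            sym,
            {"both": 0, "exact_only": 0, "disturbed_only": 0,
             "exact_total": 0, "disturbed_total": 0},
        )
        c["both"] += len(eset & dset)
        c["exact_only"] += len(eset - dset)
        c["disturbed_only"] += len(dset - eset)
        c["exact_total"] += len(eset)
        c["disturbed_total"] += len(dset)
    return RelevantCounts(inside=inside_counts, sampling=sampling_counts)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVConfig:
    """How one cross-validation experiment runs.

    ``disturbance=None`` evaluates the exact sampler; otherwise the given
    spec skews each held-out record's chart (with a per-record seed derived
    from the disturbance-spec seed and the record index).
    """

    sample_size: int = 1000
    principle: str = "MF"
    gamma: float = 1.0
    length_dependent: bool = False
    disturbance: DisturbanceSpec | None = None
    seed: int = 0
    min_hairpin: int = 1
    min_helix: int = 1


def cross_validate(
    corpus: list[StructureRecord],
    folds: int = 10,
    config: CVConfig | None = None,
) -> tuple[EvalReport, QualityReport]:
    """Seeded k-fold cross-validation: train on k-1 folds, sample and
    predict on the held-out fold, aggregate over all records."""
    if config is None:
        config = CVConfig()
    if len(corpus) < folds:
        raise ValueError(f"corpus of {len(corpus)} records cannot fill {folds} folds")
    from .grammar import build_grammar

    grammar = build_grammar(config.min_hairpin, config.min_helix)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(corpus))
    fold_indices = np.array_split(order, folds)
    report = EvalReport()
    dataset = []
    global_idx = 0
    for fold, test_idx in enumerate(fold_indices):
        test_set = set(int(t) for t in test_idx)
        train_records = [corpus[k] for k in range(len(corpus)) if k not in test_set]
        params = train(train_records, grammar, length_dependent=config.length_dependent)
        for k in sorted(test_set):
            rec = corpus[k]
            inside = compute_inside(rec.sequence, params, grammar)
            table = inside
            if config.disturbance is not None:
                spec = config.disturbance
                per_rec = DisturbanceSpec(
                    func=spec.func, prob=spec.prob, win=spec.win, op=spec.op,
                    symbols=spec.symbols,
                    seed=int((spec.seed + 1009 * global_idx) % (2**31 - 1)),
                )
                table = disturb(inside, per_rec)
            draw_rng = np.random.default_rng(
                (config.seed * 1_000_003 + global_idx) % (2**31 - 1)
            )
            sample = StructureSampler(table, params, grammar).sample_set(
                config.sample_size, draw_rng
            )
            pred = predict(
                sample, config.principle, params=params, grammar=grammar,
                gamma=config.gamma,
            )
            score = sens_ppv(pred.structure.pairs, rec.pairs, n=len(rec))
            report.add(rec.id or str(k), score, fold=fold)
            dataset.append((sample, {config.principle: pred.structure}, rec))
            global_idx += 1
    quality = quality_metrics(dataset)
    return report, quality
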