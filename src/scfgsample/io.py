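"""File formats, run configuration and experiment orchestration.

Corpus files use the paired-line Vienna dialect (``>id`` / sequence /
dot-bracket); CT files are converted to dot-bracket on reading, rejecting
crossing pairs.  Parameter sets serialize to JSON at full float precision
(well beyond 12 significant digits).  :func:`run_experiment` ties the
pipeline together — train, inside, optional disturbance, sample, predict,
evaluate, profile — and writes a manifest so a run can be reproduced
byte-for-byte from its seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import __version__
from .disturbance import DisturbanceSpec, disturb
from .evaluation import loop_profile, sens_ppv
from .grammar import (
    BASES,
    GrammarSpec,
    ParamSet,
    ParseError,
    StructureRecord,
    build_grammar,
    pair_table,
    train,
)
from .inside_outside import compute_inside
from .predictions import frequency_profile, predict
from .sampler import StructureSampler

__all__ = [
    "read_fasta",
    "read_structures",
    "write_structures",
    "read_params",
    "write_params",
    "RunConfig",
    "run_experiment",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; T normalized to U, case folded, validated."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_structures(path: str | Path, dialect: str = "vienna") -> list[StructureRecord]:
    """Read a structure corpus (``vienna`` 3-line records or ``ct``)."""
    if dialect == "vienna":
        return _read_vienna(path)
    if dialect == "ct":
        return _read_ct(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vienna(path: str | Path) -> list[StructureRecord]:
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    records = []
    k = 0
    while k < len(lines):
        header = lines[k]
        if not header.startswith(">"):
            raise ValueError(f"{path}: line {k + 1}: expected '>' header, got {header!r}")
        if k + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {header!r}")
        seq, struct = lines[k + 1].strip(), lines[k + 2].strip()
        if len(seq) != len(struct):
            raise ValueError(
                f"{path}: record {header!r}: sequence length {len(seq)} != "
                f"structure length {len(struct)}"
            )
        pair_table(struct)  # validates balance and the alphabet
        records.append(
            StructureRecord(structure=struct, sequence=seq, id=header[1:].strip())
        )
        k += 3
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def _read_ct(path: str | Path) -> list[StructureRecord]:
    lines = Path(path).read_text().splitlines()
    records = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        head = lines[k].split()
        try:
            n = int(head[0])
        except (ValueError, IndexError):
            raise ValueError(f"{path}: line {k + 1}: malformed CT header")
        name = head[1] if len(head) > 1 else ""
        seq = [""] * (n + 1)
        partner = [0] * (n + 1)
        for t in range(1, n + 1):
            fields = lines[k + t].split()
            if len(fields) < 6:
                raise ValueError(f"{path}: line {k + t + 1}: malformed CT row")
            idx, base, pair = int(fields[0]), fields[1], int(fields[4])
            seq[idx] = base
            partner[idx] = pair
        chars = ["."] * (n + 1)
        open_pairs = []
        for i in range(1, n + 1):
            jp = partner[i]
            if jp > i:
                for (a, b) in open_pairs:
                    if a < i < b < jp:
                        raise ValueError(
                            f"{path}: crossing pairs ({a},{b}) and ({i},{jp}) — "
                            "absence of pseudoknots is required"
                        )
                open_pairs.append((i, jp))
                chars[i], chars[jp] = "(", ")"
        records.append(
            StructureRecord(structure="".join(chars[1:]), sequence="".join(seq[1:]), id=name)
        )
        k += n + 1
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_structures(records, path: str | Path) -> None:
    """Write Vienna-dialect 3-line records."""
    with open(path, "w") as fh:
        for k, rec in enumerate(records):
            fh.write(f">{rec.id or k}\n{rec.sequence or ''}\n{rec.structure}\n")


def read_params(path: str | Path) -> ParamSet:
    return ParamSet.from_json(Path(path).read_text())


def write_params(params: ParamSet, path: str | Path) -> None:
    Path(path).write_text(params.to_json())


@dataclass
class RunConfig:
    """One experiment's settings; serialized alongside its outputs."""

    min_hairpin: int = 1
    min_helix: int = 1
    length_dependent: bool = False
    sample_size: int = 1000
    disturbance: dict | None = None
    gamma: float = 1.0
    seed: int = 0
    principles: tuple[str, ...] = ("mp", "mf", "mea", "centroid")

    def to_dict(self) -> dict:
        return {
            "min_hairpin": self.min_hairpin,
            "min_helix": self.min_helix,
            "length_dependent": self.length_dependent,
            "sample_size": self.sample_size,
            "disturbance": self.disturbance,
            "gamma": self.gamma,
            "seed": self.seed,
            "principles": list(self.principles),
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        for key, value in doc.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown configuration key {key!r}")
            setattr(cfg, key, tuple(value) if key == "principles" else value)
        return cfg


def run_experiment(
    config: RunConfig,
    corpus: list[StructureRecord],
    sequences: list[tuple[str, str]] | None = None,
    outdir: str | Path = "run",
    params: ParamSet | None = None,
) -> dict:
    """Train, sample, predict and evaluate; write all artifacts to ``outdir``.

    ``sequences`` defaults to the corpus records themselves, in which case
    each record's trusted structure serves as the evaluation reference.
    Per-sequence randomness is derived deterministically from the config
    seed and the record index, so identical inputs reproduce identical
    outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    grammar = build_grammar(config.min_hairpin, config.min_helix)
    if params is None:
        params = train(corpus, grammar, length_dependent=config.length_dependent)
    write_params(params, out / "params.json")
    references = {}
    if sequences is None:
        sequences = [(rec.id or str(k), rec.sequence) for k, rec in enumerate(corpus)]
        references = {rec.id or str(k): rec for k, rec in enumerate(corpus)}

    dspec = (
        DisturbanceSpec.from_dict(config.disturbance) if config.disturbance else None
    )
    metric_rows = []
    with open(out / "samples.dbn", "w") as sample_fh:
        for idx, (seq_id, seq) in enumerate(sequences):
            inside = compute_inside(seq, params, grammar)
            table = inside
            if dspec is not None:
                per_rec = DisturbanceSpec(
                    func=dspec.func, prob=dspec.prob, win=dspec.win, op=dspec.op,
                    symbols=dspec.symbols,
                    seed=int((dspec.seed + 1009 * idx) % (2**31 - 1)),
                )
                table = disturb(inside, per_rec)
            rng = np.random.default_rng((config.seed * 1_000_003 + idx) % (2**31 - 1))
            sample = StructureSampler(table, params, grammar).sample_set(
                config.sample_size, rng
            )
            for d, s in enumerate(sample.structures):
                sample_fh.write(f">{seq_id}|draw{d}\n{seq}\n{s.structure}\n")
            profile = frequency_profile(sample)
            lp = loop_profile(sample)
            lp.to_frame().to_csv(out / f"profile_{seq_id}.tsv", sep="\t", index=False)
            row = {"id": seq_id, "n": len(seq)}
            for principle in config.principles:
                pred = predict(
                    sample, principle, params=params, grammar=grammar,
                    gamma=config.gamma, profile=profile,
                )
                row[principle] = pred.structure.structure
                ref = references.get(seq_id)
                if ref is not None:
                    sc = sens_ppv(pred.structure.pairs, ref.pairs, n=len(seq))
                    row[f"{principle}_sens"] = sc.sens
                    row[f"{principle}_ppv"] = sc.ppv
            metric_rows.append(row)
    import pandas as pd

    pd.DataFrame(metric_rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
    digest = hashlib.sha256(params.to_json().encode()).hexdigest()
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "params_sha256": digest,
        "n_sequences": len(sequences),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
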