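"""Noise-robustness benchmark for ranked pre-diagnosis.

The protocol probes how gracefully an engine degrades when a casual owner's
query contains wrong observations. For every eligible target disease (one
with at least ``min_symptoms`` registered symptoms) a Noise0 query of
``query_size`` genuinely associated symptoms is drawn; each higher noise
level then replaces one more of the remaining relevant symptoms with a
uniformly drawn symptom *not* associated with the target, so NoiseL holds
exactly L irrelevant and ``query_size − L`` relevant symptoms and the
levels are nested. Accuracy at level L is the percentage of targets the
engine ranks first (top-1) or within the first three (top-3).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .engines import Engine, get_engine
from .fuzzy import FuzzyConfig
from .knowledge_base import KnowledgeBase, Query, eligible_targets
from .ranking import RankedDiagnosis

__all__ = [
    "NoiseProtocolConfig",
    "NoiseQuerySet",
    "BenchmarkCell",
    "NoiseBenchmarkReport",
    "build_noise_sets",
    "top_k_hit",
    "run_benchmark",
    "plot_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseProtocolConfig:
    """Benchmark protocol parameters.

    query_size   -- symptoms per query (5 in the reference protocol)
    levels       -- noise levels to build (subset of 0..query_size-1)
    replicates   -- independent seeded repetitions of the whole protocol
    seed         -- master RNG seed
    min_symptoms -- eligibility threshold for target diseases
    n_targets    -- optional seeded subsample of eligible targets (None = all)
    """

    query_size: int = 5
    levels: tuple[int, ...] = (0, 1, 2, 3)
    replicates: int = 1
    seed: int = 0
    min_symptoms: int = 5
    n_targets: int | None = None

    def __post_init__(self) -> None:
        if self.query_size < 1:
            raise ValueError("query_size must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(lv < 0 for lv in self.levels):
            raise ValueError("noise levels must be >= 0")
        if self.levels and max(self.levels) > self.query_size:
            raise ValueError("noise count cannot exceed query_size")


@dataclass
class NoiseQuerySet:
    """Nested noisy queries per (target disease, noise level).

    ``provenance[(target, level)]`` lists the slot indices replaced by noise
    up to that level; slot positions are stable across levels.
    """

    targets: list[int]
    queries: dict[tuple[int, int], Query]
    provenance: dict[tuple[int, int], tuple[int, ...]]
    excluded: list[int] = field(default_factory=list)


def build_noise_sets(kb: KnowledgeBase, protocol: NoiseProtocolConfig) -> NoiseQuerySet:
    """Construct the nested Noise0..NoiseL query sets for every eligible target.

    Targets with fewer than ``query_size`` associated symptoms are excluded
    with a warning. Noise replacements are drawn uniformly from symptoms not
    associated with the target (and not already in the query).
    """
    if len(kb.symptom_ids) < protocol.query_size + 1:
        raise ValueError(
            f"knowledge base has {len(kb.symptom_ids)} symptoms; "
            f"need > query_size ({protocol.query_size}) to add noise"
        )
    rng = np.random.default_rng(protocol.seed)
    targets = eligible_targets(kb, protocol.min_symptoms)
    excluded = [t for t in targets
                if len(kb.disease_symptoms[t]) < protocol.query_size]
    if excluded:
        logger.warning(
            "%d eligible targets have fewer than %d symptoms and are excluded",
            len(excluded), protocol.query_size)
        targets = [t for t in targets if t not in set(excluded)]
    if protocol.n_targets is not None and protocol.n_targets < len(targets):
        pick = rng.choice(len(targets), size=protocol.n_targets, replace=False)
        targets = [targets[i] for i in sorted(pick)]

    all_symptoms = kb.symptom_ids
    max_level = max(protocol.levels) if protocol.levels else 0
    queries: dict[tuple[int, int], Query] = {}
    provenance: dict[tuple[int, int], tuple[int, ...]] = {}

    def entry(sid: int) -> tuple[int, int]:
        return (kb.symptom_by_id[sid].observed_part, sid)

    for t in targets:
        s_t = np.array(sorted(kb.disease_symptoms[t]), dtype=int)
        base = rng.choice(s_t, size=protocol.query_size, replace=False)
        slots = [int(s) for s in base]
        replaced: list[int] = []
        if 0 in protocol.levels:
            queries[(t, 0)] = Query(tuple(entry(s) for s in slots))
            provenance[(t, 0)] = ()
        s_t_set = set(int(s) for s in s_t)
        for level in range(1, max_level + 1):
            relevant_slots = [i for i in range(len(slots)) if i not in replaced]
            slot = int(rng.choice(relevant_slots))
            forbidden = s_t_set | set(slots)
            pool = np.array(
                [int(s) for s in all_symptoms if int(s) not in forbidden], dtype=int
            )
            noise = int(rng.choice(pool))
            slots[slot] = noise
            replaced.append(slot)
            if level in protocol.levels:
                queries[(t, level)] = Query(tuple(entry(s) for s in slots))
                provenance[(t, level)] = tuple(sorted(replaced))

    return NoiseQuerySet(
        targets=targets, queries=queries, provenance=provenance, excluded=excluded
    )


def top_k_hit(result: RankedDiagnosis, target: int, k: int) -> bool:
    """True iff the target disease appears among the first min(k, len) entries."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return target in result.disease_ids[:k]


@dataclass(frozen=True)
class BenchmarkCell:
    engine: str
    level: int
    top1_mean: float
    top1_sd: float
    top3_mean: float
    top3_sd: float
    n_targets: int


@dataclass
class NoiseBenchmarkReport:
    """Engine x noise-level accuracy table with run metadata."""

    cells: list[BenchmarkCell]
    seed: int
    config_hash: str
    replicates: int
    levels: tuple[int, ...]
    engines: tuple[str, ...]

    def cell(self, engine: str, level: int) -> BenchmarkCell:
        for c in self.cells:
            if c.engine == engine and c.level == level:
                return c
        raise KeyError((engine, level))

    def to_json_str(self) -> str:
        payload = {
            "meta": {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "replicates": self.replicates,
                "levels": list(self.levels),
                "engines": list(self.engines),
            },
            "cells": [
                {
                    "engine": c.engine,
                    "level": c.level,
                    "top1": round(c.top1_mean, 6),
                    "top3": round(c.top3_mean, 6),
                    "sd1": round(c.top1_sd, 6),
                    "sd3": round(c.top3_sd, 6),
                    "n": c.n_targets,
                }
                for c in sorted(self.cells, key=lambda c: (c.engine, c.level))
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_csv_str(self) -> str:
        lines = ["engine,level,top1,top3,n,sd1,sd3"]
        for c in sorted(self.cells, key=lambda c: (c.engine, c.level)):
            lines.append(
                f"{c.engine},{c.level},{c.top1_mean:.6f},{c.top3_mean:.6f},"
                f"{c.n_targets},{c.top1_sd:.6f},{c.top3_sd:.6f}"
            )
        return "\n".join(lines) + "\n"


def _config_hash(protocol: NoiseProtocolConfig, engine_names: tuple[str, ...]) -> str:
    blob = json.dumps(
        {
            "query_size": protocol.query_size,
            "levels": list(protocol.levels),
            "replicates": protocol.replicates,
            "seed": protocol.seed,
            "min_symptoms": protocol.min_symptoms,
            "n_targets": protocol.n_targets,
            "engines": list(engine_names),
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_benchmark(
    kb: KnowledgeBase,
    engines,
    protocol: NoiseProtocolConfig,
    config: FuzzyConfig | None = None,
) -> NoiseBenchmarkReport:
    """Run every engine over every noise level, averaged over replicates.

    ``engines`` may hold engine objects or registry names. An engine failure
    on a query is recorded as a miss and logged; the run continues.
    """
    config = config or FuzzyConfig()
    resolved: list[Engine] = [
        get_engine(e) if isinstance(e, str) else e for e in engines
    ]
    names = tuple(e.name for e in resolved)
    rng = np.random.default_rng(protocol.seed)
    rep_seeds = [int(s) for s in rng.integers(2**31, size=protocol.replicates)]

    levels = tuple(sorted(protocol.levels))
    acc: dict[tuple[str, int, int], dict[int, float]] = {}
    n_targets = 0
    for r, rep_seed in enumerate(rep_seeds):
        rep_proto = NoiseProtocolConfig(
            query_size=protocol.query_size, levels=levels,
            replicates=1, seed=rep_seed,
            min_symptoms=protocol.min_symptoms, n_targets=protocol.n_targets,
        )
        qset = build_noise_sets(kb, rep_proto)
        n_targets = len(qset.targets)
        for eng in resolved:
            for level in levels:
                hits = {1: 0, 3: 0}
                for t in qset.targets:
                    try:
                        result = eng.infer(kb, qset.queries[(t, level)], config)
                    except Exception:
                        logger.exception(
                            "engine %s failed on target %d level %d; "
                            "counted as miss", eng.name, t, level)
                        continue
                    for k in (1, 3):
                        hits[k] += top_k_hit(result, t, k)
                denom = max(len(qset.targets), 1)
                acc[(eng.name, level, r)] = {
                    k: 100.0 * hits[k] / denom for k in (1, 3)
                }

    cells = []
    for eng in resolved:
        for level in levels:
            a1 = np.array([acc[(eng.name, level, r)][1]
                           for r in range(protocol.replicates)])
            a3 = np.array([acc[(eng.name, level, r)][3]
                           for r in range(protocol.replicates)])
            cells.append(BenchmarkCell(
                engine=eng.name, level=level,
                top1_mean=float(a1.mean()), top1_sd=float(a1.std()),
                top3_mean=float(a3.mean()), top3_sd=float(a3.std()),
                n_targets=n_targets,
            ))
    return NoiseBenchmarkReport(
        cells=cells, seed=protocol.seed,
        config_hash=_config_hash(protocol, names),
        replicates=protocol.replicates, levels=levels, engines=names,
    )


def plot_report(report: NoiseBenchmarkReport, path, metric: str = "top1") -> None:
    """Accuracy-vs-noise-level line plot, one line per engine."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name in report.engines:
        ys = [getattr(report.cell(name, lv), f"{metric}_mean")
              for lv in report.levels]
        ax.plot(report.levels, ys, marker="o", label=name.upper())
    ax.set_xlabel("noise level")
    ax.set_ylabel(f"{metric} accuracy (%)")
    ax.set_xticks(list(report.levels))
    ax.set_ylim(0, 105)
    ax.legend()
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
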