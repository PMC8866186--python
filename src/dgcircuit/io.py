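"""Serialization and end-to-end experiment workflows.

CSV is the canonical exchange format for matrices (patterns, activities,
weights, similarity), JSON for configurations, manifests and summaries.
`simulate_experiment`, `compare_experiments` and `optimize_experiment` tie
the modules into reproducible runs: each writes a ``RunManifest`` with all
seeds and settings needed to re-execute the run bit-compatibly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .containers import ActivityMatrix
from .dynamics import SimulationSettings, run_battery
from .metrics import (
    CrossInstanceSummary,
    KSComparison,
    MetricsReport,
    compare_distributions,
    summarize_across_instances,
)
from .optimize import OptimizeResult, optimize
from .patterns import PatternSet, generate_combinatorial_patterns
from .weights import (
    ProjectionSpec,
    VariantConfig,
    get_variant,
    realize_instance,
)

__all__ = [
    "RunManifest",
    "ExperimentResult",
    "save_activity_matrix",
    "load_activity_matrix",
    "save_pattern_set",
    "load_pattern_set",
    "variant_to_dict",
    "variant_from_dict",
    "save_variant",
    "load_variant",
    "simulate_experiment",
    "compare_experiments",
    "optimize_experiment",
]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# matrices


def save_activity_matrix(activity: ActivityMatrix, path: str | Path) -> None:
    """Write an activity matrix as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(activity.values).to_csv(path, index=False)
    _write_json(
        path.with_suffix(".json"),
        {
            "population": activity.population,
            "seed": activity.seed,
            "n_patterns": activity.n_patterns,
            "n_units": activity.n_units,
        },
    )


def load_activity_matrix(path: str | Path) -> ActivityMatrix:
    path = Path(path)
    values = pd.read_csv(path).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ActivityMatrix(values, population=meta["population"], seed=meta["seed"])


def save_pattern_set(pattern_set: PatternSet, path: str | Path) -> None:
    """Write the battery as a 0/1 CSV matrix plus a JSON ordering sidecar."""
    path = Path(path)
    pd.DataFrame(pattern_set.patterns).to_csv(path, index=False)
    _write_json(
        path.with_suffix(".json"),
        {
            "n_bits": pattern_set.n_bits,
            "ordering": "ascending binary integer, bit 0 = least significant",
        },
    )


def load_pattern_set(path: str | Path) -> PatternSet:
    path = Path(path)
    bits = pd.read_csv(path).to_numpy(dtype=np.uint8)
    meta = json.loads(path.with_suffix(".json").read_text())
    return PatternSet(n_bits=int(meta["n_bits"]), patterns=bits)


# ---------------------------------------------------------------------------
# variant configurations


def variant_to_dict(variant: VariantConfig) -> dict:
    return {
        "name": variant.name,
        "projections": [
            {
                "pre": p.pre,
                "post": p.post,
                "distribution": p.distribution,
                "mean_weight": p.mean_weight,
                "allow_autapse": p.allow_autapse,
            }
            for p in variant.projections
        ],
    }


def variant_from_dict(data: dict) -> VariantConfig:
    projections = tuple(
        ProjectionSpec(
            pre=p["pre"],
            post=p["post"],
            distribution=p["distribution"],
            mean_weight=p["mean_weight"],
            allow_autapse=p.get("allow_autapse", False),
        )
        for p in data["projections"]
    )
    return VariantConfig(name=data["name"], projections=projections)


def save_variant(variant: VariantConfig, path: str | Path) -> None:
    _write_json(Path(path), variant_to_dict(variant))


def load_variant(path: str | Path) -> VariantConfig:
    return variant_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# experiments


@dataclass
class RunManifest:
    """Provenance record sufficient to re-execute a run bit-compatibly."""

    command: str
    variant: str
    seed: int
    instance_seeds: tuple[int, ...]
    settings: dict
    version: str = __version__
    timestamp: str = ""
    outputs: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        _write_json(Path(path), dataclasses.asdict(self))


@dataclass
class ExperimentResult:
    """Activities, per-instance metrics and pooled summary for one variant."""

    variant: VariantConfig
    seed: int
    instance_seeds: tuple[int, ...]
    activities: list[dict[str, ActivityMatrix]]
    reports: list[MetricsReport]  # output-population metrics per instance
    summary: CrossInstanceSummary
    manifest: RunManifest


def _instance_seeds(seed: int, instances: int) -> tuple[int, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(int(s) % 2**31 for s in ss.generate_state(instances))


def simulate_experiment(
    variant: VariantConfig | str,
    instances: int = 5,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    pattern_set: PatternSet | None = None,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run the full battery on several weight realizations of one variant.

    Realizes ``instances`` independent weight samples (seeds derived from
    ``seed``), presents every input pattern to each, computes output-
    population metrics per instance and a pooled cross-instance summary.
    When ``out_dir`` is given, writes per-instance activity CSVs, metric
    tables, the similarity matrix of the first instance, and a manifest.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    settings = settings or SimulationSettings()
    pattern_set = pattern_set or generate_combinatorial_patterns(
        variant.populations()["Input"].size
    )
    seeds = _instance_seeds(seed, instances)
    activities, reports = [], []
    for s in seeds:
        instance = realize_instance(variant, s, settings)
        acts = run_battery(instance, pattern_set)
        activities.append(acts)
        reports.append(MetricsReport.from_activity(acts["Output"]))
    summary = summarize_across_instances(reports)
    manifest = RunManifest(
        command="simulate",
        variant=variant.name,
        seed=seed,
        instance_seeds=seeds,
        settings=dataclasses.asdict(settings),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    result = ExperimentResult(
        variant=variant,
        seed=seed,
        instance_seeds=seeds,
        activities=activities,
        reports=reports,
        summary=summary,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_experiment(result, Path(out_dir))
    return result


def _write_experiment(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    save_variant(result.variant, out_dir / "variant.json")
    for i, (s, acts, report) in enumerate(
        zip(result.instance_seeds, result.activities, result.reports)
    ):
        inst_dir = out_dir / f"instance_{i}"
        inst_dir.mkdir(exist_ok=True)
        for name, act in acts.items():
            save_activity_matrix(act, inst_dir / f"activity_{name}.csv")
        pd.DataFrame({"sparsity": report.sparsity}).to_csv(
            inst_dir / "sparsity.csv", index_label="pattern"
        )
        pd.DataFrame({"selectivity": report.selectivity}).to_csv(
            inst_dir / "selectivity.csv", index_label="unit"
        )
        iu = np.triu_indices(report.discriminability.shape[0], k=1)
        pd.DataFrame(
            {
                "pattern_k": iu[0],
                "pattern_l": iu[1],
                "discriminability": report.discriminability[iu],
            }
        ).to_csv(inst_dir / "discriminability.csv", index=False)
        result.manifest.outputs.append(str(inst_dir))
    pd.DataFrame(result.reports[0].similarity).to_csv(
        out_dir / "similarity_instance_0.csv", index=False
    )
    summary = {
        "n_instances": result.summary.n_instances,
        "mean_metrics": {
            m: result.summary.mean_metric(m)
            for m in ("sparsity", "selectivity", "discriminability")
        },
    }
    _write_json(out_dir / "summary.json", summary)
    result.manifest.save(out_dir / "manifest.json")


def compare_experiments(
    run_a: ExperimentResult,
    run_b: ExperimentResult,
    n_comparisons: int = 1,
    out_path: str | Path | None = None,
) -> dict[str, KSComparison]:
    """KS + Bonferroni comparison of pooled metric distributions of two runs."""
    comparisons = {}
    for metric in ("sparsity", "selectivity", "discriminability"):
        comparisons[metric] = compare_distributions(
            run_a.summary.pooled[metric],
            run_b.summary.pooled[metric],
            n_comparisons=n_comparisons,
        )
    if out_path is not None:
        _write_json(
            Path(out_path),
            {
                "run_a": run_a.variant.name,
                "run_b": run_b.variant.name,
                "n_comparisons": n_comparisons,
                "results": {
                    m: dataclasses.asdict(c) for m, c in comparisons.items()
                },
            },
        )
    return comparisons


def optimize_experiment(
    variant: VariantConfig | str,
    out_dir: str | Path | None = None,
    **optimize_kwargs,
) -> OptimizeResult:
    """Run the weight search and optionally write history, front and manifest.

    The per-iteration history CSV records every candidate's parameters,
    three costs, feasibility flag and Pareto rank; the final front is saved
    as variant-config JSON files directly loadable by ``load_variant``.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    result = optimize(variant, **optimize_kwargs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in result.history:
            for cand, c3, ok, rank in zip(
                rec.params, rec.costs, rec.feasible, rec.ranks
            ):
                row = {
                    "iteration": rec.iteration,
                    "temperature": rec.temperature,
                    "sparsity_cost": c3[0],
                    "selectivity_cost": c3[1],
                    "discriminability_cost": c3[2],
                    "feasible": bool(ok),
                    "rank": int(rank),
                }
                row.update(
                    {
                        f"w[{pre}->{post}]": v
                        for (pre, post), v in zip(result.param_names, cand)
                    }
                )
                rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "history.csv", index=False)
        for i, params in enumerate(result.front_params):
            front_variant = variant.with_mean_weights(
                dict(zip(result.param_names, params))
            )
            save_variant(front_variant, out_dir / f"front_{i}.json")
        manifest = RunManifest(
            command="optimize",
            variant=variant.name,
            seed=result.seed,
            instance_seeds=result.instance_seeds,
            settings={
                k: v
                for k, v in optimize_kwargs.items()
                if isinstance(v, (int, float, bool, str))
            },
            timestamp=datetime.now(timezone.utc).isoformat(),
        )
        manifest.save(out_dir / "manifest.json")
    return result
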