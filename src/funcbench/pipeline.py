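"""End-to-end benchmark orchestration.

For every configured family the pipeline: simulates (or loads) the family
and a fresh negative pool, builds the training/testing/independent triple,
encodes CTD features, tunes each machine-learning method on the testing
set, re-trains on training+testing with the chosen parameters, evaluates
every method once on the independent set, and (optionally) scans a
synthetic proteome with planted cousins for the false-discovery audit.

Every seed is derived from the master seed through a spawned
``numpy.random.SeedSequence`` stream and recorded in the manifest, so a
rerun with the same config reproduces every number byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import classifiers, evaluation, features, metrics, similarity
from .datasets import build_family_datasets
from .records import POSITIVE, ProteinRecord
from .simulate import (
    Family,
    FamilySpec,
    ProteomeSpec,
    generate_family,
    generate_negative_pool,
    generate_proteome,
)

ML_METHODS = ("svm", "pnn", "knn")


class ConfigError(ValueError):
    pass


@dataclass
class BenchmarkConfig:
    family_specs: list[FamilySpec]
    methods: tuple[str, ...] = ("blast", "svm", "pnn", "knn")
    n_negative_groups: int = 20
    group_size_range: tuple[int, int] = (3, 8)
    e_cutoff: float = 1e-3
    id_cutoff: float = 40.0
    grids: dict[str, list[dict[str, Any]]] = field(default_factory=dict)
    seed: int = 0
    scan: ProteomeSpec | None = None
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if not self.family_specs:
            raise ConfigError("at least one family is required")
        if not self.methods:
            raise ConfigError("at least one method is required")
        bad = set(self.methods) - {"blast", *ML_METHODS}
        if bad:
            raise ConfigError(f"unknown methods {bad}")


@dataclass
class FamilyResult:
    family_id: str
    metric_rows: list[dict[str, Any]]
    tuning: dict[str, Any]
    scan_rows: list[evaluation.ScanResult]
    seeds: dict[str, int]


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    families: list[FamilyResult]
    comparisons: list[dict] = field(default_factory=list)

    def metric_table(self) -> pd.DataFrame:
        rows = [r for fam in self.families for r in fam.metric_rows]
        return pd.DataFrame(rows, columns=["family_id", "method", "se", "sp", "acc", "mcc"])

    def scan_table(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(s) for fam in self.families for s in fam.scan_rows]
        return pd.DataFrame(rows)


def _labels(part) -> np.ndarray:
    return np.array([lab == POSITIVE for _, lab in part])


def _encode_part(part) -> np.ndarray:
    return features.encode_many([rec.sequence for rec, _ in part])


def run_family(
    family_id: str,
    positives: list[ProteinRecord],
    negative_pool: list[ProteinRecord],
    config: BenchmarkConfig,
    seeds: dict[str, int],
    family: Family | None = None,
) -> FamilyResult:
    """Run every configured method on one family and (optionally) scan."""
    triple = build_family_datasets(
        family_id, positives, negative_pool, seed=seeds["split"]
    )
    X = {name: _encode_part(part) for name, part in triple.parts()}
    y = {name: _labels(part) for name, part in triple.parts()}

    metric_rows: list[dict[str, Any]] = []
    tuning_tables: dict[str, Any] = {}
    scan_models: dict[str, classifiers.TrainedModel] = {}

    ml = [m for m in config.methods if m in ML_METHODS]
    for method in ml:
        scaler = features.MinMaxScaler().fit(X["training"])
        tr = classifiers.tune(
            method,
            scaler.transform(X["training"]),
            y["training"],
            scaler.transform(X["testing"]),
            y["testing"],
            grid=config.grids.get(method),
        )
        tuning_tables[method] = {
            "best": tr.best_parameters,
            "table": tr.table,
        }
        # final model: training + testing combined, tuned parameters kept
        comb_X = np.vstack([X["training"], X["testing"]])
        comb_y = np.concatenate([y["training"], y["testing"]])
        final_scaler = features.MinMaxScaler().fit(comb_X)
        model = classifiers.train(
            method,
            final_scaler.transform(comb_X),
            comb_y,
            tr.best_parameters,
            scaler=final_scaler,
        )
        pred = classifiers.predict(model, final_scaler.transform(X["independent"]))
        c = metrics.confusion_counts(pred, y["independent"])
        metric_rows.append(
            {"family_id": family_id, "method": method, **metrics.metric_row(c)}
        )
        scan_models[method] = model

    db = None
    if "blast" in config.methods:
        pos_refs = [
            rec
            for part in (triple.training, triple.testing)
            for rec, lab in part
            if lab == POSITIVE
        ]
        db = similarity.build_reference(family_id, pos_refs)
        pred = np.array(
            [
                similarity.classify_by_similarity(
                    rec.sequence, db, config.e_cutoff, config.id_cutoff
                )[0]
                for rec, _ in triple.independent
            ]
        )
        c = metrics.confusion_counts(pred, y["independent"])
        metric_rows.append(
            {"family_id": family_id, "method": "blast", **metrics.metric_row(c)}
        )

    scan_rows: list[evaluation.ScanResult] = []
    if config.scan is not None and family is not None:
        # "*" in the scan spec means "the family being scanned"
        planted = tuple(
            (family_id if fid == "*" else fid, n) for fid, n in config.scan.planted
        )
        spec = dataclasses.replace(config.scan, planted=planted, seed=seeds["scan"])
        scan_records, truth = generate_proteome(spec, {family_id: family})
        scan_X = features.encode_many([r.sequence for r in scan_records])
        scan_db = None
        if "blast" in config.methods:
            # the scan reference holds every known family sequence
            all_pos = [
                rec for _, part in triple.parts() for rec, lab in part if lab == POSITIVE
            ]
            scan_db = similarity.build_reference(family_id, all_pos)
        scan_rows = evaluation.genome_scan(
            family_id,
            scan_models,
            scan_X,
            scan_records,
            reference_db=scan_db,
            e_cutoff=config.e_cutoff,
            id_cutoff=config.id_cutoff,
            truth=truth,
        )

    return FamilyResult(
        family_id=family_id,
        metric_rows=metric_rows,
        tuning=tuning_tables,
        scan_rows=scan_rows,
        seeds=seeds,
    )


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    config.validate()
    master = np.random.SeedSequence(config.seed)
    fam_results = []
    for spec, child in zip(
        config.family_specs, master.spawn(len(config.family_specs))
    ):
        s = child.generate_state(4) % (2**31)
        seeds = {
            "family": int(s[0]),
            "pool": int(s[1]),
            "split": int(s[2]),
            "scan": int(s[3]),
        }
        family = generate_family(dataclasses.replace(spec, seed=seeds["family"]))
        pool = generate_negative_pool(
            config.n_negative_groups,
            config.group_size_range,
            seed=seeds["pool"],
            substitution_rate=spec.substitution_rate,
        )
        try:
            fam_results.append(
                run_family(
                    spec.family_id, family.members, pool, config, seeds, family=family
                )
            )
        except Exception as exc:  # name the failing family, flush nothing
            raise RuntimeError(
                f"benchmark failed at family {spec.family_id!r}: {exc}"
            ) from exc

    result = BenchmarkResult(config=config, families=fam_results)
    table = result.metric_table()
    n_methods = table["method"].nunique()
    if len(config.family_specs) >= 6 and n_methods >= 2:
        for metric in ("se", "sp", "acc", "mcc"):
            try:
                result.comparisons.append(evaluation.compare_methods(table, metric))
            except evaluation.InsufficientDataError:
                pass
    if config.out_dir is not None:
        render_reports(result, config.out_dir)
    return result


def _round2(x: float) -> str:
    return "NA" if pd.isna(x) else f"{x:.2f}"


def render_reports(result: BenchmarkResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the benchmark tables: metric TSV, scan TSV, JSON, manifest.

    Percentages are rendered at 2 decimal places in the TSVs; the JSON
    keeps full precision. Output is deterministic byte for byte for a
    fixed config.
    """
    if not result.families:
        raise ConfigError("no results to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = result.metric_table()
    shaped = table.copy()
    for col in ("se", "sp", "acc", "mcc"):
        shaped[col] = shaped[col].map(_round2)
    paths["metrics"] = out / "metrics.tsv"
    shaped.to_csv(paths["metrics"], sep="\t", index=False, lineterminator="\n")

    scan = result.scan_table()
    if not scan.empty:
        shaped = scan.copy()
        for col in shaped.columns:
            if shaped[col].dtype == float:
                shaped[col] = shaped[col].map(_round2)
        paths["scan"] = out / "scan.tsv"
        shaped.to_csv(paths["scan"], sep="\t", index=False, lineterminator="\n")

    payload = {
        "metrics": table.to_dict(orient="records"),
        "scan": result.scan_table().to_dict(orient="records"),
        "comparisons": result.comparisons,
    }
    paths["results"] = out / "results.json"
    with open(paths["results"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")

    summary_lines = []
    for metric in ("se", "sp", "acc", "mcc"):
        for method in sorted(table["method"].unique()):
            vals = table.loc[table["method"] == method, metric]
            summary_lines.append(
                f"{metric}\t{method}\tmedian={np.nanmedian(vals):.2f}"
                f"\tmean={np.nanmean(vals):.2f}"
            )
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(summary_lines) + "\n")

    manifest = {
        "seed": result.config.seed,
        "methods": list(result.config.methods),
        "e_cutoff": result.config.e_cutoff,
        "id_cutoff": result.config.id_cutoff,
        "n_negative_groups": result.config.n_negative_groups,
        "families": [
            {
                "family_id": f.family_id,
                "seeds": f.seeds,
                "tuning": {m: t["best"] for m, t in f.tuning.items()},
            }
            for f in result.families
        ],
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
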