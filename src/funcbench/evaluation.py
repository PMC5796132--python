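"""Cross-family method comparison and the genome-scan false-discovery audit.

``compare_methods`` runs a paired, per-family comparison (Wilcoxon
signed-rank by default) of one metric between every pair of methods,
dropping families where either member of a pair has an undefined metric.

``genome_scan`` applies a family's trained predictors to a whole proteome
and reports, per method, the percentage of sequences called positive —
the audit statistic: a call percentage well above the known (or planted)
family fraction signals false discoveries. For the similarity baseline
the reference database holds *all* known family sequences (training,
testing and independent), mirroring how an annotator would scan a genome
with everything known about the family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import TrainedModel, predict
from .records import ProteinRecord
from .similarity import ReferenceDB, classify_by_similarity

METHODS = ("blast", "svm", "pnn", "knn")


class InsufficientDataError(ValueError):
    pass


def compare_methods(
    rows: pd.DataFrame,
    metric: str,
    min_families: int = 6,
    test: str = "wilcoxon",
) -> dict:
    """Pairwise paired comparison of one metric across families.

    ``rows`` must have columns ``family_id, method, se, sp, acc, mcc``.
    Returns per-method medians/means plus a p-value for each method pair.
    """
    if metric not in ("se", "sp", "acc", "mcc"):
        raise ValueError(f"unknown metric {metric!r}")
    wide = rows.pivot(index="family_id", columns="method", values=metric)
    methods = [m for m in METHODS if m in wide.columns]
    summary = {
        "metric": metric,
        "medians": {m: float(np.nanmedian(wide[m])) for m in methods},
        "means": {m: float(np.nanmean(wide[m])) for m in methods},
        "pairs": [],
    }
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            paired = wide[[a, b]].dropna()
            if len(paired) < min_families:
                raise InsufficientDataError(
                    f"{a} vs {b}: only {len(paired)} families with defined "
                    f"{metric}, need >= {min_families}"
                )
            diff = paired[a] - paired[b]
            if np.allclose(diff, 0):
                p = 1.0  # identical columns: no difference detectable
            elif test == "wilcoxon":
                p = float(stats.wilcoxon(paired[a], paired[b]).pvalue)
            else:
                p = float(stats.ttest_rel(paired[a], paired[b]).pvalue)
            summary["pairs"].append(
                {"pair": f"{a}_vs_{b}", "p_value": p, "n_families": len(paired)}
            )
    return summary


@dataclass
class ScanResult:
    family_id: str
    method: str
    percent_positive: float
    n_scanned: int
    n_positive_calls: int
    # truth-based audit fields (synthetic mode only; NaN otherwise)
    percent_true_members: float = float("nan")
    se_on_planted: float = float("nan")
    percent_background_positive: float = float("nan")


def genome_scan(
    family_id: str,
    models: dict[str, TrainedModel],
    scan_X: np.ndarray | None,
    scan_records: list[ProteinRecord],
    reference_db: ReferenceDB | None = None,
    e_cutoff: float = 1e-3,
    id_cutoff: float = 40.0,
    truth: np.ndarray | None = None,
) -> list[ScanResult]:
    """Percent of a proteome called positive, per method.

    ``models`` maps method names to trained feature classifiers; passing a
    ``reference_db`` additionally runs the similarity baseline. ``scan_X``
    holds unscaled feature vectors for the scan set (scaled per model).
    When planted truth labels are supplied the result also carries the true
    recall on planted members and the background false-call percentage.
    """
    if not scan_records:
        raise ValueError("empty scan set")
    n = len(scan_records)
    results = []

    calls_by_method: dict[str, np.ndarray] = {}
    for method, model in models.items():
        X = model.scaler.transform(scan_X) if model.scaler is not None else scan_X
        calls_by_method[method] = predict(model, X)
    if reference_db is not None:
        calls_by_method["blast"] = np.array(
            [
                classify_by_similarity(
                    rec.sequence, reference_db, e_cutoff, id_cutoff
                )[0]
                for rec in scan_records
            ]
        )

    for method, calls in calls_by_method.items():
        res = ScanResult(
            family_id=family_id,
            method=method,
            percent_positive=100.0 * calls.sum() / n,
            n_scanned=n,
            n_positive_calls=int(calls.sum()),
        )
        if truth is not None:
            truth = np.asarray(truth, dtype=bool)
            res.percent_true_members = 100.0 * truth.sum() / n
            if truth.any():
                res.se_on_planted = 100.0 * (calls & truth).sum() / truth.sum()
            if (~truth).any():
                res.percent_background_positive = (
                    100.0 * (calls & ~truth).sum() / (~truth).sum()
                )
        results.append(res)
    return results
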