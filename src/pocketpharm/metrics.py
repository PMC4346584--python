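"""Confusion counts, recall/precision/MCC and feature-set ranking.

For each feature subset the screen yields hit/miss per labelled compound;
actives and inactives give TP/FN/TN/FP (blockers and unlabelled compounds
are excluded).  Subsets are ranked by the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

after filtering to recall > 0.5; MCC is defined as 0 when any denominator
factor vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ConfusionMetrics:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def mcc(self) -> float:
        return mcc(self.TP, self.FP, self.TN, self.FN)


def mcc(TP: int, FP: int, TN: int, FN: int) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    if denom == 0:
        return 0.0
    return (TP * TN - FP * FN) / math.sqrt(denom)


@dataclass
class FeatureSetResult:
    subset: tuple[int, ...]
    metrics: ConfusionMetrics
    compound_set: str = ""

    @property
    def k(self) -> int:
        return len(self.subset)


def _parent_hits(hit_table: pd.DataFrame, subset: tuple[int, ...]) -> dict[str, bool]:
    """Per-parent hit status for one subset: any stereoisomer counts."""
    sub = hit_table[hit_table["subset"].map(lambda s: tuple(s) == tuple(subset))]
    return sub.groupby("compound")["matched"].any().to_dict()


def evaluate_subset(
    hit_table: pd.DataFrame,
    subset: tuple[int, ...],
    labels: dict[str, str],
    compound_set: str = "",
) -> FeatureSetResult:
    """Confusion metrics of one feature subset against activity labels.

    Blockers and unknowns are excluded from the counts; every labelled
    active/inactive must appear in the hit table.
    """
    hits = _parent_hits(hit_table, subset)
    counted = {c: lab for c, lab in labels.items() if lab in ("active", "inactive")}
    missing = sorted(set(counted) - set(hits))
    if missing:
        raise KeyError(f"labelled compounds missing from hit table: {missing}")
    tp = fp = tn = fn = 0
    for comp, label in counted.items():
        hit = hits[comp]
        if label == "active":
            tp, fn = (tp + 1, fn) if hit else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if hit else (fp, tn + 1)
    return FeatureSetResult(
        subset=tuple(sorted(subset)),
        metrics=ConfusionMetrics(TP=tp, FP=fp, TN=tn, FN=fn),
        compound_set=compound_set,
    )


def evaluate_all_subsets(
    hit_table: pd.DataFrame,
    labels: dict[str, str],
    compound_set: str = "",
) -> list[FeatureSetResult]:
    subsets = sorted({tuple(s) for s in hit_table["subset"]})
    return [
        evaluate_subset(hit_table, s, labels, compound_set=compound_set)
        for s in subsets
    ]


def rank_feature_sets(
    results: list[FeatureSetResult],
    recall_threshold: float = 0.5,
) -> pd.DataFrame:
    """Filter to recall strictly above threshold and rank by MCC.

    Ties break by precision, then recall, then lexicographic subset.
    Returns a report table (compound set, feature set, counts, recall,
    precision, MCC); empty with a notice attribute when nothing survives.
    """
    if not results:
        raise ValueError("no results to rank")
    surviving = [r for r in results if r.metrics.recall > recall_threshold]
    surviving.sort(
        key=lambda r: (
            -r.metrics.mcc,
            -r.metrics.precision,
            -r.metrics.recall,
            r.subset,
        )
    )
    df = pd.DataFrame(
        [
            {
                "compound_set": r.compound_set,
                "feature_set": list(r.subset),
                "k": r.k,
                "TP": r.metrics.TP,
                "FP": r.metrics.FP,
                "TN": r.metrics.TN,
                "FN": r.metrics.FN,
                "recall": round(r.metrics.recall, 2),
                "precision": round(r.metrics.precision, 2),
                "mcc": round(r.metrics.mcc, 2),
            }
            for r in surviving
        ]
    )
    if df.empty:
        df.attrs["notice"] = (
            f"no feature set exceeded recall {recall_threshold}"
        )
    return df


def combined_set_evaluation(
    hit_table_a: pd.DataFrame,
    hit_table_b: pd.DataFrame,
    labels: dict[str, str],
    compound_set: str = "combined",
) -> list[FeatureSetResult]:
    """Metrics over the union of two screened sets (duplicates collapsed).

    A compound present in both tables must carry one label; conflicting
    labels raise.
    """
    both = pd.concat([hit_table_a, hit_table_b], ignore_index=True)
    dedup = (
        both.groupby(
            ["compound", "subset"], as_index=False, sort=False
        )
        .agg({"matched": "any", "stereo": "first", "entry": "first",
              "k": "first", "best_rmsd": "min"})
    )
    return evaluate_all_subsets(dedup, labels, compound_set=compound_set)


def check_label_conflicts(labels_a: dict[str, str], labels_b: dict[str, str]) -> dict[str, str]:
    """Merge two label maps, raising on conflicting labels for one id."""
    merged = dict(labels_a)
    conflicts = [
        c for c, lab in labels_b.items() if c in merged and merged[c] != lab
    ]
    if conflicts:
        raise ValueError(f"conflicting labels for: {sorted(conflicts)}")
    merged.update(labels_b)
    return merged
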