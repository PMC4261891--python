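"""Clustering quality against family truth: purity and F-measure.

Given ``N_ij``, the number of sequences in both family ``i`` and cluster
``j`` (with family sizes ``N_i``, cluster sizes ``N^_j`` and ``|D|`` total
sequences):

* cluster purity:   ``purity(j) = max_i N_ij / N^_j``
* overall purity:   ``sum_j max_i N_ij / |D|``  (cluster-size weighted)
* cluster label:    ``lbl(j) = argmax_i N_ij``  (ties -> lowest family index)
* family precision: over the ``m_i`` clusters labelled ``i``,
  ``P_i = sum_j N_ij / sum_j N^_j``
* family recall:    ``R_i = sum_j N_ij / N_i``
* family F:         ``F_i = 2 P_i R_i / (P_i + R_i)``;
  a family labelling no cluster scores ``(0, 0, 0)``
* overall F:        ``sum_i (N_i / |D|) F_i``  (family-size weighted)

Overall purity and overall F use size weighting — the standard reading,
stated here explicitly because it is a convention of this package.
Repeated k-means experiments are summarised by the arithmetic mean of the
per-repeat scores.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "EvaluationReport",
    "contingency",
    "cluster_purity",
    "overall_purity",
    "cluster_label",
    "family_prf",
    "overall_f",
    "evaluate_assignment",
    "evaluate_run",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Family x cluster co-occurrence counts.

    Rows are family labels (sorted), columns cluster indices (sorted);
    ``table.values[i, j]`` is ``N_ij``.
    """

    table: pd.DataFrame

    @property
    def families(self) -> list:
        return list(self.table.index)

    @property
    def clusters(self) -> list:
        return list(self.table.columns)

    @property
    def family_sizes(self) -> np.ndarray:
        return self.table.to_numpy().sum(axis=1)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.table.to_numpy().sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())


def contingency(assignment: Mapping[str, int], truth: Mapping[str, str]) -> ContingencyTable:
    """Cross-tabulate one clustering assignment against family truth.

    Raises
    ------
    KeyError
        If any assigned id is missing from the truth mapping (all missing
        ids are listed).
    """
    if not assignment:
        raise ValueError("empty assignment")
    missing = sorted(seq_id for seq_id in assignment if seq_id not in truth)
    if missing:
        raise KeyError(f"ids missing from truth: {missing}")
    ids = list(assignment)
    families = pd.Series([truth[i] for i in ids], name="family")
    clusters = pd.Series([assignment[i] for i in ids], name="cluster")
    table = pd.crosstab(families, clusters).sort_index(axis=0).sort_index(axis=1)
    return ContingencyTable(table)


def cluster_purity(ct: ContingencyTable, j) -> float:
    """Fraction of cluster ``j`` belonging to its dominant family."""
    col = ct.table[j].to_numpy()
    size = col.sum()
    if size == 0:
        raise ValueError(f"cluster {j!r} is empty")
    return float(col.max() / size)


def overall_purity(ct: ContingencyTable) -> float:
    """Cluster-size-weighted purity of the whole clustering."""
    counts = ct.table.to_numpy()
    if counts.sum() == 0:
        raise ValueError("empty contingency table")
    return float(counts.max(axis=0).sum() / counts.sum())


def cluster_label(ct: ContingencyTable, j):
    """The family label dominating cluster ``j`` (ties -> lowest index)."""
    col = ct.table[j].to_numpy()
    if col.sum() == 0:
        raise ValueError(f"cluster {j!r} is empty")
    return ct.families[int(col.argmax())]  # argmax ties -> lowest row index


def family_prf(ct: ContingencyTable, family) -> tuple[float, float, float]:
    """Precision, recall and F of one family over the clusters labelled
    with it; ``(0, 0, 0)`` if no cluster carries the family's label."""
    if family not in ct.table.index:
        raise KeyError(f"unknown family {family!r}")
    labelled = [j for j in ct.clusters if cluster_label(ct, j) == family]
    if not labelled:
        return (0.0, 0.0, 0.0)
    sub = ct.table[labelled]
    hits = float(sub.loc[family].to_numpy().sum())
    precision = hits / float(sub.to_numpy().sum())
    recall = hits / float(ct.table.loc[family].to_numpy().sum())
    if precision + recall == 0:
        return (precision, recall, 0.0)
    f = 2 * precision * recall / (precision + recall)
    return (precision, recall, f)


def overall_f(ct: ContingencyTable) -> float:
    """Family-size-weighted mean of per-family F-measures."""
    total = ct.total
    return float(
        sum(
            ct.table.loc[fam].to_numpy().sum() / total * family_prf(ct, fam)[2]
            for fam in ct.families
        )
    )


def evaluate_assignment(assignment: Mapping[str, int], truth: Mapping[str, str]) -> dict:
    """Purity, overall F and per-family P/R/F of one assignment."""
    ct = contingency(assignment, truth)
    per_family = {
        str(fam): dict(zip(("precision", "recall", "f"), family_prf(ct, fam)))
        for fam in ct.families
    }
    return {
        "purity": overall_purity(ct),
        "f": overall_f(ct),
        "per_family": per_family,
    }


@dataclass(frozen=True)
class EvaluationReport:
    """Repeat-averaged clustering quality."""

    purity_mean: float
    f_mean: float
    per_repeat: tuple[dict, ...]
    per_family: dict

    def to_dict(self) -> dict:
        return {
            "purity_mean": self.purity_mean,
            "f_mean": self.f_mean,
            "per_repeat": [
                {"purity": r["purity"], "f": r["f"]} for r in self.per_repeat
            ],
            "per_family": self.per_family,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_run(run_or_assignments, truth: Mapping[str, str]) -> EvaluationReport:
    """Evaluate every repeat of a clustering run and average the scores.

    Accepts a :class:`~cpfdna.clustering.ClusteringRun` or a plain list of
    id -> cluster mappings (one per repeat).
    """
    assignments: Sequence[Mapping[str, int]] = getattr(
        run_or_assignments, "assignments", run_or_assignments
    )
    per_repeat = [evaluate_assignment(a, truth) for a in assignments]
    families = sorted({fam for r in per_repeat for fam in r["per_family"]})
    per_family = {
        fam: {
            metric: float(
                np.mean(
                    [
                        r["per_family"].get(fam, {}).get(metric, 0.0)
                        for r in per_repeat
                    ]
                )
            )
            for metric in ("precision", "recall", "f")
        }
        for fam in families
    }
    return EvaluationReport(
        purity_mean=float(np.mean([r["purity"] for r in per_repeat])),
        f_mean=float(np.mean([r["f"] for r in per_repeat])),
        per_repeat=tuple(per_repeat),
        per_family=per_family,
    )
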