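"""Participant-wise stratified k-fold partitioning with leakage guards.

Folds are drawn over *participants*, never over windows or images, so
data from one subject can never appear in both training and testing.
Stratification deals the shuffled participants of each class round-robin
into folds with a running counter, which bounds both the per-fold
positive-class counts and the overall fold sizes to within one of each
other. One serialised plan is shared by the image and feature branches
so the two methods are compared on identical partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class LeakageError(RuntimeError):
    """A participant appeared in both a training and a test set."""


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: dict[str, int]  # participant_id -> fold index
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignments.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignments.items() if f != fold)

    def fold_sizes(self) -> list[int]:
        return [len(self.test_ids(f)) for f in range(self.k)]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"k": self.k, "seed": self.seed, "assignments": self.assignments},
            indent=2, sort_keys=True,
        ))

    @classmethod
    def load(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(k=int(d["k"]), assignments={p: int(f) for p, f in d["assignments"].items()},
                   seed=int(d["seed"]))


def make_folds(manifest: pd.DataFrame, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified participant-wise fold assignment.

    ``manifest`` needs ``participant_id`` and ``class_label`` columns.
    Within each class participants are shuffled by the seed and dealt
    round-robin; fold labels are then permuted so no fold index is
    systematically larger. Deterministic given the seed.
    """
    pids = manifest["participant_id"].tolist()
    labels = manifest["class_label"].tolist()
    n = len(pids)
    if len(set(pids)) != n:
        raise ValueError("duplicate participant ids in manifest")
    if not (2 <= k <= n):
        raise ValueError(f"k must satisfy 2 <= k <= {n}; got {k}")
    rng = np.random.default_rng(seed)
    fold_order = rng.permutation(k)
    assignments: dict[str, int] = {}
    counter = 0
    by_class: dict[str, list[str]] = {}
    for pid, lab in zip(pids, labels):
        by_class.setdefault(lab, []).append(pid)
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        rng.shuffle(members)
        for pid in members:
            assignments[pid] = int(fold_order[counter % k])
            counter += 1
    plan = FoldPlan(k=k, assignments=assignments, seed=seed)
    _validate_stratification(plan, dict(zip(pids, labels)))
    return plan


def _validate_stratification(plan: FoldPlan, labels: dict[str, str]) -> None:
    sizes = plan.fold_sizes()
    if max(sizes) - min(sizes) > 1:
        raise AssertionError(f"fold sizes differ by more than 1: {sizes}")
    for lab in set(labels.values()):
        counts = [sum(1 for p in plan.test_ids(f) if labels[p] == lab) for f in range(plan.k)]
        if max(counts) - min(counts) > 1:
            raise AssertionError(f"class {lab!r} counts differ by more than 1 across folds: {counts}")


def run_cv(
    fit_predict: Callable[[np.ndarray, np.ndarray, int], pd.DataFrame],
    item_participants: Sequence[str],
    plan: FoldPlan,
) -> pd.DataFrame:
    """Generic participant-wise CV driver.

    ``item_participants`` maps each data item (image, window or
    participant row) to its participant. For each fold, boolean train
    and test masks over the items are built from the plan and handed to
    ``fit_predict(train_mask, test_mask, fold)``, which must return a
    predictions frame for the test items. Participant disjointness is
    asserted at runtime; every item is predicted exactly once.
    """
    pids = np.asarray(item_participants)
    present = set(pids.tolist())
    missing = present - set(plan.assignments)
    if missing:
        raise ValueError(f"participants missing from fold plan: {sorted(missing)[:5]}")
    results = []
    for fold in range(plan.k):
        test_set = set(plan.test_ids(fold)) & present
        train_set = set(plan.train_ids(fold)) & present
        if test_set & train_set:
            raise LeakageError(f"participants in both train and test of fold {fold}: {sorted(test_set & train_set)}")
        if not test_set:
            continue
        test_mask = np.isin(pids, sorted(test_set))
        train_mask = np.isin(pids, sorted(train_set))
        if np.any(test_mask & train_mask):
            raise LeakageError(f"items shared between train and test in fold {fold}")
        out = fit_predict(train_mask, test_mask, fold)
        out = out.copy()
        out["fold"] = fold
        results.append(out)
    combined = pd.concat(results, ignore_index=True)
    if len(combined) != len(pids):
        raise AssertionError(
            f"each item must be predicted exactly once; got {len(combined)} predictions for {len(pids)} items"
        )
    return combined
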