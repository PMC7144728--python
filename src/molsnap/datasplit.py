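"""Top-quantile labeling and rotating-group Tra/Val/Test split plans.

A continuous activity is binarized by ranking: the top fraction ``q`` of
molecules is the positive class.  Evaluation uses a rotating-group
protocol: the dataset is shuffled into near-equal groups (5 for a 2:2:1
Tra/Val/Test ratio, 3 for 1:1:1); within one such segmentation each group
serves once as the test set while the remaining groups supply training
and validation.  Repeating the segmentation with fresh shuffles gives,
e.g., 5 x 5 = 25 evaluation rounds for 2:2:1.  Label permutation (for a
chance-level null model) lives here too.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LabeledDataset",
    "SplitRound",
    "SplitPlan",
    "label_by_threshold",
    "make_split_plan",
    "permute_labels",
]


@dataclass(frozen=True)
class LabeledDataset:
    """Ids, continuous activities and rank-derived binary labels."""

    ids: tuple[str, ...]
    activities: tuple[float, ...]
    labels: tuple[int, ...]
    q: float

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.activities) == len(self.labels)):
            raise ValueError("ids, activities and labels must align")

    @property
    def n_positive(self) -> int:
        return int(sum(self.labels))


@dataclass(frozen=True)
class SplitRound:
    """One evaluation round: disjoint Tra/Val/Test id sets covering the data."""

    round_id: str
    tra: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        parts = [set(self.tra), set(self.val), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError(f"{self.round_id}: Tra/Val/Test partitions overlap")


@dataclass(frozen=True)
class SplitPlan:
    """All rounds of a rotating-group evaluation for one ratio."""

    ratio: str
    rounds: tuple[SplitRound, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.rounds)

    def to_csv(self, path: str | Path) -> None:
        """Serialize as a plain-text ``round,partition,id`` table."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["round", "partition", "id"])
            for rnd in self.rounds:
                for part, ids in (("tra", rnd.tra), ("val", rnd.val), ("test", rnd.test)):
                    for i in ids:
                        writer.writerow([rnd.round_id, part, i])

    @classmethod
    def from_csv(cls, path: str | Path, ratio: str = "?", seed: int = -1) -> "SplitPlan":
        rows: dict[str, dict[str, list[str]]] = {}
        order: list[str] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rid = row["round"]
                if rid not in rows:
                    rows[rid] = {"tra": [], "val": [], "test": []}
                    order.append(rid)
                rows[rid][row["partition"]].append(row["id"])
        rounds = tuple(
            SplitRound(rid, tuple(rows[rid]["tra"]), tuple(rows[rid]["val"]),
                       tuple(rows[rid]["test"]))
            for rid in order
        )
        return cls(ratio, rounds, seed)


def label_by_threshold(activities: Sequence[float], q: float) -> np.ndarray:
    """Binary labels from a top-``q`` activity cut.

    Molecules are ranked by activity descending and the top ceil(q * n)
    are labeled 1.  Boundary ties are broken by input order (earlier
    index wins), so labeling depends only on ranks and is invariant under
    any strictly increasing transform of the activities.
    """
    acts = np.asarray(activities, dtype=float)
    if acts.ndim != 1 or acts.size == 0:
        raise ValueError("activities must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(acts)):
        raise ValueError("activities must be finite")
    if not (0 < q < 1):
        raise ValueError(f"threshold fraction q={q} outside (0, 1)")
    if np.all(acts == acts[0]):
        raise ValueError("all activities identical: rank-based labeling undefined")
    n_pos = math.ceil(q * acts.size)
    # stable sort on (-activity, index): ties go to the earlier input row
    order = np.lexsort((np.arange(acts.size), -acts))
    labels = np.zeros(acts.size, dtype=int)
    labels[order[:n_pos]] = 1
    return labels


def _deal_into_groups(ids: Sequence[str], labels: Sequence[int], n_groups: int,
                      rng: np.random.Generator, stratify: bool) -> list[list[str]]:
    """Shuffle ids and deal them round-robin into near-equal groups.

    With stratification each class is dealt separately, so every group's
    class ratio matches the dataset within one molecule.
    """
    ids = list(ids)
    labels = list(labels)
    groups: list[list[str]] = [[] for _ in range(n_groups)]
    if stratify:
        pools = [[i for i, l in zip(ids, labels) if l == 1],
                 [i for i, l in zip(ids, labels) if l == 0]]
    else:
        pools = [ids]
    offset = 0
    for pool in pools:
        pool = list(pool)
        rng.shuffle(pool)
        for k, mol_id in enumerate(pool):
            groups[(k + offset) % n_groups].append(mol_id)
        offset += len(pool)  # continue dealing where the last class stopped
    return groups


_RATIOS = {"2:2:1": (5, 2, 2), "1:1:1": (3, 1, 1)}


def make_split_plan(ids: Sequence[str], labels: Sequence[int], ratio: str,
                    n_segmentations: int, seed: int,
                    stratify: bool = True) -> SplitPlan:
    """Build the rotating-group evaluation plan.

    For ratio 2:2:1 each segmentation shuffles the ids into 5 near-equal
    (label-stratified) groups and yields 5 rounds, each using one group
    as Test and the remaining four as Tra (2 groups) + Val (2 groups);
    ``n_segmentations=5`` therefore gives 25 rounds.  Ratio 1:1:1 uses 3
    groups and 3 rounds per segmentation.  Deterministic for a fixed
    (ids, labels, ratio, n_segmentations, seed).
    """
    if ratio not in _RATIOS:
        raise ValueError(f"unrecognized ratio {ratio!r}; expected one of {sorted(_RATIOS)}")
    n_groups, n_tra, n_val = _RATIOS[ratio]
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if len(ids) < n_groups:
        raise ValueError(f"need at least {n_groups} molecules for ratio {ratio}")
    if n_segmentations < 1:
        raise ValueError("n_segmentations must be >= 1")
    labels = list(labels)
    if len(labels) != len(ids):
        raise ValueError("labels must align with ids")

    rng = np.random.default_rng(seed)
    rounds: list[SplitRound] = []
    for seg in range(n_segmentations):
        groups = _deal_into_groups(ids, labels, n_groups, rng, stratify)
        for g in range(n_groups):
            rest = [(g + k) % n_groups for k in range(1, n_groups)]
            tra = [i for k in rest[:n_tra] for i in groups[k]]
            val = [i for k in rest[n_tra:n_tra + n_val] for i in groups[k]]
            rid = f"{ratio}_{seg * n_groups + g + 1:02d}"
            rounds.append(SplitRound(rid, tuple(tra), tuple(val), tuple(groups[g])))
    return SplitPlan(ratio, tuple(rounds), seed)


def permute_labels(labels: Sequence[int], seed: int) -> np.ndarray:
    """Uniformly random permutation of the label multiset (seeded).

    Used to build the chance-level null model: class counts are exactly
    preserved while any association between structure and label is
    destroyed.
    """
    arr = np.asarray(labels)
    rng = np.random.default_rng(seed)
    return rng.permutation(arr)
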