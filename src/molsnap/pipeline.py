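"""End-to-end experiment runner for the snapshot-image and baseline arms.

Given activity-annotated molecules, an experiment (i) binarizes the
activity by a top-quantile cut, (ii) builds the rotating-group split
plan, (iii) embeds one conformer per molecule and renders its snapshot
ensemble, (iv) trains the image classifier per round and aggregates
per-image probabilities to per-molecule medians, and (v) evaluates every
round with the Youden-cutoff metric suite.  The descriptor baseline arm
reuses the same labels and the same Tra/Test molecule partitions.  A
label-permuted variant of either arm provides the chance-level null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chemio, datasplit, evalmetrics, modeling, snapshot
from .chemio import MoleculeRecord
from .datasplit import SplitPlan
from .evalmetrics import MetricReport
from .modeling import TrainSpec
from .snapshot import RenderConfig

__all__ = ["ExperimentConfig", "ExperimentResult", "render_dataset",
           "run_image_experiment", "run_baseline_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions of one evaluation experiment.

    ``increment`` is the per-axis snapshot angle (176 deg -> 27 images
    per molecule), ``q`` the top-quantile activity threshold, ``ratio``
    and ``n_segmentations`` the split protocol (2:2:1 with 5
    segmentations gives 25 rounds; 1 segmentation the 5-round variant),
    ``permute`` replaces the labels with a seeded permutation (null
    model).  ``seed`` drives conformer embedding, the split shuffles,
    the permutation and the classifier initialization.
    """

    increment: float = 176.0
    q: float = 0.40
    ratio: str = "2:2:1"
    n_segmentations: int = 1
    permute: bool = False
    seed: int = 0
    train: TrainSpec = field(default_factory=TrainSpec)
    render: RenderConfig = field(default_factory=RenderConfig)


@dataclass
class ExperimentResult:
    """Per-round reports plus prediction tables of one experiment arm.

    ``summary()`` gives the cross-round mean and sample SD of every
    metric, the per-arm analogue of one row of the study's performance
    tables.
    """

    arm: str
    config: ExperimentConfig
    reports: list[MetricReport]
    predictions: list[pd.DataFrame]
    labels: pd.Series

    def summary(self) -> pd.DataFrame:
        return evalmetrics.summarize_rounds(self.reports)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(r, metric) for r in self.reports]))

    def __repr__(self) -> str:
        s = self.summary()
        lines = [f"ExperimentResult(arm={self.arm!r}, rounds={len(self.reports)})"]
        for m in ("auc", "bac", "mcc", "accuracy", "f_measure"):
            lines.append(f"  {m:<10} {s.loc[m, 'mean']:.3f} +/- {s.loc[m, 'sd']:.3f}")
        return "\n".join(lines)


def _labels_for(records: list[MoleculeRecord], cfg: ExperimentConfig) -> pd.Series:
    acts = [r.activity for r in records]
    labels = datasplit.label_by_threshold(acts, cfg.q)
    if cfg.permute:
        labels = datasplit.permute_labels(labels, seed=cfg.seed + 101)
    return pd.Series(labels, index=[r.id for r in records])


def _split_plan(records: list[MoleculeRecord], labels: pd.Series,
                cfg: ExperimentConfig) -> SplitPlan:
    return datasplit.make_split_plan(
        [r.id for r in records], labels.to_numpy(), cfg.ratio,
        cfg.n_segmentations, seed=cfg.seed,
    )


def render_dataset(records: list[MoleculeRecord], increment: float,
                   config: RenderConfig, seed: int
                   ) -> tuple[dict[str, np.ndarray], list[snapshot.Orientation]]:
    """Embed one conformer per molecule and render its snapshot ensemble.

    Returns ``{id: (n_images, H, W, 3) uint8}`` plus the shared grid
    orientation order.  Molecules that fail to embed are skipped with a
    warning (per-record error, pipeline continues).
    """
    import warnings

    grid = snapshot.rotation_grid(increment)
    images: dict[str, np.ndarray] = {}
    for rec in records:
        try:
            mol3d = chemio.embed_3d(rec, seed=seed)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"skipping {rec.id}: {exc}", stacklevel=2)
            continue
        images[rec.id] = snapshot.snapshot_ensemble(mol3d, increment, config).images()
    return images, grid


def _round_metrics(round_id: str, scores: pd.Series, labels: pd.Series
                   ) -> MetricReport:
    y = labels.loc[scores.index].to_numpy()
    s = scores.to_numpy()
    auc = evalmetrics.roc_auc(s, y)
    cutoff = evalmetrics.youden_cutoff(s, y)
    counts = evalmetrics.confusion(s, y, cutoff)
    return evalmetrics.metric_suite(counts, round_id=round_id, auc=auc,
                                    cutoff=cutoff)


def run_image_experiment(records: list[MoleculeRecord],
                         cfg: ExperimentConfig = ExperimentConfig(),
                         images: dict[str, np.ndarray] | None = None,
                         grid: list[snapshot.Orientation] | None = None,
                         ) -> ExperimentResult:
    """The snapshot-image arm over all rounds of the split plan.

    Pre-rendered ``images``/``grid`` (from :func:`render_dataset`) may
    be passed to amortize rendering across experiments; they must match
    ``cfg.increment`` and ``cfg.render``.
    """
    records = list(records)
    if images is None or grid is None:
        images, grid = render_dataset(records, cfg.increment, cfg.render, cfg.seed)
    records = [r for r in records if r.id in images]
    labels = _labels_for(records, cfg)
    plan = _split_plan(records, labels, cfg)

    def stack(ids):
        x = np.concatenate([images[i] for i in ids])
        y = np.repeat(labels.loc[list(ids)].to_numpy(), [len(images[i]) for i in ids])
        return x, y

    reports, tables = [], []
    for k, rnd in enumerate(plan.rounds):
        x_tra, y_tra = stack(rnd.tra)
        x_val, y_val = stack(rnd.val)
        spec = replace(cfg.train, seed=cfg.train.seed + cfg.seed * 1009 + k)
        model, _ = modeling.train_image_classifier(x_tra, y_tra, x_val, y_val, spec)
        x_test, _ = stack(rnd.test)
        probs = modeling.predict_images(model, x_test)
        ids = [i for i in rnd.test for _ in range(len(images[i]))]
        orients = [o for i in rnd.test for o in grid]
        table = modeling.make_prediction_table(ids, orients, probs)
        scores = evalmetrics.aggregate_median(table)
        reports.append(_round_metrics(rnd.round_id, scores, labels))
        tables.append(table)
    return ExperimentResult("deepsnap", cfg, reports, tables, labels)


def run_baseline_experiment(records: list[MoleculeRecord], learner: str,
                            cfg: ExperimentConfig = ExperimentConfig(),
                            descriptors: pd.DataFrame | None = None,
                            ) -> ExperimentResult:
    """The descriptor arm: one conventional learner over the same plan.

    Trains on each round's Tra groups and scores its Test molecules
    (Tra/Test = 2:1 for the 2:2:1 plan; the Val groups are unused by the
    descriptor learners), so both arms see identical test partitions.
    """
    records = list(records)
    if descriptors is None:
        descriptors = modeling.compute_descriptors(records)
    labels = _labels_for(records, cfg)
    plan = _split_plan(records, labels, cfg)

    reports, tables = [], []
    for k, rnd in enumerate(plan.rounds):
        y_tra = labels.loc[list(rnd.tra)].to_numpy()
        model = modeling.train_baseline(
            descriptors.loc[list(rnd.tra)], y_tra, learner,
            seed=cfg.seed * 1009 + k,
        )
        probs = model.predict_proba(descriptors.loc[list(rnd.test)].to_numpy())[:, 1]
        table = pd.DataFrame({
            "id": list(rnd.test), "rx": 0.0, "ry": 0.0, "rz": 0.0, "prob": probs,
        })
        scores = evalmetrics.aggregate_median(table)
        reports.append(_round_metrics(rnd.round_id, scores, labels))
        tables.append(table)
    return ExperimentResult(learner, cfg, reports, tables, labels)
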