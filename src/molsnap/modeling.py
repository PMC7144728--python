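"""Image-ensemble classifier and descriptor-table baseline learners.

The image arm trains a classifier on the per-image snapshots (every
image inherits its molecule's label) and scores test images with a
class-1 probability; the backend is pluggable, with a default compact
feed-forward network over block-averaged pixels that trains on a CPU in
seconds and supports the six classic solvers (NAG, AdaGrad, AdaDelta,
Adam, RMSprop, SGD).  Model selection returns the epoch checkpoint with
the minimum validation loss.  The baseline arm fits conventional
learners (random forest and gradient-boosting variants) on a fixed 2D
molecular-descriptor table computed with RDKit.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemio import MoleculeRecord

__all__ = [
    "TrainSpec",
    "EpochTrace",
    "SmallImageNet",
    "train_image_classifier",
    "predict_images",
    "make_prediction_table",
    "compute_descriptors",
    "train_baseline",
    "BASELINE_LEARNERS",
    "SOLVERS",
]

SOLVERS = ("NAG", "AdaGrad", "AdaDelta", "Adam", "RMSprop", "SGD")


@dataclass(frozen=True)
class TrainSpec:
    """Training hyperparameters of the image classifier.

    Defaults are the tuned operating point of the method: Nesterov
    accelerated gradient, learning rate 0.0025, batch size 37, 30
    epochs.
    """

    solver: str = "NAG"
    learning_rate: float = 0.0025
    batch_size: int = 37
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.solver not in SOLVERS:
            raise ValueError(f"unknown solver {self.solver!r}; choose from {SOLVERS}")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")


@dataclass(frozen=True)
class EpochTrace:
    """Per-epoch validation loss and validation accuracy (percent)."""

    val_loss: tuple[float, ...]
    val_acc: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.val_loss) != len(self.val_acc):
            raise ValueError("loss and accuracy traces must align")
        if any(l < 0 for l in self.val_loss):
            raise ValueError("validation loss must be >= 0")
        if any(not (0 <= a <= 100) for a in self.val_acc):
            raise ValueError("validation accuracy must be in [0, 100]")

    @property
    def best_epoch(self) -> int:
        """Index (0-based) of the minimum validation loss."""
        return int(np.argmin(self.val_loss))

    def __len__(self) -> int:
        return len(self.val_loss)


class ImageClassifier(Protocol):
    """Contract of a pluggable image-classifier backend."""

    def fit(self, images: np.ndarray, labels: np.ndarray,
            val_images: np.ndarray, val_labels: np.ndarray,
            spec: TrainSpec) -> EpochTrace: ...

    def predict_proba(self, images: np.ndarray) -> np.ndarray: ...


class _Optimizer:
    """The six solver update rules over a flat list of parameter arrays."""

    def __init__(self, solver: str, lr: float, shapes: list[tuple[int, ...]]):
        self.solver = solver
        self.lr = lr
        self.mom = 0.9
        self.rho = 0.95
        self.eps = 1e-7
        self.t = 0
        self.slot1 = [np.zeros(s) for s in shapes]
        self.slot2 = [np.zeros(s) for s in shapes]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for k, (p, g) in enumerate(zip(params, grads)):
            if self.solver == "SGD":
                p -= self.lr * g
            elif self.solver == "NAG":
                v = self.slot1[k]
                v *= self.mom
                v += g
                p -= self.lr * (g + self.mom * v)
            elif self.solver == "AdaGrad":
                acc = self.slot1[k]
                acc += g * g
                p -= self.lr * g / (np.sqrt(acc) + self.eps)
            elif self.solver == "AdaDelta":
                eg, ed = self.slot1[k], self.slot2[k]
                eg *= self.rho
                eg += (1 - self.rho) * g * g
                update = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
                ed *= self.rho
                ed += (1 - self.rho) * update * update
                p += update  # AdaDelta derives its own step size; lr unused
            elif self.solver == "RMSprop":
                eg = self.slot1[k]
                eg *= self.rho
                eg += (1 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(eg) + self.eps)
            elif self.solver == "Adam":
                m, v = self.slot1[k], self.slot2[k]
                m *= 0.9
                m += 0.1 * g
                v *= 0.999
                v += 0.001 * g * g
                mhat = m / (1 - 0.9 ** self.t)
                vhat = v / (1 - 0.999 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _chromatic_anchors() -> np.ndarray:
    """Chromaticity anchors of the clearly colored palette entries.

    Achromatic palette colors (carbon gray, hydrogen white, stick gray)
    share the same chromaticity and are handled separately by luminance
    binning; duplicate chromaticities (iodine purple vs the magenta
    fallback) are merged.
    """
    from .snapshot import CPK_COLORS, DEFAULT_COLOR

    palette = np.array(list(CPK_COLORS.values()) + [DEFAULT_COLOR], dtype=float)
    chrom = palette / palette.sum(axis=1, keepdims=True)
    kept: list[np.ndarray] = []
    for row in chrom:
        if np.sum((row - 1.0 / 3.0) ** 2) < 0.03**2:
            continue  # achromatic
        if any(np.sum((row - k) ** 2) < 0.03**2 for k in kept):
            continue  # chromaticity duplicate
        kept.append(row)
    return np.array(kept)


class SmallImageNet:
    """Committee of compact feed-forward networks over color-bin features.

    Each image is summarized by fixed features: the share of molecule
    (non-background) pixels falling in each color bin — chromaticity
    bins anchored at the clearly colored CPK element hues, plus three
    luminance bins splitting the achromatic pixels (shaded carbon gray,
    bond-stick gray, hydrogen white) — together with the molecule's
    pixel fraction of the frame and, as spatial context, the image
    average-pooled by ``pool`` (default: one global block, the mean
    color; a finer grid can be requested when shape matters).
    Normalizing shares over molecule pixels removes the per-molecule
    zoom; the shares expose the per-element pixel budget, which is
    where these renders carry the structure-activity signal.  Features
    are standardized with statistics computed on the training images
    only, then fed through one ReLU hidden layer into a two-class
    softmax.  ``n_models`` committee members differ only in their seeded
    initialization and batch order; their probabilities are averaged.
    Deliberately small and CPU-deterministic; any backend satisfying
    :class:`ImageClassifier` can be substituted.
    """

    #: pixels darker than this luminance (sum of unit-scaled channels)
    #: count as background
    _DARK = 0.15
    #: luminance edges splitting achromatic pixels (shadow / gray / white)
    _LUM_EDGES = (1.0, 1.9)

    def __init__(self, hidden: int = 64, pool: int | None = None,
                 n_models: int = 3):
        if hidden < 1 or (pool is not None and pool < 1) or n_models < 1:
            raise ValueError("hidden width, pool factor and n_models must be >= 1")
        self.hidden = hidden
        self.pool = pool
        self.n_models = n_models
        self.anchors = _chromatic_anchors()
        self.members: list[list[np.ndarray]] | None = None
        self.feature_mean: np.ndarray | None = None
        self.feature_std: np.ndarray | None = None
        self.input_shape: tuple[int, int, int] | None = None
        self.trace: EpochTrace | None = None
        self.member_traces: list[EpochTrace] | None = None

    @property
    def params(self) -> list[np.ndarray] | None:
        """Parameters of the first committee member (None before fit)."""
        return self.members[0] if self.members else None

    # -- features ----------------------------------------------------------
    def _featurize_chunk(self, images: np.ndarray) -> np.ndarray:
        n, h, w, _ = images.shape
        x = images.astype(np.float32) / np.float32(255.0)
        if self.pool is None:
            pooled = x.mean(axis=(1, 2))  # global mean color
        else:
            p = self.pool
            pooled = x.reshape(n, h // p, p, w // p, p, 3).mean(axis=(2, 4))
            pooled = pooled.reshape(n, -1)

        flat = x.reshape(-1, 3)
        lum = flat.sum(axis=1)
        chrom = flat / (lum[:, None] + np.float32(1e-9))
        anchors = self.anchors.astype(np.float32)
        # argmin over |c - a|^2 = argmax over c.a - |a|^2/2 (|c| is constant per pixel)
        score = chrom @ anchors.T - 0.5 * (anchors**2).sum(axis=1)
        nearest = score.argmax(axis=1)
        best_d2 = ((chrom - anchors[nearest]) ** 2).sum(axis=1)
        ach_d2 = ((chrom - np.float32(1.0 / 3.0)) ** 2).sum(axis=1)
        n_chrom = len(anchors)
        achromatic = ach_d2 <= best_d2
        bins = np.where(achromatic,
                        n_chrom + np.digitize(lum, self._LUM_EDGES), nearest)
        n_bins = n_chrom + 3 + 1
        bins[lum < self._DARK] = n_bins - 1  # background
        npx = h * w
        offsets = np.repeat(np.arange(n) * n_bins, npx)
        counts = np.bincount(offsets + bins, minlength=n * n_bins)
        counts = counts.reshape(n, n_bins).astype(np.float64)
        # shares over molecule (non-background) pixels: invariant to the
        # per-molecule zoom, which otherwise dilutes every color share
        mol_px = counts[:, :-1].sum(axis=1) + 1e-9
        shares = counts[:, :-1] / mol_px[:, None]
        size = mol_px[:, None] / float(npx)
        return np.concatenate([pooled, shares, size], axis=1).astype(np.float64)

    def _featurize(self, images: np.ndarray) -> np.ndarray:
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError("images must be an (n, H, W, 3) array")
        h, w = images.shape[1:3]
        if self.pool is not None and (h % self.pool or w % self.pool):
            raise ValueError(f"image size {h}x{w} not divisible by pool={self.pool}")
        chunks = [self._featurize_chunk(images[i:i + 256])
                  for i in range(0, len(images), 256)]
        return np.concatenate(chunks, axis=0)

    # -- forward/backward --------------------------------------------------
    @staticmethod
    def _forward(params: list[np.ndarray], x: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        w1, b1, w2, b2 = params
        h = np.maximum(x @ w1 + b1, 0.0)
        logits = h @ w2 + b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return h, e / e.sum(axis=1, keepdims=True)

    @staticmethod
    def _loss(probs: np.ndarray, y: np.ndarray) -> float:
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    def _fit_member(self, x: np.ndarray, y: np.ndarray, xv: np.ndarray,
                    yv: np.ndarray, spec: TrainSpec, member_seed: int
                    ) -> tuple[list[np.ndarray], EpochTrace]:
        rng = np.random.default_rng(member_seed)
        d = x.shape[1]
        params = [
            rng.normal(0.0, math.sqrt(2.0 / d), (d, self.hidden)),
            np.zeros(self.hidden),
            rng.normal(0.0, math.sqrt(2.0 / self.hidden), (self.hidden, 2)),
            np.zeros(2),
        ]
        opt = _Optimizer(spec.solver, spec.learning_rate, [p.shape for p in params])
        losses, accs = [], []
        best = (np.inf, copy.deepcopy(params))
        for epoch in range(spec.epochs):
            order = rng.permutation(len(x))
            for start in range(0, len(x), spec.batch_size):
                idx = order[start:start + spec.batch_size]
                xb, yb = x[idx], y[idx]
                h, probs = self._forward(params, xb)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads = [None, None, h.T @ dlogits, dlogits.sum(axis=0)]
                dh = dlogits @ params[2].T
                dh[h <= 0] = 0.0
                grads[0] = xb.T @ dh
                grads[1] = dh.sum(axis=0)
                opt.step(params, grads)
            _, pv = self._forward(params, xv)
            vloss = self._loss(pv, yv)
            if not math.isfinite(vloss):
                raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
            losses.append(vloss)
            accs.append(100.0 * float(np.mean(pv.argmax(axis=1) == yv)))
            if vloss < best[0]:
                best = (vloss, copy.deepcopy(params))
        return best[1], EpochTrace(tuple(losses), tuple(accs))

    def fit(self, images: np.ndarray, labels: np.ndarray,
            val_images: np.ndarray, val_labels: np.ndarray,
            spec: TrainSpec) -> EpochTrace:
        """Train all committee members; each keeps its min-val-loss checkpoint.

        The returned trace (also ``self.trace``) is the first member's;
        all traces are kept in ``self.member_traces``.
        """
        y = np.asarray(labels, dtype=int)
        yv = np.asarray(val_labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        if len(images) == 0 or len(val_images) == 0:
            raise ValueError("training and validation sets must be non-empty")
        self.input_shape = images.shape[1:]
        x = self._featurize(images)
        self.feature_mean = x.mean(axis=0)
        self.feature_std = x.std(axis=0) + 1e-6
        x = (x - self.feature_mean) / self.feature_std
        xv = (self._featurize(val_images) - self.feature_mean) / self.feature_std

        self.members, self.member_traces = [], []
        for m in range(self.n_models):
            params, trace = self._fit_member(x, y, xv, yv, spec,
                                             spec.seed + 7919 * m)
            self.members.append(params)
            self.member_traces.append(trace)
        self.trace = self.member_traces[0]
        return self.trace

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Committee-mean class-1 probability per image (pure function)."""
        if self.members is None:
            raise RuntimeError("model is not trained")
        if images.shape[1:] != self.input_shape:
            raise ValueError(
                f"image shape {images.shape[1:]} does not match training "
                f"resolution {self.input_shape}"
            )
        x = (self._featurize(images) - self.feature_mean) / self.feature_std
        return np.mean([self._forward(m, x)[1][:, 1] for m in self.members],
                       axis=0)


def train_image_classifier(images: np.ndarray, labels: Sequence[int],
                           val_images: np.ndarray, val_labels: Sequence[int],
                           spec: TrainSpec,
                           model: ImageClassifier | None = None
                           ) -> tuple[ImageClassifier, EpochTrace]:
    """Train a backend on per-image labels; keep the min-val-loss checkpoint.

    The returned model is the epoch checkpoint with the lowest
    validation loss over the trace, not the final epoch.  Deterministic
    for a fixed (data, spec, backend) triple.
    """
    if model is None:
        model = SmallImageNet()
    trace = model.fit(np.asarray(images), np.asarray(labels),
                      np.asarray(val_images), np.asarray(val_labels), spec)
    return model, trace


def predict_images(model: ImageClassifier, images: np.ndarray) -> np.ndarray:
    """Order-stable per-image class-1 probabilities in [0, 1]."""
    probs = np.asarray(model.predict_proba(np.asarray(images)), dtype=float)
    if probs.ndim != 1 or len(probs) != len(images):
        raise ValueError("backend must return one probability per image")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("backend probabilities outside [0, 1]")
    return probs


def make_prediction_table(ids: Sequence[str], orientations: Sequence,
                          probs: Sequence[float]) -> pd.DataFrame:
    """Assemble the per-image prediction table ``id, rx, ry, rz, prob``."""
    frame = pd.DataFrame({
        "id": list(ids),
        "rx": [o.rx for o in orientations],
        "ry": [o.ry for o in orientations],
        "rz": [o.rz for o in orientations],
        "prob": np.asarray(probs, dtype=float),
    })
    if frame.duplicated(["id", "rx", "ry", "rz"]).any():
        raise ValueError("duplicate (id, orientation) rows in prediction table")
    return frame


# ---------------------------------------------------------------------------
# descriptor baseline arm
# ---------------------------------------------------------------------------

def compute_descriptors(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    """Fixed 2D molecular-descriptor table (RDKit descriptor list).

    One row per molecule (indexed by id), one column per descriptor in
    RDKit's standard list (~210 columns: counts, topological indices,
    physicochemical estimates).  Columns containing any non-finite value
    are dropped dataset-wide so every model sees the same feature set.
    """
    rows, index = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ValueError(f"{rec.id}: unparseable SMILES")
        rows.append(Descriptors.CalcMolDescriptors(mol))
        index.append(rec.id)
    frame = pd.DataFrame(rows, index=index).astype(float)
    finite = frame.columns[np.isfinite(frame).all(axis=0)]
    return frame[finite]


def _make_rf(seed: int):
    from sklearn.ensemble import RandomForestClassifier
    return RandomForestClassifier(random_state=seed)


def _make_xgb(seed: int):
    try:
        from xgboost import XGBClassifier
    except ImportError as exc:
        raise ImportError("XGB baseline arm requires the xgboost package") from exc
    return XGBClassifier(random_state=seed, n_jobs=1)


def _make_lgbm(seed: int):
    try:
        from lightgbm import LGBMClassifier
    except ImportError as exc:
        raise ImportError("LGBM baseline arm requires the lightgbm package") from exc
    return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)


def _make_cb(seed: int):
    try:
        from catboost import CatBoostClassifier
    except ImportError as exc:
        raise ImportError("CB baseline arm requires the catboost package") from exc
    return CatBoostClassifier(random_state=seed, verbose=False)


BASELINE_LEARNERS = {"RF": _make_rf, "XGB": _make_xgb, "LGBM": _make_lgbm,
                     "CB": _make_cb}


def train_baseline(descriptors: pd.DataFrame, labels: Sequence[int],
                   learner: str, seed: int = 0):
    """Fit a conventional learner on the descriptor table (seeded).

    ``learner`` is RF, XGB, LGBM or CB, at library-default
    hyperparameters.  A missing backend raises ImportError naming the
    arm.  The fitted model exposes ``predict_proba``.
    """
    if learner not in BASELINE_LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; choose from "
                         f"{sorted(BASELINE_LEARNERS)}")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("baseline training needs both classes present")
    model = BASELINE_LEARNERS[learner](seed)
    model.fit(descriptors.to_numpy(), y)
    return model
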