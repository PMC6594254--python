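"""Base neural learner, validation schemes, hybrid wirings and the n-hyper
recursion.

The base learner is a four-layer feedforward network (input, two hidden
layers, output) trained by backpropagation with momentum.  Three validation
schemes are supported: a 67/33 split, a 50/50 split, and leave-one-out
cross-validation.  Hybrids wire several learners so that each member's
per-item predictions are appended to the feature matrix of the next member
in the flow ("results transferred to input"); members never share weights.
An n-hyper hybrid replaces each member of the wiring by a whole (n-1)-hyper
system, recursively, so a level-n series hybrid trains 3^n times as many
leaf learners as its level-0 counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence as Seq, Tuple

import numpy as np

__all__ = [
    "LearnerConfig",
    "EvaluationScheme",
    "HybridTopology",
    "LabeledDataset",
    "Learner",
    "EvaluationResult",
    "HybridResult",
    "train_learner",
    "evaluate",
    "run_hybrid",
    "run_hyper_hybrid",
    "percent_agreement",
    "wiring_trace",
]


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters of the four-layer base network.

    Learning rate 0.7, momentum 0.6 and the two tolerances (0.2 on the
    learning set, 0.02 on the test set) are the reference settings; hidden
    widths are a package default since none are prescribed.
    """

    hidden: Tuple[int, int] = (8, 4)
    learning_rate: float = 0.7
    momentum: float = 0.6
    test_tolerance: float = 0.02
    train_tolerance: float = 0.2
    max_epochs: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1 or not 0 < self.momentum <= 1:
            raise ValueError("learning_rate and momentum must be in (0, 1]")
        if self.train_tolerance <= 0 or self.test_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class EvaluationScheme:
    """Validation scheme: 'split67_33', 'split50_50' or 'loocv'.

    For splits the test size is round(fraction * n); the partition is a
    seeded permutation.
    """

    kind: str = "loocv"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("split67_33", "split50_50", "loocv"):
            raise ValueError("kind must be split67_33, split50_50 or loocv")

    @property
    def test_fraction(self) -> Optional[float]:
        return {"split67_33": 0.33, "split50_50": 0.5, "loocv": None}[self.kind]


@dataclass(frozen=True)
class LabeledDataset:
    """Feature rows plus binary labels (1 = cancer-associated)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=int))
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2D with one row per label")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.y)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class Learner:
    """Four-layer sigmoidal network trained by gradient descent with momentum.

    Inputs are standardized on the training set.  Training stops when every
    training item is within ``train_tolerance`` of its target, or at
    ``max_epochs``.  Deterministic given the config seed.
    """

    def __init__(self, config: LearnerConfig):
        self.config = config
        self.constant: Optional[int] = None
        self._weights: List[np.ndarray] = []
        self._mean: Optional[np.ndarray] = None
        self._scale: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Learner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        classes = set(np.unique(y))
        if len(classes) == 1:
            warnings.warn("single-class training set: constant predictor")
            self.constant = int(y[0])
            return self
        self._mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self._scale = scale
        Xs = (X - self._mean) / self._scale

        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        sizes = [X.shape[1], cfg.hidden[0], cfg.hidden[1], 1]
        # weight matrices include a bias row
        self._weights = [
            rng.uniform(-0.5, 0.5, size=(sizes[i] + 1, sizes[i + 1]))
            for i in range(3)
        ]
        velocity = [np.zeros_like(w) for w in self._weights]
        n = len(Xs)
        for _ in range(cfg.max_epochs):
            acts = self._forward(Xs)
            out = acts[-1][:, 0]
            if np.max(np.abs(out - y)) <= cfg.train_tolerance:
                break
            delta = (out - y)[:, None] * out[:, None] * (1 - out[:, None])
            grads = []
            for layer in reversed(range(3)):
                a_prev = np.hstack([acts[layer], np.ones((n, 1))])
                grads.append(a_prev.T @ delta / n)
                if layer:
                    back = delta @ self._weights[layer][:-1].T
                    delta = back * acts[layer] * (1 - acts[layer])
            grads.reverse()
            for w, v, g in zip(self._weights, velocity, grads):
                v *= cfg.momentum
                v -= cfg.learning_rate * g
                w += v
        return self

    def _forward(self, Xs: np.ndarray) -> List[np.ndarray]:
        acts = [Xs]
        for w in self._weights:
            a = _sigmoid(np.hstack([acts[-1], np.ones((len(Xs), 1))]) @ w)
            acts.append(a)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.constant is not None:
            return np.full(len(X), float(self.constant))
        Xs = (X - self._mean) / self._scale
        return self._forward(Xs)[-1][:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def train_learner(data: LabeledDataset, config: LearnerConfig) -> Learner:
    """Train a base learner on the full dataset."""
    if len(data) < 2:
        raise ValueError("training requires at least 2 rows")
    return Learner(config).fit(data.X, data.y)


@dataclass(frozen=True)
class EvaluationResult:
    """Held-out predictions, their agreement with truth, and per-item
    predictions over the whole dataset (used for hybrid transfer)."""

    held_out: Tuple[int, ...]
    predictions: np.ndarray          # over held_out, 0/1
    agreement: float                 # percent, on held_out
    item_predictions: np.ndarray     # over all items, 0/1


def percent_agreement(predicted: Seq[int], reference: Seq[int]) -> float:
    """100 x (matching positions) / length."""
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    if predicted.shape != reference.shape or predicted.size == 0:
        raise ValueError("vectors must be non-empty and of equal length")
    return 100.0 * float(np.mean(predicted == reference))


def evaluate(
    data: LabeledDataset, config: LearnerConfig, scheme: EvaluationScheme
) -> EvaluationResult:
    """Evaluate a base learner under a validation scheme.

    Splits train one model on the learning part and score the test part;
    LOOCV predicts every item from a model trained on the others.  The
    returned ``item_predictions`` cover all items: out-of-fold predictions
    under LOOCV, and the split model's predictions elsewhere.
    """
    n = len(data)
    if scheme.kind == "loocv":
        if n < 2:
            raise ValueError("loocv requires at least 2 items")
        preds = np.empty(n, dtype=int)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = Learner(config).fit(data.X[mask], data.y[mask])
            preds[i] = model.predict(data.X[i : i + 1])[0]
        held = tuple(range(n))
        return EvaluationResult(
            held_out=held,
            predictions=preds,
            agreement=percent_agreement(preds, data.y),
            item_predictions=preds,
        )
    if n < 3:
        raise ValueError("split schemes require at least 3 items")
    n_test = round(scheme.test_fraction * n)
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(scheme.seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_mask = np.ones(n, dtype=bool)
    train_mask[test_idx] = False
    model = Learner(config).fit(data.X[train_mask], data.y[train_mask])
    item_preds = model.predict(data.X)
    preds = item_preds[test_idx]
    return EvaluationResult(
        held_out=tuple(int(i) for i in test_idx),
        predictions=preds,
        agreement=percent_agreement(preds, data.y[test_idx]),
        item_predictions=item_preds,
    )


# ---------------------------------------------------------------------------
# Hybrid wirings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HybridTopology:
    """A wiring of members: series 1->2->...->k; cyclic adds k->1 (one full
    cycle, member 1's second pass emits the output); cascade runs forward
    then backward (1->...->k->...->1)."""

    wiring: str
    members: Tuple[LearnerConfig, ...]
    hyper_level: int = 0

    def __post_init__(self) -> None:
        if self.wiring not in ("series", "cyclic", "cascade"):
            raise ValueError("wiring must be series, cyclic or cascade")
        if not self.members:
            raise ValueError("at least one member is required")
        if self.hyper_level < 0:
            raise ValueError("hyper_level must be >= 0")


def wiring_trace(wiring: str, k: int) -> Tuple[int, ...]:
    """Execution order of member indices for a k-member wiring."""
    forward = tuple(range(k))
    if wiring == "series":
        return forward
    if wiring == "cyclic":
        return forward + (0,)
    return forward + tuple(reversed(range(k - 1)))  # cascade


class _SeedStream:
    """Deterministic stream of per-execution seeds (< 2^31)."""

    def __init__(self, base_seed: int):
        self._base = np.random.SeedSequence(base_seed)
        self._count = 0

    def next_seed(self) -> int:
        seed = np.random.SeedSequence(
            entropy=self._base.entropy, spawn_key=(self._count,)
        ).generate_state(1)[0]
        self._count += 1
        return int(seed % (2**31))

    @property
    def executions(self) -> int:
        return self._count


@dataclass(frozen=True)
class HybridResult:
    held_out: Tuple[int, ...]
    predictions: np.ndarray
    agreement: float
    item_predictions: np.ndarray
    trace: Tuple[int, ...]           # executed member indices, in order
    n_learners: int                  # leaf learners trained
    tree: object                     # nested structure log


def _run_wiring(
    data: LabeledDataset,
    topology: HybridTopology,
    scheme: EvaluationScheme,
    stream: _SeedStream,
) -> HybridResult:
    trace = wiring_trace(topology.wiring, len(topology.members))
    X = data.X
    before = stream.executions
    result: Optional[EvaluationResult] = None
    log = []
    for pos, member_idx in enumerate(trace):
        cfg = replace(topology.members[member_idx], seed=stream.next_seed())
        result = evaluate(
            LabeledDataset(X, data.y, data.feature_names), cfg, scheme
        )
        log.append({"member": member_idx, "seed": cfg.seed})
        if pos < len(trace) - 1:
            X = np.hstack([X, result.item_predictions[:, None].astype(float)])
    return HybridResult(
        held_out=result.held_out,
        predictions=result.predictions,
        agreement=result.agreement,
        item_predictions=result.item_predictions,
        trace=trace,
        n_learners=stream.executions - before,
        tree={"wiring": topology.wiring, "members": log},
    )


def run_hybrid(
    data: LabeledDataset,
    topology: HybridTopology,
    scheme: EvaluationScheme,
    seed: int = 0,
) -> HybridResult:
    """Execute a (level-0) hybrid wiring of base learners.

    Each transfer appends the executed member's per-item predictions as one
    extra feature column for the next member in the flow; the final member
    in the flow emits the output.
    """
    return _run_wiring(data, topology, scheme, _SeedStream(seed))


def run_hyper_hybrid(
    data: LabeledDataset,
    n: int,
    base_topology: HybridTopology,
    scheme: EvaluationScheme,
    seed: int = 0,
) -> HybridResult:
    """Execute an n-hyper hybrid.

    Level 0 is :func:`run_hybrid`; level L wires three level-(L-1) systems
    under the same wiring, transferring each subsystem's per-item
    predictions into the next subsystem's features.
    """
    if n < 0:
        raise ValueError("hyper level must be >= 0")
    stream = _SeedStream(seed)

    def run_system(level: int, X: np.ndarray) -> Tuple[HybridResult, object]:
        ds = LabeledDataset(X, data.y, data.feature_names)
        if level == 0:
            res = _run_wiring(ds, base_topology, scheme, stream)
            return res, res.tree
        trace = wiring_trace(base_topology.wiring, 3)
        cur = X
        res = None
        subtrees = []
        for pos, sub_idx in enumerate(trace):
            res, subtree = run_system(level - 1, cur)
            subtrees.append({"subsystem": sub_idx, "tree": subtree})
            if pos < len(trace) - 1:
                cur = np.hstack([cur, res.item_predictions[:, None].astype(float)])
        return res, {"level": level, "wiring": base_topology.wiring, "children": subtrees}

    final, tree = run_system(n, data.X)
    return HybridResult(
        held_out=final.held_out,
        predictions=final.predictions,
        agreement=final.agreement,
        item_predictions=final.item_predictions,
        trace=final.trace,
        n_learners=stream.executions,
        tree=tree,
    )
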