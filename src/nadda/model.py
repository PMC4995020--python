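"""Random Subspace ensemble of decision trees over window features.

Each tree is trained on a feature subset drawn uniformly without replacement
from the ``2w + 1`` window positions; training rows are never bootstrapped
(this is Random Subspace, not Random Forest). Prediction is a strict-majority
hard vote, with exact ties resolved to non-conserved — the conservative call.
The split thresholds the trees learn play the role of the per-window-position
threshold set {tau_1 .. tau_2w+1} that separates conserved from background
frequency patterns.

``mss`` is pre-pruning strength: the minimum number of instances an internal
node must hold to be eligible for splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import sklearn
from sklearn.tree import DecisionTreeClassifier

from .errors import InputError, ModelLoadError, ParameterError
from .featurize import InstanceBlock

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Ensemble hyper-parameters.

    mss: minimum instances in an internal node to allow a split (default 100).
    max_features_per_tree: features drawn per tree (default 7).
    n_trees: ensemble size (default 100).
    seed: RNG seed driving subset draws and tree randomness.
    class_weight: optional sklearn class-weight spec (e.g. "balanced");
        no imbalance correction by default.
    """

    mss: int = 100
    max_features_per_tree: int = 7
    n_trees: int = 100
    seed: int = 0
    class_weight: str | None = None

    def __post_init__(self) -> None:
        if self.mss < 2:
            raise ParameterError(f"mss must be >= 2, got {self.mss}")
        if self.max_features_per_tree < 1:
            raise ParameterError(
                f"max_features_per_tree must be >= 1, got "
                f"{self.max_features_per_tree}"
            )
        if self.n_trees < 1:
            raise ParameterError(f"n_trees must be >= 1, got {self.n_trees}")


@dataclass
class TrainedModel:
    """A fitted ensemble plus the settings needed to apply it.

    ``feature_subsets[t]`` lists the window positions tree ``t`` sees;
    ``constant`` short-circuits prediction for degenerate single-class
    training data. Prediction depends only on profile frequencies, never on
    residue identity.
    """

    config: ModelConfig
    w: int
    k: int
    feature_subsets: list[np.ndarray] = field(default_factory=list)
    trees: list[DecisionTreeClassifier] = field(default_factory=list)
    constant: bool | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return 2 * self.w + 1


def _stack_blocks(
    blocks: Sequence[InstanceBlock],
) -> tuple[np.ndarray, np.ndarray, int]:
    if not blocks:
        raise InputError("no instance blocks to train on")
    width = blocks[0].width
    for block in blocks:
        if block.width != width:
            raise InputError(
                f"mismatched feature widths across blocks: "
                f"{block.width} != {width}"
            )
        if block.labels is None:
            raise InputError(
                f"block for {block.seq_id!r} has no labels; run "
                "label_instances first"
            )
    X = np.vstack([b.rows for b in blocks])
    y = np.concatenate([b.labels for b in blocks])
    return X, y, width


def train(
    blocks: Sequence[InstanceBlock],
    config: ModelConfig = ModelConfig(),
    *,
    k: int = 6,
) -> TrainedModel:
    """Fit the ensemble on labeled instance blocks.

    Reproducible for a fixed (data, config, seed). With only one class
    present the model degenerates to a constant predictor (logged warning).
    """
    X, y, width = _stack_blocks(blocks)
    w = (width - 1) // 2
    if config.max_features_per_tree > width:
        raise ParameterError(
            f"max_features_per_tree={config.max_features_per_tree} exceeds "
            f"feature width {width}"
        )
    metadata = {
        "n_instances": int(X.shape[0]),
        "positive_fraction": float(y.mean()),
        "impurity": "gini",
        "sklearn_version": sklearn.__version__,
    }
    classes = np.unique(y)
    if len(classes) < 2:
        only = bool(classes[0])
        logger.warning(
            "degenerate training data: single class %r; model predicts it "
            "everywhere",
            only,
        )
        return TrainedModel(
            config=config, w=w, k=k, constant=only, metadata=metadata
        )
    rng = np.random.default_rng(config.seed)
    subsets: list[np.ndarray] = []
    trees: list[DecisionTreeClassifier] = []
    for _ in range(config.n_trees):
        subset = np.sort(
            rng.choice(width, size=config.max_features_per_tree, replace=False)
        )
        tree = DecisionTreeClassifier(
            min_samples_split=config.mss,
            class_weight=config.class_weight,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[:, subset], y)
        subsets.append(subset)
        trees.append(tree)
    return TrainedModel(
        config=config,
        w=w,
        k=k,
        feature_subsets=subsets,
        trees=trees,
        metadata=metadata,
    )


def predict_indices(model: TrainedModel, block: InstanceBlock) -> np.ndarray:
    """Per-index boolean predictions by strict-majority vote.

    An exact tie (possible with an even tree count) resolves to
    non-conserved.
    """
    if block.width != model.width:
        raise InputError(
            f"feature width mismatch: block has {block.width}, model "
            f"expects {model.width} (w={model.w})"
        )
    if model.constant is not None:
        return np.full(block.n_rows, model.constant, dtype=bool)
    votes = np.zeros(block.n_rows, dtype=np.int64)
    for subset, tree in zip(model.feature_subsets, model.trees):
        votes += tree.predict(block.rows[:, subset]).astype(np.int64)
    # strict majority: votes_true > n_trees / 2, so ties go negative
    return votes * 2 > len(model.trees)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the model; the file embeds k, w, config and a format version."""
    payload = {
        "format_version": FORMAT_VERSION,
        "k": model.k,
        "w": model.w,
        "config": model.config,
        "feature_subsets": model.feature_subsets,
        "trees": model.trees,
        "constant": model.constant,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; prediction-identical."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelLoadError(f"{path}: cannot read model file: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelLoadError(f"{path}: not a nadda model file")
    version = payload["format_version"]
    if version != FORMAT_VERSION:
        raise ModelLoadError(
            f"{path}: unsupported model format version {version!r} "
            f"(expected {FORMAT_VERSION})"
        )
    return TrainedModel(
        config=payload["config"],
        w=payload["w"],
        k=payload["k"],
        feature_subsets=payload["feature_subsets"],
        trees=payload["trees"],
        constant=payload["constant"],
        metadata=payload["metadata"],
    )
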