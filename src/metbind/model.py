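"""Two-tier feed-forward classifier for metal-binding.

Tier 1 is a binary metal-binding classifier; tier 2 is one classifier
per ion that receives the tier-1 score as an extra input feature.  Each
tier is a fully connected network with two hidden ReLU layers whose
width equals the input dimension, dropout 0.2 during training, a
single sigmoid output, binary cross-entropy loss, and an RMSprop
optimizer (default learning rate 5e-6, selected by a geometric search
starting at 0.5 and dividing by 10).  The network is implemented
directly in numpy so that initialization, dropout and the update rule
are seeded and bit-reproducible; inference is deterministic.

Feature columns are standardized to zero mean / unit variance with
statistics estimated on the training set and stored in the model, so
blocks on very different natural scales (compositions vs. molecular
weights) enter the network comparably.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import FeatureSchema, KmerVocabulary, PropertyTable, featurize
from .structure_labeling import ION_ORDER

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1

#: Default decision cutoffs: tier-1 cutoff chosen at maximum F1, tier-2 at
#: the plain 0.5 convention; 0.9 marks high-confidence tier-2 calls.
DEFAULT_CUTOFF_TIER1 = 0.4
DEFAULT_CUTOFF_TIER2 = 0.5
HIGH_CONFIDENCE_TIER2 = 0.9


@dataclass
class MLPConfig:
    hidden_layers: int = 2
    hidden_width: int | None = None  # None -> track the input dimension
    dropout: float = 0.2
    learning_rate: float = 5e-6
    epochs: int = 1000
    batch_size: int | None = None  # None -> full batch if n<=512 else 32
    seed: int = 0
    rho: float = 0.9  # RMSprop decay
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.hidden_width is not None and self.hidden_width < 1:
            raise ValueError("hidden width must be >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(scores: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(scores, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class TierModel:
    """A trained single-output MLP with its scaler and training record."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MLPConfig
    feature_mean: np.ndarray
    feature_std: np.ndarray
    schema_digest: str = ""
    loss_curve: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout is a training-only device)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} features, got {X.shape[1]}"
            )
        h = (X - self.feature_mean) / self.feature_std
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < last:
                h = np.maximum(h, 0.0)
        return _sigmoid(h[:, 0])


def _init_layers(
    dims: Sequence[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _train_mlp(
    X: np.ndarray, y: np.ndarray, config: MLPConfig, schema_digest: str = ""
) -> TierModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n, d = X.shape
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-12] = 1.0
    Xs = (X - mean) / std

    width = config.hidden_width or d
    dims = [d] + [width] * config.hidden_layers + [1]
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_layers(dims, rng)
    cache_w = [np.zeros_like(W) for W in weights]
    cache_b = [np.zeros_like(b) for b in biases]

    batch = config.batch_size or (n if n <= 512 else 32)
    losses: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb = Xs[idx], y[idx]
            # forward with inverted dropout on hidden activations
            activations = [xb]
            masks = []
            h = xb
            for i in range(config.hidden_layers):
                h = np.maximum(h @ weights[i] + biases[i], 0.0)
                if config.dropout > 0:
                    mask = (rng.random(h.shape) >= config.dropout) / (
                        1.0 - config.dropout
                    )
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                activations.append(h)
            scores = _sigmoid(activations[-1] @ weights[-1] + biases[-1])[:, 0]
            # backward (mean BCE; d(loss)/d(logit) = (p - y)/m)
            m = len(idx)
            delta = ((scores - yb) / m)[:, None]
            grads_w = [np.zeros_like(W) for W in weights]
            grads_b = [np.zeros_like(b) for b in biases]
            grads_w[-1] = activations[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            back = delta @ weights[-1].T
            for i in range(config.hidden_layers - 1, -1, -1):
                if masks[i] is not None:
                    back = back * masks[i]
                pre = activations[i] @ weights[i] + biases[i]
                back = back * (pre > 0)
                grads_w[i] = activations[i].T @ back
                grads_b[i] = back.sum(axis=0)
                if i > 0:
                    back = back @ weights[i].T
            for i in range(len(weights)):
                cache_w[i] = config.rho * cache_w[i] + (1 - config.rho) * grads_w[i] ** 2
                cache_b[i] = config.rho * cache_b[i] + (1 - config.rho) * grads_b[i] ** 2
                weights[i] -= (
                    config.learning_rate * grads_w[i] / (np.sqrt(cache_w[i]) + config.eps)
                )
                biases[i] -= (
                    config.learning_rate * grads_b[i] / (np.sqrt(cache_b[i]) + config.eps)
                )
        # epoch loss without dropout
        h = Xs
        for i in range(config.hidden_layers):
            h = np.maximum(h @ weights[i] + biases[i], 0.0)
        losses.append(_bce(_sigmoid(h @ weights[-1] + biases[-1])[:, 0], y))

    return TierModel(
        weights=weights,
        biases=biases,
        config=config,
        feature_mean=mean,
        feature_std=std,
        schema_digest=schema_digest,
        loss_curve=losses,
    )


# ---------------------------------------------------------------------------
# Learning-rate search


def lr_candidates(start: float = 0.5, factor: float = 10.0,
                  floor: float = 5e-7) -> list[float]:
    """Geometric candidate schedule: start, start/factor, ... down to the
    last value >= floor."""
    out = []
    lr = start
    while lr >= floor * (1 - 1e-12):
        out.append(lr)
        lr /= factor
    return out


def lr_search(
    X: np.ndarray,
    y: np.ndarray,
    config: MLPConfig,
    start: float = 0.5,
    factor: float = 10.0,
    floor: float = 5e-7,
) -> float:
    """Pick the learning rate minimizing final training BCE.

    One short run per candidate (length set by ``config.epochs``); all
    runs share the config seed, so the selection is deterministic.  Ties
    go to the first (largest) candidate.
    """
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("lr search needs both classes present")
    best_lr, best_loss = None, np.inf
    for lr in lr_candidates(start, factor, floor):
        cfg = MLPConfig(**{**asdict(config), "learning_rate": lr})
        model = _train_mlp(X, y, cfg)
        final = model.loss_curve[-1]
        logger.debug("lr %.1e -> final loss %.5f", lr, final)
        if final < best_loss:
            best_lr, best_loss = lr, final
    return float(best_lr)


# ---------------------------------------------------------------------------
# Tier training


def train_tier1(
    X: np.ndarray, y: np.ndarray, config: MLPConfig, schema_digest: str = ""
) -> TierModel:
    """Train the binary metal-binding network on base features."""
    return _train_mlp(X, y, config, schema_digest)


def train_tier2(
    X: np.ndarray,
    tier1_scores: np.ndarray,
    ion_labels: Mapping[str, np.ndarray],
    config: MLPConfig,
    min_positives: int = 2,
    balance: bool = True,
) -> dict[str, TierModel]:
    """Train one per-ion network on features + tier-1 score.

    For each ion, positives are that ion's binders and negatives are all
    remaining sequences (metal-binding or not); negatives are
    down-sampled to the positive count when ``balance`` is set.  Ions
    with fewer than ``min_positives`` positives are skipped with a
    warning (too few structures to support a model).
    """
    Xp = np.hstack([np.asarray(X, dtype=float),
                    np.asarray(tier1_scores, dtype=float).reshape(-1, 1)])
    models: dict[str, TierModel] = {}
    for ion, labels in ion_labels.items():
        labels = np.asarray(labels, dtype=bool).ravel()
        n_pos = int(labels.sum())
        if n_pos < min_positives or n_pos == len(labels):
            logger.warning("ion %s: %d positives; tier-2 model skipped", ion, n_pos)
            continue
        idx = np.arange(len(labels))
        if balance:
            rng = np.random.default_rng(config.seed + 1)
            neg_idx = idx[~labels]
            keep = rng.choice(neg_idx, size=min(n_pos, len(neg_idx)), replace=False)
            idx = np.sort(np.concatenate([idx[labels], keep]))
        models[ion] = _train_mlp(Xp[idx], labels[idx].astype(float), config)
    return models


# ---------------------------------------------------------------------------
# Bundle and prediction


@dataclass
class PredictionResult:
    sequence_id: str
    tier1_score: float
    tier1_call: bool
    ion_scores: dict[str, float] = field(default_factory=dict)
    ion_calls: dict[str, bool] = field(default_factory=dict)


@dataclass
class ModelBundle:
    """Everything needed to score new sequences, serialized as one file."""

    tier1: TierModel
    tier2: dict[str, TierModel]
    vocab: KmerVocabulary
    schema: FeatureSchema
    property_table: PropertyTable
    cutoff_tier1: float = DEFAULT_CUTOFF_TIER1
    cutoff_tier2: float = DEFAULT_CUTOFF_TIER2
    high_confidence_tier2: float = HIGH_CONFIDENCE_TIER2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        d = self.schema.dimension
        if self.tier1.input_dim != d:
            raise ValueError(
                f"tier-1 input dimension {self.tier1.input_dim} != schema {d}"
            )
        for ion, model in self.tier2.items():
            if model.input_dim != d + 1:
                raise ValueError(
                    f"tier-2 model for {ion} has input dimension "
                    f"{model.input_dim}, expected {d + 1}"
                )

    # -- serialization ------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "cutoff_tier1": self.cutoff_tier1,
            "cutoff_tier2": self.cutoff_tier2,
            "high_confidence_tier2": self.high_confidence_tier2,
            "schema": {
                "physchem_names": list(self.schema.physchem_names),
                "ions": list(self.schema.ions),
            },
            "vocab": {
                "k": self.vocab.k,
                "provenance": self.vocab.provenance,
                "per_ion": {i: sorted(v) for i, v in self.vocab.per_ion.items()},
            },
            "property_table": self.property_table.to_dict(),
            "tier1": _tier_meta(self.tier1),
            "tier2": {ion: _tier_meta(m) for ion, m in self.tier2.items()},
        }
        arrays: dict[str, np.ndarray] = {}
        _tier_arrays("tier1", self.tier1, arrays)
        for ion, model in self.tier2.items():
            _tier_arrays(f"tier2_{ion}", model, arrays)
        buffer = io.BytesIO()
        np.savez(buffer, **arrays)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=1))
            zf.writestr("weights.npz", buffer.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with zf.open("weights.npz") as handle:
                arrays = dict(np.load(io.BytesIO(handle.read())))
        if meta["format_version"] != BUNDLE_FORMAT_VERSION:
            raise ValueError(f"unsupported bundle version {meta['format_version']}")
        vocab = KmerVocabulary(
            k=meta["vocab"]["k"],
            per_ion={i: frozenset(v) for i, v in meta["vocab"]["per_ion"].items()},
            provenance=meta["vocab"].get("provenance", ""),
        )
        schema = FeatureSchema(
            physchem_names=tuple(meta["schema"]["physchem_names"]),
            ions=tuple(meta["schema"]["ions"]),
        )
        table = PropertyTable(properties=meta["property_table"])
        tier1 = _tier_from(meta["tier1"], "tier1", arrays)
        tier2 = {
            ion: _tier_from(m, f"tier2_{ion}", arrays)
            for ion, m in meta["tier2"].items()
        }
        return cls(
            tier1=tier1,
            tier2=tier2,
            vocab=vocab,
            schema=schema,
            property_table=table,
            cutoff_tier1=meta["cutoff_tier1"],
            cutoff_tier2=meta["cutoff_tier2"],
            high_confidence_tier2=meta["high_confidence_tier2"],
        )


def _tier_meta(model: TierModel) -> dict:
    return {
        "n_layers": len(model.weights),
        "config": asdict(model.config),
        "schema_digest": model.schema_digest,
        "loss_curve": model.loss_curve,
    }


def _tier_arrays(prefix: str, model: TierModel, out: dict[str, np.ndarray]) -> None:
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        out[f"{prefix}_W{i}"] = W
        out[f"{prefix}_b{i}"] = b
    out[f"{prefix}_mean"] = model.feature_mean
    out[f"{prefix}_std"] = model.feature_std


def _tier_from(meta: dict, prefix: str, arrays: Mapping[str, np.ndarray]) -> TierModel:
    n = meta["n_layers"]
    return TierModel(
        weights=[arrays[f"{prefix}_W{i}"] for i in range(n)],
        biases=[arrays[f"{prefix}_b{i}"] for i in range(n)],
        config=MLPConfig(**meta["config"]),
        feature_mean=arrays[f"{prefix}_mean"],
        feature_std=arrays[f"{prefix}_std"],
        schema_digest=meta.get("schema_digest", ""),
        loss_curve=list(meta.get("loss_curve", [])),
    )


def predict(
    seqs: Iterable[tuple[str, str]],
    bundle: ModelBundle,
    cutoff_tier1: float | None = None,
    cutoff_tier2: float | None = None,
) -> list[PredictionResult]:
    """Score sequences with both tiers.

    Calls use the >= convention at each tier's cutoff; the tiers are
    reported independently (they may disagree).  Sequences without a
    single canonical residue are skipped with a warning.
    """
    c1 = bundle.cutoff_tier1 if cutoff_tier1 is None else cutoff_tier1
    c2 = bundle.cutoff_tier2 if cutoff_tier2 is None else cutoff_tier2
    results: list[PredictionResult] = []
    for rid, seq in seqs:
        try:
            vec = featurize(seq, bundle.schema, bundle.vocab, bundle.property_table)
        except ValueError as exc:
            logger.warning("sequence %s skipped: %s", rid, exc)
            continue
        s1 = float(bundle.tier1.predict_scores(vec)[0])
        extended = np.append(vec, s1)
        ion_scores = {
            ion: float(model.predict_scores(extended)[0])
            for ion, model in bundle.tier2.items()
        }
        results.append(
            PredictionResult(
                sequence_id=rid,
                tier1_score=s1,
                tier1_call=s1 >= c1,
                ion_scores=ion_scores,
                ion_calls={ion: s >= c2 for ion, s in ion_scores.items()},
            )
        )
    return results


def predictions_to_rows(results: Sequence[PredictionResult]) -> list[dict]:
    """Flatten results for TSV export (one score+call column pair per ion)."""
    ions = sorted({ion for r in results for ion in r.ion_scores},
                  key=lambda i: (ION_ORDER.index(i) if i in ION_ORDER else 99, i))
    rows = []
    for r in results:
        row: dict = {
            "id": r.sequence_id,
            "tier1_score": r.tier1_score,
            "tier1_call": int(r.tier1_call),
        }
        for ion in ions:
            row[f"{ion}_score"] = r.ion_scores.get(ion, "")
            call = r.ion_calls.get(ion)
            row[f"{ion}_call"] = "" if call is None else int(call)
        rows.append(row)
    return rows
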