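"""Training, evaluation and cross-validation of the fusion risk model.

The training loop optimizes the negative Cox log partial likelihood with
Adam ("momentum 0.99" read as Adam's beta1; beta2 at its conventional 0.999)
for a fixed number of epochs — the stopping criterion is simply the last
epoch.  Mini-batches use the batch as the Cox risk set, a standard
approximation to the full-cohort partial likelihood; shuffling is
event-stratified so every batch almost surely contains an event and thus an
informative loss term.  The per-batch loss is divided by the number of
events in the batch so the gradient scale does not depend on batch size.

The full-scale profile trains at input resolution 256 with patch size 8,
lr 1e-4, weight decay 5e-3, batch 64, 100 epochs.  A desk profile (resolution
64, patch 4, width 32, lr 1e-3, batch 50, 30 epochs) ships for CPU-scale
experiments and is what the test suite and the reproduction script use.

Evaluation reports risks, the concordance index (and the event-masked
variant, since feeding the event scalar to the model is a leakage concern),
the quantile-scheme cutoff (derived on the training cohort by default),
Kaplan-Meier curves per stratum, and the two-sided log-rank test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import survival_stats as ss
from .cohort import make_folds
from .embedding import AugmentationSpec, EmbeddedMap, augment, prepare_model_input
from .fusion_model import Adam, DualGlobalFusionModel, ModelConfig, desk_model_config
from .survival_stats import SurvivalRecord, records_to_arrays


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the full-scale profile)."""

    learning_rate: float = 1e-4
    weight_decay: float = 5e-3
    beta1: float = 0.99
    beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0
    input_resolution: int = 256
    normalization: str = "log1p"
    augmentation: AugmentationSpec | None = None
    dtype: str = "float32"  # training compute precision

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.input_resolution) <= 0 or self.epochs < 0:
            raise ValueError("invalid training configuration")


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """CPU-scale profile matching :func:`desk_model_config`."""
    defaults = dict(
        learning_rate=1e-3, beta1=0.9, batch_size=50, epochs=30, input_resolution=64, seed=seed
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


@dataclass
class SurvivalDataset:
    """Model-ready inputs paired with outcomes."""

    inputs: np.ndarray  # (N, 3, R, R), normalized
    mu: np.ndarray  # (N,)
    times: np.ndarray  # (N,)
    events: np.ndarray  # (N,)
    patient_ids: list[str]

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, indices) -> "SurvivalDataset":
        idx = np.asarray(indices)
        return SurvivalDataset(
            inputs=self.inputs[idx],
            mu=self.mu[idx],
            times=self.times[idx],
            events=self.events[idx],
            patient_ids=[self.patient_ids[i] for i in idx],
        )


def prepare_dataset(
    maps: Sequence[EmbeddedMap],
    records: Sequence[SurvivalRecord],
    resolution: int,
    normalization: str = "log1p",
) -> SurvivalDataset:
    """Resize + normalize maps and align them with survival records."""
    if len(maps) != len(records):
        raise ValueError("one map per survival record required")
    inputs = np.stack(
        [prepare_model_input(m, resolution, normalization) for m in maps]
    )
    times, events = records_to_arrays(records)
    return SurvivalDataset(
        inputs=inputs,
        mu=events.copy(),
        times=times,
        events=events,
        patient_ids=[r.patient_id for r in records],
    )


def _event_stratified_order(events: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffled index order with events spread evenly across batches."""
    ev = np.flatnonzero(events == 1)
    ce = np.flatnonzero(events == 0)
    rng.shuffle(ev)
    rng.shuffle(ce)
    order = np.concatenate([ev, ce])
    keys = np.concatenate(
        [
            (np.arange(len(ev)) + rng.random()) / max(len(ev), 1),
            (np.arange(len(ce)) + rng.random()) / max(len(ce), 1),
        ]
    )
    return order[np.argsort(keys, kind="stable")]


def train(
    dataset: SurvivalDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[DualGlobalFusionModel, dict]:
    """Fit the model for exactly ``epochs`` epochs; returns (model, manifest)."""
    if dataset.events.sum() == 0:
        raise ValueError("training data contains no events; the Cox loss is uninformative")
    model = DualGlobalFusionModel(
        replace(model_config, seed=train_config.seed, dtype=train_config.dtype)
    )
    opt = Adam(
        model.params,
        lr=train_config.learning_rate,
        beta1=train_config.beta1,
        beta2=train_config.beta2,
        weight_decay=train_config.weight_decay,
    )
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 7]))
    epoch_losses: list[float] = []
    for _ in range(train_config.epochs):
        order = _event_stratified_order(dataset.events, rng)
        total_loss, total_events = 0.0, 0.0
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            n_ev = float(dataset.events[idx].sum())
            if n_ev == 0:
                continue
            x = dataset.inputs[idx]
            if train_config.augmentation is not None:
                x = np.stack([augment(xi, train_config.augmentation, rng) for xi in x])
            risks, cache = model.forward(x, dataset.mu[idx], return_cache=True)
            loss, dr = ss.cox_loss_and_grad(risks, dataset.times[idx], dataset.events[idx])
            grads = model.backward(dr / n_ev, cache)
            opt.step(grads)
            total_loss += loss
            total_events += n_ev
        epoch_losses.append(total_loss / max(total_events, 1.0))
    manifest = {
        "model_config": asdict(model.config),
        "train_config": {
            k: (asdict(v) if isinstance(v, AugmentationSpec) else v)
            for k, v in asdict(train_config).items()
        },
        "seed": train_config.seed,
        "n_train": len(dataset),
        "n_events": int(dataset.events.sum()),
        "epoch_losses": epoch_losses,
    }
    return model, manifest


def evaluate(
    model: DualGlobalFusionModel,
    dataset: SurvivalDataset,
    cutoff: float | None = None,
    quantile_grid=ss.DEFAULT_QUANTILE_GRID,
) -> dict:
    """Risks, C-index (both event-input modes), stratification and KM curves.

    ``cutoff`` should normally be derived on the training cohort
    (:func:`survival_stats.optimal_quantile_cutoff`); when omitted it is
    derived on this dataset instead.
    """
    risks = model.predict(dataset.inputs, dataset.mu)
    masked_model = DualGlobalFusionModel(
        replace(model.config, mask_event=True), params=model.params
    )
    risks_masked = masked_model.predict(dataset.inputs, dataset.mu)
    cindex = ss.concordance_index(risks, dataset.times, dataset.events)
    cindex_masked = ss.concordance_index(risks_masked, dataset.times, dataset.events)
    if cutoff is None:
        cutoff = ss.optimal_quantile_cutoff(risks, dataset.times, dataset.events, quantile_grid)
    strat = ss.stratify(risks, cutoff, dataset.times, dataset.events)
    curves = {}
    for label in ("low", "high"):
        mask = strat.labels == label
        if mask.any():
            curves[label] = ss.km_estimate(dataset.times[mask], dataset.events[mask])
    return {
        "risks": risks,
        "risks_event_masked": risks_masked,
        "patient_ids": dataset.patient_ids,
        "cindex": cindex,
        "cindex_event_masked": cindex_masked,
        "cutoff": float(cutoff),
        "stratification": strat,
        "logrank_chi2": strat.logrank_chi2,
        "logrank_p": strat.p_value,
        "km_curves": curves,
    }


def crossvalidate(
    maps: Sequence[EmbeddedMap],
    records: Sequence[SurvivalRecord],
    k: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int = 0,
) -> dict:
    """k-fold cross-validation; per-fold metrics plus mean +/- SD summary.

    Folds come from the stratified cohort splitter; the risk cutoff is
    derived on each fold's training cohort and applied to its test cohort.
    """
    dataset = prepare_dataset(
        maps, records, train_config.input_resolution, train_config.normalization
    )
    times, events = dataset.times, dataset.events
    folds = make_folds(dataset.patient_ids, times, events, k=k, seed=seed)
    pos = {pid: i for i, pid in enumerate(dataset.patient_ids)}
    per_fold = []
    for fold in folds:
        tr = dataset.subset([pos[p] for p in fold.train_ids])
        te = dataset.subset([pos[p] for p in fold.test_ids])
        model, manifest = train(tr, model_config, replace(train_config, seed=train_config.seed + fold.fold_index))
        train_risks = model.predict(tr.inputs, tr.mu)
        cutoff = ss.optimal_quantile_cutoff(train_risks, tr.times, tr.events)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small test folds may split unevenly
            metrics = evaluate(model, te, cutoff=cutoff)
        per_fold.append(
            {
                "fold": fold.fold_index,
                "n_test": len(te),
                "cindex": metrics["cindex"],
                "cindex_event_masked": metrics["cindex_event_masked"],
                "logrank_chi2": metrics["logrank_chi2"],
                "logrank_p": metrics["logrank_p"],
                "cutoff": metrics["cutoff"],
                "final_train_loss": manifest["epoch_losses"][-1] if manifest["epoch_losses"] else None,
            }
        )
    table = pd.DataFrame(per_fold).set_index("fold")
    return {
        "per_fold": table,
        "mean_cindex": float(table["cindex"].mean()),
        "sd_cindex": float(table["cindex"].std(ddof=1)) if k > 1 else 0.0,
        "mean_cindex_event_masked": float(table["cindex_event_masked"].mean()),
    }


def project_features(
    model: DualGlobalFusionModel,
    dataset: SurvivalDataset,
    n_neighbors: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D UMAP of fused features, with and without the event coordinate.

    Exports both feature variants (lengths head_input_len and
    head_input_len - 1) for qualitative structure inspection; one row per
    patient.
    """
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")
    if len(dataset) <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} patients, got {len(dataset)}")
    import umap  # heavy import; deferred

    feats_with = model.features(dataset.inputs, dataset.mu)
    feats_without = feats_with[:, :-1]
    out = {"patient_id": dataset.patient_ids, "time": dataset.times, "event": dataset.events}
    for tag, feats in (("with_event", feats_with), ("without_event", feats_without)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2, random_state=seed)
            xy = reducer.fit_transform(feats)
        out[f"umap1_{tag}"] = xy[:, 0]
        out[f"umap2_{tag}"] = xy[:, 1]
    return pd.DataFrame(out)


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))
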