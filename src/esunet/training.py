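"""Training orchestration: splitting, scheduling, optimisation, evaluation.

The training loop mirrors the study conditions the architecture was designed
for: Adam with betas (0.9, 0.99), cosine-annealing learning rate with warm
restarts (1e-3 down to 1e-5, restart every 25 epochs), per-step augmentation
(mirror -> rotate -> region-specific scaling), and a deep-supervision loss
that averages the combined focal + DWD objective over all auxiliary heads.
Everything — splitting, augmentation, weight init — derives from one seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_sample
from .io import Sample
from .losses import LossConfig, total_loss, total_loss_grad
from .metrics import MetricsRecord, metrics_table, segmentation_metrics
from .network import ESUNet, NetworkConfig, build_network
from .nn import Adam

__all__ = [
    "TrainConfig",
    "split_cases",
    "lr_at",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class TrainConfig:
    """All knobs of one training run."""

    epochs: int = 100
    restart_period: int = 25
    lr_max: float = 1e-3
    lr_min: float = 1e-5
    adam_betas: tuple[float, float] = (0.9, 0.99)
    batch_size: int = 1
    val_fraction: float = 0.2
    seed: int = 0
    augment_enabled: bool = True
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    model: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if not self.lr_min < self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs % self.restart_period:
            raise ValueError("restart_period must divide epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


def split_cases(case_ids: list, val_fraction: float, seed: int) -> tuple[list, list]:
    """Random train/validation partition with a floor-based hold-out size.

    n_val = floor(val_fraction * n); the shuffle is deterministic under
    ``seed`` and the partitions are disjoint and exhaustive.  This floor rule
    yields (180, 44) from 224 cases, (16, 4) from 20 and (33, 8) from 41 at a
    20% fraction.
    """
    case_ids = list(case_ids)
    n = len(case_ids)
    if n == 0:
        raise ValueError("case list is empty")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    n_val = int(np.floor(val_fraction * n))
    if n_val == 0 or n_val == n:
        raise ValueError(
            f"val_fraction {val_fraction} with {n} cases gives a degenerate split"
        )
    perm = np.random.default_rng(seed).permutation(n)
    val = [case_ids[i] for i in perm[:n_val]]
    tr = [case_ids[i] for i in perm[n_val:]]
    return tr, val


def lr_at(step_epoch: float, cfg: TrainConfig) -> float:
    """Cosine-annealing learning rate with warm restarts.

    lr(t) = lr_min + (lr_max - lr_min)/2 * (1 + cos(pi * (t mod T) / T))
    with T the restart period; the rate is lr_max at every restart boundary
    and approaches lr_min at the end of each cycle.
    """
    t = float(step_epoch) % cfg.restart_period
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * (
        1.0 + np.cos(np.pi * t / cfg.restart_period)
    )


def _deep_supervision_loss(label: np.ndarray, heads: dict[int, np.ndarray],
                           cfg: LossConfig) -> tuple[float, dict[int, np.ndarray]]:
    """Mean combined loss over heads, plus the per-head probability gradients."""
    n = len(heads)
    losses = {j: total_loss(label, p, cfg) for j, p in heads.items()}
    grads = {j: total_loss_grad(label, heads[j], cfg) / n for j in heads}
    return float(np.mean(list(losses.values()))), grads


def train(
    cfg: TrainConfig,
    cases: list[Sample],
    train_ids: list[int] | None = None,
    val_ids: list[int] | None = None,
    log_fn=None,
) -> tuple[ESUNet, pd.DataFrame]:
    """Train an ES-UNet on a list of in-memory cases.

    By default the cases are partitioned with :func:`split_cases`; explicit
    index lists override that (the memorisation regime passes the same single
    case as train and validation).  Returns the model restored to its
    best-validation-DSC weights and a per-epoch history frame.
    """
    if train_ids is None or val_ids is None:
        train_ids, val_ids = split_cases(list(range(len(cases))), cfg.val_fraction, cfg.seed)
    if len(train_ids) == 0:
        raise ValueError("empty training split")

    model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed)
    net = build_network(model_cfg)
    opt = Adam(net.params(), betas=cfg.adam_betas)
    rng = np.random.default_rng([cfg.seed, 1])

    history: list[dict] = []
    best = {"dsc": -1.0, "weights": None, "epoch": -1}
    steps_per_epoch = max(1, int(np.ceil(len(train_ids) / cfg.batch_size)))

    for epoch in range(cfg.epochs):
        net.set_training(True)
        order = rng.permutation(len(train_ids))
        epoch_losses = []
        for step in range(steps_per_epoch):
            batch = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            if batch.size == 0:
                continue
            lr = lr_at(epoch + step / steps_per_epoch, cfg)
            net.zero_grad()
            batch_loss = 0.0
            for bi in batch:
                sample = cases[train_ids[bi]]
                if cfg.augment_enabled:
                    sample = augment_sample(sample, cfg.augment, rng)
                fused, heads = net.forward(sample.image)
                loss, grads = _deep_supervision_loss(sample.label, heads, cfg.loss)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, case {train_ids[bi]}: {loss}"
                    )
                for j in grads:
                    grads[j] = grads[j] / batch.size
                net.backward(grads)
                batch_loss += loss / batch.size
            opt.step(lr)
            epoch_losses.append(batch_loss)

        val_recs = []
        net.set_training(False)
        for vi in val_ids:
            mask = net.predict_mask(cases[vi].image)
            val_recs.append(segmentation_metrics(mask, cases[vi].label))
        row = {
            "epoch": epoch,
            "lr": lr_at(epoch, cfg),
            "train_loss": float(np.mean(epoch_losses)),
            "val_dsc": float(np.mean([r.dsc for r in val_recs])),
            "val_iou": float(np.mean([r.iou for r in val_recs])),
            "val_voe": float(np.mean([r.voe for r in val_recs])),
        }
        history.append(row)
        if log_fn:
            log_fn(row)
        if row["val_dsc"] > best["dsc"]:
            best = {
                "dsc": row["val_dsc"],
                "weights": [p.value.copy() for p in net.params()],
                "buffers": [b.copy() for b in net.buffers()],
                "epoch": epoch,
            }

    if best["weights"] is not None:
        for p, w in zip(net.params(), best["weights"]):
            p.value[...] = w
        for b, w in zip(net.buffers(), best["buffers"]):
            b[...] = w
    return net, pd.DataFrame(history)


def evaluate(net: ESUNet, cases: list[Sample]) -> pd.DataFrame:
    """Per-case whole-volume evaluation (no patching, no test-time augmentation).

    Each case is pushed through the network in evaluation mode, the fused
    probability map is thresholded (probability >= threshold is foreground)
    and DSC/IoU/VOE are computed against the reference; per-case failures are
    reported as rows with NaN metrics and the run continues.
    """
    if not cases:
        raise ValueError("empty evaluation manifest")
    rows: list[tuple[str, MetricsRecord]] = []
    failures = []
    for sample in cases:
        cid = sample.meta.get("case_id", "?")
        try:
            mask = net.predict_mask(sample.image)
            rows.append((cid, segmentation_metrics(mask, sample.label)))
        except (ValueError, RuntimeError) as exc:
            failures.append({"case_id": cid, "error": str(exc)})
    table = metrics_table(rows)
    if failures:
        table = pd.concat(
            [table, pd.DataFrame([{**f, "dsc": np.nan} for f in failures])],
            ignore_index=True,
        )
    return table


def save_checkpoint(path: str | Path, net: ESUNet, train_cfg: TrainConfig | None = None,
                    extra: dict | None = None) -> None:
    """Persist weights + architecture config (npz alongside a json sidecar)."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(net.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(net.buffers())})
    np.savez_compressed(path, **arrays)
    meta = {
        "model": net.cfg.to_dict(),
        "train": _cfg_to_jsonable(train_cfg) if train_cfg else None,
        "extra": extra or {},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> ESUNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    net = build_network(NetworkConfig(**meta["model"]))
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"p{i}"]
        for i, b in enumerate(net.buffers()):
            if f"b{i}" in data:
                b[...] = data[f"b{i}"]
    net.set_training(False)
    return net


def _cfg_to_jsonable(cfg) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [conv(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return conv(cfg)
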