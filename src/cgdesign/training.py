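"""Training loop: cross-entropy loss, residue-budget batching, AdamW with a
one-cycle learning-rate schedule, and optional Gaussian coordinate-noise
augmentation.

A "batch" is a set of structures whose lengths sum to at most the residue
budget (default 4096). No operation in the network crosses structure
boundaries, so the batch is processed one graph at a time with gradient
accumulation; the accumulated gradient equals the gradient of the
residue-weighted mean loss over the batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, softmax
from .model import CgnnModel, EncodedStructure
from .structures import BackboneStructure
from .synthetic import perturb


def cross_entropy_value(logits: np.ndarray, labels: np.ndarray) -> float:
    """Float64 mean cross-entropy of class ``labels`` under row ``logits``.

    Used for logging so that exp(training loss) agrees exactly with the
    evaluation module's perplexity on the same predictions.
    """
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(labels)), labels].mean())


def sequence_loss(logits: Tensor | np.ndarray, labels: np.ndarray,
                  mask: np.ndarray | None = None) -> Tensor:
    """Mean categorical cross-entropy (natural log, no label smoothing).

    ``logits`` has one row per residue; ``labels`` are class indices;
    rows where ``mask`` is False (or the label is negative) are excluded.
    """
    logits = Tensor.as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    keep = labels >= 0
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("loss is undefined: no unmasked labeled residues")
    rows = logits.gather(idx)
    probs = softmax(rows, axis=-1)
    onehot = np.zeros((idx.size, logits.shape[-1]))
    onehot[np.arange(idx.size), labels[idx]] = 1.0
    picked = (probs * onehot).sum(axis=-1)
    return -(picked.log().mean())


def make_batches(lengths: list[int], budget: int = 4096,
                 seed: int = 0) -> list[list[int]]:
    """Randomly permute structure indices and greedily pack them into
    batches whose residue counts sum to at most ``budget``."""
    for length in lengths:
        if length > budget:
            raise ValueError(
                f"structure of {length} residues exceeds the batch budget "
                f"{budget}; increase the budget")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(lengths))
    batches: list[list[int]] = []
    current: list[int] = []
    used = 0
    for idx in order:
        n = lengths[idx]
        if current and used + n > budget:
            batches.append(current)
            current, used = [], 0
        current.append(int(idx))
        used += n
    if current:
        batches.append(current)
    return batches


def onecycle_lr(step: int, total_steps: int, max_lr: float,
                pct_start: float = 0.3, div_factor: float = 25.0,
                final_div_factor: float = 1e4) -> float:
    """Cosine-annealed one-cycle schedule peaking at ``max_lr``."""
    initial = max_lr / div_factor
    final = initial / final_div_factor
    warm = max(int(round(pct_start * total_steps)), 1)
    if step < warm:
        frac = step / warm
        return initial + (max_lr - initial) * 0.5 * (1 - math.cos(math.pi * frac))
    frac = (step - warm) / max(total_steps - warm, 1)
    frac = min(frac, 1.0)
    return final + (max_lr - final) * 0.5 * (1 + math.cos(math.pi * frac))


class AdamW:
    """Decoupled-weight-decay Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


@dataclass
class TrainConfig:
    epochs: int = 100
    max_lr: float = 0.004
    batch_budget: int = 4096
    weight_decay: float = 0.01
    grad_clip: float | None = None
    noise_sd: float = 0.0  # per-epoch Gaussian coordinate noise, Angstroms
    seed: int = 0
    pct_start: float = 0.3
    div_factor: float = 25.0
    final_div_factor: float = 1e4


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    accuracy: float
    lr: float


@dataclass
class TrainResult:
    model: CgnnModel
    log: list[EpochRecord] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def final_loss(self) -> float:
        return self.log[-1].loss


def train(model: CgnnModel, dataset: list[BackboneStructure],
          config: TrainConfig, verbose: bool = False) -> TrainResult:
    """Fit ``model`` to the native sequences of ``dataset``.

    Returns the trained model plus one structured record per epoch with the
    mean training loss, token accuracy and the learning rate at epoch end.
    """
    for s in dataset:
        if s.native_seq is None:
            raise ValueError(f"structure {s.name} has no native sequence")
    lengths = [s.length for s in dataset]
    rng = np.random.default_rng(config.seed)
    steps_per_epoch = len(make_batches(lengths, config.batch_budget, seed=0))
    total_steps = config.epochs * steps_per_epoch
    optimizer = AdamW(model.parameters(), weight_decay=config.weight_decay)

    cache: dict[int, EncodedStructure] = {}
    if config.noise_sd == 0:
        for i, s in enumerate(dataset):
            cache[i] = model.encode_structure(s)

    log: list[EpochRecord] = []
    step = 0
    for epoch in range(config.epochs):
        batches = make_batches(lengths, config.batch_budget,
                               seed=config.seed + epoch)
        epoch_loss = 0.0
        epoch_correct = 0
        epoch_count = 0
        lr = optimizer.lr
        for batch in batches:
            lr = onecycle_lr(step, total_steps, config.max_lr,
                             config.pct_start, config.div_factor,
                             config.final_div_factor)
            optimizer.lr = lr
            optimizer.zero_grad()
            encs = []
            for i in batch:
                if i in cache:
                    encs.append(cache[i])
                else:
                    noisy = perturb(dataset[i], config.noise_sd,
                                    seed=int(rng.integers(2 ** 31)))
                    noisy.native_seq = dataset[i].native_seq
                    encs.append(model.encode_structure(noisy))
            batch_labels = sum(e.labels.size for e in encs)
            batch_loss = 0.0
            for enc in encs:
                logits = model.forward_encoded(enc, rng=rng, training=True)
                loss = sequence_loss(logits, enc.labels)
                weight = enc.labels.size / batch_labels
                (loss * weight).backward()
                batch_loss += (cross_entropy_value(logits.data, enc.labels)
                               * enc.labels.size)
                pred = np.argmax(logits.data, axis=1)
                epoch_correct += int(np.sum(pred == enc.labels))
                epoch_count += enc.labels.size
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}, lr {lr:g}")
            if config.grad_clip is not None:
                total_norm = math.sqrt(sum(
                    float(np.sum(p.grad ** 2)) for p in model.parameters()
                    if p.grad is not None))
                if total_norm > config.grad_clip:
                    scale = config.grad_clip / (total_norm + 1e-12)
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            optimizer.step()
            epoch_loss += batch_loss
            step += 1
        record = EpochRecord(
            epoch=epoch,
            loss=epoch_loss / max(epoch_count, 1),
            accuracy=epoch_correct / max(epoch_count, 1),
            lr=lr,
        )
        log.append(record)
        if verbose:
            print(f"epoch {epoch:4d}  loss {record.loss:.4f}  "
                  f"acc {record.accuracy:.3f}  lr {record.lr:.2e}")
    return TrainResult(model=model, log=log,
                       config_echo={"train": asdict(config),
                                    "model": asdict(model.config)})
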