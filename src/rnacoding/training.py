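"""Training objectives, batching and the training loop.

Four tasks share one architecture:

``seq``
    Full sequence-to-sequence: class token then the protein, all output
    positions weighted uniformly (mean cross-entropy).
``seq_wt``
    Position-weighted variant: per-position cross-entropies are combined
    with a truncated discrete exponential pmf
    ``p(i, lam) = (1 - e^-lam) e^(-lam i) / (1 - e^(-lam N))``.
    As lam -> 0 the weights become uniform (recovering ``seq``); as
    lam -> inf all weight falls on the leading class token (recovering
    ``class``).
``class``
    Cross-entropy on the single leading classification token.
``start``
    Pointer-network cross-entropy on the start-codon position (last
    position for noncoding records).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from . import model as M
from .sequences import Transcript

logger = logging.getLogger(__name__)

TASKS = ("seq", "seq_wt", "class", "start")


@dataclass
class ObjectiveConfig:
    task: str = "seq_wt"
    lam: float = 0.1  #: decay rate of the positional weighting (seq_wt only)
    label_smoothing: float = 0.0
    max_protein_len: Optional[int] = None  #: truncate seq targets (scaled-down training)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


@dataclass
class BatchPlan:
    max_tokens_per_batch: int = 9000
    gradient_accumulation_steps: int = 8


@dataclass
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 3e-3
    seed: int = 0
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    eval_every: int = 1  #: validate every k-th epoch (always on the last)


def position_weights(N: int, lam: float) -> np.ndarray:
    """Truncated discrete exponential pmf over output positions 0..N-1.

    Sums to one; strictly decreasing for lam > 0; uniform in the lam -> 0
    limit (returned exactly for lam == 0).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        return np.full(N, 1.0 / N)
    i = np.arange(N)
    # (1-e^-lam) e^(-lam i) / (1-e^(-lam N)); expm1 keeps tiny lam stable
    w = np.exp(-lam * i)
    return w * np.expm1(-lam) / np.expm1(-lam * N)


def sequence_loss(per_position_losses, objective: ObjectiveConfig):
    """Combine per-position cross-entropies according to the task.

    ``seq`` averages (uniform weights), ``seq_wt`` takes the pmf-weighted
    sum, ``class`` keeps only the first position.
    """
    losses = anp.asarray(per_position_losses) if not hasattr(per_position_losses, "shape") else per_position_losses
    N = losses.shape[-1]
    if objective.task == "class":
        return losses[..., 0]
    if objective.task == "seq":
        w = position_weights(N, 0.0)
    elif objective.task == "seq_wt":
        w = position_weights(N, objective.lam)
    else:
        raise ValueError(f"sequence_loss undefined for task {objective.task!r}")
    return anp.sum(losses * w, axis=-1)


def start_loss(pointer_distribution, true_index: int, eps: float = 1e-12):
    """Cross-entropy of the pointer distribution at the true start index."""
    return -anp.log(pointer_distribution[..., true_index] + eps)


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------


@dataclass
class Batch:
    x: np.ndarray          # (N, L, 4)
    mask: np.ndarray       # (N, L)
    dec_in: np.ndarray     # (N, T) int, starts with <sos>
    targets: np.ndarray    # (N, T) int, <pad> after each example's end
    target_weights: np.ndarray  # (N, T) float, pmf (or uniform) per example
    start_index: np.ndarray     # (N,) int pointer targets
    ids: list[str] = field(default_factory=list)


def _pointer_target(t: Transcript) -> int:
    if t.is_coding and t.cds is not None:
        return t.cds[0]
    return len(t) - 1


def make_batches(
    transcripts: Sequence[Transcript],
    objective: ObjectiveConfig,
    plan: BatchPlan,
    rng: Optional[np.random.RandomState] = None,
) -> list[Batch]:
    """Length-binned batches whose padded input token count respects the plan."""
    order = sorted(range(len(transcripts)), key=lambda i: len(transcripts[i]))
    groups: list[list[int]] = []
    current: list[int] = []
    for i in order:
        trial = current + [i]
        padded = max(len(transcripts[j]) for j in trial) * len(trial)
        if current and padded > plan.max_tokens_per_batch:
            groups.append(current)
            current = [i]
        else:
            current = trial
    if current:
        groups.append(current)
    if rng is not None:
        rng.shuffle(groups)

    batches = []
    for g in groups:
        items = [transcripts[i] for i in g]
        L = max(len(t) for t in items)
        toks = [M.target_tokens(t, objective.task, objective.max_protein_len) for t in items]
        T = max(len(tk) for tk in toks)
        N = len(items)
        x = np.zeros((N, L, 4))
        mask = np.zeros((N, L))
        dec_in = np.full((N, T), M.PAD, dtype=int)
        targets = np.full((N, T), M.PAD, dtype=int)
        weights = np.zeros((N, T))
        starts = np.zeros(N, dtype=int)
        for n, (t, tk) in enumerate(zip(items, toks)):
            x[n, : len(t)] = M.one_hot(t.sequence)
            mask[n, : len(t)] = 1.0
            dec_in[n, 0] = M.SOS
            dec_in[n, 1 : len(tk)] = tk[:-1]
            targets[n, : len(tk)] = tk
            if objective.task == "class":
                weights[n, 0] = 1.0
            elif objective.task == "seq":
                weights[n, : len(tk)] = position_weights(len(tk), 0.0)
            else:  # seq_wt (start task ignores weights)
                weights[n, : len(tk)] = position_weights(len(tk), objective.lam)
            starts[n] = _pointer_target(t)
        batches.append(
            Batch(x=x, mask=mask, dec_in=dec_in, targets=targets, target_weights=weights,
                  start_index=starts, ids=[t.id for t in items])
        )
    return batches


# ---------------------------------------------------------------------------
# Loss and loop
# ---------------------------------------------------------------------------


def _log_softmax(logits):
    m = anp.max(logits, axis=-1, keepdims=True)
    return logits - m - anp.log(anp.sum(anp.exp(logits - m), axis=-1, keepdims=True))


def batch_loss(params, batch: Batch, objective: ObjectiveConfig, config: M.ModelConfig):
    """Mean per-example objective over one batch (differentiable in params)."""
    H = M.encode(batch.x, params, config, batch.mask)
    if objective.task == "start":
        probs = M.pointer_forward(H, params, batch.mask)
        N = batch.x.shape[0]
        losses = -anp.log(probs[anp.arange(N), batch.start_index] + 1e-12)
        return anp.mean(losses)
    logits, _ = M.decode_tokens(batch.dec_in, H, params, config, batch.mask)
    lp = _log_softmax(logits)
    if objective.label_smoothing > 0:
        eps = objective.label_smoothing
        nll = -(1 - eps) * _gather(lp, batch.targets) - eps * anp.mean(lp, axis=-1)
    else:
        nll = -_gather(lp, batch.targets)
    per_example = anp.sum(nll * batch.target_weights, axis=-1)
    return anp.mean(per_example)


def _gather(lp, idx):
    N, T, V = lp.shape
    flat = anp.reshape(lp, (N * T, V))
    return anp.reshape(flat[anp.arange(N * T), idx.reshape(-1)], (N, T))


@dataclass
class TrainResult:
    params: dict
    config: M.ModelConfig
    objective: ObjectiveConfig
    history: list[dict]
    best_epoch: int


def evaluate_f1(params, config, objective, transcripts, max_tokens=9000) -> float:
    """Classification F1 (PC positive) using the task's inference mode."""
    from .inference import classify_batch, confusion_metrics

    mode = "pointer" if objective.task == "start" else "first_token"
    preds = classify_batch(params, config, transcripts, mode=mode, max_tokens=max_tokens)
    labels = [t.label for t in transcripts]
    return confusion_metrics([p.label for p in preds], labels)["F1"]


def train(
    transcripts: Sequence[Transcript],
    objective: ObjectiveConfig,
    config: M.ModelConfig,
    plan: Optional[BatchPlan] = None,
    train_config: Optional[TrainConfig] = None,
    validation: Optional[Sequence[Transcript]] = None,
    init: Optional[dict] = None,
    metrics_path=None,
) -> TrainResult:
    """Adam training loop; deterministic for a fixed seed on one device.

    The best checkpoint (by validation F1 when a validation set is given,
    else by training loss) is retained. Non-finite loss aborts.
    """
    plan = plan or BatchPlan()
    tc = train_config or TrainConfig()
    rng = np.random.RandomState(tc.seed)
    params = init if init is not None else M.init_params(config, seed=tc.seed)
    flat, unflatten = flatten(params)
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    b1, b2 = tc.adam_betas
    step = 0
    history: list[dict] = []
    best = (-np.inf, 0, flat.copy())

    loss_and_grad = value_and_grad(
        lambda p, b: batch_loss(p, b, objective, config)
    )

    accum = max(1, plan.gradient_accumulation_steps)
    for epoch in range(tc.epochs):
        batches = make_batches(transcripts, objective, plan, rng)
        epoch_losses = []
        g_acc = np.zeros_like(flat)
        n_acc = 0
        for bi, batch in enumerate(batches):
            loss, grads = loss_and_grad(unflatten(flat), batch)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {bi}"
                )
            epoch_losses.append(float(loss))
            gflat, _ = flatten(grads)
            g_acc = g_acc + gflat
            n_acc += 1
            if n_acc == accum or bi == len(batches) - 1:
                step += 1
                g = g_acc / n_acc
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1**step)
                vhat = v / (1 - b2**step)
                flat = flat - tc.learning_rate * mhat / (np.sqrt(vhat) + tc.adam_eps)
                g_acc = np.zeros_like(flat)
                n_acc = 0
        train_loss = float(np.mean(epoch_losses))
        row = {"epoch": epoch, "loss": train_loss, "val_F1": np.nan}
        do_eval = validation and (epoch % tc.eval_every == 0 or epoch == tc.epochs - 1)
        if do_eval:
            row["val_F1"] = evaluate_f1(unflatten(flat), config, objective, validation)
            score = row["val_F1"]
        elif validation:
            score = -np.inf  # not a selection point
        else:
            score = -train_loss
        if score > best[0]:
            best = (score, epoch, flat.copy())
        history.append(row)
        logger.info("epoch %d loss %.4f val_F1 %s", epoch, train_loss, row["val_F1"])

    if metrics_path is not None:
        with open(metrics_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "val_F1"])
            writer.writeheader()
            writer.writerows(history)

    return TrainResult(
        params=unflatten(best[2]),
        config=config,
        objective=objective,
        history=history,
        best_epoch=best[1],
    )
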