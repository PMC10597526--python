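"""Decoding and evaluation: classification modes, beam search, CDS detection, metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from . import model as M
from .sequences import OrfSpan, Transcript, find_orfs

logger = logging.getLogger(__name__)


@dataclass
class ClassificationResult:
    id: str
    label: str           # "PC" | "NC"
    S: float             # logit difference l_<PC> - l_<NC> (or log-odds for pointer mode)
    p_pc: float

    def __post_init__(self) -> None:
        assert self.label in ("PC", "NC")


@dataclass
class BeamHypothesis:
    tokens: list[int]        # generated output tokens (no <sos>)
    raw_log_prob: float
    normalized_score: float
    completed: bool

    def protein(self) -> str:
        toks = [t for t in self.tokens if t >= 5]
        return "".join(M.OUTPUT_TOKENS[t] for t in toks)

    @property
    def leading_class(self) -> Optional[str]:
        if self.tokens and self.tokens[0] in (M.TOK_PC, M.TOK_NC):
            return "PC" if self.tokens[0] == M.TOK_PC else "NC"
        return None


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def classify(params, config, transcript: Transcript, mode: str = "first_token") -> ClassificationResult:
    """Coding-potential call for one transcript.

    ``first_token`` reads the <PC>/<NC> logits at the first decode position
    (decoding halted after the class token). ``pointer`` sums the pointer
    distribution over all positions before the last; the argmax landing on
    the last position means noncoding.
    """
    return classify_batch(params, config, [transcript], mode=mode)[0]


def pointer_classification(probs: np.ndarray, transcript_id: str = "") -> ClassificationResult:
    """Classification read off a pointer distribution over L positions.

    p(PC) is the total mass before the last position; the argmax landing on
    the last position means noncoding.
    """
    p = np.asarray(probs, dtype=float)
    p_pc = float(np.sum(p[:-1]))
    label = "NC" if int(np.argmax(p)) == len(p) - 1 else "PC"
    s = float(np.log((p_pc + 1e-12) / (1 - p_pc + 1e-12)))
    return ClassificationResult(id=transcript_id, label=label, S=s, p_pc=p_pc)


def classify_batch(
    params, config, transcripts: Sequence[Transcript], mode: str = "first_token",
    max_tokens: int = 20000,
) -> list[ClassificationResult]:
    if mode not in ("first_token", "pointer"):
        raise ValueError(f"unknown classification mode {mode!r}")
    order = sorted(range(len(transcripts)), key=lambda i: len(transcripts[i]))
    results: dict[int, ClassificationResult] = {}
    group: list[int] = []

    def flush(idxs):
        if not idxs:
            return
        L = max(len(transcripts[i]) for i in idxs)
        x = np.zeros((len(idxs), L, 4))
        mask = np.zeros((len(idxs), L))
        for n, i in enumerate(idxs):
            t = transcripts[i]
            x[n, : len(t)] = M.one_hot(t.sequence)
            mask[n, : len(t)] = 1.0
        if mode == "first_token":
            logits = M.first_token_logits(x, params, config, mask)
            S = logits[:, M.TOK_PC] - logits[:, M.TOK_NC]
            for n, i in enumerate(idxs):
                s = float(S[n])
                results[i] = ClassificationResult(
                    id=transcripts[i].id, label="PC" if s > 0 else "NC", S=s, p_pc=_sigmoid(s)
                )
        else:
            H = M.encode(x, params, config, mask)
            probs = M.pointer_forward(H, params, mask)
            for n, i in enumerate(idxs):
                t = transcripts[i]
                results[i] = pointer_classification(probs[n, : len(t)], t.id)

    for i in order:
        trial = group + [i]
        if group and max(len(transcripts[j]) for j in trial) * len(trial) > max_tokens:
            flush(group)
            group = [i]
        else:
            group = trial
    flush(group)
    return [results[i] for i in range(len(transcripts))]


# ---------------------------------------------------------------------------
# Beam search
# ---------------------------------------------------------------------------


def beam_search(
    params,
    config,
    transcript: Transcript,
    beam_size: int = 4,
    alpha: float = 0.6,
    max_len: Optional[int] = None,
) -> list[BeamHypothesis]:
    """Length-normalised beam decoding; returns all final beams, ranked.

    ``normalized_score = raw_log_prob / len(tokens)**alpha`` (alpha = 0
    ranks by raw log probability). Class tokens are only legal at the first
    output position; <pad>/<sos> are never legal.
    """
    if beam_size < 1:
        raise ValueError("beam_size must be >= 1")
    max_len = max_len or config.max_decode_len
    x = M.one_hot(transcript.sequence)
    H = M.encode(x, params, config)
    log_probs_cache = {}

    def step_log_probs(prefix: tuple[int, ...]) -> np.ndarray:
        if prefix not in log_probs_cache:
            logits, _ = M.decode_step(np.array(prefix), H, params, config)
            m = logits - np.max(logits)
            log_probs_cache[prefix] = m - np.log(np.sum(np.exp(m)))
        return log_probs_cache[prefix]

    def legal_mask(t: int) -> np.ndarray:
        # output grammar: a class token first, then amino acids / <eos> only
        mask = np.zeros(M.V_OUT)
        mask[M.PAD] = -np.inf
        mask[M.SOS] = -np.inf
        if t == 0:
            mask[:] = -np.inf
            mask[M.TOK_PC] = 0.0
            mask[M.TOK_NC] = 0.0
        else:
            mask[M.TOK_PC] = -np.inf
            mask[M.TOK_NC] = -np.inf
        return mask

    live: list[tuple[tuple[int, ...], float]] = [((M.SOS,), 0.0)]
    done: list[BeamHypothesis] = []
    for t in range(max_len):
        candidates: list[tuple[tuple[int, ...], float]] = []
        for prefix, lp in live:
            step = step_log_probs(prefix) + legal_mask(t)
            top = np.argsort(step)[::-1][:beam_size]
            for tok in top:
                if not np.isfinite(step[tok]):
                    continue
                candidates.append((prefix + (int(tok),), lp + float(step[tok])))
        candidates.sort(key=lambda c: c[1], reverse=True)
        live = []
        for prefix, lp in candidates[: beam_size * 2]:
            if prefix[-1] == M.EOS or len(prefix) - 1 >= max_len:
                tokens = list(prefix[1:])
                n = max(len(tokens), 1)
                done.append(
                    BeamHypothesis(
                        tokens=tokens,
                        raw_log_prob=lp,
                        normalized_score=lp / (n**alpha) if alpha else lp,
                        completed=prefix[-1] == M.EOS,
                    )
                )
            elif len(live) < beam_size:
                live.append((prefix, lp))
        if not live or len(done) >= beam_size * 3:
            break
    for prefix, lp in live:
        tokens = list(prefix[1:])
        n = max(len(tokens), 1)
        done.append(
            BeamHypothesis(tokens=tokens, raw_log_prob=lp,
                           normalized_score=lp / (n**alpha) if alpha else lp, completed=False)
        )
    done.sort(key=lambda h: h.normalized_score, reverse=True)
    return done


def greedy_decode(params, config, transcript: Transcript, max_len: Optional[int] = None) -> BeamHypothesis:
    return beam_search(params, config, transcript, beam_size=1, alpha=0.0, max_len=max_len)[0]


# ---------------------------------------------------------------------------
# CDS detection by global alignment
# ---------------------------------------------------------------------------


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


def global_identity(a: str, b: str, match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0) -> float:
    """Needleman-Wunsch percent identity = matches / alignment length."""
    if not a or not b:
        return 0.0
    al = _aligner(match, mismatch, gap)
    alignment = al.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def cds_detect(
    predicted_protein: str,
    transcript: Transcript,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> Optional[tuple[OrfSpan, float, bool]]:
    """Best-matching ORF for a predicted protein by global alignment identity.

    Returns ``(best_orf, percent_identity, is_annotated_cds)``; None when
    the transcript has no ORF. Ties keep the longest, then 5'-most ORF
    (the order produced by :func:`find_orfs`).
    """
    orfs = find_orfs(transcript.sequence)
    if not orfs:
        return None
    best, best_ident = None, -1.0
    for orf in orfs:
        ident = global_identity(predicted_protein, orf.protein, match, mismatch, gap)
        if ident > best_ident:
            best, best_ident = orf, ident
    is_cds = transcript.cds is not None and (best.start, best.end) == transcript.cds
    return best, best_ident, is_cds


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------


def confusion_counts(predictions: Sequence[str], labels: Sequence[str]) -> tuple[int, int, int, int]:
    tp = sum(1 for p, l in zip(predictions, labels) if p == "PC" and l == "PC")
    tn = sum(1 for p, l in zip(predictions, labels) if p == "NC" and l == "NC")
    fp = sum(1 for p, l in zip(predictions, labels) if p == "PC" and l == "NC")
    fn = sum(1 for p, l in zip(predictions, labels) if p == "NC" and l == "PC")
    return tp, tn, fp, fn


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """F1/precision/recall/MCC with PC as positive class.

    MCC numerator is TP*TN - FP*FN (Matthews' definition); any zero factor
    in the denominator yields MCC = 0 by convention, and empty
    precision/recall denominators yield 0.
    """
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"F1": f1, "precision": precision, "recall": recall, "MCC": float(mcc)}


def confusion_metrics(predictions: Sequence[str], labels: Sequence[str]) -> dict[str, float]:
    return metrics_from_counts(*confusion_counts(predictions, labels))


def auprc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Area under the precision-recall curve (PC positive), by threshold integration."""
    from sklearn.metrics import auc, precision_recall_curve

    y = np.array([1 if l == "PC" else 0 for l in labels])
    precision, recall, _ = precision_recall_curve(y, np.asarray(scores, dtype=float))
    return float(auc(recall, precision))
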