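"""Mutation-effect prediction: saturated ISM and its gradient-based approximators.

The quantity approximated everywhere is ``delta S`` — the change in
``S = l_<PC> - l_<NC>`` (the classification logit difference at the first
decode position) between a single-nucleotide variant and its wild type.
Saturated in-silico mutagenesis (ISM) computes it exactly with 3L model
evaluations; the Taylor, uniform-baseline integrated-gradients and
mutation-directed integrated-gradients (MDIG) estimators trade accuracy for
one-to-four gradient passes.

Sign conventions
----------------
``integrated_gradients(dest, src)`` follows the standard definition
``IG_ik = (dest - src)_ik * mean_alpha dF(src + alpha (dest - src))/dx_ik``
(midpoint rule), satisfying completeness against ``F(dest) - F(src)``.

For the uniform-baseline pairing the displacement factor is divided out
before pairing (i.e. path-averaged gradients are paired, Taylor-style, with
a minus sign); this is the unique reading under which the minus-pairing
reduces to ISM exactly for a linear scorer. MDIG keeps the displacement
factor and pairs with a plus sign, which likewise reduces to ISM exactly at
beta = 1 on a linear scorer. :func:`sign_convention_diagnostic` reports
which pairing sign correlates better with ISM on a given model, surfacing
the ambiguity instead of hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import grad

from . import model as M
from .sequences import RNA_ALPHABET, Transcript

BASES = np.array(list(RNA_ALPHABET))


@dataclass
class MutationEffectMatrix:
    """L x 3 matrix of delta-S values, one per non-endogenous substitution.

    Column order at each position: the three alternate bases in A,C,G,U
    order with the endogenous base skipped.
    """

    values: np.ndarray
    sequence: str
    method: str
    beta: Optional[float] = None
    steps: Optional[int] = None
    model_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sequence), 3):
            raise ValueError("values must be (L, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite mutation effects")

    @property
    def L(self) -> int:
        return len(self.sequence)

    def alt_bases(self) -> np.ndarray:
        """(L, 3) array of the alternate base at each (position, column)."""
        out = np.empty((self.L, 3), dtype="<U1")
        for i, ref in enumerate(self.sequence):
            out[i] = [b for b in RNA_ALPHABET if b != ref]
        return out

    def to_dense(self) -> np.ndarray:
        """(L, 4) layout with zeros in the endogenous column."""
        dense = np.zeros((self.L, 4))
        alts = self.alt_bases()
        base_idx = {b: k for k, b in enumerate(RNA_ALPHABET)}
        for i in range(self.L):
            for c in range(3):
                dense[i, base_idx[alts[i, c]]] = self.values[i, c]
        return dense

    def to_table(self, transcript_id: str = ""):
        import pandas as pd

        alts = self.alt_bases()
        rows = []
        for i in range(self.L):
            for c in range(3):
                rows.append((transcript_id, i, self.sequence[i], alts[i, c], self.values[i, c]))
        return pd.DataFrame(rows, columns=["id", "position", "ref_base", "alt_base", "delta_S"])


def _pair_columns(dense: np.ndarray, sequence: str, sign: float = -1.0) -> np.ndarray:
    """Pair an (L, 4) per-character matrix into (L, 3) mutation effects.

    ``sign=-1`` computes ``dense_ib - dense_ij`` (Taylor/Eq-4 style);
    ``sign=+1`` computes ``dense_ib + dense_ij`` (the MDIG pairing).
    """
    L = len(sequence)
    base_idx = {b: k for k, b in enumerate(RNA_ALPHABET)}
    out = np.zeros((L, 3))
    for i, ref in enumerate(sequence):
        j = base_idx[ref]
        c = 0
        for k in range(4):
            if k == j:
                continue
            out[i, c] = dense[i, k] + sign * dense[i, j]
            c += 1
    return out


# ---------------------------------------------------------------------------
# Score functions
# ---------------------------------------------------------------------------


def make_score_fn(params, config) -> Callable:
    """Batched scalar score: S(x) = l_<PC> - l_<NC> for dense (N, L, 4) inputs."""

    def score(xb):
        return M.score_pc_nc(xb, params, config)

    return score


def _batched_scores(score_fn, xs: np.ndarray, batch_size: int = 128) -> np.ndarray:
    out = []
    for k in range(0, len(xs), batch_size):
        out.append(np.asarray(score_fn(xs[k : k + batch_size])))
    return np.concatenate(out)


def _batched_input_grads(score_fn, xs: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Per-example gradient of S with respect to the dense input rows."""
    g = grad(lambda xb: anp.sum(score_fn(xb)))
    out = []
    for k in range(0, len(xs), batch_size):
        out.append(np.asarray(g(xs[k : k + batch_size])))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# ISM and approximators
# ---------------------------------------------------------------------------


def ism(
    params_or_fn, config=None, transcript: Transcript | str = None, batch_size: int = 128,
    model_id: str = "",
) -> MutationEffectMatrix:
    """Saturated in-silico mutagenesis: score all 3L single-base variants.

    ``params_or_fn`` may be a parameter pytree (with ``config``) or a
    batched score function directly.
    """
    score_fn, sequence = _resolve(params_or_fn, config, transcript)
    x = M.one_hot(sequence)
    L = len(sequence)
    variants = np.repeat(x[None], 3 * L, axis=0)
    alt_idx = []
    base_idx = {b: k for k, b in enumerate(RNA_ALPHABET)}
    n = 0
    for i, ref in enumerate(sequence):
        j = base_idx[ref]
        for k in range(4):
            if k == j:
                continue
            variants[n, i, j] = 0.0
            variants[n, i, k] = 1.0
            alt_idx.append((i, k))
            n += 1
    s_wt = float(np.asarray(score_fn(x[None]))[0])
    s_var = _batched_scores(score_fn, variants, batch_size)
    values = (s_var - s_wt).reshape(L, 3)
    return MutationEffectMatrix(values=values, sequence=sequence, method="ism", model_id=model_id)


def _resolve(params_or_fn, config, transcript):
    sequence = transcript.sequence if isinstance(transcript, Transcript) else str(transcript)
    if callable(params_or_fn) and config is None:
        return params_or_fn, sequence
    return make_score_fn(params_or_fn, config), sequence


def input_gradient(params_or_fn, config=None, transcript=None) -> np.ndarray:
    """(L, 4) gradient of S at the one-hot input (one forward/backward pass)."""
    score_fn, sequence = _resolve(params_or_fn, config, transcript)
    x = M.one_hot(sequence)
    return _batched_input_grads(score_fn, x[None])[0]


def taylor(
    params_or_fn, config=None, transcript=None, gradient: Optional[np.ndarray] = None,
    model_id: str = "",
) -> MutationEffectMatrix:
    """First-order Taylor estimate: delta-S(i, j->b) ~ dS/dx_ib - dS/dx_ij."""
    _, sequence = _resolve(params_or_fn, config, transcript)
    if gradient is None:
        gradient = input_gradient(params_or_fn, config, transcript)
    values = _pair_columns(np.asarray(gradient), sequence, sign=-1.0)
    return MutationEffectMatrix(values=values, sequence=sequence, method="taylor", model_id=model_id)


def integrated_gradients(
    score_fn, x: np.ndarray, baseline: np.ndarray, steps: int = 32, batch_size: int = 32
) -> tuple[np.ndarray, float]:
    """Midpoint-rule integrated gradients along the path baseline -> x.

    Returns ``(attributions (L, V), completeness_residual)`` where the
    residual is ``|sum(attributions) - (S(x) - S(baseline))|``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != x.shape:
        raise ValueError("baseline shape must match input shape")
    disp = x - baseline
    alphas = (np.arange(steps) + 0.5) / steps
    points = baseline[None] + alphas[:, None, None] * disp[None]
    grads = _batched_input_grads(score_fn, points, batch_size)
    attr = disp * grads.mean(axis=0)
    s = _batched_scores(score_fn, np.stack([x, baseline]))
    residual = float(abs(attr.sum() - (s[0] - s[1])))
    return attr, residual


def ig_uniform_ism(
    params_or_fn, config=None, transcript=None, steps: int = 32, model_id: str = "",
    displacement_normalized: bool = True,
) -> MutationEffectMatrix:
    """Mutation effects from a single uniform-baseline IG run.

    Gradients are averaged along the path from the one-hot input toward the
    uniform [0.25, 0.25, 0.25, 0.25] rows (the baseline as the destination)
    and paired with a minus sign. With ``displacement_normalized`` (default)
    the path-averaged gradients are paired directly, which reduces to ISM
    exactly for a linear scorer; otherwise the raw displacement-weighted IG
    attributions are paired as printed conventions would have it.
    """
    score_fn, sequence = _resolve(params_or_fn, config, transcript)
    x = M.one_hot(sequence)
    uniform = np.full_like(x, 0.25)
    # destination = uniform, source = x
    disp = uniform - x
    alphas = (np.arange(steps) + 0.5) / steps
    points = x[None] + alphas[:, None, None] * disp[None]
    avg_grad = _batched_input_grads(score_fn, points).mean(axis=0)
    dense = avg_grad if displacement_normalized else disp * avg_grad
    values = _pair_columns(dense, sequence, sign=-1.0)
    return MutationEffectMatrix(
        values=values, sequence=sequence, method="ig_uniform", steps=steps, model_id=model_id
    )


def mdig(
    params_or_fn, config=None, transcript=None, beta: float = 0.25, steps: int = 8,
    model_id: str = "", pairing_sign: float = 1.0,
) -> MutationEffectMatrix:
    """Mutation-directed integrated gradients.

    For each base ``b`` the baseline is ``X(b, beta) = beta poly(b) +
    (1 - beta) x`` and one IG run is integrated from the input toward it;
    entries are combined as ``IG_ib + IG_ij`` (``pairing_sign`` flips the
    convention for the diagnostic). Four IG evaluations; default eight
    integration steps per baseline.
    """
    if not (0 < beta <= 1):
        raise ValueError("beta must be in (0, 1]")
    score_fn, sequence = _resolve(params_or_fn, config, transcript)
    x = M.one_hot(sequence)
    L = len(sequence)
    base_idx = {b: k for k, b in enumerate(RNA_ALPHABET)}
    dense_by_base = {}
    for k, b in enumerate(RNA_ALPHABET):
        poly = np.zeros_like(x)
        poly[:, k] = 1.0
        baseline = beta * poly + (1 - beta) * x
        attr, _ = integrated_gradients(score_fn, baseline, x, steps=steps)
        dense_by_base[b] = attr
    values = np.zeros((L, 3))
    for i, ref in enumerate(sequence):
        j = base_idx[ref]
        c = 0
        for k, b in enumerate(RNA_ALPHABET):
            if k == j:
                continue
            attr = dense_by_base[b]
            values[i, c] = attr[i, k] + pairing_sign * attr[i, j]
            c += 1
    return MutationEffectMatrix(
        values=values, sequence=sequence, method="mdig", beta=beta, steps=steps, model_id=model_id
    )


# ---------------------------------------------------------------------------
# Agreement metrics
# ---------------------------------------------------------------------------


def pearson_flat(m1, m2) -> float:
    """Pearson r over the flattened L x 3 matrices."""
    a = _values(m1).ravel()
    b = _values(m2).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def median_positionwise_cosine(m1, m2) -> float:
    """Median over positions of the cosine between the per-position rows."""
    a, b = _values(m1), _values(m2)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    both_zero = (na == 0) & (nb == 0)
    denom = np.where(na * nb == 0, 1.0, na * nb)
    cos = np.sum(a * b, axis=1) / denom
    cos = np.where(both_zero, 1.0, np.where((na == 0) ^ (nb == 0), 0.0, cos))
    return float(np.median(cos))


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, MutationEffectMatrix) else np.asarray(m, dtype=float)


METRICS = {"pearson": pearson_flat, "cosine": median_positionwise_cosine}


def inter_replicate_agreement(matrices: Sequence, metric: str | Callable = "pearson") -> float:
    """Mean of the metric over all unordered replicate pairs for one transcript."""
    fn = METRICS[metric] if isinstance(metric, str) else metric
    n = len(matrices)
    if n < 2:
        raise ValueError("need at least two replicates")
    vals = [fn(matrices[i], matrices[j]) for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(vals))


def agreement_with_ism(
    ism_per_replicate: Sequence, approx_per_replicate: Sequence, metric: str | Callable = "pearson"
) -> float:
    """Mean of the metric over matched (intra-replicate) ISM/approximation pairs."""
    if len(ism_per_replicate) != len(approx_per_replicate):
        raise ValueError("replicate lists must align")
    fn = METRICS[metric] if isinstance(metric, str) else metric
    vals = [fn(a, b) for a, b in zip(ism_per_replicate, approx_per_replicate)]
    return float(np.mean(vals))


DEFAULT_BETA_GRID = (0.05, 0.1, 0.25, 0.5, 1.0)


def tune_beta(
    params, config, transcripts: Sequence[Transcript], grid: Sequence[float] = DEFAULT_BETA_GRID,
    steps: int = 8, metric: str = "pearson",
    ism_matrices: Optional[Sequence[MutationEffectMatrix]] = None,
) -> tuple[float, dict[float, float]]:
    """Select the MDIG beta maximising the median per-transcript agreement with ISM."""
    fn = METRICS[metric]
    score_fn = params if callable(params) and config is None else make_score_fn(params, config)
    if ism_matrices is None:
        ism_matrices = [ism(score_fn, transcript=t) for t in transcripts]
    results = {}
    for beta in grid:
        rs = [
            fn(ism_m, mdig(score_fn, transcript=t, beta=beta, steps=steps))
            for t, ism_m in zip(transcripts, ism_matrices)
        ]
        results[beta] = float(np.median(rs))
    best = max(results, key=results.get)
    return best, results


def sign_convention_diagnostic(
    params, config, transcript: Transcript, beta: float = 0.25, steps: int = 8
) -> dict:
    """Correlation with ISM of the plus- vs minus-pairing of MDIG attributions."""
    score_fn = make_score_fn(params, config)
    ism_m = ism(score_fn, transcript=transcript)
    plus = mdig(score_fn, transcript=transcript, beta=beta, steps=steps, pairing_sign=1.0)
    minus = mdig(score_fn, transcript=transcript, beta=beta, steps=steps, pairing_sign=-1.0)
    r_plus = pearson_flat(ism_m, plus)
    r_minus = pearson_flat(ism_m, minus)
    return {
        "pearson_plus": r_plus,
        "pearson_minus": r_minus,
        "better": "plus" if r_plus >= r_minus else "minus",
    }
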