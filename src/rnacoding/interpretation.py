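"""Importance tracks, metagenes, motif-window extraction and perturbation scans.

Importance of an endogenous base is defined through the *counterfactual*
class: under the ``up_PC`` setting a position matters to the extent that
some substitution there pushes the score strongly toward noncoding
(most negative delta-S), and symmetrically for ``up_NC``. Tracks can mask
canonical signals (start/stop codons and nonsense-creating substitutions)
to expose secondary features; 21-nt windows around the unmasked maxima form
the primary sets handed to external motif-discovery tools (STREME-style
FASTA output), with two control strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import model as M
from .attribution import MutationEffectMatrix
from .sequences import STOP_CODONS, Transcript, longest_orf

logger = logging.getLogger(__name__)

DIRECTIONS = ("up_PC", "up_NC")


@dataclass
class ImportanceTrack:
    values: np.ndarray          # length L, nonnegative
    direction: str              # up_PC | up_NC
    mask: np.ndarray            # length L boolean; True = excluded
    sequence: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite importance values")

    def masked_argmax(self, start: int = 0, end: Optional[int] = None) -> Optional[int]:
        """5'-most argmax over unmasked positions of [start, end); None if all masked."""
        end = len(self.values) if end is None else end
        vals = self.values[start:end].copy()
        vals[self.mask[start:end]] = -np.inf
        if not np.isfinite(vals).any():
            return None
        return start + int(np.argmax(vals))  # argmax returns the first (5'-most) maximum


@dataclass
class RegionPartition:
    """Ordered, disjoint intervals covering a transcript (0-based half-open)."""

    intervals: list[tuple[str, int, int]]
    anchored_on: str = "cds"  # cds | longest_orf | none

    def __post_init__(self) -> None:
        prev = 0
        for name, s, e in self.intervals:
            if s != prev or e < s:
                raise ValueError("intervals must be ordered, disjoint and covering")
            prev = e

    def get(self, name: str) -> Optional[tuple[int, int]]:
        for n, s, e in self.intervals:
            if n == name and e > s:
                return (s, e)
        return None

    @property
    def names(self) -> list[str]:
        return [n for n, s, e in self.intervals if e > s]

    @property
    def orf_span(self) -> Optional[tuple[int, int]]:
        return self.get("cds") or self.get("orf")


def partition_regions(transcript: Transcript) -> RegionPartition:
    """5'UTR/CDS/3'UTR for mRNAs; upstream/longest-ORF/downstream for lncRNAs."""
    L = len(transcript)
    if transcript.is_coding and transcript.cds is not None:
        s, e = transcript.cds
        return RegionPartition([("utr5", 0, s), ("cds", s, e), ("utr3", e, L)], "cds")
    orf = longest_orf(transcript.sequence)
    if orf is None:
        return RegionPartition([("upstream", 0, L), ("orf", L, L), ("downstream", L, L)], "none")
    return RegionPartition(
        [("upstream", 0, orf.start), ("orf", orf.start, orf.end), ("downstream", orf.end, L)],
        "longest_orf",
    )


# ---------------------------------------------------------------------------
# Importance tracks
# ---------------------------------------------------------------------------


def importance_track(effects: MutationEffectMatrix, direction: str) -> ImportanceTrack:
    """Counterfactual-class importance from a mutation-effect matrix.

    ``up_PC``: strength of the strongest push toward NC, i.e.
    ``max_b(-delta_S)`` clipped at zero; ``up_NC`` symmetric with ``+delta_S``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    signed = -effects.values if direction == "up_PC" else effects.values
    values = np.clip(signed.max(axis=1), 0.0, None)
    return ImportanceTrack(
        values=values, direction=direction, mask=np.zeros(effects.L, dtype=bool),
        sequence=effects.sequence,
    )


def _selected_alt(effects: MutationEffectMatrix, direction: str) -> np.ndarray:
    """The alternate base chosen as strongest at each position (length-L chars)."""
    signed = -effects.values if direction == "up_PC" else effects.values
    alts = effects.alt_bases()
    idx = signed.argmax(axis=1)
    return alts[np.arange(effects.L), idx]


def mask_canonical(
    track: ImportanceTrack, transcript: Transcript, effects: MutationEffectMatrix
) -> ImportanceTrack:
    """Mask start/stop codons and positions whose strongest mutation creates a premature stop.

    The ORF of reference is the annotated CDS for mRNAs, else the longest
    ORF; transcripts with no ORF get an empty mask.
    """
    part = partition_regions(transcript)
    span = part.orf_span
    mask = track.mask.copy()
    if span is None:
        return ImportanceTrack(track.values, track.direction, mask, track.sequence)
    start, end = span
    mask[start : start + 3] = True
    mask[end - 3 : end] = True
    seq = transcript.sequence
    chosen = _selected_alt(effects, track.direction)
    for i in range(start, end - 3):
        ci = start + 3 * ((i - start) // 3)
        codon = list(seq[ci : ci + 3])
        codon[i - ci] = chosen[i]
        if "".join(codon) in STOP_CODONS:
            mask[i] = True
    return ImportanceTrack(track.values, track.direction, mask, track.sequence)


# ---------------------------------------------------------------------------
# Metagenes
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    positions: np.ndarray  # relative positions (or bin indices)
    mean: np.ndarray
    coverage: np.ndarray   # fraction of series contributing per retained position
    anchor: str = "start_codon"


def metagene(
    series: Sequence[np.ndarray],
    anchors: Sequence[int],
    coverage_threshold: float = 0.70,
    anchor_name: str = "start_codon",
) -> MetageneProfile:
    """Average per-position series aligned at per-series anchors.

    Relative positions present in fewer than ``coverage_threshold`` of the
    series are dropped.
    """
    if len(series) != len(anchors):
        raise ValueError("series and anchors must align")
    n = len(series)
    lo = min(-a for a in anchors)
    hi = max(len(s) - a for s, a in zip(series, anchors))
    width = hi - lo
    sums = np.zeros(width)
    counts = np.zeros(width)
    for s, a in zip(series, anchors):
        s = np.asarray(s, dtype=float)
        off = -a - lo
        sums[off : off + len(s)] += s
        counts[off : off + len(s)] += 1
    keep = counts / n >= coverage_threshold
    positions = np.arange(lo, hi)[keep]
    mean = sums[keep] / counts[keep]
    return MetageneProfile(positions=positions, mean=mean, coverage=counts[keep] / n, anchor=anchor_name)


def binned_metagene(
    effects: Sequence[MutationEffectMatrix],
    partitions: Optional[Sequence[RegionPartition]] = None,
    n_bins: int = 25,
) -> MetageneProfile:
    """Mean |delta-S| in equal-width positional bins spanning each whole transcript.

    |delta-S| is averaged over the three substitutions at each position,
    then within each of ``n_bins`` bins per transcript, then across
    transcripts. When partitions are supplied the profile's anchor notes the
    average ORF start/end bins (as metadata only).
    """
    per_bin = np.zeros((len(effects), n_bins))
    for t, m in enumerate(effects):
        vals = np.abs(m.values).mean(axis=1)
        L = m.L
        bins = (np.arange(L) * n_bins) // max(L, 1)
        for b in range(n_bins):
            sel = bins == b
            per_bin[t, b] = vals[sel].mean() if sel.any() else np.nan
    mean = np.nanmean(per_bin, axis=0)
    coverage = np.mean(~np.isnan(per_bin), axis=0)
    anchor = "transcript_bins"
    if partitions:
        starts, ends = [], []
        for m, p in zip(effects, partitions):
            span = p.orf_span
            if span:
                starts.append((span[0] * n_bins) // m.L)
                ends.append(((span[1] - 1) * n_bins) // m.L)
        if starts:
            anchor = f"transcript_bins(orf_start~{int(np.median(starts))},orf_end~{int(np.median(ends))})"
    return MetageneProfile(positions=np.arange(n_bins), mean=mean, coverage=coverage, anchor=anchor)


# ---------------------------------------------------------------------------
# Motif windows
# ---------------------------------------------------------------------------


@dataclass
class MotifWindow:
    transcript_id: str
    region: str
    direction: str
    start: int
    end: int
    sequence: str
    strategy: str = "primary"

    @property
    def name(self) -> str:
        return f"{self.transcript_id}|{self.region}|{self.direction}|{self.start}-{self.end}|{self.strategy}"


def extract_motif_windows(
    tracks: dict[str, ImportanceTrack],
    transcripts: Sequence[Transcript],
    window_flank: int = 10,
    regions: Optional[Sequence[str]] = None,
) -> list[MotifWindow]:
    """One window per transcript x region around the unmasked importance maximum.

    Windows are ``2*flank + 1`` nt, clipped to region bounds; regions whose
    clipped window would be shorter than the full width are skipped (keeps
    external motif-tool input lengths uniform). Ties at the maximum resolve
    to the 5'-most position.
    """
    width = 2 * window_flank + 1
    out: list[MotifWindow] = []
    for t in transcripts:
        track = tracks.get(t.id)
        if track is None:
            continue
        part = partition_regions(t)
        for name in part.names:
            if regions and name not in regions:
                continue
            s, e = part.get(name)
            if e - s < width:
                logger.info("skipping %s/%s: region shorter than window", t.id, name)
                continue
            peak = track.masked_argmax(s, e)
            if peak is None:
                logger.info("skipping %s/%s: fully masked", t.id, name)
                continue
            ws = min(max(peak - window_flank, s), e - width)
            out.append(
                MotifWindow(
                    transcript_id=t.id, region=name, direction=track.direction,
                    start=ws, end=ws + width, sequence=t.sequence[ws : ws + width],
                )
            )
    return out


def build_control_set(
    strategy: int,
    primaries: Sequence[MotifWindow],
    transcripts: Sequence[Transcript],
    seed: int = 0,
    opposite_primaries: Optional[Sequence[MotifWindow]] = None,
) -> list[MotifWindow]:
    """Control windows for differential motif discovery.

    Strategy 1 draws, per primary window, a uniformly random same-region
    window from the same transcript that does not overlap the primary.
    Strategy 2 reuses the most-important windows from the opposite RNA class
    (pass them as ``opposite_primaries``).
    """
    if strategy == 2:
        if opposite_primaries is None:
            raise ValueError("strategy 2 requires the opposite class's primary windows")
        return [
            MotifWindow(w.transcript_id, w.region, w.direction, w.start, w.end, w.sequence, "control2")
            for w in opposite_primaries
        ]
    if strategy != 1:
        raise ValueError("strategy must be 1 or 2")
    rng = np.random.RandomState(seed)
    by_id = {t.id: t for t in transcripts}
    out = []
    for w in primaries:
        t = by_id[w.transcript_id]
        part = partition_regions(t)
        s, e = part.get(w.region)
        width = w.end - w.start
        starts = [
            c for c in range(s, e - width + 1)
            if c + width <= w.start or c >= w.end  # no overlap with the primary
        ]
        if not starts:
            logger.info("no non-overlapping control position for %s/%s", w.transcript_id, w.region)
            continue
        c = int(rng.choice(starts))
        out.append(
            MotifWindow(t.id, w.region, w.direction, c, c + width, t.sequence[c : c + width], "control1")
        )
    return out


def write_windows_fasta(windows: Sequence[MotifWindow], path) -> None:
    """FASTA output suitable as a STREME primary or control set."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.name}\n{w.sequence}\n")


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


@dataclass
class PerturbationResult:
    perturbation: str
    delta_s: np.ndarray            # one value per variant
    meta: list = field(default_factory=list)  # per-variant annotation (e.g. codon index)
    reason: str = ""               # non-empty when inapplicable

    @property
    def empty(self) -> bool:
        return self.delta_s.size == 0


PERTURBATIONS = (
    "utr5_dinuc_shuffle",
    "utr3_dinuc_shuffle",
    "codon_shuffle",
    "start_knockout",
    "nonsense_scan",
)


def dinucleotide_shuffle(sequence: str, rng: np.random.RandomState, max_tries: int = 200) -> str:
    """Shuffle preserving the exact dinucleotide count vector (Euler-path walk).

    Altschul-Erickson style: pick a random last-exit edge per vertex forming
    an arborescence into the terminal vertex, shuffle the remaining
    adjacency lists, and walk the Eulerian path.
    """
    if len(sequence) < 3:
        return sequence
    verts = sorted(set(sequence))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    last = sequence[-1]
    for _ in range(max_tries):
        # choose a candidate last-exit edge for every non-terminal vertex
        last_exit = {}
        ok = True
        for v in verts:
            if v == last:
                continue
            if not edges[v]:
                continue
            last_exit[v] = edges[v][rng.randint(len(edges[v]))]
        # the chosen edges must form a tree pointing into the terminal vertex
        for v in last_exit:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        walk_lists = {}
        for v in verts:
            pool = list(edges[v])
            if v in last_exit:
                pool.remove(last_exit[v])
            rng.shuffle(pool)
            if v in last_exit:
                pool.append(last_exit[v])
            walk_lists[v] = pool
        out = [sequence[0]]
        cur = sequence[0]
        ptr = {v: 0 for v in verts}
        for _ in range(len(sequence) - 1):
            nxt = walk_lists[cur][ptr[cur]]
            ptr[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian ordering")


def codon_shuffle(transcript: Transcript, rng: np.random.RandomState) -> str:
    """Shuffle internal CDS codons, fixing start and stop (CDS length preserved)."""
    if transcript.cds is None:
        raise ValueError("codon shuffle requires a CDS")
    s, e = transcript.cds
    seq = transcript.sequence
    codons = [seq[i : i + 3] for i in range(s + 3, e - 3, 3)]
    rng.shuffle(codons)
    return seq[: s + 3] + "".join(codons) + seq[e - 3 :]


def _score_sequences(params, config, sequences: Sequence[str], batch_size: int = 64) -> np.ndarray:
    from .attribution import _batched_scores, make_score_fn

    score_fn = make_score_fn(params, config)
    L = max(len(s) for s in sequences)
    if len(set(len(s) for s in sequences)) == 1:
        xs = np.stack([M.one_hot(s) for s in sequences])
        return _batched_scores(score_fn, xs, batch_size)
    # mixed lengths: score with masks, one length-group at a time
    out = np.zeros(len(sequences))
    for L in sorted(set(len(s) for s in sequences)):
        idx = [i for i, s in enumerate(sequences) if len(s) == L]
        xs = np.stack([M.one_hot(sequences[i]) for i in idx])
        out[np.asarray(idx)] = _batched_scores(score_fn, xs, batch_size)
    return out


def perturb_and_score(
    params, config, transcript: Transcript, perturbation: str, seed: int = 0,
    min_utr_len: int = 25, nonsense_bin_codons: int = 50,
) -> PerturbationResult:
    """Score a family of sequence perturbations as delta-S versus wild type.

    UTR shuffles preserve dinucleotide frequencies and apply only to UTRs
    longer than ``min_utr_len``; codon shuffling fixes the start and stop
    codons; ``start_knockout`` scores the nine single-base substitutions in
    the start codon; ``nonsense_scan`` scores every substitution creating a
    premature in-frame stop, annotated with its codon index (for
    fifty-codon binning).
    """
    if perturbation not in PERTURBATIONS:
        raise ValueError(f"unknown perturbation {perturbation!r}")
    rng = np.random.RandomState(seed)
    part = partition_regions(transcript)
    span = part.orf_span
    seq = transcript.sequence
    empty = lambda reason: PerturbationResult(perturbation, np.zeros(0), [], reason)
    if span is None:
        return empty("no ORF / CDS")
    s, e = span

    variants: list[str] = []
    meta: list = []
    if perturbation in ("utr5_dinuc_shuffle", "utr3_dinuc_shuffle"):
        if perturbation == "utr5_dinuc_shuffle":
            lo, hi = 0, s
        else:
            lo, hi = e, len(seq)
        if hi - lo <= min_utr_len:
            return empty(f"UTR shorter than {min_utr_len} nt")
        shuffled = dinucleotide_shuffle(seq[lo:hi], rng)
        variants.append(seq[:lo] + shuffled + seq[hi:])
        meta.append((lo, hi))
    elif perturbation == "codon_shuffle":
        if transcript.cds is None:
            return empty("no annotated CDS")
        variants.append(codon_shuffle(transcript, rng))
        meta.append(transcript.cds)
    elif perturbation == "start_knockout":
        for i in range(s, s + 3):
            for b in "ACGU":
                if b == seq[i]:
                    continue
                variants.append(seq[:i] + b + seq[i + 1 :])
                meta.append((i, b))
    else:  # nonsense_scan
        for i in range(s + 3, e - 3):
            ci = s + 3 * ((i - s) // 3)
            for b in "ACGU":
                if b == seq[i]:
                    continue
                codon = list(seq[ci : ci + 3])
                codon[i - ci] = b
                if "".join(codon) in STOP_CODONS:
                    variants.append(seq[:i] + b + seq[i + 1 :])
                    meta.append({"position": i, "alt": b, "codon_index": (i - s) // 3,
                                 "bin": ((i - s) // 3) // nonsense_bin_codons})
        if not variants:
            return empty("no nonsense-creating substitution")

    scores = _score_sequences(params, config, [seq] + variants)
    delta = scores[1:] - scores[0]
    return PerturbationResult(perturbation, delta, meta)


def nonsense_bin_means(result: PerturbationResult) -> dict[int, float]:
    """Mean delta-S of nonsense variants per fifty-codon bin."""
    if result.perturbation != "nonsense_scan" or result.empty:
        return {}
    bins: dict[int, list[float]] = {}
    for v, m in zip(result.delta_s, result.meta):
        bins.setdefault(m["bin"], []).append(float(v))
    return {b: float(np.mean(vs)) for b, vs in sorted(bins.items())}


# ---------------------------------------------------------------------------
# Attention metagenes
# ---------------------------------------------------------------------------


def attention_summary(
    params, config, transcripts: Sequence[Transcript], head: int = 0, layer: int = 0,
    coverage_threshold: float = 0.70,
) -> MetageneProfile:
    """Metagene of first-decode-step encoder-decoder attention, anchored at ORF starts."""
    series, anchors = [], []
    for t in transcripts:
        part = partition_regions(t)
        span = part.orf_span
        if span is None:
            continue
        x = M.one_hot(t.sequence)
        H = M.encode(x, params, config)
        _, attns = M.decode_step(np.array([M.SOS]), H, params, config)
        row = np.asarray(attns[layer][head, 0])  # attention over encoder positions
        series.append(row)
        anchors.append(span[0])
    if not series:
        raise ValueError("no transcripts with an ORF")
    return metagene(series, anchors, coverage_threshold, anchor_name="start_codon")
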