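"""Synthetic transcriptome generator.

Emulates the statistical structure of a balanced mRNA/lncRNA corpus:
mRNAs carry a 5'UTR, an AUG-initiated CDS with Kozak-like start context and
a codon-usage bias that produces 3-nt periodicity, an in-frame stop and a
3'UTR; lncRNAs have matched lengths but no genuine long ORF, only spurious
short ones. A *hard mode* plants long spurious ORFs (without codon bias or
start context) inside lncRNAs so that ORF length alone stops separating
the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sequences import (
    CODON_TABLE,
    NC,
    PC,
    START_CODON,
    STOP_CODONS,
    DatasetSplit,
    Transcript,
    longest_orf,
    make_splits,
)

# codons per amino acid, from the standard genetic code
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


def default_codon_bias(strength: float = 4.0) -> dict[str, np.ndarray]:
    """Codon-probability vectors favouring C and disfavouring U at the wobble position.

    Within each synonymous group, a codon ending in C gets relative weight
    ``strength``, one ending in U weight ``1/strength``, others weight 1 —
    a planted third-position preference that attribution analyses can
    recover as a known signal.
    """
    bias = {}
    for aa, codons in _CODONS_BY_AA.items():
        w = np.ones(len(codons))
        for k, c in enumerate(codons):
            if c.endswith("C"):
                w[k] = strength
            elif c.endswith("U"):
                w[k] = 1.0 / strength
        bias[aa] = w / w.sum()
    return bias


@dataclass
class GeneratorParams:
    """Parameters of the synthetic transcriptome.

    Defaults describe the standard (easy) world: classes separable by ORF
    length with codon bias and Kozak context as secondary signals. Set
    ``hard=True`` for lncRNAs harbouring long unbiased ORFs.
    """

    n_per_class: int = 500
    length_range: tuple[int, int] = (200, 1000)
    codon_bias: dict = field(default_factory=default_codon_bias)
    kozak_strength: float = 0.9  #: P(G at +1 after AUG... i.e. position +4 of the CDS context)
    utr_gc: float = 0.5
    spurious_orf_max_codons: int = 30
    hard: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi <= 1200):
            raise ValueError("length_range must satisfy 0 < lo <= hi <= 1200")
        if lo < 60:
            raise ValueError("minimum length must allow UTRs plus a short CDS (>= 60 nt)")
        for aa, p in self.codon_bias.items():
            if abs(float(np.sum(p)) - 1.0) > 1e-9:
                raise ValueError(f"codon probabilities for {aa} do not sum to 1")


_AA_LIST = sorted(_CODONS_BY_AA)


def _random_utr(n: int, gc: float, rng: np.random.RandomState) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(rng.choice(list("ACGU"), size=n, p=p)) if n else ""


def _sample_cds(n_codons: int, params: GeneratorParams, rng: np.random.RandomState) -> tuple[str, str]:
    """CDS of ``n_codons`` coding codons (incl. the AUG) plus one stop; returns (nt, protein)."""
    aas = ["M"]
    aas += list(rng.choice(_AA_LIST, size=n_codons - 1))
    codons = []
    for aa in aas:
        opts = _CODONS_BY_AA[aa]
        p = params.codon_bias[aa]
        codons.append(opts[rng.choice(len(opts), p=p)])
    stop = rng.choice(sorted(STOP_CODONS))
    return "".join(codons) + stop, "".join(aas)


def generate_mrna(params: GeneratorParams, rng: np.random.RandomState, idx: int = 0) -> Transcript:
    """One synthetic mRNA: 5'UTR + AUG-initiated biased CDS + stop + 3'UTR."""
    lo, hi = params.length_range
    total = int(rng.randint(lo, hi + 1))
    # ~15% 5'UTR, ~20% 3'UTR, remainder CDS
    utr5 = max(6, int(round(total * 0.15)))
    utr3 = max(6, int(round(total * 0.20)))
    n_cds = total - utr5 - utr3
    n_codons = n_cds // 3 - 1  # coding codons, one codon reserved for the stop
    if n_codons < 2:
        raise ValueError("length constraints leave no room for a CDS")
    utr5 += n_cds - 3 * (n_codons + 1)  # absorb the remainder upstream
    cds, protein = _sample_cds(n_codons, params, rng)
    utr5_seq = _random_utr(utr5, params.utr_gc, rng)
    utr3_seq = _random_utr(utr3, params.utr_gc, rng)
    seq = utr5_seq + cds + utr3_seq
    # Kozak-like context: force G at +1 relative to the start codon (CDS position +3)
    if rng.rand() < params.kozak_strength:
        pos = utr5 + 3
        seq = seq[:pos] + "G" + seq[pos + 1 :]
        cds_fixed = seq[utr5 : utr5 + len(cds)]
        protein = protein[0] + _retranslate(cds_fixed[3:-3])
    start = utr5
    end = utr5 + len(cds)
    # forcing G may have created a premature stop in codon 2; retry in that case
    from .sequences import translate

    if translate(seq[start : end - 3]) != protein or len(protein) != n_codons:
        return generate_mrna(params, rng, idx)
    return Transcript(
        id=f"mrna_{idx}", sequence=seq, label=PC, cds=(start, end), protein=protein
    )


def _retranslate(cds_nt: str) -> str:
    from .sequences import translate

    return translate(cds_nt) if len(cds_nt) >= 3 else ""


def generate_lncrna(
    params: GeneratorParams, rng: np.random.RandomState, idx: int = 0, max_tries: int = 60
) -> Transcript:
    """One synthetic lncRNA with no ORF longer than the spurious cap.

    A random sequence is drawn at an mRNA-matched length; any ORF exceeding
    the cap is broken by replacing a mid-ORF codon with a stop, iterating
    until compliant (cheaper than pure rejection at 1000 nt). In hard mode
    a long ORF of unbiased random codons (no Kozak context) is planted
    instead, so length alone cannot separate the classes.
    """
    lo, hi = params.length_range
    total = int(rng.randint(lo, hi + 1))
    if params.hard:
        for _ in range(max_tries):
            seq = _hard_lncrna(total, params, rng)
            if seq is not None:
                return Transcript(id=f"lnc_{idx}", sequence=seq, label=NC)
        raise RuntimeError("hard-mode lncRNA generation failed: lengths leave no room for an ORF")
    seq = _random_utr(total, params.utr_gc, rng)
    cap_nt = 3 * (params.spurious_orf_max_codons + 1)  # span includes the stop codon
    stops = sorted(STOP_CODONS)
    for _ in range(max_tries):
        from .sequences import find_orfs

        too_long = [o for o in find_orfs(seq) if o.n_nucleotides > cap_nt]
        if not too_long:
            return Transcript(id=f"lnc_{idx}", sequence=seq, label=NC)
        for orf in too_long:
            n_codons = orf.n_nucleotides // 3
            cut = orf.start + 3 * (n_codons // 2)
            seq = seq[:cut] + rng.choice(stops) + seq[cut + 3 :]
    raise RuntimeError(
        f"ORF-breaking budget ({max_tries}) exceeded for lncRNA of length {total} "
        f"with spurious ORF cap {params.spurious_orf_max_codons}"
    )


def _hard_lncrna(total: int, params: GeneratorParams, rng: np.random.RandomState) -> Optional[str]:
    """Plant a long unbiased ORF: AUG + uniform-random non-stop codons + stop."""
    utr5 = max(6, int(round(total * 0.15)))
    utr3 = max(6, int(round(total * 0.20)))
    n_cds = total - utr5 - utr3
    n_codons = n_cds // 3 - 1
    if n_codons < 2:
        return None
    utr5 += n_cds - 3 * (n_codons + 1)
    non_stop = sorted(set(CODON_TABLE) - {START_CODON})
    codons = [START_CODON] + list(rng.choice(non_stop, size=n_codons - 1))
    stop = rng.choice(sorted(STOP_CODONS))
    return (
        _random_utr(utr5, params.utr_gc, rng)
        + "".join(codons)
        + stop
        + _random_utr(utr3, params.utr_gc, rng)
    )


def generate_dataset(
    params: GeneratorParams, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> tuple[list[Transcript], DatasetSplit]:
    """Balanced synthetic transcriptome plus a deterministic split."""
    rng = np.random.RandomState(params.seed)
    transcripts: list[Transcript] = []
    for i in range(params.n_per_class):
        transcripts.append(generate_mrna(params, rng, i))
    for i in range(params.n_per_class):
        transcripts.append(generate_lncrna(params, rng, i))
    split = make_splits(transcripts, fractions, seed=params.seed)
    return transcripts, split
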