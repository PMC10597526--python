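"""Transcript domain types, FASTA/annotation I/O, translation, ORF logic and splits.

Conventions used throughout the package:

* All coordinates are 0-based, half-open ``[start, end)``.
* The CDS interval *includes* the stop codon (RefSeq convention).
* Sequences are stored over the RNA alphabet ``{A, C, G, U}``; ``T`` is
  normalized to ``U`` on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
PC, NC = "PC", "NC"
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
START_CODON = "AUG"
DEFAULT_MAX_LENGTH = 1200

#: Standard genetic code keyed on RNA codons, stops excluded.
_standard = CodonTable.unambiguous_rna_by_name["Standard"]
CODON_TABLE: dict = dict(_standard.forward_table)


class AnnotationError(ValueError):
    """Raised when a FASTA record and its annotation row disagree."""


def _normalize(sequence: str) -> str:
    return sequence.strip().upper().replace("T", "U")


@dataclass
class Transcript:
    """A transcript record: the universal input unit of the package.

    Parameters
    ----------
    id : str
        Record identifier (FASTA id).
    sequence : str
        Nucleotides over ``{A, C, G, U}``.
    label : str
        ``"PC"`` (protein coding) or ``"NC"`` (noncoding).
    cds : tuple of (int, int), optional
        0-based half-open CDS span including the stop codon.
    protein : str, optional
        Amino-acid sequence of the CDS (stop excluded).
    non_aug : bool
        Set for coding records whose CDS does not begin with AUG
        (non-AUG initiation); relaxes the start-codon invariant.
    """

    id: str
    sequence: str
    label: str
    cds: Optional[tuple[int, int]] = None
    protein: Optional[str] = None
    non_aug: bool = False

    def __post_init__(self) -> None:
        self.sequence = _normalize(self.sequence)
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_coding(self) -> bool:
        return self.label == PC

    def validate(self) -> None:
        bad = set(self.sequence) - set(RNA_ALPHABET)
        if bad:
            raise AnnotationError(f"{self.id}: invalid characters {sorted(bad)}")
        if self.label not in (PC, NC):
            raise AnnotationError(f"{self.id}: label must be PC or NC, got {self.label!r}")
        if self.cds is not None:
            start, end = self.cds
            if not (0 <= start < end <= len(self.sequence)):
                raise AnnotationError(f"{self.id}: CDS [{start}, {end}) out of bounds")
            if (end - start) % 3 != 0:
                raise AnnotationError(f"{self.id}: CDS length not a multiple of 3")
            if not self.non_aug and self.sequence[start : start + 3] != START_CODON:
                raise AnnotationError(f"{self.id}: CDS does not begin with AUG")
            if self.protein is not None:
                expected = translate(self.sequence[start : end - 3])
                if expected != self.protein:
                    raise AnnotationError(
                        f"{self.id}: protein does not match CDS translation "
                        f"({self.protein!r} vs {expected!r})"
                    )

    def regions(self) -> "RegionPartition":
        # local import keeps module dependencies one-directional
        from .interpretation import partition_regions

        return partition_regions(self)


@dataclass(frozen=True)
class OrfSpan:
    """An AUG-initiated, in-frame-stop-terminated open reading frame.

    ``[start, end)`` includes the stop codon; ``protein`` excludes it.
    """

    start: int
    end: int
    frame: int
    protein: str

    @property
    def n_nucleotides(self) -> int:
        return self.end - self.start


@dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int

    def as_dict(self) -> dict[str, list[str]]:
        return {"train": self.train, "validation": self.validation, "test": self.test}


def translate(sequence: str, frame_offset: int = 0) -> str:
    """Translate an RNA sequence with the standard genetic code.

    Translation starts at ``frame_offset`` and terminates at the first
    in-frame stop codon (which is not emitted). Trailing nucleotides that
    do not fill a codon are ignored.
    """
    seq = _normalize(sequence)
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    if len(seq) - frame_offset < 3:
        raise ValueError("fewer than one codon from the given offset")
    out = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            break
        out.append(CODON_TABLE[codon])
    return "".join(out)


def find_orfs(sequence: str) -> list[OrfSpan]:
    """All sense ORFs (AUG .. in-frame stop) in the three reading frames.

    Nested ORFs sharing a stop are all reported. Result is sorted by
    descending nucleotide length, ties broken by 5'-most start, then
    lowest frame index.
    """
    seq = _normalize(sequence)
    orfs: list[OrfSpan] = []
    for frame in range(3):
        # position of next in-frame stop, scanned once per frame
        i = frame
        starts: list[int] = []
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon == START_CODON:
                starts.append(i)
            if codon in STOP_CODONS and starts:
                for s in starts:
                    orfs.append(
                        OrfSpan(start=s, end=i + 3, frame=frame, protein=translate(seq[s : i]))
                    )
                starts = []
            i += 3
    orfs.sort(key=lambda o: (-o.n_nucleotides, o.start, o.frame))
    return orfs


def longest_orf(sequence: str) -> Optional[OrfSpan]:
    """Longest ORF by nucleotide length (ties: 5'-most start, lowest frame)."""
    orfs = find_orfs(sequence)
    return orfs[0] if orfs else None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["id", "label", "cds_start", "cds_end", "protein", "non_aug"]


def read_transcripts(fasta_path, annotation_path) -> list[Transcript]:
    """Read transcripts from FASTA plus the TSV annotation table.

    The annotation table has columns ``id, label, cds_start, cds_end,
    protein, non_aug`` (the last optional). Coding records must carry a
    CDS; a missing annotation row for any record is a hard error.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        return []
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"id": str}, keep_default_na=False)
    ann = ann.set_index("id")
    transcripts = []
    for rec in records:
        if rec.id not in ann.index:
            raise AnnotationError(f"no annotation row for FASTA record {rec.id!r}")
        row = ann.loc[rec.id]
        label = str(row["label"])
        cds = None
        protein = None
        if str(row.get("cds_start", "")) not in ("", "nan"):
            cds = (int(row["cds_start"]), int(row["cds_end"]))
        if str(row.get("protein", "")) not in ("", "nan"):
            protein = str(row["protein"])
        if label == PC and cds is None:
            raise AnnotationError(f"coding record {rec.id!r} lacks a CDS annotation")
        non_aug = bool(int(row["non_aug"])) if "non_aug" in ann.columns and str(row["non_aug"]) not in ("", "nan") else False
        transcripts.append(
            Transcript(
                id=rec.id,
                sequence=str(rec.seq),
                label=label,
                cds=cds,
                protein=protein,
                non_aug=non_aug,
            )
        )
    return transcripts


def write_transcripts(transcripts: Sequence[Transcript], fasta_path, annotation_path) -> None:
    """Write transcripts as FASTA + TSV; inverse of :func:`read_transcripts`."""
    recs = [SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts]
    SeqIO.write(recs, str(fasta_path), "fasta")
    rows = []
    for t in transcripts:
        rows.append(
            {
                "id": t.id,
                "label": t.label,
                "cds_start": "" if t.cds is None else t.cds[0],
                "cds_end": "" if t.cds is None else t.cds[1],
                "protein": t.protein or "",
                "non_aug": int(t.non_aug),
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(annotation_path, sep="\t", index=False)


def filter_by_length(
    transcripts: Iterable[Transcript], max_length: int = DEFAULT_MAX_LENGTH
) -> list[Transcript]:
    """Drop transcripts longer than ``max_length`` nucleotides."""
    return [t for t in transcripts if len(t) <= max_length]


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def make_splits(
    transcripts: Sequence[Transcript],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    bin_width: int = 100,
) -> DatasetSplit:
    """Class-balanced train/validation/test split with matched length histograms.

    The training portion is balanced between PC and NC, and the per-class
    length histograms (bins of ``bin_width`` nt) are matched greedily: within
    every length bin the two classes contribute ``min(count_PC, count_NC)``
    training records each, the surplus spilling into validation/test.
    Deterministic for a given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.RandomState(seed)
    by_class = {PC: [t for t in transcripts if t.label == PC], NC: [t for t in transcripts if t.label == NC]}
    n_total = len(transcripts)
    n_train = int(round(fractions[0] * n_total))
    n_train_per_class = n_train // 2
    if min(len(v) for v in by_class.values()) < n_train_per_class:
        warnings.warn(
            "not enough records in one class for a balanced training split; "
            "using best effort",
            stacklevel=2,
        )
        n_train_per_class = min(len(v) for v in by_class.values()) * fractions[0]
        n_train_per_class = int(n_train_per_class)

    # greedy per-bin matching of length histograms
    def bin_of(t: Transcript) -> int:
        return len(t) // bin_width

    bins: dict[int, dict[str, list[Transcript]]] = {}
    for label, items in by_class.items():
        items = list(items)
        rng.shuffle(items)
        for t in items:
            bins.setdefault(bin_of(t), {PC: [], NC: []})[label].append(t)

    train_ids: list[str] = []
    remainder: list[Transcript] = []
    quota = {PC: n_train_per_class, NC: n_train_per_class}
    for b in sorted(bins):
        matched = min(len(bins[b][PC]), len(bins[b][NC]))
        for label in (PC, NC):
            take = min(matched, quota[label])
            chosen = bins[b][label][:take]
            train_ids.extend(t.id for t in chosen)
            quota[label] -= take
            remainder.extend(bins[b][label][take:])
    # top up quotas from the remainder if bins were too uneven
    if quota[PC] or quota[NC]:
        rng.shuffle(remainder)
        rest = []
        for t in remainder:
            if quota[t.label] > 0:
                train_ids.append(t.id)
                quota[t.label] -= 1
            else:
                rest.append(t)
        remainder = rest

    rng.shuffle(remainder)
    n_val = int(round(fractions[1] * n_total))
    val_ids = [t.id for t in remainder[:n_val]]
    test_ids = [t.id for t in remainder[n_val:]]
    return DatasetSplit(train=sorted(train_ids), validation=sorted(val_ids), test=sorted(test_ids), seed=seed)


def length_histogram_discrepancy(
    transcripts: Sequence[Transcript], ids: Iterable[str], bin_width: int = 100
) -> int:
    """Max over length bins of the |PC − NC| count difference within ``ids``.

    A diagnostic for how well a split balanced the class length
    distributions (lower is better matched).
    """
    ids = set(ids)
    counts: dict[tuple[int, str], int] = {}
    for t in transcripts:
        if t.id in ids:
            key = (len(t) // bin_width, t.label)
            counts[key] = counts.get(key, 0) + 1
    bins = {b for b, _ in counts}
    return max(abs(counts.get((b, PC), 0) - counts.get((b, NC), 0)) for b in bins) if bins else 0
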