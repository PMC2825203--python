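"""Sequence domain types, FASTA I/O, polyA trimming, translation, ORF finding
and global pairwise alignment.

ESTs are treated as mRNA-sense throughout: the spliced leader (if any) sits at
the 5' end and the polyA tail at the 3' end, which is how 5'-oligo-capped,
oligo(dT)-primed cDNA libraries are oriented. Reverse-strand ORF scanning is
available behind a flag but off by default.

Coordinates are 1-based and inclusive at both ends, so positions can be read
directly against published residue/base numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
# 20 standard residues + U (selenocysteine) + X (unknown) + * (stop marker,
# never stored in ProteinSequence.residues but produced transiently).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYUX")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # TAA, TAG, TGA


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


@dataclass(frozen=True)
class NucleotideSequence:
    """One EST/cDNA read in mRNA sense."""

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.bases) - NUCLEOTIDE_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: invalid nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ProteinSequence:
    """A predicted protein. ``U`` marks selenocysteine from UGA read-through."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty protein sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrfAnnotation:
    """An ATG-initiated reading frame located on a (trimmed) EST.

    ``start`` is the 1-based position of the A of the initiator ATG; ``end``
    the 1-based position of the last base of the stop codon (inclusive), or of
    the last complete codon for an open-ended ORF.
    """

    start: int
    end: int
    frame: int
    strand: Literal["+", "-"]
    protein: ProteinSequence
    uga_readthroughs: int = 0
    has_stop: bool = True

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignmentResult:
    """A global (Needleman-Wunsch) pairwise alignment."""

    aligned_a: str
    aligned_b: str
    score: int
    identity_percent: float
    alignment_length: int


def read_fasta(
    path: str | Path, mode: Literal["nucleotide", "protein"] = "nucleotide"
) -> list[NucleotideSequence] | list[ProteinSequence]:
    """Read a multi-record FASTA file, preserving record order.

    Sequences are uppercased. A record whose sequence contains characters
    outside the declared alphabet raises :class:`AlphabetError` naming the
    record; duplicate ids raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        if mode == "nucleotide":
            records.append(NucleotideSequence(id=rec.id, bases=seq, description=desc))
        elif mode == "protein":
            records.append(ProteinSequence(id=rec.id, residues=seq, description=desc))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if not records:
        logger.warning("no records parsed from %s", path)
    return records


def write_fasta(records: Iterable[NucleotideSequence | ProteinSequence],
                path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.bases if isinstance(rec, NucleotideSequence) else rec.residues
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def trim_polya(
    seq: NucleotideSequence, min_run: int = 8
) -> tuple[NucleotideSequence, int]:
    """Remove the 3' polyA tail, returning ``(trimmed, polya_len)``.

    The tail is the longest suffix that starts and ends with A and contains at
    most one non-A per 10 bases (to absorb single base-calling errors inside
    a long tail). It is removed only when its length is at least ``min_run``;
    otherwise the sequence is returned unchanged with ``polya_len = 0``.
    The operation is idempotent: because a qualifying tail must end with A and
    trimming stops at a non-A (or consumes the whole read), a second call
    never finds a new tail.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    bases = seq.bases
    n = len(bases)
    best = 0  # length of best qualifying suffix
    non_a = 0
    if bases.endswith("A"):
        for length in range(1, n + 1):
            ch = bases[n - length]
            if ch != "A":
                non_a += 1
            # suffix must start with A and respect the error tolerance
            if ch == "A" and non_a <= length // 10:
                best = length
    if best < min_run:
        return seq, 0
    trimmed = bases[: n - best]
    if not trimmed:
        logger.warning("record %r is entirely polyA tail after trimming", seq.id)
        return _empty_nucleotide(seq.id, seq.description), best
    return NucleotideSequence(seq.id, trimmed, seq.description), best


def _empty_nucleotide(id_: str, description: str) -> NucleotideSequence:
    """Construct an empty NucleotideSequence (bypasses the non-empty check,
    which applies to parsed input, not to fully-trimmed degenerate reads)."""
    obj = object.__new__(NucleotideSequence)
    object.__setattr__(obj, "id", id_)
    object.__setattr__(obj, "bases", "")
    object.__setattr__(obj, "description", description)
    return obj


def translate(
    codons: str, readthrough_uga: int = 0, id: str = "translation"
) -> ProteinSequence:
    """Translate an in-frame nucleotide string by the standard genetic code.

    Translation stops at the first stop codon, except that up to
    ``readthrough_uga`` UGA codons are decoded as selenocysteine (``U``)
    before UGA is treated as stop — the behaviour of a ribosome reading
    through UGA at a selenocysteine insertion element. UAA/UAG always stop.
    Codons containing N translate as ``X``.
    """
    if len(codons) % 3 != 0:
        raise ValueError(f"sequence length {len(codons)} is not divisible by 3")
    codons = codons.upper()
    residues: list[str] = []
    remaining_uga = readthrough_uga
    for i in range(0, len(codons), 3):
        codon = codons[i:i + 3]
        if codon == "TGA" and remaining_uga > 0:
            residues.append("U")
            remaining_uga -= 1
            continue
        if codon in _STOP_CODONS:
            break
        if "N" in codon:
            residues.append("X")
            continue
        residues.append(_STANDARD_TABLE.forward_table[codon])
    return ProteinSequence(id=id, residues="".join(residues))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def find_longest_orf(
    seq: NucleotideSequence,
    require_atg: bool = True,
    forward_only: bool = True,
    readthrough_uga: int = 0,
    allow_open_end: bool = False,
) -> OrfAnnotation | None:
    """Find the ATG-initiated reading frame encoding the longest protein.

    All three frames on the forward strand are scanned (both strands when
    ``forward_only`` is false). An ORF runs from an ATG to the first in-frame
    stop codon, where up to ``readthrough_uga`` in-frame UGA codons are read
    through as selenocysteine before UGA terminates. ORFs reaching the
    sequence end without a stop are eligible only when ``allow_open_end``.
    Ties on protein length are broken by smaller start position (forward
    strand preferred over reverse).

    Returns ``None`` when no qualifying ORF exists.
    """
    candidates: list[OrfAnnotation] = []
    strands = [("+", seq.bases)]
    if not forward_only:
        strands.append(("-", reverse_complement(seq.bases)))
    n = len(seq.bases)
    for strand, bases in strands:
        for frame in range(3):
            candidates.extend(
                _scan_frame(seq.id, bases, frame, strand, require_atg,
                            readthrough_uga, allow_open_end)
            )
    if not candidates:
        return None

    def sort_key(orf: OrfAnnotation):
        # longest protein first; then forward strand; then smallest start
        return (-len(orf.protein), orf.strand != "+", orf.start)

    best = min(candidates, key=sort_key)
    if best.strand == "-":
        # map coordinates back onto the forward strand
        start = n - best.end + 1
        end = n - best.start + 1
        best = OrfAnnotation(start=start, end=end, frame=best.frame,
                             strand="-", protein=best.protein,
                             uga_readthroughs=best.uga_readthroughs,
                             has_stop=best.has_stop)
    return best


def _scan_frame(
    seq_id: str, bases: str, frame: int, strand: str, require_atg: bool,
    readthrough_uga: int, allow_open_end: bool,
) -> list[OrfAnnotation]:
    orfs: list[OrfAnnotation] = []
    n = len(bases)
    for i in range(frame, n - 2, 3):
        codon = bases[i:i + 3]
        if require_atg and codon != "ATG":
            continue
        # extend from this start to the terminating stop
        remaining_uga = readthrough_uga
        j = i
        terminated = False
        uga_used = 0
        while j + 3 <= n:
            c = bases[j:j + 3]
            if c in _STOP_CODONS and not (c == "TGA" and remaining_uga > 0):
                terminated = True
                break
            if c == "TGA":
                remaining_uga -= 1
                uga_used += 1
            j += 3
        if terminated:
            end = j + 3  # include the stop codon
            coding = bases[i:end]
        elif allow_open_end:
            end = j
            coding = bases[i:end]
            if not coding:
                continue
        else:
            continue
        protein = translate(coding, readthrough_uga=uga_used, id=seq_id)
        if len(protein.residues) == 0:
            continue
        orfs.append(OrfAnnotation(
            start=i + 1, end=end, frame=frame, strand=strand,  # 1-based incl.
            protein=protein, uga_readthroughs=uga_used, has_stop=terminated,
        ))
    return orfs


def global_align(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -1
) -> AlignmentResult:
    """Optimal global alignment under linear match/mismatch/gap scores.

    Needleman-Wunsch with deterministic traceback: at score ties the move
    preference is diagonal, then up (consume ``a``), then left (consume
    ``b``). Identity is 100 x matches / alignment length; an empty-vs-empty
    alignment has identity 0 by convention.
    """
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    S = np.empty((n + 1, m + 1), dtype=np.int64)
    S[0, :] = np.arange(m + 1) * gap
    S[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        row_prev = S[i - 1]
        row = S[i]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = row_prev[j] + gap
            left = row[j - 1] + gap
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            row[j] = best
    # traceback, diagonal > up > left on ties
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = S[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            if S[i, j] == diag:
                out_a.append(a[i - 1]); out_b.append(b[j - 1])
                i -= 1; j -= 1
                continue
        if i > 0 and S[i, j] == S[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append("-")
            i -= 1
            continue
        out_a.append("-"); out_b.append(b[j - 1])
        j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    length = len(aligned_a)
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    identity = 100.0 * matches / length if length else 0.0
    return AlignmentResult(
        aligned_a=aligned_a, aligned_b=aligned_b, score=int(S[n, m]),
        identity_percent=identity, alignment_length=length,
    )
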