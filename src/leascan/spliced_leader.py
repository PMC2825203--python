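"""Spliced-leader detection and family assignment.

Nematode mRNAs frequently begin with a short (~22 nt) spliced leader (SL)
added by trans-splicing. *A. avenae* transcripts carry a remarkably
polymorphic set of leaders: four SL1 variants (SL1a-d) plus eight further
variants, several of which resemble the *C. elegans* SL2 family associated
with downstream operon genes. The default catalogue embeds those 12 leaders
together with the canonical *C. elegans* SL1 and SL2 reference sequences.

Detection is a mismatch-tolerant prefix scan of an EST's 5' end; family
assignment of a variant leader is by global alignment against the two
canonical leaders (higher score wins).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal

from .seq_records import AlignmentResult, NucleotideSequence, global_align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SLEntry:
    name: str
    sequence: str
    family: Literal["SL1", "SL2", "unassigned"]
    organism: str


@dataclass(frozen=True)
class SLCatalogue:
    entries: tuple[SLEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate names in SL catalogue")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> SLEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"no catalogue entry named {name!r}")

    def canonical(self, family: str) -> SLEntry:
        """The canonical C. elegans reference leader for a family."""
        for e in self.entries:
            if e.name == family:
                return e
        raise KeyError(f"no canonical entry for family {family!r}")


@dataclass(frozen=True)
class SLMatch:
    """A spliced-leader hit at an EST 5' end."""

    name: str
    offset: int          # 0-based start of the leader within the EST
    mismatches: int
    matched_length: int


@dataclass(frozen=True)
class FamilyAssignment:
    """SL1-vs-SL2 family call for a variant leader."""

    variant: str
    score_sl1: int
    score_sl2: int
    family: Literal["SL1", "SL2", "ambiguous"]


def load_catalogue(path: str | Path) -> SLCatalogue:
    """Load a catalogue from a TSV file (name, sequence, family, organism)."""
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        entries = tuple(
            SLEntry(name=row["name"], sequence=row["sequence"].upper(),
                    family=row["family"], organism=row.get("organism", ""))
            for row in reader
        )
    return SLCatalogue(entries=entries)


@lru_cache(maxsize=1)
def load_default_catalogue() -> SLCatalogue:
    """The built-in catalogue: 12 *A. avenae* leaders + canonical SL1/SL2."""
    with resources.as_file(
        resources.files("leascan.data") / "sl_catalogue.tsv"
    ) as path:
        return load_catalogue(path)


def detect_sl(
    est: NucleotideSequence,
    catalogue: SLCatalogue | None = None,
    max_mismatch: int = 2,
    max_offset: int = 3,
) -> SLMatch | None:
    """Best spliced-leader prefix match at the 5' end of an EST.

    Every catalogue entry is tried at offsets 0..max_offset; candidates are
    ranked by (fewest mismatches, smallest offset, catalogue order). Returns
    ``None`` when no entry matches within the thresholds.
    """
    catalogue = catalogue or load_default_catalogue()
    best: tuple[int, int, int] | None = None
    best_match: SLMatch | None = None
    for order, entry in enumerate(catalogue):
        sl = entry.sequence
        for offset in range(0, max_offset + 1):
            segment = est.bases[offset:offset + len(sl)]
            if len(segment) < len(sl):
                continue
            mismatches = sum(a != b for a, b in zip(sl, segment))
            if mismatches > max_mismatch:
                continue
            key = (mismatches, offset, order)
            if best is None or key < best:
                best = key
                best_match = SLMatch(name=entry.name, offset=offset,
                                     mismatches=mismatches,
                                     matched_length=len(sl))
    return best_match


def classify_family(
    variant: str,
    catalogue: SLCatalogue | None = None,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -1,
    name: str = "variant",
) -> FamilyAssignment:
    """Assign a variant leader to the SL1 or SL2 family by global alignment
    against the canonical *C. elegans* leaders; ties are ``ambiguous``."""
    variant = variant.upper()
    if not 15 <= len(variant) <= 30:
        raise ValueError(f"variant length {len(variant)} outside [15, 30]")
    catalogue = catalogue or load_default_catalogue()
    sl1 = catalogue.canonical("SL1").sequence
    sl2 = catalogue.canonical("SL2").sequence
    s1 = global_align(variant, sl1, match, mismatch, gap).score
    s2 = global_align(variant, sl2, match, mismatch, gap).score
    if s1 > s2:
        family = "SL1"
    elif s2 > s1:
        family = "SL2"
    else:
        family = "ambiguous"
    return FamilyAssignment(variant=name, score_sl1=s1, score_sl2=s2,
                            family=family)


def strip_sl(est: NucleotideSequence, match: SLMatch) -> NucleotideSequence:
    """Return the EST downstream of a matched leader.

    Bases upstream of the match offset (at most ``max_offset`` of them) are
    removed too, with a log message.
    """
    end = match.offset + match.matched_length
    if end > len(est.bases):
        raise ValueError(
            f"match extends past the end of record {est.id!r} "
            f"({end} > {len(est.bases)})")
    if match.offset:
        logger.info("record %r: removing %d bases upstream of the leader",
                    est.id, match.offset)
    return NucleotideSequence(est.id, est.bases[end:], est.description)


def candidate_novel_leader(
    est: NucleotideSequence,
    catalogue: SLCatalogue | None = None,
    min_len: int = 20,
    max_len: int = 24,
    score_fraction: float = 0.60,
) -> AlignmentResult | None:
    """Flag a possible novel leader: a 5'-terminal 20-24-mer ending in AG that
    aligns to either canonical leader at >= ``score_fraction`` of its
    self-alignment score. Reported as a candidate only; never added to the
    catalogue automatically."""
    catalogue = catalogue or load_default_catalogue()
    best: AlignmentResult | None = None
    for length in range(min_len, max_len + 1):
        prefix = est.bases[:length]
        if len(prefix) < length or not prefix.endswith("AG"):
            continue
        for family in ("SL1", "SL2"):
            canon = catalogue.canonical(family).sequence
            self_score = global_align(canon, canon).score
            res = global_align(prefix, canon)
            if res.score >= score_fraction * self_score:
                if best is None or res.score > best.score:
                    best = res
    return best


def matches_to_tsv(matches: list[tuple[str, SLMatch | None]]) -> str:
    """Render per-record SL matches as TSV."""
    lines = ["record\tsl_name\toffset\tmismatches\tmatched_length"]
    for rec_id, m in matches:
        if m is None:
            lines.append(f"{rec_id}\tnone\t\t\t")
        else:
            lines.append(f"{rec_id}\t{m.name}\t{m.offset}\t{m.mismatches}\t"
                         f"{m.matched_length}")
    return "\n".join(lines) + "\n"
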