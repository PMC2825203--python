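"""Amino-acid periodicity detection.

A residue "recurs with period p" when it occupies positions forming an
arithmetic chain with common difference p: in the peptide GAGPG the glycines
at positions 1, 3, 5 form a period-2 run. Group 3 LEA proteins characteristically
show lysines recurring every 11 residues (K11 periodicity), often as several
interlaced runs in different phases.

Runs are reported **maximal**: a run cannot be extended by another occurrence
of the same residue at (first - p) or (last + p). Interlaced runs with the
same period but different phases are therefore reported separately and never
share positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seq_records import ProteinSequence

logger = logging.getLogger(__name__)

LEA_PERIOD = 11


@dataclass(frozen=True)
class PeriodicRun:
    """A maximal arithmetic chain of one residue type (1-based positions)."""

    residue: str
    period: int
    positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.positions)

    def __post_init__(self) -> None:
        diffs = {b - a for a, b in zip(self.positions, self.positions[1:])}
        if diffs and diffs != {self.period}:
            raise ValueError("positions are not an arithmetic chain of the period")


def find_periodic_runs(
    p: ProteinSequence,
    period: int,
    min_run: int = 3,
    residue: str | None = None,
) -> list[PeriodicRun]:
    """All maximal period-``period`` runs of length >= ``min_run``.

    ``residue`` restricts the search to one residue type; ``None`` considers
    every residue type present. Runs are sorted by (residue, first position).
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if period >= len(p):
        logger.warning("period %d >= protein length %d; no runs possible",
                       period, len(p))
        return []
    targets = [residue] if residue else sorted(set(p.residues))
    runs: list[PeriodicRun] = []
    for res in targets:
        occ = {i + 1 for i, r in enumerate(p.residues) if r == res}
        for start in sorted(occ):
            if start - period in occ:
                continue  # not the head of a maximal chain
            chain = [start]
            nxt = start + period
            while nxt in occ:
                chain.append(nxt)
                nxt += period
            if len(chain) >= min_run:
                runs.append(PeriodicRun(res, period, tuple(chain)))
    runs.sort(key=lambda r: (r.residue, r.positions[0]))
    return runs


@dataclass(frozen=True)
class K11Summary:
    """Aggregate of period-11 runs in one protein."""

    n_runs: int
    n_lysine_runs: int
    covered: tuple[int, ...]  # all positions participating in any run


def k11_summary(p: ProteinSequence, min_run: int = 3) -> K11Summary:
    """Summarise 11-residue periodicity, the Group 3 LEA signature."""
    runs = find_periodic_runs(p, period=LEA_PERIOD, min_run=min_run)
    covered = sorted({pos for run in runs for pos in run.positions})
    return K11Summary(
        n_runs=len(runs),
        n_lysine_runs=sum(1 for r in runs if r.residue == "K"),
        covered=tuple(covered),
    )


def runs_to_tsv(runs: list[PeriodicRun]) -> str:
    """Render runs as TSV (residue, period, start, length, positions)."""
    lines = ["residue\tperiod\tstart\tlength\tpositions"]
    for r in runs:
        lines.append(
            f"{r.residue}\t{r.period}\t{r.positions[0]}\t{r.length}\t"
            + ",".join(map(str, r.positions))
        )
    return "\n".join(lines) + "\n"
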