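"""Rule-based LEA protein classification and the per-EST characterisation
report.

Group 3 LEA (late embryogenesis abundant) proteins are extremely hydrophilic,
natively unfolded stress proteins with a characteristic 11-residue lysine
periodicity, and typically lack cysteine and tryptophan. The classifier
codifies those lines of evidence as an explicit rule cascade:

* ``group3_lea`` — hydrophilic (GRAVY below the threshold, default −0.43, the
  GRAVY of bovine serum albumin) AND charge-hydropathy unfolded AND at least
  one period-11 lysine run AND no Cys/Trp;
* ``lea_like`` — hydrophilic AND unfolded (but missing the K11 or Cys/Trp
  evidence);
* ``hydrophilic_novel`` — hydrophilic OR largely disordered (> 50 percent of
  residues in negative-index windows);
* ``not_lea_like`` — none of the above.

All thresholds are strict inequalities and exposed in :class:`LeaCriteria`.
Compositional (POPP-style) clustering evidence is outside this cascade and is
recorded as "not evaluated" in the evidence list.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Literal

import pandas as pd

from . import periodicity, physchem, spliced_leader
from .disorder import FoldIndexProfile, UverskyPoint, foldindex_profile, uversky_classify
from .periodicity import K11Summary
from .physchem import PhyschemProfile
from .seq_records import NucleotideSequence, find_longest_orf, trim_polya

logger = logging.getLogger(__name__)

Label = Literal["group3_lea", "lea_like", "hydrophilic_novel", "not_lea_like"]


@dataclass(frozen=True)
class LeaCriteria:
    """Thresholds of the classification cascade (all strict inequalities)."""

    gravy_max: float = -0.43          # GRAVY of bovine serum albumin
    disorder_min_percent: float = 50.0
    min_k11_lysine_runs: int = 1
    forbid_cys_trp: bool = True

    def __post_init__(self) -> None:
        if self.gravy_max >= 0:
            raise ValueError("gravy_max must be negative")
        if not 0 < self.disorder_min_percent < 100:
            raise ValueError("disorder_min_percent must be in (0, 100)")


@dataclass(frozen=True)
class LeaClassification:
    label: Label
    evidence: tuple[str, ...]


def flag_hydrophilic_novel(
    gravy: float, percent_disorder: float, criteria: LeaCriteria = LeaCriteria()
) -> bool:
    """Hydrophilic/disordered screening rule: GRAVY strictly below the
    threshold OR percent disorder strictly above it."""
    return (gravy < criteria.gravy_max
            or percent_disorder > criteria.disorder_min_percent)


def classify_lea(
    profile: PhyschemProfile,
    uversky: UverskyPoint,
    foldindex: FoldIndexProfile,
    k11: K11Summary,
    criteria: LeaCriteria = LeaCriteria(),
) -> LeaClassification:
    """Apply the rule cascade to one protein's computed evidence."""
    hydrophilic = profile.gravy < criteria.gravy_max
    unfolded = uversky.classification == "unfolded"
    k11_ok = k11.n_lysine_runs >= criteria.min_k11_lysine_runs
    no_cw = not (profile.has_cys or profile.has_trp)
    disordered = foldindex.percent_disorder > criteria.disorder_min_percent

    evidence = (
        f"gravy={profile.gravy:.2f} {'<' if hydrophilic else '>='} "
        f"{criteria.gravy_max} ({'pass' if hydrophilic else 'fail'})",
        f"uversky={uversky.classification} "
        f"({'pass' if unfolded else 'fail'})",
        f"k11_lysine_runs={k11.n_lysine_runs} "
        f"({'pass' if k11_ok else 'fail'})",
        f"cys_trp={'absent' if no_cw else 'present'} "
        f"({'pass' if no_cw else 'fail'})",
        f"percent_disorder={foldindex.percent_disorder:.0f} "
        f"({'pass' if disordered else 'fail'})",
        "compositional_clustering=not evaluated",
    )
    if hydrophilic and unfolded and k11_ok and (no_cw or not criteria.forbid_cys_trp):
        label: Label = "group3_lea"
    elif hydrophilic and unfolded:
        label = "lea_like"
    elif flag_hydrophilic_novel(profile.gravy, foldindex.percent_disorder, criteria):
        label = "hydrophilic_novel"
    else:
        label = "not_lea_like"
    return LeaClassification(label=label, evidence=evidence)


REPORT_COLUMNS = [
    "id", "status", "sl_name", "sl_mismatches", "cdna_len_with_sl",
    "cdna_len_no_sl", "polya_len", "protein_len", "mr", "pi", "gravy",
    "mean_scaled_hydropathy", "mean_net_charge", "uversky_class",
    "percent_disorder", "k11_runs", "k11_lysine_runs", "label",
]


def characterise_protein(protein, criteria: LeaCriteria = LeaCriteria(),
                         foldindex_window: int = 51):
    """Profile + classify one protein; returns all intermediate evidence."""
    prof = physchem.physchem_profile(protein)
    upoint = uversky_classify(prof.mean_scaled_hydropathy, prof.mean_net_charge)
    fidx = foldindex_profile(protein, window=foldindex_window)
    k11 = periodicity.k11_summary(protein)
    cls = classify_lea(prof, upoint, fidx, k11, criteria)
    return prof, upoint, fidx, k11, cls


def characterise(
    ests: list[NucleotideSequence],
    criteria: LeaCriteria = LeaCriteria(),
    catalogue: spliced_leader.SLCatalogue | None = None,
    min_polya: int = 8,
    readthrough_uga: int = 0,
    foldindex_window: int = 51,
) -> pd.DataFrame:
    """Run the full per-EST characterisation and return one row per record.

    Pipeline per EST: trim polyA -> detect/strip spliced leader -> longest
    ORF -> physicochemical profile -> disorder -> K11 periodicity -> LEA
    rule cascade. Per-record failures are reported in the ``status`` column
    and never abort the batch. Row order equals input order; cDNA length is
    reported both with and without the spliced leader, since published
    transcript lengths may follow either convention.
    """
    catalogue = catalogue or spliced_leader.load_default_catalogue()
    rows = []
    for est in ests:
        row = {c: None for c in REPORT_COLUMNS}
        row["id"] = est.id
        try:
            trimmed, polya_len = trim_polya(est, min_run=min_polya)
            row["polya_len"] = polya_len
            row["cdna_len_with_sl"] = len(trimmed.bases)
            if not trimmed.bases:
                row["status"] = "empty after polyA trim"
                rows.append(row)
                continue
            match = catalogue and spliced_leader.detect_sl(trimmed, catalogue)
            if match is not None:
                row["sl_name"] = match.name
                row["sl_mismatches"] = match.mismatches
                body = spliced_leader.strip_sl(trimmed, match)
            else:
                row["sl_name"] = "none"
                body = trimmed
            row["cdna_len_no_sl"] = len(body.bases)
            orf = find_longest_orf(body, readthrough_uga=readthrough_uga)
            if orf is None:
                row["status"] = "no ORF"
                rows.append(row)
                continue
            prof, upoint, fidx, k11, cls = characterise_protein(
                orf.protein, criteria, foldindex_window)
            row.update(
                status="ok",
                protein_len=prof.length,
                mr=round(prof.mr, 1),
                pi=round(prof.pi, 2),
                gravy=round(prof.gravy, 3),
                mean_scaled_hydropathy=round(prof.mean_scaled_hydropathy, 4),
                mean_net_charge=round(prof.mean_net_charge, 4),
                uversky_class=upoint.classification,
                percent_disorder=round(fidx.percent_disorder, 1),
                k11_runs=k11.n_runs,
                k11_lysine_runs=k11.n_lysine_runs,
                label=cls.label,
            )
        except Exception as exc:  # per-record failures must not abort the batch
            logger.error("record %r failed: %s", est.id, exc)
            row["status"] = f"error: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


@lru_cache(maxsize=1)
def load_novel_est_table() -> pd.DataFrame:
    """Published physicochemical parameters of the 12 novel dehydration-
    induced *A. avenae* ESTs (protein length, pI, GRAVY, percent disorder);
    the standing regression input for :func:`flag_hydrophilic_novel`."""
    with resources.as_file(
        resources.files("leascan.data") / "novel_est_table2.tsv"
    ) as path:
        return pd.read_csv(path, sep="\t", comment="#")
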