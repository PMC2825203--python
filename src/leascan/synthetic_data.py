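"""Seeded generators for synthetic ESTs and proteins with known ground truth.

The generator emulates the anatomy of an oriented, 5'-oligo-capped nematode
EST: an optional 21-23 nt spliced leader, a short 5' UTR, an ATG-initiated
ORF back-translated from a designed protein (optionally with internal UGA
selenocysteine codons), a 3' UTR and a polyA tail. Proteins are built
strictly inside (never on) the classifier thresholds they target — GRAVY at
least 0.2 below the hydrophilicity cutoff, disorder well away from the 50%
line — so classification recovery from generated data must be exact.

Everything is deterministic given (spec, seed): generation draws integers
from one ``numpy.random.default_rng`` stream in a fixed order, and every
self-check failure consumes further draws from the same stream, so repeated
calls yield byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import lea_classifier, periodicity, physchem, spliced_leader
from .disorder import foldindex_profile, uversky_classify
from .seq_records import (NucleotideSequence, ProteinSequence, find_longest_orf,
                          translate, trim_polya, write_fasta)

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_CODONS_FOR["U"] = ["TGA"]  # selenocysteine by UGA read-through

_MAX_RETRIES = 50

# Hydrophilic background pool for LEA-like proteins: no K (reserved for the
# planted period-11 runs), no C/W (Group 3 LEA proteins typically lack them).
_HYDROPHILIC_POOL = np.array(list("DENQRSTH"))
_HYDROPHILIC_WEIGHTS = np.array([4, 4, 2, 2, 6, 1, 1, 1], dtype=float)
_HYDROPHILIC_WEIGHTS /= _HYDROPHILIC_WEIGHTS.sum()

# Hydrophobic pool for globular decoys (no K, no ionisable excess).
_GLOBULAR_POOL = np.array(list("ILVFAMGTS"))
_GLOBULAR_WEIGHTS = np.array([3, 3, 3, 2, 2, 1, 1, 1, 1], dtype=float)
_GLOBULAR_WEIGHTS /= _GLOBULAR_WEIGHTS.sum()


@dataclass(frozen=True)
class ProteinSpec:
    """Recipe for a LEA-like protein with planted K11 runs."""

    length: int = 85
    n_k11_runs: int = 2
    hydrophilic_bias: float = -1.0  # target GRAVY ceiling
    include_cys_trp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_k11_runs and self.length < 2 + (self.n_k11_runs - 1) + 22 + 1:
            raise ValueError(
                f"{self.n_k11_runs} period-11 runs of length 3 do not fit in "
                f"{self.length} residues")
        if self.n_k11_runs > 11:
            raise ValueError("at most 11 interlaced period-11 phases exist")


@dataclass(frozen=True)
class ESTSpec:
    """Recipe for one synthetic EST."""

    sl_name: str | None = "SL1c"
    utr5_len: int = 30
    utr3_len: int = 50
    protein: ProteinSpec | ProteinSequence = field(default_factory=ProteinSpec)
    polya_len: int = 15
    n_uga_readthrough_codons: int = 0
    seed: int = 0


@dataclass(frozen=True)
class ManifestEntry:
    """Ground truth for one generated EST."""

    id: str
    class_label: str
    sl_name: str
    polya_len: int
    orf_start: int   # 1-based, within the SL-stripped, polyA-trimmed body
    orf_end: int     # inclusive, covers the stop codon
    protein: str
    n_uga: int
    seed: int


def _sample_background(rng: np.random.Generator, n: int,
                       pool: np.ndarray, weights: np.ndarray) -> list[str]:
    idx = rng.choice(len(pool), size=n, p=weights)
    return [str(pool[i]) for i in idx]


def make_lea_like_protein(spec: ProteinSpec) -> ProteinSequence:
    """A hydrophilic, disordered protein with exactly ``n_k11_runs`` maximal
    period-11 lysine chains (length 3, interlaced in adjacent phases).

    The generated protein is verified against its own spec — GRAVY strictly
    below ``hydrophilic_bias``, charge-hydropathy unfolded, exact K11 run
    count — and resampled (bounded retries) on failure.
    """
    rng = np.random.default_rng(spec.seed)
    planted = []
    for j in range(spec.n_k11_runs):
        start = 2 + j  # 1-based; adjacent phases interlace without merging
        planted.extend([start, start + 11, start + 22])
    planted_set = set(planted)
    for attempt in range(_MAX_RETRIES):
        residues = _sample_background(rng, spec.length, _HYDROPHILIC_POOL,
                                      _HYDROPHILIC_WEIGHTS)
        residues[0] = "M"  # translation-ready: position 1 is the initiator
        for pos in planted_set:
            residues[pos - 1] = "K"
        if spec.include_cys_trp:
            free = [i for i in range(1, spec.length) if i + 1 not in planted_set]
            ci, wi = rng.choice(free, size=2, replace=False)
            residues[ci] = "C"
            residues[wi] = "W"
        protein = ProteinSequence(id=f"synthetic-lea-{spec.seed}",
                                  residues="".join(residues))
        g = physchem.gravy(protein)
        h, r = physchem.uversky_coordinates(protein)
        unfolded = uversky_classify(h, r).classification == "unfolded"
        k11 = periodicity.k11_summary(protein)
        if (g < spec.hydrophilic_bias and unfolded
                and k11.n_lysine_runs == spec.n_k11_runs):
            return protein
    raise RuntimeError(f"could not satisfy {spec} in {_MAX_RETRIES} attempts")


def make_globular_protein(length: int = 85, seed: int = 0) -> ProteinSequence:
    """A hydrophobic, folded decoy protein (GRAVY > 0, no lysines)."""
    if length < 20:
        raise ValueError("length must be >= 20")
    rng = np.random.default_rng(seed)
    for attempt in range(_MAX_RETRIES):
        chars = _sample_background(rng, length, _GLOBULAR_POOL,
                                   _GLOBULAR_WEIGHTS)
        chars[0] = "M"  # translation-ready
        protein = ProteinSequence(id=f"synthetic-globular-{seed}",
                                  residues="".join(chars))
        g = physchem.gravy(protein)
        h, r = physchem.uversky_coordinates(protein)
        if g > 0 and uversky_classify(h, r).classification == "folded":
            return protein
    raise RuntimeError("could not generate a globular protein")


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


_NT = np.array(list("ACGT"))


def _random_utr(rng: np.random.Generator, n: int) -> str:
    """Random UTR sequence with every ATG occurrence broken."""
    seq = list(_NT[rng.integers(4, size=n)])
    s = "".join(seq)
    while "ATG" in s:
        i = s.index("ATG")
        seq[i + 1] = "C"
        s = "".join(seq)
    return s


def make_est(spec: ESTSpec) -> tuple[NucleotideSequence, ManifestEntry]:
    """Assemble one synthetic EST and its ground-truth manifest entry.

    Layout: [SL] + UTR5 + ATG...stop + UTR3 + polyA. The ORF is a uniform
    seeded back-translation of the protein; ``n_uga_readthrough_codons``
    extra selenocysteine (U) residues are inserted at internal positions and
    encoded as UGA. The assembled EST is verified post hoc: polyA trimming
    recovers ``polya_len`` exactly, SL detection returns the planted leader
    with zero mismatches, and the longest ORF decodes to exactly the planted
    protein; offending UTRs are resampled (bounded retries).
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.protein, ProteinSpec):
        base_protein = make_lea_like_protein(spec.protein)
    else:
        base_protein = spec.protein
    residues = base_protein.residues
    n_uga = spec.n_uga_readthrough_codons
    if n_uga:
        # internal positions only: never first or last residue
        slots = rng.choice(np.arange(1, len(residues)), size=n_uga,
                           replace=False)
        chars = list(residues)
        for s in sorted(slots, reverse=True):
            chars.insert(int(s), "U")
        residues = "".join(chars)
    protein = ProteinSequence(base_protein.id, residues)

    sl_seq = ""
    sl_name = "none"
    if spec.sl_name:
        cat_entry = spliced_leader.load_default_catalogue().get(spec.sl_name)
        sl_seq, sl_name = cat_entry.sequence, cat_entry.name

    if not protein.residues.startswith("M"):
        raise ValueError("EST proteins must be Met-initiated (ATG start codon)")
    for attempt in range(_MAX_RETRIES):
        orf_nt = _back_translate(protein.residues, rng)  # M encodes the ATG
        stop = ["TAA", "TAG"][rng.integers(2)]  # TGA reserved for readthrough
        utr5 = _random_utr(rng, spec.utr5_len)
        utr3 = _random_utr(rng, spec.utr3_len)
        bases = sl_seq + utr5 + orf_nt + stop + utr3 + "A" * spec.polya_len
        est = NucleotideSequence(id=f"synthetic-est-{spec.seed}", bases=bases)

        trimmed, polya = trim_polya(est)
        if polya != spec.polya_len:
            continue
        if spec.sl_name:
            m = spliced_leader.detect_sl(trimmed)
            if m is None or m.name != sl_name or m.mismatches or m.offset:
                continue
            body = spliced_leader.strip_sl(trimmed, m)
        else:
            body = trimmed
        orf = find_longest_orf(body, readthrough_uga=n_uga)
        expected_start = spec.utr5_len + 1
        expected_end = expected_start + 3 * (len(protein.residues) + 1) - 1
        if (orf is None or orf.start != expected_start
                or orf.end != expected_end
                or orf.protein.residues != protein.residues):
            continue
        entry = ManifestEntry(
            id=est.id, class_label="", sl_name=sl_name,
            polya_len=spec.polya_len, orf_start=expected_start,
            orf_end=expected_end, protein=protein.residues,
            n_uga=n_uga, seed=spec.seed,
        )
        return est, entry
    raise RuntimeError(f"could not assemble an EST for {spec} "
                       f"in {_MAX_RETRIES} attempts")


def _make_no_orf_decoy(seed: int, polya_len: int,
                       body_len: int = 300) -> NucleotideSequence:
    """A decoy EST with no ATG anywhere (hence no ORF), no spliced leader,
    and an exactly recoverable polyA tail; verified post hoc and resampled
    deterministically on failure."""
    rng = np.random.default_rng(seed)
    for attempt in range(_MAX_RETRIES):
        # GCT spacer keeps the tail's boundary non-A without forming ATG
        bases = _random_utr(rng, body_len - 3) + "GCT" + "A" * polya_len
        est = NucleotideSequence(id=f"synthetic-est-{seed}", bases=bases)
        trimmed, pa = trim_polya(est)
        if pa != polya_len:
            continue
        if spliced_leader.detect_sl(trimmed) is not None:
            continue
        if find_longest_orf(trimmed) is not None:
            continue
        return est
    raise RuntimeError("could not generate a no-ORF decoy")


DEFAULT_CLASS_WEIGHTS = {"group3_lea": 0.4, "not_lea_like": 0.4, "no_orf": 0.2}


def make_est_collection(
    n: int,
    class_weights: dict[str, float] | None = None,
    seed: int = 0,
    out_fasta: str | Path | None = None,
    out_manifest: str | Path | None = None,
) -> tuple[list[NucleotideSequence], pd.DataFrame]:
    """A seeded mixture of LEA-like, globular and no-ORF decoy ESTs.

    Returns the records and a ground-truth manifest (one row per record);
    optionally writes them as FASTA and TSV. Class proportions follow a
    seeded multinomial draw over ``class_weights``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    weights = class_weights or DEFAULT_CLASS_WEIGHTS
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class weights must sum to 1 (got {total})")
    rng = np.random.default_rng(seed)
    classes = list(weights)
    draws = rng.choice(len(classes), size=n, p=[weights[c] for c in classes])
    sl_names = [e.name for e in spliced_leader.load_default_catalogue()
                if e.organism == "Aphelenchus avenae"]

    records: list[NucleotideSequence] = []
    entries: list[dict] = []
    for i, ci in enumerate(draws):
        cls = classes[ci]
        rec_seed = int((seed * 100003 + 7919 * i + 1) % (2 ** 31))
        length = int(rng.integers(60, 121))
        sl = sl_names[int(rng.integers(len(sl_names)))]
        polya = int(rng.integers(10, 26))
        if cls == "group3_lea":
            pspec = ProteinSpec(length=max(length, 40), n_k11_runs=2,
                                seed=rec_seed)
            espec = ESTSpec(sl_name=sl, protein=pspec, polya_len=polya,
                            seed=rec_seed)
            est, entry = make_est(espec)
        elif cls == "not_lea_like":
            protein = make_globular_protein(length=length, seed=rec_seed)
            espec = ESTSpec(sl_name=sl, protein=protein, polya_len=polya,
                            seed=rec_seed)
            est, entry = make_est(espec)
        elif cls == "no_orf":
            est = _make_no_orf_decoy(rec_seed, polya)
            entry = ManifestEntry(id=est.id, class_label=cls, sl_name="none",
                                  polya_len=polya, orf_start=0, orf_end=0,
                                  protein="", n_uga=0, seed=rec_seed)
        else:
            raise ValueError(f"unknown class {cls!r}")
        est = NucleotideSequence(id=f"syn{i:04d}", bases=est.bases)
        entry_dict = entry.__dict__ | {"id": est.id, "class_label": cls}
        records.append(est)
        entries.append(entry_dict)
    manifest = pd.DataFrame(entries)
    if out_fasta:
        write_fasta(records, out_fasta)
    if out_manifest:
        manifest.to_csv(out_manifest, sep="\t", index=False)
    return records, manifest
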