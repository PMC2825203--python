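"""Per-protein physicochemical scalars.

Two hydropathy systems deliberately coexist:

* GRAVY (grand average of hydropathy) uses the **Eisenberg normalised
  consensus** scale, which avoids some well-known anomalies of the
  Kyte-Doolittle scale for highly hydrophilic proteins.
* The charge-hydropathy ("Uversky") plot coordinates use **Kyte-Doolittle
  rescaled to [0, 1]** by (h + 4.5) / 9 with a short smoothing window —
  the convention of the charge-hydropathy disorder predictors.

Both scales, and the pKa tables behind net charge and pI, ship as plain-text
data files under ``leascan/data`` and are selectable by name.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .seq_records import ProteinSequence

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Average (not monoisotopic) residue masses in Da; free protein = sum + water.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    # selenocysteine, C3H5NOSe
    "U": 150.0489,
}
WATER_MASS = 18.01524


@dataclass(frozen=True)
class HydropathyScale:
    """A named per-residue hydropathy table (all 20 standard residues)."""

    name: str
    values: dict[str, float]
    # how selenocysteine maps onto the 20-residue scale
    u_as: str = "C"

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        if residue == "U":
            residue = self.u_as
        return self.values[residue]


@dataclass(frozen=True)
class PhyschemProfile:
    """Scalar summary of one protein, mirroring a per-EST report row."""

    length: int
    mr: float
    pi: float
    gravy: float
    mean_scaled_hydropathy: float  # <H> in [0, 1]
    mean_net_charge: float         # <R> in [0, 1]
    has_cys: bool
    has_trp: bool


@lru_cache(maxsize=None)
def _load_scales() -> dict[str, HydropathyScale]:
    path = resources.files("leascan.data") / "hydropathy_scales.tsv"
    with path.open() as fh:
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")]
    scales: dict[str, HydropathyScale] = {}
    for col in rows[0].keys():
        if col == "residue":
            continue
        scales[col] = HydropathyScale(
            name=col, values={r["residue"]: float(r[col]) for r in rows})
    return scales


def get_scale(name: str = "eisenberg") -> HydropathyScale:
    """Look up a hydropathy scale by name (``eisenberg``, ``kyte_doolittle``)."""
    scales = _load_scales()
    if name not in scales:
        raise KeyError(f"unknown hydropathy scale {name!r}; have {sorted(scales)}")
    return scales[name]


@lru_cache(maxsize=None)
def _load_pka_sets() -> dict[str, dict[str, float]]:
    path = resources.files("leascan.data") / "pka_sets.tsv"
    with path.open() as fh:
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")]
    sets: dict[str, dict[str, float]] = {}
    for col in rows[0].keys():
        if col == "group":
            continue
        sets[col] = {r["group"]: float(r[col]) for r in rows}
    return sets


def get_pka_set(name: str = "emboss") -> dict[str, float]:
    sets = _load_pka_sets()
    if name not in sets:
        raise KeyError(f"unknown pKa set {name!r}; have {sorted(sets)}")
    return sets[name]


def gravy(p: ProteinSequence, scale: HydropathyScale | str = "eisenberg") -> float:
    """Grand average of hydropathy: the mean per-residue scale value.

    ``X`` (unknown) residues are excluded from both numerator and denominator;
    a protein consisting only of ``X`` raises ``ValueError``.
    """
    if isinstance(scale, str):
        scale = get_scale(scale)
    values = [scale[r] for r in p.residues if r != "X"]
    if not values:
        raise ValueError(f"protein {p.id!r} has no non-X residues")
    return float(np.mean(values))


def molecular_weight(p: ProteinSequence) -> float:
    """Average molecular mass in Da (residue masses + one water)."""
    bad = [i + 1 for i, r in enumerate(p.residues) if r == "X"]
    if bad:
        raise ValueError(
            f"protein {p.id!r}: molecular weight undefined with X at positions {bad}")
    return sum(RESIDUE_MASSES[r] for r in p.residues) + WATER_MASS


# groups ionising positive / negative; U side chain treated like Cys
_POSITIVE_GROUPS = ("H", "K", "R")
_NEGATIVE_GROUPS = ("D", "E", "C", "Y")


def net_charge(p: ProteinSequence, pH: float = 7.0,
               pka_set: str | dict[str, float] = "emboss") -> float:
    """Henderson-Hasselbalch net charge over side chains and free termini."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} out of range [0, 14]")
    pka = get_pka_set(pka_set) if isinstance(pka_set, str) else pka_set
    counts: dict[str, int] = {}
    for r in p.residues:
        r = "C" if r == "U" else r
        counts[r] = counts.get(r, 0) + 1
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - pH))
    for g in _POSITIVE_GROUPS:
        charge += counts.get(g, 0) / (1.0 + 10.0 ** (pH - pka[g]))
    for g in _NEGATIVE_GROUPS:
        charge -= counts.get(g, 0) / (1.0 + 10.0 ** (pka[g] - pH))
    return charge


def isoelectric_point(p: ProteinSequence,
                      pka_set: str | dict[str, float] = "emboss",
                      tol: float = 0.01) -> float:
    """pH at which the net charge is zero, found by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(p, mid, pka_set) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def scaled_kd_hydropathy(residues: str, window: int = 5) -> np.ndarray:
    """Per-residue Kyte-Doolittle hydropathy rescaled to [0,1], smoothed with
    a centred window truncated at the sequence ends. X residues are excluded
    from window averages."""
    scale = get_scale("kyte_doolittle")
    raw = np.array([np.nan if r == "X" else (scale[r] + 4.5) / 9.0
                    for r in residues])
    n = len(raw)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = raw[lo:hi]
        seg = seg[~np.isnan(seg)]
        out[i] = seg.mean() if seg.size else np.nan
    return out


def mean_net_charge(residues: str) -> float:
    """<R>: per-residue absolute net charge at neutral pH, counting only the
    fully-charged side chains K, R (+) and D, E (-)."""
    pos = residues.count("K") + residues.count("R")
    neg = residues.count("D") + residues.count("E")
    return abs(pos - neg) / len(residues)


def uversky_coordinates(p: ProteinSequence, window: int = 5) -> tuple[float, float]:
    """Charge-hydropathy plot coordinates (<H>, <R>) for one protein.

    <H> is the mean over residues of window-averaged rescaled Kyte-Doolittle
    hydropathy; <R> the absolute per-residue net charge at pH 7 from K/R/D/E
    counts. Proteins shorter than the window use the full sequence as one
    window (with a warning).
    """
    if len(p) < window:
        logger.warning("protein %r shorter than window %d; using full length",
                       p.id, window)
        window = len(p)
    h = scaled_kd_hydropathy(p.residues, window=window)
    h = h[~np.isnan(h)]
    if h.size == 0:
        raise ValueError(f"protein {p.id!r} has no non-X residues")
    return float(h.mean()), mean_net_charge(p.residues)


def physchem_profile(p: ProteinSequence,
                     gravy_scale: str = "eisenberg",
                     pka_set: str = "emboss",
                     window: int = 5) -> PhyschemProfile:
    """Compute the full scalar profile for one protein."""
    h, r = uversky_coordinates(p, window=window)
    return PhyschemProfile(
        length=len(p),
        mr=molecular_weight(p),
        pi=isoelectric_point(p, pka_set=pka_set),
        gravy=gravy(p, scale=gravy_scale),
        mean_scaled_hydropathy=h,
        mean_net_charge=r,
        has_cys="C" in p.residues,
        has_trp="W" in p.residues,
    )
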