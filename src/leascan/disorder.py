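"""Charge-hydropathy disorder calls.

Natively unfolded proteins combine low mean hydropathy with high mean net
charge. On a plot of mean scaled hydropathy <H> against mean net charge <R>,
folded and unfolded proteins separate around the empirical boundary

    <H>_b = (<R> + 1.151) / 2.785

A whole-protein call places the point on one side of that line; the windowed
profile applies the same relation per window, giving a FoldIndex-style
per-residue unfoldability index

    I = 2.785 * <H>_w - |<R>_w| - 1.151

whose sign (negative = disordered) yields a percent-disorder summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .physchem import get_scale, mean_net_charge
from .seq_records import ProteinSequence

BOUNDARY_INTERCEPT = 1.151
BOUNDARY_SLOPE = 2.785

# default window of the published FoldIndex server
DEFAULT_FOLDINDEX_WINDOW = 51


@dataclass(frozen=True)
class UverskyPoint:
    """One protein's position in charge-hydropathy space and its call."""

    h: float
    r: float
    h_boundary: float
    classification: Literal["folded", "unfolded"]


@dataclass(frozen=True)
class FoldIndexProfile:
    """Per-residue unfoldability indices and their percent-disorder summary."""

    window: int
    indices: np.ndarray
    percent_disorder: float


def boundary_hydropathy(r: float) -> float:
    """<H> value of the folded/unfolded boundary at mean net charge ``r``."""
    return (r + BOUNDARY_INTERCEPT) / BOUNDARY_SLOPE


def uversky_classify(h: float, r: float) -> UverskyPoint:
    """Classify a (mean scaled hydropathy, mean net charge) point.

    Unfolded iff ``h`` lies strictly below the boundary; points exactly on
    the boundary are called folded (tie-break documented here).
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"<H> = {h} out of range [0, 1]")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"<R> = {r} out of range [0, 1]")
    hb = boundary_hydropathy(r)
    return UverskyPoint(
        h=h, r=r, h_boundary=hb,
        classification="unfolded" if h < hb else "folded",
    )


def foldindex_profile(
    p: ProteinSequence, window: int = DEFAULT_FOLDINDEX_WINDOW
) -> FoldIndexProfile:
    """Windowed unfoldability profile.

    Each residue's index comes from the full-length window centred on it;
    near the termini the window is shifted inward so it always covers exactly
    ``window`` residues (residues near an end share the terminal window).
    Proteins shorter than the window use the full sequence as one window, so
    ``window >= len(p)`` gives a uniform index. X residues are excluded from
    window hydropathy means but count toward window length for the charge
    term.
    """
    n = len(p)
    window = min(window, n)
    scale = get_scale("kyte_doolittle")
    raw_h = np.array([np.nan if r == "X" else (scale[r] + 4.5) / 9.0
                      for r in p.residues])
    half = window // 2
    indices = np.empty(n)
    for i in range(n):
        lo = min(max(0, i - half), n - window)
        hi = lo + window
        seg_h = raw_h[lo:hi]
        seg_h = seg_h[~np.isnan(seg_h)]
        h_w = seg_h.mean() if seg_h.size else 0.0
        r_w = mean_net_charge(p.residues[lo:hi])
        indices[i] = BOUNDARY_SLOPE * h_w - abs(r_w) - BOUNDARY_INTERCEPT
    percent = 100.0 * float(np.count_nonzero(indices < 0.0)) / n
    return FoldIndexProfile(window=window, indices=indices, percent_disorder=percent)


def profile_to_tsv(p: ProteinSequence, profile: FoldIndexProfile) -> str:
    """Render a profile as TSV (position, index, call) for plotting."""
    lines = ["position\tindex\tcall"]
    for i, idx in enumerate(profile.indices, start=1):
        call = "disordered" if idx < 0 else "ordered"
        lines.append(f"{i}\t{idx:.4f}\t{call}")
    return "\n".join(lines) + "\n"
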