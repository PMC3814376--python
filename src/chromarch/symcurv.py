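"""Nucleosome-forming potential from the mirror symmetry of predicted DNA
curvature.

Nucleosomal DNA wraps a protein core with an approximate two-fold (dyad)
symmetry, so sequences whose intrinsic curvature is mirror-symmetric around a
candidate dyad are good nucleosome formers. The score has two stages:

1. **Curvature** ``c(i)``: a dinucleotide wedge model. Every dinucleotide
   contributes a bend of fixed magnitude (degrees, bundled consensus-style
   table, editable) whose direction rotates with the helical phase
   (2*pi/helical_repeat per step). Over a sliding window (default 31 bp) the
   deflections are summed as 2-D vectors and the mean resultant magnitude is
   assigned to the center base. Straight but flexible sequences cancel;
   helically phased bends (e.g. A-tracts every ~10.5 bp) add coherently.
2. **Symmetry** ``S(i) = 1 / (1 + D(i))`` with
   ``D(i) = mean_{k=1..w} |c(i-k) - c(i+k)|`` over a half-window of
   ``w = 73`` bp (half a nucleosome). S lies in (0, 1] and reaches 1 exactly
   when the two flanks are mirror images.

The bundled wedge table is reverse-complement symmetric, which makes the
whole score strand-invariant: recomputing on the reverse complement and
mirroring coordinates reproduces ``S`` exactly. This module implements the
curvature-symmetry concept with documented default parameters; it does not
claim numerical equality with any previously published score track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment_stats import zscore
from .promoter_sequence import CompositionProfile, tss_meta_profile

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Consensus-style dinucleotide wedge magnitudes (degrees per step).
#: Reverse-complement symmetric: wedge[XY] == wedge[revcomp(XY)].
DEFAULT_WEDGE: dict[str, float] = {
    "AA": 7.2, "TT": 7.2,
    "AC": 1.3, "GT": 1.3,
    "AG": 2.8, "CT": 2.8,
    "AT": 1.1,
    "CA": 3.3, "TG": 3.3,
    "CC": 2.1, "GG": 2.1,
    "CG": 3.6,
    "GA": 4.5, "TC": 4.5,
    "GC": 2.5,
    "TA": 2.5,
}

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CurvatureModel:
    """Dinucleotide wedge-angle table plus helical repeat."""

    wedge: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEDGE))
    helical_repeat: float = 10.4

    def __post_init__(self):
        missing = set(DINUCLEOTIDES) - set(self.wedge)
        if missing:
            raise ValueError(f"wedge table missing dinucleotides: {sorted(missing)}")
        for d in DINUCLEOTIDES:
            rc = reverse_complement(d)
            if abs(self.wedge[d] - self.wedge[rc]) > 1e-9:
                raise ValueError(
                    f"wedge table not reverse-complement consistent: "
                    f"{d}={self.wedge[d]} vs {rc}={self.wedge[rc]}")
        if self.helical_repeat <= 0:
            raise ValueError("helical repeat must be positive")


def predict_curvature(sequence: str, model: CurvatureModel | None = None,
                      window: int = 31) -> np.ndarray:
    """Per-base predicted curvature magnitude (NaN where undefined).

    The value at base i is the magnitude of the vector sum of the wedge
    deflections of the ``window`` dinucleotide steps centered on i, divided by
    the window size. Positions whose window does not fit, or touches an
    ambiguous base, are NaN.
    """
    if model is None:
        model = CurvatureModel()
    seq = sequence.upper()
    L = len(seq)
    if L <= window:
        raise ValueError(f"sequence length {L} must exceed window {window}")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(L, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[arr == ord(b)] = i
    di = code[:-1] * 4 + code[1:]
    valid = (code[:-1] >= 0) & (code[1:] >= 0)
    table = np.array([model.wedge[d] for d in DINUCLEOTIDES])
    b = np.where(valid, table[np.where(valid, di, 0)], np.nan)
    phase = 2.0 * np.pi * np.arange(L - 1) / model.helical_repeat
    vx = b * np.cos(phase)
    vy = b * np.sin(phase)
    # windowed sums with NaN propagation via cumulative counts
    half = window // 2
    csx = np.concatenate(([0.0], np.cumsum(np.nan_to_num(vx))))
    csy = np.concatenate(([0.0], np.cumsum(np.nan_to_num(vy))))
    csn = np.concatenate(([0], np.cumsum(~valid)))
    starts = np.arange(0, L - window)  # window dinucleotide steps from each start
    sx = csx[starts + window] - csx[starts]
    sy = csy[starts + window] - csy[starts]
    bad = (csn[starts + window] - csn[starts]) > 0
    mag = np.sqrt(sx ** 2 + sy ** 2) / window
    mag[bad] = np.nan
    c = np.full(L, np.nan)
    centers = starts + half
    c[centers] = mag
    return c


def symcurv_score(curvature: np.ndarray, half_window: int = 73) -> np.ndarray:
    """Mirror-symmetry score S(i) = 1/(1+D(i)) of a curvature track.

    ``D(i)`` is the mean absolute difference between mirrored flank values
    ``|c(i-k) - c(i+k)|`` for k = 1..half_window. S is in (0, 1], equals 1
    exactly for mirror-symmetric flanks, and is NaN wherever any flank value
    is undefined or out of range.
    """
    c = np.asarray(curvature, dtype=float)
    L = c.size
    w = half_window
    if w < 1:
        raise ValueError("half_window must be >= 1")
    s = np.full(L, np.nan)
    if L < 2 * w + 1:
        return s
    acc = np.zeros(L - 2 * w)
    ok = np.ones(L - 2 * w, dtype=bool)
    center = slice(w, L - w)
    for k in range(1, w + 1):
        left = c[w - k: L - w - k]
        right = c[w + k: L - w + k]
        diff = np.abs(left - right)
        ok &= ~np.isnan(diff)
        acc += np.nan_to_num(diff)
    d = acc / w
    vals = 1.0 / (1.0 + d)
    vals[~ok] = np.nan
    s[center] = vals
    return s


def symcurv_track(sequence: str, model: CurvatureModel | None = None,
                  window: int = 31, half_window: int = 73):
    """Curvature and symmetry score for one sequence."""
    c = predict_curvature(sequence, model, window)
    return c, symcurv_score(c, half_window)


def genome_symcurv(genome: Mapping[str, str], model: CurvatureModel | None = None,
                   window: int = 31, half_window: int = 73) -> dict[str, np.ndarray]:
    """Per-chromosome symmetry-score tracks."""
    return {chrom: symcurv_track(seq, model, window, half_window)[1]
            for chrom, seq in genome.items()}


def symcurv_meta_profile(genome: Mapping[str, str], annotation: pd.DataFrame,
                         gene_ids, upstream: int = 500, downstream: int = 500,
                         model: CurvatureModel | None = None,
                         window: int = 31, half_window: int = 73,
                         tracks: Mapping[str, np.ndarray] | None = None):
    """Z-scored TSS meta-profile of the symmetry score for a gene set.

    Returns ``(profile, degenerate)``; when the averaged profile has zero
    variance the raw profile is returned with ``degenerate=True`` instead of
    a Z-scored one. Precomputed score ``tracks`` may be passed to avoid
    recomputing the genome.
    """
    if tracks is None:
        tracks = genome_symcurv(genome, model, window, half_window)
    prof = tss_meta_profile(tracks, annotation, gene_ids, upstream, downstream,
                            flip_sign=False, statistic="symcurv")
    finite = np.isfinite(prof.values)
    vals = prof.values[finite]
    # windowed cumulative sums leave ~1e-13 jitter on flat tracks
    if vals.size < 2 or vals.std(ddof=0) <= 1e-9 * max(1.0, abs(vals.mean())):
        return prof, True
    out = prof.values.copy()
    out[finite] = zscore(vals)
    return CompositionProfile(prof.offsets, out, "symcurv", prof.n_genes,
                              prof.n_dropped, "zscore"), False
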