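"""Promoter geometry, TFBS positional matrices and sequence-composition profiles.

Everything is anchored at the transcription start site (TSS) and oriented
5'->3' along the gene: offset 0 is the TSS base, upstream offsets are
negative. Gene annotations are pandas frames with columns
``gene_id, chrom, start, end, strand`` (0-based half-open; TSS = start for
'+' genes and end-1 for '-' genes).

Composition statistics over sliding windows:

* ``gc_fraction`` = (G+C) / (A+C+G+T)
* ``at_skew``     = (A-T) / (A+T)   (Chargaff second-parity-rule deviation)
* ``gc_skew``     = (G-C) / (G+C)

Skews are strand statistics: extracting along the '-' strand both mirrors the
window and negates the skew, which :func:`tss_meta_profile` handles via
``flip_sign``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment_stats import zscore

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene interval with derived TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PromoterRegion:
    """Intergenic interval upstream of a gene's TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    kind: str = "unidirectional"
    partner_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TFBSMatrix:
    """Per-factor binned TFBS counts around the TSS."""

    matrix: pd.DataFrame  # factors x bin-start offsets
    bin_size: int
    region: tuple[int, int]
    normalization: str
    flagged_factors: list[str] = field(default_factory=list)


@dataclass
class CompositionProfile:
    """TSS-anchored, gene-averaged positional profile."""

    offsets: np.ndarray
    values: np.ndarray
    statistic: str
    n_genes: int
    n_dropped: int = 0
    normalization: str = "raw"


def tss_position(row) -> int:
    return int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1


def annotation_tss(annotation: pd.DataFrame) -> np.ndarray:
    return np.where(annotation["strand"] == "+", annotation["start"],
                    annotation["end"] - 1).astype(int)


def promoter_region(gene_id: str, annotation: pd.DataFrame,
                    chrom_lengths: Mapping[str, int] | None = None) -> PromoterRegion:
    """The complete intergenic region upstream of a gene's TSS.

    Extends from the TSS-side gene boundary to the nearest boundary (5' or 3')
    of the closest other gene on either strand, clipped at the chromosome edge.
    An immediately abutting neighbor yields a zero-length promoter.
    """
    rows = annotation.loc[annotation["gene_id"] == gene_id]
    if rows.empty:
        raise KeyError(f"gene '{gene_id}' not in annotation")
    gene = rows.iloc[0]
    chrom = gene["chrom"]
    others = annotation.loc[(annotation["chrom"] == chrom)
                            & (annotation["gene_id"] != gene_id)]
    if gene["strand"] == "+":
        edge = 0
        for o_start, o_end in others[["start", "end"]].itertuples(index=False):
            if o_start < gene["start"]:
                edge = max(edge, min(int(o_end), int(gene["start"])))
        return PromoterRegion(gene_id, chrom, int(edge), int(gene["start"]))
    if chrom_lengths is not None and chrom in chrom_lengths:
        chrom_end = int(chrom_lengths[chrom])
    else:
        chrom_end = int(annotation.loc[annotation["chrom"] == chrom, "end"].max())
    edge = chrom_end
    for o_start, o_end in others[["start", "end"]].itertuples(index=False):
        if o_end > gene["end"]:
            edge = min(edge, max(int(o_start), int(gene["end"])))
    return PromoterRegion(gene_id, chrom, int(gene["end"]), int(edge))


def find_bidirectional_pairs(annotation: pd.DataFrame,
                             max_span: int = 600) -> pd.DataFrame:
    """Divergent ('-','+' in coordinate order) adjacent gene pairs sharing a
    single upstream region with TSS-to-TSS span at most ``max_span`` bp.

    Each gene belongs to at most one pair. Returns a frame with columns
    ``minus_gene, plus_gene, chrom, span``.
    """
    rows = []
    used: set[str] = set()
    for chrom, sub in annotation.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        for i in range(len(sub) - 1):
            left, right = sub.iloc[i], sub.iloc[i + 1]
            if left["strand"] != "-" or right["strand"] != "+":
                continue
            if left["gene_id"] in used or right["gene_id"] in used:
                continue
            span = int(right["start"]) - (int(left["end"]) - 1)
            if 0 <= span <= max_span:
                rows.append((left["gene_id"], right["gene_id"], chrom, span))
                used.update((left["gene_id"], right["gene_id"]))
    return pd.DataFrame(rows, columns=["minus_gene", "plus_gene", "chrom", "span"])


def tfbs_bin_matrix(tfbs: pd.DataFrame, annotation: pd.DataFrame,
                    gene_ids, upstream: int = 500, downstream: int = 300,
                    bin_size: int = 20, normalize: str | None = None) -> TFBSMatrix:
    """Count TFBS occurrences per factor in strand-oriented bins around TSSs.

    ``tfbs`` needs columns ``chrom, start, factor``; a site's position is its
    start. Offsets are computed gene-strand-aware (site at the TSS of a '-'
    gene also lands in the bin containing offset 0). With
    ``normalize='zscore'`` each factor row is standardized; zero-variance rows
    are left raw and reported in ``flagged_factors``.
    """
    n_bins = (upstream + downstream) // bin_size
    offsets = np.arange(-upstream, downstream, bin_size)
    factors = sorted(tfbs["factor"].unique()) if len(tfbs) else []
    genes = annotation.loc[annotation["gene_id"].isin(set(gene_ids))]
    counts = pd.DataFrame(np.zeros((len(factors), n_bins)),
                          index=factors, columns=offsets)
    if factors and len(genes):
        by_chrom = {c: s for c, s in tfbs.groupby("chrom")}
        for _, gene in genes.iterrows():
            sites = by_chrom.get(gene["chrom"])
            if sites is None:
                continue
            tss = tss_position(gene)
            pos = sites["start"].to_numpy()
            d = pos - tss if gene["strand"] == "+" else tss - pos
            inside = (d >= -upstream) & (d < downstream)
            if not inside.any():
                continue
            bins = (d[inside] + upstream) // bin_size
            for factor, b in zip(sites["factor"].to_numpy()[inside], bins):
                counts.loc[factor, offsets[int(b)]] += 1
    flagged = []
    norm = "raw"
    if normalize == "zscore":
        norm = "zscore"
        for factor in counts.index:
            row = counts.loc[factor].to_numpy()
            if row.std(ddof=0) == 0:
                flagged.append(factor)
            else:
                counts.loc[factor] = zscore(row)
    return TFBSMatrix(counts, bin_size, (-upstream, downstream), norm, flagged)


_BASE_SETS = {"A": "A", "C": "C", "G": "G", "T": "T"}


def _base_indicator(sequence: str, base: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    return (arr == ord(base)).astype(float)


def sliding_composition(sequence: str, window: int = 100, step: int = 1,
                        statistic: str = "gc_fraction"):
    """Per-position composition statistic over sliding windows.

    The value of each window is assigned to its center position
    (``start + window // 2``); positions whose window does not fit the
    sequence are NaN. Returns ``(values, zero_denominator)`` arrays of the
    sequence length; windows with a zero denominator yield 0 and are flagged
    instead of dropped, keeping profiles rectangular.
    """
    L = len(sequence)
    if L < window:
        raise ValueError(f"sequence length {L} shorter than window {window}")
    ind = {b: np.concatenate(([0.0], np.cumsum(_base_indicator(sequence, b))))
           for b in "ACGT"}
    starts = np.arange(0, L - window + 1, step)
    win = {b: ind[b][starts + window] - ind[b][starts] for b in "ACGT"}
    if statistic == "gc_fraction":
        num = win["G"] + win["C"]
        den = win["A"] + win["C"] + win["G"] + win["T"]
    elif statistic == "at_skew":
        num = win["A"] - win["T"]
        den = win["A"] + win["T"]
    elif statistic == "gc_skew":
        num = win["G"] - win["C"]
        den = win["G"] + win["C"]
    else:
        raise ValueError(f"unknown statistic: {statistic}")
    zero = den == 0
    vals = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    values = np.full(L, np.nan)
    flags = np.zeros(L, dtype=bool)
    centers = starts + window // 2
    values[centers] = vals
    flags[centers] = zero
    return values, flags


def tss_meta_profile(values_by_chrom: Mapping[str, np.ndarray],
                     annotation: pd.DataFrame, gene_ids,
                     upstream: int = 500, downstream: int = 500,
                     flip_sign: bool = False,
                     statistic: str = "track") -> CompositionProfile:
    """Average a per-base track over TSS-anchored, gene-oriented windows.

    Offsets run from -upstream to downstream-1 with 0 at the TSS base. '-'
    strand genes are extracted in reverse; ``flip_sign=True`` additionally
    negates their values (required for strand-antisymmetric statistics such as
    PR2 skews, since complementation negates A-T and G-C). Genes whose window
    crosses a chromosome edge are dropped and counted; positions missing from
    the track (NaN) are averaged over the genes that do have them.
    """
    gene_ids = set(gene_ids)
    genes = annotation.loc[annotation["gene_id"].isin(gene_ids)]
    if genes.empty:
        raise ValueError("empty gene set for meta profile")
    width = upstream + downstream
    stack = []
    n_dropped = 0
    for _, gene in genes.iterrows():
        track = values_by_chrom[gene["chrom"]]
        tss = tss_position(gene)
        if gene["strand"] == "+":
            lo, hi = tss - upstream, tss + downstream
            if lo < 0 or hi > len(track):
                n_dropped += 1
                continue
            vec = track[lo:hi]
        else:
            lo, hi = tss - downstream + 1, tss + upstream + 1
            if lo < 0 or hi > len(track):
                n_dropped += 1
                continue
            vec = track[lo:hi][::-1]
            if flip_sign:
                vec = -vec
        stack.append(vec)
    if not stack:
        raise ValueError("no gene window fits inside its chromosome")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(np.vstack(stack), axis=0)
    return CompositionProfile(np.arange(-upstream, downstream), mean,
                              statistic, len(stack), n_dropped)


def conservation_meta_profile(track_by_chrom: Mapping[str, np.ndarray],
                              annotation: pd.DataFrame, gene_ids,
                              upstream: int = 500,
                              downstream: int = 500) -> CompositionProfile:
    """Position-wise mean conservation around TSSs, orientation-aware.

    Missing positions (NaN in the track) are treated as absent, not zero; a
    warning is recorded when more than half of the interrogated positions are
    missing.
    """
    prof = tss_meta_profile(track_by_chrom, annotation, gene_ids,
                            upstream, downstream, flip_sign=False,
                            statistic="conservation")
    frac_missing = _missing_fraction(track_by_chrom, annotation, gene_ids,
                                     upstream, downstream)
    if frac_missing > 0.5:
        warnings.warn(f"conservation track missing for {frac_missing:.0%} "
                      "of interrogated positions")
    return prof


def _missing_fraction(track_by_chrom, annotation, gene_ids, upstream, downstream):
    total = missing = 0
    genes = annotation.loc[annotation["gene_id"].isin(set(gene_ids))]
    for _, gene in genes.iterrows():
        track = track_by_chrom[gene["chrom"]]
        tss = tss_position(gene)
        lo = tss - upstream if gene["strand"] == "+" else tss - downstream + 1
        hi = lo + upstream + downstream
        if lo < 0 or hi > len(track):
            continue
        window = track[lo:hi]
        total += window.size
        missing += int(np.isnan(window).sum())
    return missing / total if total else 0.0


def profile_extremum_offset(profile: CompositionProfile, lo: int, hi: int,
                            mode: str = "min") -> int:
    """Offset of the profile extremum restricted to offsets in [lo, hi)."""
    sel = (profile.offsets >= lo) & (profile.offsets < hi)
    vals = profile.values[sel]
    offs = profile.offsets[sel]
    idx = np.nanargmin(vals) if mode == "min" else np.nanargmax(vals)
    return int(offs[idx])
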