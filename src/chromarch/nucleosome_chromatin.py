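"""Nucleosome spacing, TSS occupancy profiles, dynamic-nucleosome overlap,
remodeler-target enrichment and histone-mark enrichment.

Nucleosomes are 0-based half-open intervals with a label among ``bulk``,
``appearing``, ``evicted`` and ``fragile`` (heat-shock gained/lost and
MNase-hypersensitive positions from published maps; the synthetic world
plants equivalents). Spacing is the edge-to-edge linker length between
consecutive nucleosomes: for a gene carrying N nucleosomes the mean of the
N-1 gaps is its average spacing (center-to-center distances would be bounded
below by the ~147 bp particle width and could never reproduce 21-29 bp
linkers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment_stats import (EnrichmentResult, bootstrap_enrichment,
                               relative_enrichment, wilcoxon_rank_sum, zscore)

NUCLEOSOME_LABELS = ("bulk", "appearing", "evicted", "fragile")
DYNAMIC_LABELS = ("appearing", "evicted", "fragile")


@dataclass
class SpacingResult:
    """Mean internucleosomal linker length within one gene body."""

    gene_id: str
    n_nucleosomes: int
    mean_spacing: float
    defined: bool


@dataclass
class OccupancyProfile:
    """Binned nucleosome overlap fraction around the TSS, gene-averaged."""

    offsets: np.ndarray  # bin start offsets relative to the TSS
    values: np.ndarray
    bin: int
    n_genes: int
    normalization: str = "raw"
    n_dropped: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return self.offsets + self.bin / 2.0


def gene_nucleosome_spacing(gene, nucleosomes: pd.DataFrame,
                            assignment: str = "midpoint") -> SpacingResult:
    """Mean edge-to-edge gap between consecutive nucleosomes in a gene body.

    Nucleosomes are assigned to the gene by the midpoint-in-body rule
    (default) or by any overlap (``assignment='overlap'``). Undefined (not an
    error) when fewer than two nucleosomes are assigned.
    """
    gid = gene["gene_id"]
    sub = nucleosomes.loc[nucleosomes["chrom"] == gene["chrom"]]
    start, end = int(gene["start"]), int(gene["end"])
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    if assignment == "midpoint":
        mid = (s + e) / 2.0
        keep = (mid >= start) & (mid < end)
    elif assignment == "overlap":
        keep = (e > start) & (s < end)
    else:
        raise ValueError(f"unknown assignment rule: {assignment}")
    s, e = s[keep], e[keep]
    order = np.argsort(s)
    s, e = s[order], e[order]
    n = len(s)
    if n < 2:
        return SpacingResult(gid, n, float("nan"), False)
    gaps = s[1:] - e[:-1]
    return SpacingResult(gid, n, float(gaps.mean()), True)


def spacing_table(annotation: pd.DataFrame, gene_ids, nucleosomes: pd.DataFrame,
                  assignment: str = "midpoint") -> pd.DataFrame:
    bulk = nucleosomes
    if "label" in nucleosomes.columns:
        bulk = nucleosomes.loc[nucleosomes["label"] == "bulk"]
    genes = annotation.loc[annotation["gene_id"].isin(set(gene_ids))]
    rows = [gene_nucleosome_spacing(g, bulk, assignment)
            for _, g in genes.iterrows()]
    return pd.DataFrame([(r.gene_id, r.n_nucleosomes, r.mean_spacing, r.defined)
                         for r in rows],
                        columns=["gene_id", "n_nucleosomes", "mean_spacing", "defined"])


def coverage_arrays(nucleosomes: pd.DataFrame,
                    chrom_lengths: Mapping[str, int],
                    label: str | None = None) -> dict[str, np.ndarray]:
    """Boolean per-base coverage (union of intervals), optionally one label."""
    sub = nucleosomes
    if label is not None:
        if "label" not in nucleosomes.columns:
            raise ValueError("nucleosome frame has no 'label' column")
        sub = nucleosomes.loc[nucleosomes["label"] == label]
    cov = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for chrom, start, end in sub[["chrom", "start", "end"]].itertuples(index=False):
        arr = cov[chrom]
        arr[max(0, int(start)): min(len(arr), int(end))] = True
    return cov


def occupancy_meta_profile(nucleosomes: pd.DataFrame, annotation: pd.DataFrame,
                           gene_ids, chrom_lengths: Mapping[str, int],
                           upstream: int = 500, downstream: int = 500,
                           bin: int = 10, normalize: str | None = None,
                           label: str | None = None) -> OccupancyProfile:
    """Fraction of each TSS-anchored bin covered by nucleosomes, gene-averaged.

    Per gene and bin the fraction of the bin's base pairs covered by any
    nucleosome is computed on the gene-oriented window, then averaged over
    genes. ``normalize='zscore'`` standardizes the averaged profile (as done
    for gene-class occupancy landscapes).
    """
    from .promoter_sequence import tss_position

    gene_ids = set(gene_ids)
    genes = annotation.loc[annotation["gene_id"].isin(gene_ids)]
    if genes.empty:
        raise ValueError("empty gene set for occupancy profile")
    if (upstream + downstream) % bin:
        raise ValueError("profile width must be a multiple of the bin size")
    cov = coverage_arrays(nucleosomes, chrom_lengths, label)
    width = upstream + downstream
    n_bins = width // bin
    acc = np.zeros(n_bins)
    n_used = 0
    n_dropped = 0
    for _, gene in genes.iterrows():
        arr = cov[gene["chrom"]]
        tss = tss_position(gene)
        if gene["strand"] == "+":
            lo, hi = tss - upstream, tss + downstream
            if lo < 0 or hi > len(arr):
                n_dropped += 1
                continue
            vec = arr[lo:hi].astype(float)
        else:
            lo, hi = tss - downstream + 1, tss + upstream + 1
            if lo < 0 or hi > len(arr):
                n_dropped += 1
                continue
            vec = arr[lo:hi][::-1].astype(float)
        acc += vec.reshape(n_bins, bin).mean(axis=1)
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene window fits inside its chromosome")
    values = acc / n_used
    norm = "raw"
    if normalize == "zscore":
        values = zscore(values)
        norm = "zscore"
    return OccupancyProfile(np.arange(-upstream, downstream, bin), values,
                            bin, n_used, norm, n_dropped)


def dynamic_overlap_profile(nucleosomes: pd.DataFrame, label: str,
                            annotation: pd.DataFrame, gene_ids,
                            chrom_lengths: Mapping[str, int],
                            upstream: int = 500, downstream: int = 500,
                            bin: int = 10) -> OccupancyProfile:
    """Mean percent overlap with one dynamic nucleosome class around the TSS."""
    if label not in DYNAMIC_LABELS:
        raise ValueError(f"label must be one of {DYNAMIC_LABELS}, got {label!r}")
    prof = occupancy_meta_profile(nucleosomes, annotation, gene_ids,
                                  chrom_lengths, upstream, downstream, bin,
                                  normalize=None, label=label)
    return OccupancyProfile(prof.offsets, prof.values * 100.0, prof.bin,
                            prof.n_genes, "percent", prof.n_dropped)


def remodeler_enrichment(deregulated: Mapping[str, set],
                         targets: Mapping[str, set], universe: set,
                         n_trials: int = 1000, seed: int = 0) -> list[EnrichmentResult]:
    """Observed/expected enrichment of each deregulated set among each
    remodeler's target genes, with bootstrap p-values (add-one smoothed).

    Ratios deviate from 1, the genome-average expectation. Empty target lists
    (after intersection with the universe) are skipped with a warning. Each
    (remodeler, set) pair uses a seed deterministically derived from ``seed``.
    """
    universe = set(universe)
    results = []
    counter = 0
    for remodeler in sorted(targets):
        target = set(targets[remodeler]) & universe
        if not target:
            warnings.warn(f"remodeler '{remodeler}' has no targets in the "
                          "universe; skipped")
            continue
        for set_name in sorted(deregulated):
            subset = set(deregulated[set_name]) & universe
            counter += 1
            if not subset:
                warnings.warn(f"deregulated set '{set_name}' empty; skipped")
                continue
            res = relative_enrichment(subset, target, universe,
                                      subset_name=set_name, class_name=remodeler)
            pair_seed = seed + counter
            res.p_value = bootstrap_enrichment(len(subset), target, universe,
                                               res.ratio, n_trials, pair_seed)
            res.method = "bootstrap"
            res.n_trials = n_trials
            res.seed = pair_seed
            results.append(res)
    return results


def histone_mark_enrichment(marks: pd.DataFrame, subset: set, universe: set,
                            alpha: float = 0.001) -> pd.DataFrame:
    """Wilcoxon rank-sum enrichment of mark scores in a gene subset.

    For every mark and compartment (promoter, ORF) the subset's scores are
    compared against the rest of the universe; the direction is the sign of
    the median difference and marks are flagged significant at ``p < alpha``
    (no multiplicity correction; the fixed threshold is the analysis's
    convention). Marks scored for less than half the subset are skipped with
    a warning. Returns columns ``mark, compartment, n_subset, n_background,
    median_diff, direction, p_value, significant``.
    """
    subset = set(subset)
    universe = set(universe)
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    background = universe - subset
    if not subset or not background:
        raise ValueError("subset and its complement must both be non-empty")
    rows = []
    for mark, sub in marks.groupby("mark", sort=True):
        sub = sub.loc[sub["gene_id"].isin(universe)]
        for compartment, column in (("promoter", "promoter_score"),
                                    ("orf", "orf_score")):
            scored = sub.dropna(subset=[column])
            in_sub = scored.loc[scored["gene_id"].isin(subset), column].to_numpy()
            in_bg = scored.loc[scored["gene_id"].isin(background), column].to_numpy()
            if in_sub.size < 0.5 * len(subset):
                warnings.warn(f"mark '{mark}' ({compartment}) scored for under "
                              "half of the subset; skipped")
                continue
            if in_bg.size == 0:
                warnings.warn(f"mark '{mark}' ({compartment}) has no background "
                              "scores; skipped")
                continue
            p = wilcoxon_rank_sum(in_sub, in_bg)
            diff = float(np.median(in_sub) - np.median(in_bg))
            direction = "enriched" if diff > 0 else ("depleted" if diff < 0 else "none")
            rows.append((mark, compartment, in_sub.size, in_bg.size, diff,
                         direction, p, p < alpha))
    return pd.DataFrame(rows, columns=["mark", "compartment", "n_subset",
                                       "n_background", "median_diff",
                                       "direction", "p_value", "significant"])
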