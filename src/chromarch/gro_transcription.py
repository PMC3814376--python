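"""From raw genomic run-on (GRO) replicate signals to deregulated gene sets.

The input is a long-format table with one row per (gene, strain, replicate)
measurement for exactly two strains, ``control`` and ``mutant``, plus a
genomic-DNA normalization intensity per row. Processing steps:

1. normalize each replicate's signals by its genomic-DNA signal;
2. discard within-gene replicate outliers by a median-absolute-deviation rule;
3. average the surviving replicates (a gene needs at least two valid
   replicates per strain, otherwise it is excluded);
4. form the transcription-rate ratio R = mutant mean / control mean and call
   genes up (R > 1.5), down (R < 0.65) or unchanged — strict inequalities;
5. optionally subtract environmental-stress-response (ESR) genes to isolate
   the strictly perturbation-specific sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STRAIN_CONTROL = "control"
STRAIN_MUTANT = "mutant"

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"
STATUS_EXCLUDED = "excluded"


@dataclass(frozen=True)
class OutlierRule:
    """MAD-based replicate outlier rule.

    A value x is retained iff |x - median| <= k * MAD, with
    MAD = median(|x - median|) (unscaled). Degenerate cases keep everything:
    MAD = 0, or fewer than ``min_values`` values — with very few replicates
    the sample MAD reduces to the smaller gap around the median and would flag
    ordinary noise as outlying, so filtering only engages from ``min_values``
    observations. ``max_discard_frac`` is a sanity cap used for reporting.
    """

    k: float = 3.0
    max_discard_frac: float = 0.02
    min_values: int = 4

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("outlier rule multiplier k must be positive")


@dataclass
class DeregulatedSets:
    """Up/down gene-id sets before and after ESR subtraction."""

    up_raw: frozenset
    down_raw: frozenset
    up_strict: frozenset
    down_strict: frozenset
    up_esr_overlap_frac: float
    down_esr_overlap_frac: float


def normalize_signals(gro: pd.DataFrame) -> pd.DataFrame:
    """Divide each signal by its genomic-DNA normalization signal.

    Works for per-filter scalar gdna (same value repeated within a replicate)
    and per-gene gdna alike, since normalization is row-wise.
    """
    bad = ~(np.isfinite(gro["gdna_signal"]) & (gro["gdna_signal"] > 0))
    if bad.any():
        row = gro[bad].iloc[0]
        raise ValueError(
            "non-positive or missing gdna signal for strain "
            f"'{row['strain']}' replicate '{row['replicate']}'")
    out = gro.copy()
    out["signal"] = gro["signal"] / gro["gdna_signal"]
    out["gdna_signal"] = 1.0
    return out


def filter_outliers(values, rule: OutlierRule = OutlierRule()) -> np.ndarray:
    """Boolean mask of replicate values retained by the MAD rule."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.zeros(0, dtype=bool)
    if v.size < rule.min_values:
        return np.ones(v.size, dtype=bool)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.ones(v.size, dtype=bool)
    return np.abs(v - med) <= rule.k * mad


def merge_replicates(values, min_valid: int = 2) -> tuple[float, int]:
    """Mean of the retained replicates, or (nan, n) when fewer than min_valid."""
    v = np.asarray(values, dtype=float)
    n_valid = int(v.size)
    if n_valid < min_valid:
        return float("nan"), n_valid
    return float(v.mean()), n_valid


def classify_change(ratio: float, up_threshold: float = 1.5,
                    down_threshold: float = 0.65) -> str:
    """Call a mutant/control ratio up, down or unchanged (strict thresholds)."""
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"transcription ratio must be positive, got {ratio}")
    if ratio > up_threshold:
        return STATUS_UP
    if ratio < down_threshold:
        return STATUS_DOWN
    return STATUS_UNCHANGED


def compute_changes(gro: pd.DataFrame, rule: OutlierRule = OutlierRule(),
                    min_valid: int = 2, up_threshold: float = 1.5,
                    down_threshold: float = 0.65,
                    normalized: bool = False) -> pd.DataFrame:
    """Per-gene transcription-rate change table.

    Returns a frame with columns ``gene_id, ratio, n_valid_control,
    n_valid_mutant, status``; the overall fraction of replicate values
    discarded by the outlier filter is stored in ``df.attrs['discarded_frac']``.
    """
    strains = set(gro["strain"].unique())
    if strains != {STRAIN_CONTROL, STRAIN_MUTANT}:
        raise ValueError(f"strains must be exactly {{control, mutant}}, got {sorted(strains)}")
    if (gro["signal"] < 0).any():
        raise ValueError("GRO signals must be non-negative")
    norm = gro if normalized else normalize_signals(gro)

    n_total = 0
    n_discarded = 0
    rows = []
    for gene_id, sub in norm.groupby("gene_id", sort=True):
        means = {}
        counts = {}
        for strain in (STRAIN_CONTROL, STRAIN_MUTANT):
            vals = sub.loc[sub["strain"] == strain, "signal"].to_numpy()
            mask = filter_outliers(vals, rule)
            n_total += vals.size
            n_discarded += int(vals.size - mask.sum())
            means[strain], counts[strain] = merge_replicates(vals[mask], min_valid)
        ratio = np.nan
        status = STATUS_EXCLUDED
        if np.isfinite(means[STRAIN_CONTROL]) and np.isfinite(means[STRAIN_MUTANT]) \
                and means[STRAIN_CONTROL] > 0 and means[STRAIN_MUTANT] > 0:
            ratio = means[STRAIN_MUTANT] / means[STRAIN_CONTROL]
            status = classify_change(ratio, up_threshold, down_threshold)
        rows.append((gene_id, ratio, counts[STRAIN_CONTROL], counts[STRAIN_MUTANT], status))

    df = pd.DataFrame(rows, columns=["gene_id", "ratio", "n_valid_control",
                                     "n_valid_mutant", "status"])
    df.attrs["discarded_frac"] = (n_discarded / n_total) if n_total else 0.0
    return df


def subtract_esr(up_raw: set, down_raw: set, esr_up: set,
                 esr_down: set) -> DeregulatedSets:
    """Remove general-stress (ESR) genes from the raw deregulated sets."""
    up_raw, down_raw = set(up_raw), set(down_raw)
    up_strict = up_raw - set(esr_up)
    down_strict = down_raw - set(esr_down)
    return DeregulatedSets(
        frozenset(up_raw), frozenset(down_raw),
        frozenset(up_strict), frozenset(down_strict),
        (len(up_raw) - len(up_strict)) / len(up_raw) if up_raw else 0.0,
        (len(down_raw) - len(down_strict)) / len(down_raw) if down_raw else 0.0,
    )


def deregulated_sets(changes: pd.DataFrame, esr_up: set = frozenset(),
                     esr_down: set = frozenset()) -> DeregulatedSets:
    """Build DeregulatedSets from a compute_changes table."""
    up = set(changes.loc[changes["status"] == STATUS_UP, "gene_id"])
    down = set(changes.loc[changes["status"] == STATUS_DOWN, "gene_id"])
    return subtract_esr(up, down, esr_up, esr_down)


def replicate_concordance(gro: pd.DataFrame, normalized: bool = False) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlation matrix of replicates, per strain.

    Computed on normalized signals over the genes present in both replicates
    of each pair. Raises when a strain has fewer than two replicates or a
    replicate pair shares fewer than two genes.
    """
    norm = gro if normalized else normalize_signals(gro)
    out = {}
    for strain, sub in norm.groupby("strain"):
        wide = sub.pivot_table(index="gene_id", columns="replicate",
                               values="signal", aggfunc="first")
        if wide.shape[1] < 2:
            raise ValueError(f"strain '{strain}' has fewer than 2 replicates")
        reps = list(wide.columns)
        mat = pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1:]:
                both = wide[[r1, r2]].dropna()
                if len(both) < 2:
                    raise ValueError(
                        f"replicates '{r1}' and '{r2}' of strain '{strain}' "
                        "share fewer than 2 genes")
                r = float(np.corrcoef(both[r1], both[r2])[0, 1])
                mat.loc[r1, r2] = mat.loc[r2, r1] = r
        out[strain] = mat
    return out
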