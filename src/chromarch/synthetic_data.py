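"""Synthetic "world" generator: a complete, self-consistent input set with
planted, recoverable structure for every downstream analysis stage.

The generator emulates the statistical features the pipeline is designed to
measure in real data:

* two-strain GRO tables with log-normal replicate noise around planted
  mutant/control fold changes (a configurable fraction of genes planted up
  at ``fold_up`` and down at ``fold_down``);
* a nucleosome-free region (NFR) upstream of every TSS followed by a phased
  nucleosome array with gene-class-specific linker lengths;
* a GC dip over (-250, 0) upstream of the TSS, and a purine-excess /
  pyrimidine-excess switch across the TSS violating Chargaff's second parity
  rule with configurable amplitude;
* gene-class biased TFBS positions, conservation, histone-mark scores,
  remodeler target lists and partially overlapping ESR lists;
* a reverse-complement-palindromic high-curvature cassette at the +1
  nucleosome position of upregulated genes, giving them a recoverable
  curvature-symmetry peak.

A single seed drives everything; sub-generators are derived from it at fixed
offsets so worlds are bit-identical across runs and platforms.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: left half of the +1 cassette: A-tracts phased at the helical repeat.
_CASSETTE_UNIT = "AAAAACGGGC"

REMODELERS = ("Ioc3", "Isw2", "Arp5", "Ino80", "Rsc8", "Snf2", "Ioc4", "Isw1")

DEFAULT_MARKS = ("H3K4me1", "H3K4me3", "H3K9ac", "H3K14ac", "H4K5ac",
                 "H4K12ac", "H3K36me2", "H2AZ", "H2AZK14ac")


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Study conditions for a synthetic world.

    Fold thresholds downstream are >1.5 (up) and <0.65 (down); the planted
    folds must be recoverable through them, hence the invariant
    ``fold_up > 1.5 and fold_down < 0.65``.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 120_000
    n_genes: int = 120
    frac_up: float = 0.05
    frac_down: float = 0.03
    fold_up: float = 2.0
    fold_down: float = 0.5
    noise_sigma: float = 0.1
    n_replicates: int = 3
    nfr_halfwidth: int = 90
    nucleosome_width: int = 147
    spacing_by_class: Mapping[str, int] = field(
        default_factory=lambda: {CLASS_UP: 29, CLASS_DOWN: 21, CLASS_UNCHANGED: 25})
    min_gene_length: int = 1000
    max_gene_length: int = 2000
    mean_intergenic_gap: int = 400
    edge_margin: int = 700
    gc_background: float = 0.375
    gc_dip_depth: float = 0.10
    pr2_switch_amp: float = 0.10
    mark_shift: float = 1.0
    esr_overlap_frac: float = 1.0 / 3.0
    remodeler_boost: float = 3.0
    base_log_mean: float = math.log(1000.0)
    base_log_sigma: float = 0.5
    gdna_sigma: float = 0.05
    n_tf_factors: int = 10
    marks: tuple = DEFAULT_MARKS

    def __post_init__(self):
        if self.frac_up + self.frac_down >= 1:
            raise ValueError("frac_up + frac_down must be < 1")
        for name in ("frac_up", "frac_down", "esr_overlap_frac", "gc_background",
                     "gc_dip_depth", "pr2_switch_amp"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (self.fold_up > 1.5 and 0 < self.fold_down < 0.65):
            raise ValueError("planted folds must satisfy fold_up > 1.5 and "
                             "fold_down < 0.65 to be recoverable")
        if self.nucleosome_width <= 0:
            raise ValueError("nucleosome_width must be positive")
        if self.noise_sigma < 0 or self.n_replicates < 1:
            raise ValueError("invalid replicate noise configuration")
        if self.gc_dip_depth > self.gc_background:
            raise ValueError("gc_dip_depth cannot exceed gc_background")


@dataclass
class SyntheticWorld:
    """A generated world plus the planted ground truth."""

    config: SyntheticWorldConfig
    genome: dict[str, str]
    annotation: pd.DataFrame  # gene_id chrom start end strand
    gro: pd.DataFrame
    nucleosomes: pd.DataFrame  # chrom start end label
    tfbs: pd.DataFrame  # chrom start end factor
    tracks: dict[str, dict[str, np.ndarray]]
    marks: pd.DataFrame
    gene_lists: dict[str, set[str]]
    truth: dict[str, set[str]]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _rng(seed: int, stream: int) -> np.random.Generator:
    # sub-generators at fixed offsets from the world seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(stream,)))


def _cassette() -> str:
    left = (_CASSETTE_UNIT * 8)[:73]
    right = left.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return left + right  # reverse-complement palindrome, length 146


def _place_genes(config: SyntheticWorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_placed = 0
    width = len(str(config.n_genes))
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = config.edge_margin
        while n_placed < config.n_genes:
            glen = int(rng.integers(config.min_gene_length, config.max_gene_length + 1))
            if pos + glen + config.edge_margin > config.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            n_placed += 1
            rows.append((f"g{n_placed:0{width}d}", chrom, pos, pos + glen, strand))
            gap = int(rng.geometric(1.0 / config.mean_intergenic_gap))
            pos += glen + gap
        if n_placed >= config.n_genes:
            break
    if n_placed < config.n_genes:
        raise ValueError(
            f"genome too short: placed {n_placed} of {config.n_genes} genes; "
            "increase chrom_length or n_chroms")
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _assign_classes(annotation: pd.DataFrame, config: SyntheticWorldConfig,
                    rng: np.random.Generator) -> dict[str, str]:
    ids = list(annotation["gene_id"])
    n = len(ids)
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    perm = rng.permutation(n)
    classes = {gid: CLASS_UNCHANGED for gid in ids}
    for i in perm[:n_up]:
        classes[ids[i]] = CLASS_UP
    for i in perm[n_up: n_up + n_down]:
        classes[ids[i]] = CLASS_DOWN
    return classes


def _oriented_slice(tss: int, strand: str, a: int, b: int, length: int):
    """Reference-strand slice of gene-oriented offsets [a, b) around a TSS."""
    if strand == "+":
        lo, hi = tss + a, tss + b
    else:
        lo, hi = tss - b + 1, tss - a + 1
    return max(0, lo), min(length, hi)


def _build_sequences(annotation: pd.DataFrame, classes: Mapping[str, str],
                     config: SyntheticWorldConfig,
                     rng: np.random.Generator) -> dict[str, str]:
    genome: dict[str, str] = {}
    cassette = _cassette()
    for chrom in sorted(annotation["chrom"].unique()):
        L = config.chrom_length
        gc = np.full(L, config.gc_background)
        skew = np.zeros(L)  # reference-strand skew amplitude
        for _, gene in annotation.loc[annotation["chrom"] == chrom].iterrows():
            tss = int(gene["start"]) if gene["strand"] == "+" else int(gene["end"]) - 1
            sgn = 1.0 if gene["strand"] == "+" else -1.0
            lo, hi = _oriented_slice(tss, gene["strand"], -250, 0, L)
            gc[lo:hi] = config.gc_background - config.gc_dip_depth
            lo, hi = _oriented_slice(tss, gene["strand"], 0, 500, L)
            skew[lo:hi] = sgn * config.pr2_switch_amp
            lo, hi = _oriented_slice(tss, gene["strand"], -500, 0, L)
            skew[lo:hi] = -sgn * config.pr2_switch_amp
        at = 1.0 - gc
        # purine excess: on the skewed strand both A>T and G>C by `skew`
        p = np.empty((L, 4))
        p[:, 0] = at * (1 + skew) / 2.0  # A
        p[:, 1] = gc * (1 - skew) / 2.0  # C
        p[:, 2] = gc * (1 + skew) / 2.0  # G
        p[:, 3] = at * (1 - skew) / 2.0  # T
        cum = np.cumsum(p, axis=1)
        r = rng.random(L)
        idx = (r[:, None] > cum).sum(axis=1).clip(0, 3)
        seq = bytearray(_BASES[idx].tobytes())
        # +1 curvature-symmetry cassette for upregulated genes
        for _, gene in annotation.loc[annotation["chrom"] == chrom].iterrows():
            if classes[gene["gene_id"]] != CLASS_UP:
                continue
            tss = int(gene["start"]) if gene["strand"] == "+" else int(gene["end"]) - 1
            lo, hi = _oriented_slice(tss, gene["strand"], 0, len(cassette), L)
            if hi - lo == len(cassette):
                seq[lo:hi] = cassette.encode("ascii")  # RC-palindrome: strand-neutral
        genome[chrom] = seq.decode("ascii")
    return genome


def _place_nucleosomes(annotation: pd.DataFrame, classes: Mapping[str, str],
                       config: SyntheticWorldConfig) -> pd.DataFrame:
    """Deterministic NFR + phased array placement.

    The downstream array starts at the TSS (+1 nucleosome) and continues with
    the class linker while it fits in the gene body. Up to two upstream
    nucleosomes (-1, -2) are placed beyond the NFR, but only within the share
    of the intergenic gap that belongs to this gene (half the gap when the
    neighbor's promoter faces the same gap), so bulk nucleosomes never
    overlap and gene bodies contain only their own array.
    """
    width = config.nucleosome_width
    rows = []
    for chrom, sub in annotation.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        for i, gene in sub.iterrows():
            gid = gene["gene_id"]
            cls = classes[gid]
            linker = int(config.spacing_by_class.get(cls,
                         config.spacing_by_class[CLASS_UNCHANGED]))
            strand = gene["strand"]
            tss = int(gene["start"]) if strand == "+" else int(gene["end"]) - 1
            glen = int(gene["end"]) - int(gene["start"])
            # downstream array within the gene body
            a = 0
            positions = []
            while a + width <= glen:
                positions.append((a, a + width))
                a += width + linker
            # upstream room: distance from TSS to this gene's share of the gap
            if strand == "+":
                if i == 0:
                    prev_end = 0
                    prev_faces = False
                else:
                    prev = sub.iloc[i - 1]
                    prev_end = int(prev["end"])
                    prev_faces = prev["strand"] == "-"
                gap_lo = prev_end
                gap_hi = int(gene["start"])
                room = gap_hi - ((gap_lo + gap_hi) // 2 if prev_faces else gap_lo)
            else:
                if i == len(sub) - 1:
                    next_start = config.chrom_length
                    next_faces = False
                else:
                    nxt = sub.iloc[i + 1]
                    next_start = int(nxt["start"])
                    next_faces = nxt["strand"] == "+"
                gap_lo = int(gene["end"])
                gap_hi = next_start
                room = ((gap_lo + gap_hi) // 2 if next_faces else gap_hi) - gap_lo
            b = -config.nfr_halfwidth
            for _ in range(2):  # -1 and -2 nucleosomes
                if -(b - width) > room:
                    break
                positions.append((b - width, b))
                b -= width + linker
            for a_off, b_off in positions:
                lo, hi = _oriented_slice(tss, strand, a_off, b_off, config.chrom_length)
                if hi - lo == width:
                    rows.append((chrom, lo, hi, "bulk"))
            # dynamic classes: appearing at +1 of down genes; evicted/fragile
            # at the -1/-2 promoter positions of deregulated genes
            if cls == CLASS_DOWN:
                lo, hi = _oriented_slice(tss, strand, 0, width, config.chrom_length)
                rows.append((chrom, lo, hi, "appearing"))
            if cls in (CLASS_UP, CLASS_DOWN):
                up1 = (-config.nfr_halfwidth - width, -config.nfr_halfwidth)
                lo, hi = _oriented_slice(tss, strand, *up1, config.chrom_length)
                rows.append((chrom, lo, hi, "evicted"))
                up2 = (up1[0] - width - linker, up1[0] - linker)
                lo, hi = _oriented_slice(tss, strand, *up2, config.chrom_length)
                rows.append((chrom, lo, hi, "fragile"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return df.sort_values(["chrom", "start", "end", "label"]).reset_index(drop=True)


def _gro_table(annotation: pd.DataFrame, classes: Mapping[str, str],
               config: SyntheticWorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = list(annotation["gene_id"])
    n = len(ids)
    base = np.exp(config.base_log_mean
                  + config.base_log_sigma * rng.standard_normal(n))
    fold = np.array([{CLASS_UP: config.fold_up, CLASS_DOWN: config.fold_down,
                      CLASS_UNCHANGED: 1.0}[classes[g]] for g in ids])
    rows = []
    for strain, mult in (("control", np.ones(n)), ("mutant", fold)):
        for rep in range(1, config.n_replicates + 1):
            gdna = float(np.exp(config.gdna_sigma * rng.standard_normal()))
            noise = np.exp(config.noise_sigma * rng.standard_normal(n)) \
                if config.noise_sigma > 0 else np.ones(n)
            signal = base * mult * noise * gdna
            for gid, s in zip(ids, signal):
                rows.append((gid, strain, rep, s, gdna))
    return pd.DataFrame(rows, columns=io.GRO_COLUMNS)


def _tfbs_sites(annotation: pd.DataFrame, classes: Mapping[str, str],
                config: SyntheticWorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Class-biased site placement: upregulated promoters concentrate sites
    farther upstream (~-300), downregulated ones close to the TSS (~-150)."""
    center = {CLASS_UP: -300.0, CLASS_DOWN: -150.0, CLASS_UNCHANGED: -200.0}
    factors = [f"TF{i:02d}" for i in range(1, config.n_tf_factors + 1)]
    rows = []
    for _, gene in annotation.iterrows():
        cls = classes[gene["gene_id"]]
        tss = int(gene["start"]) if gene["strand"] == "+" else int(gene["end"]) - 1
        for factor in factors:
            for _ in range(int(rng.poisson(0.8))):
                d = int(round(rng.normal(center[cls], 80.0)))
                d = int(np.clip(d, -499, -1))
                pos = tss + d if gene["strand"] == "+" else tss - d
                if 0 <= pos < config.chrom_length:
                    rows.append((gene["chrom"], pos, pos + 1, factor))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "factor"])
    return df.sort_values(["chrom", "start", "factor"]).reset_index(drop=True)


def _conservation_track(annotation: pd.DataFrame, classes: Mapping[str, str],
                        config: SyntheticWorldConfig) -> dict[str, np.ndarray]:
    tracks = {f"chr{i + 1}": np.full(config.chrom_length, 0.30)
              for i in range(config.n_chroms)}
    for _, gene in annotation.iterrows():
        if classes[gene["gene_id"]] != CLASS_DOWN:
            continue
        tss = int(gene["start"]) if gene["strand"] == "+" else int(gene["end"]) - 1
        lo, hi = _oriented_slice(tss, gene["strand"], -400, 400, config.chrom_length)
        tracks[gene["chrom"]][lo:hi] = 0.65
    return tracks


def _mark_table(annotation: pd.DataFrame, classes: Mapping[str, str],
                config: SyntheticWorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for mark in config.marks:
        is_acetyl = mark.endswith("ac")
        for gid in annotation["gene_id"]:
            cls = classes[gid]
            prom = float(rng.standard_normal())
            orf = float(rng.standard_normal())
            if cls == CLASS_UP and (is_acetyl or mark == "H3K36me2"):
                prom -= config.mark_shift
                orf -= config.mark_shift
            if cls == CLASS_DOWN:
                if mark == "H2AZK14ac":
                    prom += config.mark_shift
                if mark == "H3K4me3":
                    orf += config.mark_shift
            rows.append((gid, mark, prom, orf))
    return pd.DataFrame(rows, columns=io.MARK_COLUMNS)


def _gene_lists(annotation: pd.DataFrame, classes: Mapping[str, str],
                config: SyntheticWorldConfig,
                rng: np.random.Generator) -> tuple[dict[str, set], dict[str, set]]:
    ids = list(annotation["gene_id"])
    up = [g for g in ids if classes[g] == CLASS_UP]
    down = [g for g in ids if classes[g] == CLASS_DOWN]

    def biased(base_p: float, up_mult: float, down_mult: float) -> set[str]:
        chosen = set()
        for g in ids:
            p = base_p * {CLASS_UP: up_mult, CLASS_DOWN: down_mult,
                          CLASS_UNCHANGED: 1.0}[classes[g]]
            if rng.random() < min(1.0, p):
                chosen.add(g)
        return chosen

    lists: dict[str, set] = {}
    lists["essential"] = biased(0.18, 0.2, 2.0)
    lists["tata"] = biased(0.18, 3.0, 1.0)
    n_esr_up = int(round(config.esr_overlap_frac * len(up)))
    n_esr_down = int(round(config.esr_overlap_frac * len(down)))
    esr_up_planted = set(rng.choice(up, size=n_esr_up, replace=False)) if n_esr_up else set()
    esr_down_planted = set(rng.choice(down, size=n_esr_down, replace=False)) if n_esr_down else set()
    background = [g for g in ids if classes[g] == CLASS_UNCHANGED]
    lists["esr_up"] = esr_up_planted | {g for g in background if rng.random() < 0.12}
    lists["esr_down"] = esr_down_planted | {g for g in background if rng.random() < 0.12}
    for remodeler in REMODELERS:
        lists[f"remodeler_{remodeler}"] = biased(0.10, 0.3, config.remodeler_boost)
    truth_extra = {"esr_up_planted": esr_up_planted,
                   "esr_down_planted": esr_down_planted}
    return lists, truth_extra


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world (deterministic for a fixed seed)."""
    ann = _place_genes(config, _rng(config.seed, 1))
    classes = _assign_classes(ann, config, _rng(config.seed, 2))
    genome = _build_sequences(ann, classes, config, _rng(config.seed, 3))
    nucleosomes = _place_nucleosomes(ann, classes, config)
    gro = _gro_table(ann, classes, config, _rng(config.seed, 4))
    tfbs = _tfbs_sites(ann, classes, config, _rng(config.seed, 5))
    tracks = {"conservation": _conservation_track(ann, classes, config)}
    marks = _mark_table(ann, classes, config, _rng(config.seed, 6))
    gene_lists, truth_extra = _gene_lists(ann, classes, config, _rng(config.seed, 7))
    truth = {
        CLASS_UP: {g for g, c in classes.items() if c == CLASS_UP},
        CLASS_DOWN: {g for g, c in classes.items() if c == CLASS_DOWN},
        **truth_extra,
    }
    assert truth[CLASS_UP].isdisjoint(truth[CLASS_DOWN])
    return SyntheticWorld(config, genome, ann, gro, nucleosomes, tfbs, tracks,
                          marks, gene_lists, truth)


def write_world(world: SyntheticWorld, directory) -> dict[str, Path]:
    """Write a world as plain-text files; round-trips through the readers.

    Layout: genome.fa, genes.bed (BED6), nucleosomes.bed (BED4, label in the
    name field), tfbs.bed (BED6, factor in the name field), gro.tsv,
    marks.tsv, tracks/<name>.bedgraph, gene_lists/<name>.txt,
    truth_up.txt / truth_down.txt, config.yaml.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "tracks").mkdir(exist_ok=True)
        (directory / "gene_lists").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create world directory {directory}: {exc}") from exc
    paths: dict[str, Path] = {}

    paths["genome"] = directory / "genome.fa"
    io.write_fasta(world.genome, paths["genome"])

    genes = world.annotation.copy()
    genes["score"] = 0
    paths["genes"] = directory / "genes.bed"
    io.write_bed(genes.rename(columns={"gene_id": "name"}), paths["genes"],
                 columns=["chrom", "start", "end", "name", "score", "strand"])

    paths["nucleosomes"] = directory / "nucleosomes.bed"
    io.write_bed(world.nucleosomes.rename(columns={"label": "name"}),
                 paths["nucleosomes"], columns=["chrom", "start", "end", "name"])

    tf = world.tfbs.copy()
    tf["score"] = 0
    tf["strand"] = "+"
    paths["tfbs"] = directory / "tfbs.bed"
    io.write_bed(tf.rename(columns={"factor": "name"}), paths["tfbs"],
                 columns=["chrom", "start", "end", "name", "score", "strand"])

    paths["gro"] = directory / "gro.tsv"
    io.write_gro_table(world.gro, paths["gro"])

    paths["marks"] = directory / "marks.tsv"
    io.write_marks_table(world.marks, paths["marks"])

    for name, arrays in world.tracks.items():
        p = directory / "tracks" / f"{name}.bedgraph"
        io.write_bedgraph(io.arrays_to_bedgraph(arrays), p)
        paths[f"track_{name}"] = p

    for name, ids in world.gene_lists.items():
        p = directory / "gene_lists" / f"{name}.txt"
        io.write_gene_list(ids, p)
        paths[f"list_{name}"] = p

    paths["truth_up"] = directory / "truth_up.txt"
    io.write_gene_list(world.truth[CLASS_UP], paths["truth_up"])
    paths["truth_down"] = directory / "truth_down.txt"
    io.write_gene_list(world.truth[CLASS_DOWN], paths["truth_down"])

    cfg = dataclasses.asdict(world.config)
    cfg["spacing_by_class"] = dict(cfg["spacing_by_class"])
    cfg["marks"] = list(cfg["marks"])
    paths["config"] = directory / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def load_world(directory) -> SyntheticWorld:
    """Reconstruct a written world through the pipeline's readers."""
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    cfg["spacing_by_class"] = dict(cfg["spacing_by_class"])
    cfg["marks"] = tuple(cfg["marks"])
    config = SyntheticWorldConfig(**cfg)
    genome = io.read_fasta(directory / "genome.fa")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    genes = io.read_bed(directory / "genes.bed")
    annotation = genes.rename(columns={"name": "gene_id"})[
        ["gene_id", "chrom", "start", "end", "strand"]]
    nucleosomes = io.read_bed(directory / "nucleosomes.bed").rename(
        columns={"name": "label"})[["chrom", "start", "end", "label"]]
    tf = io.read_bed(directory / "tfbs.bed")
    if len(tf):
        tfbs = tf.rename(columns={"name": "factor"})[["chrom", "start", "end", "factor"]]
    else:
        tfbs = pd.DataFrame(columns=["chrom", "start", "end", "factor"])
    gro = io.read_gro_table(directory / "gro.tsv")
    marks = io.read_marks_table(directory / "marks.tsv")
    tracks = {}
    for p in sorted((directory / "tracks").glob("*.bedgraph")):
        tracks[p.stem] = io.track_to_arrays(io.read_bedgraph(p), chrom_lengths)
    gene_lists = {p.stem: io.read_gene_list(p)
                  for p in sorted((directory / "gene_lists").glob("*.txt"))}
    truth = {
        CLASS_UP: io.read_gene_list(directory / "truth_up.txt"),
        CLASS_DOWN: io.read_gene_list(directory / "truth_down.txt"),
    }
    return SyntheticWorld(config, genome, annotation, gro, nucleosomes, tfbs,
                          tracks, marks, gene_lists, truth)
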