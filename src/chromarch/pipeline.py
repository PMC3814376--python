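"""End-to-end orchestration: load inputs, run every analysis stage, and emit
per-stage TSV tables plus one machine-readable JSON summary.

The stage order mirrors the analysis: GRO differential calls and ESR
subtraction first, then gene-class enrichment, promoter geometry and TFBS
matrices, sequence composition and conservation profiles, nucleosome
spacing/occupancy/dynamics and remodeler enrichment, curvature-symmetry
profiles, and histone-mark enrichment. All randomness flows from the single
configured seed, so a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .enrichment_stats import fisher_exact_2x2, bootstrap_enrichment, relative_enrichment
from .gro_transcription import (OutlierRule, compute_changes, deregulated_sets,
                                replicate_concordance)
from .nucleosome_chromatin import (dynamic_overlap_profile, histone_mark_enrichment,
                                   occupancy_meta_profile, remodeler_enrichment,
                                   spacing_table, DYNAMIC_LABELS)
from .promoter_sequence import (find_bidirectional_pairs, conservation_meta_profile,
                                promoter_region, sliding_composition,
                                tfbs_bin_matrix, tss_meta_profile)
from .symcurv import genome_symcurv, symcurv_meta_profile
from .synthetic_data import SyntheticWorldConfig, generate_world, write_world


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the original cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and sizes for a full pipeline run."""

    gro: str
    genome: str
    genes: str
    nucleosomes: str
    outdir: str
    tfbs: str | None = None
    conservation: str | None = None
    marks: str | None = None
    gene_lists_dir: str | None = None
    up_threshold: float = 1.5
    down_threshold: float = 0.65
    bidirectional_span: int = 600
    alpha: float = 0.001
    tfbs_bin: int = 20
    tfbs_upstream: int = 500
    tfbs_downstream: int = 300
    occupancy_bin: int = 10
    composition_window: int = 100
    upstream: int = 500
    downstream: int = 500
    n_trials: int = 1000
    min_valid: int = 2
    outlier_k: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("up_threshold", "down_threshold", "bidirectional_span",
                     "alpha", "tfbs_bin", "occupancy_bin", "composition_window",
                     "n_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def world_pipeline_config(world_dir, outdir, **overrides) -> PipelineConfig:
    """PipelineConfig pointing at a written synthetic world directory."""
    d = Path(world_dir)
    defaults = dict(
        gro=str(d / "gro.tsv"), genome=str(d / "genome.fa"),
        genes=str(d / "genes.bed"), nucleosomes=str(d / "nucleosomes.bed"),
        tfbs=str(d / "tfbs.bed"),
        conservation=str(d / "tracks" / "conservation.bedgraph"),
        marks=str(d / "marks.tsv"), gene_lists_dir=str(d / "gene_lists"),
        outdir=str(outdir))
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def _require(path, stage: str, what: str):
    if path is None or not Path(path).exists():
        raise PipelineError(stage, f"missing {what} file: {path}")
    return path


def load_inputs(config: PipelineConfig) -> dict:
    """Read every configured input; missing required files abort with the
    stage name and the offending path."""
    stage = "load_inputs"
    inputs: dict = {}
    inputs["gro"] = io.read_gro_table(_require(config.gro, stage, "GRO table"))
    inputs["genome"] = io.read_fasta(_require(config.genome, stage, "genome FASTA"))
    inputs["chrom_lengths"] = {c: len(s) for c, s in inputs["genome"].items()}
    genes = io.read_bed(_require(config.genes, stage, "gene annotation BED"))
    inputs["annotation"] = genes.rename(columns={"name": "gene_id"})[
        ["gene_id", "chrom", "start", "end", "strand"]]
    nuc = io.read_bed(_require(config.nucleosomes, stage, "nucleosome BED"))
    if "name" not in nuc.columns:
        nuc["name"] = "bulk"
    inputs["nucleosomes"] = nuc.rename(columns={"name": "label"})[
        ["chrom", "start", "end", "label"]]
    if config.tfbs:
        tf = io.read_bed(_require(config.tfbs, stage, "TFBS BED"))
        inputs["tfbs"] = (tf.rename(columns={"name": "factor"})
                          [["chrom", "start", "end", "factor"]] if len(tf)
                          else pd.DataFrame(columns=["chrom", "start", "end", "factor"]))
    if config.conservation:
        track = io.read_bedgraph(_require(config.conservation, stage,
                                          "conservation bedGraph"))
        inputs["conservation"] = io.track_to_arrays(track, inputs["chrom_lengths"])
    if config.marks:
        inputs["marks"] = io.read_marks_table(_require(config.marks, stage,
                                                       "mark score table"))
    inputs["gene_lists"] = {}
    if config.gene_lists_dir and Path(config.gene_lists_dir).is_dir():
        for p in sorted(Path(config.gene_lists_dir).glob("*.txt")):
            inputs["gene_lists"][p.stem] = io.read_gene_list(p)
    return inputs


def _round_list(values, nd: int = 6) -> list:
    return [None if not np.isfinite(v) else round(float(v), nd) for v in values]


def stage_gro(inputs, config: PipelineConfig):
    rule = OutlierRule(k=config.outlier_k)
    changes = compute_changes(inputs["gro"], rule, config.min_valid,
                              config.up_threshold, config.down_threshold)
    lists = inputs["gene_lists"]
    sets = deregulated_sets(changes, lists.get("esr_up", set()),
                            lists.get("esr_down", set()))
    concordance = replicate_concordance(inputs["gro"])
    universe = set(changes.loc[changes["status"] != "excluded", "gene_id"])
    return changes, sets, concordance, universe


def stage_classes(sets, universe, inputs, config: PipelineConfig):
    """Essential/TATA enrichment with Fisher and bootstrap p-values."""
    results = []
    lists = inputs["gene_lists"]
    counter = 0
    for class_name in ("essential", "tata"):
        class_set = lists.get(class_name)
        if not class_set:
            continue
        for set_name, subset in (("up", sets.up_strict), ("down", sets.down_strict)):
            subset = set(subset) & universe
            if not subset:
                continue
            counter += 1
            res = relative_enrichment(subset, class_set, universe,
                                      subset_name=set_name, class_name=class_name)
            k = len(class_set & universe)
            a = res.observed
            table = [[a, len(subset) - a],
                     [k - a, len(universe) - len(subset) - (k - a)]]
            fisher_p = fisher_exact_2x2(table)
            boot_p = bootstrap_enrichment(len(subset), class_set, universe,
                                          res.ratio, config.n_trials,
                                          config.seed + counter)
            row = res.as_dict()
            row["fisher_p"] = fisher_p
            row["p_value"] = boot_p
            row["method"] = "bootstrap+fisher"
            row["n_trials"] = config.n_trials
            row["seed"] = config.seed + counter
            results.append(row)
    return results


def stage_promoter(sets, universe, inputs, config: PipelineConfig):
    ann = inputs["annotation"]
    pairs = find_bidirectional_pairs(ann, config.bidirectional_span)
    paired = set(pairs["minus_gene"]) | set(pairs["plus_gene"])
    gene_sets = {"all": universe, "up": set(sets.up_strict) & universe,
                 "down": set(sets.down_strict) & universe}
    sizes = {}
    bidir_frac = {}
    promoter_rows = []
    for name, ids in gene_sets.items():
        lengths = []
        for gid in sorted(ids):
            region = promoter_region(gid, ann, inputs["chrom_lengths"])
            lengths.append(region.length)
            if name == "all":
                promoter_rows.append((gid, region.chrom, region.start, region.end,
                                      region.length, gid in paired))
        sizes[name] = float(np.mean(lengths)) if lengths else float("nan")
        bidir_frac[name] = (len(ids & paired) / len(ids)) if ids else float("nan")
    promoters = pd.DataFrame(promoter_rows, columns=["gene_id", "chrom", "start",
                                                     "end", "length", "bidirectional"])
    matrices = {}
    if "tfbs" in inputs:
        for name, ids in gene_sets.items():
            if ids:
                matrices[name] = tfbs_bin_matrix(
                    inputs["tfbs"], ann, ids, config.tfbs_upstream,
                    config.tfbs_downstream, config.tfbs_bin, normalize="zscore")
    return pairs, promoters, sizes, bidir_frac, matrices


def stage_composition(sets, universe, inputs, config: PipelineConfig):
    ann = inputs["annotation"]
    gene_sets = {"all": universe, "up": set(sets.up_strict) & universe,
                 "down": set(sets.down_strict) & universe}
    stats = ("gc_fraction", "at_skew", "gc_skew")
    tracks = {stat: {c: sliding_composition(seq, config.composition_window,
                                            1, stat)[0]
                     for c, seq in inputs["genome"].items()}
              for stat in stats}
    profiles: dict[str, dict] = {stat: {} for stat in stats}
    for stat in stats:
        flip = stat in ("at_skew", "gc_skew")
        for name, ids in gene_sets.items():
            if ids:
                profiles[stat][name] = tss_meta_profile(
                    tracks[stat], ann, ids, config.upstream, config.downstream,
                    flip_sign=flip, statistic=stat)
    conservation = {}
    if "conservation" in inputs:
        for name, ids in gene_sets.items():
            if ids:
                conservation[name] = conservation_meta_profile(
                    inputs["conservation"], ann, ids, config.upstream,
                    config.downstream)
    return profiles, conservation


def stage_chromatin(sets, universe, inputs, config: PipelineConfig):
    ann = inputs["annotation"]
    nuc = inputs["nucleosomes"]
    lengths = inputs["chrom_lengths"]
    gene_sets = {"all": universe, "up": set(sets.up_strict) & universe,
                 "down": set(sets.down_strict) & universe}
    spacing = {}
    occupancy = {}
    dynamics: dict[str, dict] = {}
    for name, ids in gene_sets.items():
        if not ids:
            continue
        table = spacing_table(ann, ids, nuc)
        spacing[name] = {"mean": float(table.loc[table["defined"],
                                                 "mean_spacing"].mean()),
                         "n_defined": int(table["defined"].sum()),
                         "table": table}
        occupancy[name] = occupancy_meta_profile(
            nuc, ann, ids, lengths, config.upstream, config.downstream,
            config.occupancy_bin, normalize="zscore")
        for label in DYNAMIC_LABELS:
            if (nuc["label"] == label).any():
                dynamics.setdefault(label, {})[name] = dynamic_overlap_profile(
                    nuc, label, ann, ids, lengths, config.upstream,
                    config.downstream, config.occupancy_bin)
    remodelers = {k[len("remodeler_"):]: v
                  for k, v in inputs["gene_lists"].items()
                  if k.startswith("remodeler_")}
    remodeler_results = []
    if remodelers:
        dereg = {"up": set(sets.up_strict) & universe,
                 "down": set(sets.down_strict) & universe}
        dereg = {k: v for k, v in dereg.items() if v}
        remodeler_results = remodeler_enrichment(dereg, remodelers, universe,
                                                 config.n_trials,
                                                 config.seed + 1000)
    return spacing, occupancy, dynamics, remodeler_results


def stage_symcurv(sets, universe, inputs, config: PipelineConfig):
    tracks = genome_symcurv(inputs["genome"])
    ann = inputs["annotation"]
    gene_sets = {"all": universe, "up": set(sets.up_strict) & universe,
                 "down": set(sets.down_strict) & universe}
    out = {}
    for name, ids in gene_sets.items():
        if ids:
            prof, degenerate = symcurv_meta_profile(
                inputs["genome"], ann, ids, config.upstream, config.downstream,
                tracks=tracks)
            out[name] = (prof, degenerate)
    return out


def stage_marks(sets, universe, inputs, config: PipelineConfig):
    results = {}
    for name, subset in (("up", set(sets.up_strict) & universe),
                         ("down", set(sets.down_strict) & universe)):
        if subset and subset != universe:
            results[name] = histone_mark_enrichment(inputs["marks"], subset,
                                                    universe, config.alpha)
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Outputs are staged in a temporary directory and moved into place only
    after all stages succeed, so a failure leaves no partial results. Returns
    the JSON-serializable summary.
    """
    def run_stage(name, fn, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    inputs = load_inputs(config)
    summary: dict = {"seed": config.seed,
                     "thresholds": {"up": config.up_threshold,
                                    "down": config.down_threshold,
                                    "bidirectional_span": config.bidirectional_span,
                                    "alpha": config.alpha},
                     "n_trials": config.n_trials}
    tables: dict[str, pd.DataFrame] = {}

    changes, sets, concordance, universe = run_stage("gro", stage_gro, inputs, config)
    lists = inputs["gene_lists"]
    changes_out = changes.copy()
    changes_out["in_esr"] = changes_out["gene_id"].isin(
        set(lists.get("esr_up", set())) | set(lists.get("esr_down", set())))
    strict = {"up": set(sets.up_strict), "down": set(sets.down_strict)}
    changes_out["strict_status"] = [
        s if (s in ("unchanged", "excluded") or g in strict.get(s, set()))
        else "unchanged"
        for g, s in zip(changes_out["gene_id"], changes_out["status"])]
    tables["gro_changes"] = changes_out
    summary["gro"] = {
        "n_genes": int(len(changes)),
        "n_excluded": int((changes["status"] == "excluded").sum()),
        "discarded_frac": round(changes.attrs["discarded_frac"], 6),
        "n_up_raw": len(sets.up_raw), "n_down_raw": len(sets.down_raw),
        "n_up_strict": len(sets.up_strict), "n_down_strict": len(sets.down_strict),
        "min_concordance": round(min(
            float(m.values[np.triu_indices(len(m), 1)].min())
            for m in concordance.values()), 6),
    }

    summary["gene_classes"] = run_stage("gene_classes", stage_classes,
                                        sets, universe, inputs, config)
    if summary["gene_classes"]:
        tables["gene_class_enrichment"] = pd.DataFrame(summary["gene_classes"])

    pairs, promoters, sizes, bidir_frac, matrices = run_stage(
        "promoter", stage_promoter, sets, universe, inputs, config)
    tables["bidirectional_pairs"] = pairs
    tables["promoters"] = promoters
    summary["promoter"] = {"mean_size": {k: round(v, 3) for k, v in sizes.items()},
                           "bidirectional_frac": {k: round(v, 6)
                                                  for k, v in bidir_frac.items()},
                           "n_pairs": int(len(pairs))}
    for name, mat in matrices.items():
        tables[f"tfbs_matrix_{name}"] = mat.matrix.reset_index(names="factor")
    if matrices:
        summary["tfbs"] = {
            name: {"peak_offset": int(mat.matrix.sum(axis=0).idxmax()),
                   "flagged_factors": mat.flagged_factors}
            for name, mat in matrices.items()}

    profiles, conservation = run_stage("composition", stage_composition,
                                       sets, universe, inputs, config)
    summary["composition"] = {}
    for stat, per_set in profiles.items():
        summary["composition"][stat] = {}
        for name, prof in per_set.items():
            summary["composition"][stat][name] = {
                "values": _round_list(prof.values), "n_genes": prof.n_genes}
            tables[f"composition_{stat}_{name}"] = pd.DataFrame(
                {"offset": prof.offsets, "value": prof.values})
    if conservation:
        summary["composition"]["conservation"] = {
            name: {"values": _round_list(p.values), "n_genes": p.n_genes}
            for name, p in conservation.items()}

    spacing, occupancy, dynamics, remodeler_results = run_stage(
        "chromatin", stage_chromatin, sets, universe, inputs, config)
    summary["nucleosomes"] = {
        "mean_spacing": {k: round(v["mean"], 3) for k, v in spacing.items()},
        "occupancy": {k: {"values": _round_list(p.values), "bin": p.bin,
                          "n_genes": p.n_genes}
                      for k, p in occupancy.items()},
        "dynamics": {label: {k: {"values": _round_list(p.values),
                                 "n_genes": p.n_genes}
                             for k, p in per_set.items()}
                     for label, per_set in dynamics.items()},
    }
    for name, entry in spacing.items():
        tables[f"spacing_{name}"] = entry["table"]
    if remodeler_results:
        remodeler_df = pd.DataFrame([r.as_dict() for r in remodeler_results])
        tables["remodeler_enrichment"] = remodeler_df
        summary["remodelers"] = [r.as_dict() for r in remodeler_results]

    symcurv_profiles = run_stage("symcurv", stage_symcurv,
                                 sets, universe, inputs, config)
    summary["symcurv"] = {
        name: {"values": _round_list(prof.values), "degenerate": degenerate,
               "n_genes": prof.n_genes}
        for name, (prof, degenerate) in symcurv_profiles.items()}

    if "marks" in inputs:
        mark_results = run_stage("histone_marks", stage_marks,
                                 sets, universe, inputs, config)
        summary["histone_marks"] = {}
        for name, df in mark_results.items():
            tables[f"histone_marks_{name}"] = df
            summary["histone_marks"][name] = [
                {"mark": r["mark"], "compartment": r["compartment"],
                 "direction": r["direction"], "p_value": float(r["p_value"]),
                 "significant": bool(r["significant"])}
                for _, r in df.iterrows()]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".staging_", dir=outdir))
    try:
        for name, df in tables.items():
            df.to_csv(staging / f"{name}.tsv", sep="\t", index=False)
        with open(staging / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        for p in sorted(staging.iterdir()):
            shutil.move(str(p), outdir / p.name)
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return summary


def make_fixtures(seed: int, directory, n_genes: int = 60,
                  chrom_length: int = 70_000) -> SyntheticWorldConfig:
    """Write a small synthetic world for test suites; idempotent per seed."""
    config = SyntheticWorldConfig(seed=seed, n_chroms=2,
                                  chrom_length=chrom_length, n_genes=n_genes)
    write_world(generate_world(config), directory)
    return config
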