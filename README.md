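# chromarch

Analysis pipeline for asking how an acute perturbation — the thermal
inactivation of topoisomerase II in budding yeast is the motivating case —
changes gene-level **transcription rates**, and what is structurally special
about the affected genes: their promoter geometry, transcription-factor
binding-site layout, DNA base composition, nucleosome organization,
intrinsic nucleosome-forming potential and histone-modification landscape.

It is aimed at computational genomicists working with genomic run-on (GRO)
or similar nascent-transcription array data plus the standard yeast genomic
resources (annotation, nucleosome maps, TFBS catalogs, per-gene mark
scores). A first-class synthetic-data module generates a complete input
"world" with planted, recoverable structure, so the entire pipeline runs
and is validated offline.

## What it computes

**Differential transcription.** For each gene, replicate GRO signals of two
strains (`control`, `mutant`) are divided by their genomic-DNA
normalization signal, within-gene outliers are removed by a
median-absolute-deviation rule (|x − median| ≤ k·MAD, k = 3), and
replicates are averaged (a gene needs ≥ 2 valid replicates per strain).
The transcription-rate change is

&nbsp;&nbsp;&nbsp;&nbsp;R = mean(mutant) / mean(control),

called **up** if R > 1.5, **down** if R < 0.65, else unchanged.
Environmental-stress-response (ESR) genes can be subtracted to leave
strictly perturbation-specific sets.

**Gene-set statistics.** Class enrichment is the observed/expected ratio
|S ∩ C| / (|S|·|C|/|U|) with Fisher exact and bootstrap p-values
(1000 random gene sets, add-one smoothing so p ≥ 1/1001); mark enrichment
uses the Wilcoxon rank-sum test per mark and compartment (promoter vs ORF)
flagged at p < 0.001; expression variability is |q98 − q2| after trimming
the extreme 1%.

**Promoter & sequence architecture.** Promoters are the complete intergenic
region upstream of the TSS; bidirectional promoters are divergent gene
pairs with TSS-to-TSS span ≤ 600 bp. TFBS positions are binned (20 bp) and
Z-scored per factor. GC content and Chargaff second-parity-rule deviations
(A−T)/(A+T) and (G−C)/(G+C) are computed in 100-nt sliding windows and
averaged in TSS-anchored, strand-oriented meta-profiles (skews sign-flip on
the minus strand).

**Chromatin.** Nucleosome spacing is the mean of the N−1 edge-to-edge
linkers in a gene body; occupancy meta-profiles are the fraction of each
10-bp bin covered by nucleosomes; appearing/evicted/fragile nucleosome
classes get percent-overlap profiles; remodeler target lists get bootstrap
enrichment ratios.

**SymCurv-style nucleosome-forming potential.** A dinucleotide wedge model
predicts per-base curvature c(i); the score

&nbsp;&nbsp;&nbsp;&nbsp;S(i) = 1 / (1 + D(i)),&nbsp;&nbsp;
D(i) = mean<sub>k=1..73</sub> |c(i−k) − c(i+k)|

measures mirror symmetry of curvature around a candidate dyad
(S ∈ (0, 1], S = 1 exactly for mirror-symmetric flanks).

## Worked example

```python
from chromarch import (SyntheticWorldConfig, generate_world, compute_changes,
                       deregulated_sets, spacing_table)

config = SyntheticWorldConfig(seed=11, n_chroms=4, chrom_length=1_150_000,
                              n_genes=2000, frac_up=0.05, frac_down=0.03,
                              fold_up=2.0, fold_down=0.5, noise_sigma=0.1)
world = generate_world(config)

changes = compute_changes(world.gro)             # normalize, filter, merge, call
sets = deregulated_sets(changes, world.gene_lists["esr_up"],
                        world.gene_lists["esr_down"])
print(f"up: {len(sets.up_raw)} raw -> {len(sets.up_strict)} after ESR subtraction")
print(f"down: {len(sets.down_raw)} raw -> {len(sets.down_strict)} after ESR subtraction")

for name, ids in (("down", sets.down_raw), ("up", sets.up_raw)):
    t = spacing_table(world.annotation, ids, world.nucleosomes)
    print(f"mean nucleosome spacing ({name}): "
          f"{t.loc[t['defined'], 'mean_spacing'].mean():.1f} bp")
```

prints

```
up: 100 raw -> 67 after ESR subtraction
down: 60 raw -> 40 after ESR subtraction
mean nucleosome spacing (down): 21.0 bp
mean nucleosome spacing (up): 29.0 bp
```

All 100 planted upregulated and 60 downregulated genes are recovered
(5%/3% of 2000), one-third of each lands in the planted ESR lists and is
subtracted, and the class-specific linker lengths planted in the nucleosome
arrays (21 bp for downregulated, 29 bp for upregulated genes) are recovered
exactly by the spacing estimator.

The command line mirrors the library:

```bash
chromarch all --seed 4 --out demo          # synthetic world + full report
chromarch report --world demo/world --out demo/report2 --seed 4
chromarch symcurv --fasta demo/world/genome.fa --out demo/sc
```

`demo/report/summary.json` holds every number (set sizes, enrichment
tables, profiles); one TSV per analysis sits beside it.

## Documentation

`docs/methods.md` describes the models, parameter choices, synthetic-data
assumptions and known limitations.
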