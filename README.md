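# ystrkit

Forensic and population-genetic analysis of Y-chromosomal STR haplotypes.

Y-STRs are short tandem repeats on the male-specific region of the Y
chromosome. They are inherited patrilineally without recombination, so a
man's multi-locus profile is a single haplotype, and forensic usefulness
hinges on how rare haplotypes are in the relevant population. `ystrkit` is
aimed at forensic geneticists building or evaluating Y-STR population
reference data: it reads multi-locus haplotype tables (one row per male;
multi-copy markers such as DYS385a/b held as unordered allele
combinations), computes the standard forensic parameters, derives pairwise
Rst genetic distances between populations by AMOVA on repeat counts, and
summarizes population structure with classical MDS, a UPGMA tree, PCA and
heatmap ordering. A stepwise-mutation-model simulator generates datasets
with known structure for validation and power exploration.

## Statistics

With haplotype (or per-locus allele) frequencies `p_i` obtained by direct
counting in a sample of `n` males:

- **Gene diversity / haplotype diversity** (Nei):
  `GD = HD = n (1 − Σ p_i²) / (n − 1)`
- **Match probability**: `MP = Σ p_i²` over haplotype frequencies — the
  probability that two random males share a haplotype
- **Discrimination capacity**: `DC = (number of distinct haplotypes) / n`

Between populations, the molecular distance between two haplotypes is the
summed squared difference in repeat counts over shared markers (multi-copy
markers pair their sorted allele lists copy by copy). A single-level AMOVA
partitions the total sum of squares into among- and within-population
variance components `σ²_a` and `σ²_w`, giving Slatkin's

```
Rst = σ²_a / (σ²_a + σ²_w)
```

with a permutation test for significance. Built-in marker panels cover the
AGCU Y37 kit (34 markers, 37 locus copies) and its Yfiler (17) and Yfiler
Plus (27) subsets; panels are editable YAML files.

## Worked example

Simulate two populations that split 400 generations ago (effective male
size 500, mutation rate 2×10⁻³ per locus per generation), then summarize:

```python
import ystrkit as yk

panel = yk.builtin_panel("AGCU37")
cfg = yk.SimulationConfig(
    panel=panel, n_populations=2, samples_per_population=(206, 246),
    divergence_generations=400, effective_males_per_population=500,
    mutation_rate_per_locus=2e-3, seed=7,
)
sim = yk.simulate_dataset(cfg)
for ds in sim.datasets:
    print(yk.summarize_population(ds).rounded())
r = yk.amova_pair(*sim.datasets)
print("Rst =", round(r.rst, 4))
print("p =", yk.permutation_pvalue(*sim.datasets, n_perm=999, seed=1))
```

prints

```
{'population': 'pop1', 'panel': 'AGCU37', 'n': 206, 'distinct_haplotypes': 97,
 'HD': 0.9868, 'MP': 0.018, 'DC': 0.4709, 'DC_percent': 47.09}
{'population': 'pop2', 'panel': 'AGCU37', 'n': 246, 'distinct_haplotypes': 114,
 'HD': 0.988, 'MP': 0.0161, 'DC': 0.4634, 'DC_percent': 46.34}
Rst = 0.1811
p = 0.001
```

i.e. after 400 generations of isolation the simulated populations retain
high within-population haplotype diversity (HD ≈ 0.99) while about 18% of
repeat-size variance lies between populations, a highly significant
differentiation (p = 0.001 with 999 permutations). Real population surveys
show much higher DC because founders are diverse rather than a single
ancestral haplotype.

The same pipeline is available from the shell:

```
ystr simulate --pops 2 --n 100 --generations 400 --seed 7 --out sim.tsv
ystr run --input sim.tsv --panel AGCU37 --rst-panel YFILERPLUS27 \
    --seed 7 --outdir results/
```

which writes the forensic summary table, per-locus GD table, Rst matrix,
MDS coordinates, Newick UPGMA tree, PCA report, heatmap-ordered matrix and
a checksummed manifest.

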