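# msapop

Population epigenetics from MSAP/TMD isoschizomer band patterns.

`msapop` is for researchers who profile cytosine methylation in natural
plant populations with the methylation-sensitive amplified polymorphism
(MSAP) assay or its transposon-anchored variant (TMD), and want a
reproducible, scriptable path from digitized band tables to methylation
levels, CG/CHG context fractions and formal tests of population structure.

## The method

MSAP digests every DNA sample twice with the isoschizomers **HpaII** (H
lane) and **MspI** (M lane), which both recognize CCGG but differ in
methylation sensitivity: MspI still cuts when the internal cytosine is
CG-methylated, while HpaII still cuts when the external cytosine is
CHG-hemimethylated. Reading the paired presence/absence calls at one band
site classifies it:

| H | M | state |
|---|---|-------|
| 1 | 1 | unmethylated |
| 0 | 1 | CG (internal cytosine methylated) |
| 1 | 0 | CHG (external cytosine hemimethylated) |
| 0 | 0 | uninformative (full methylation ≡ fragment absence) |

A sample's **methylation level** is the fraction of its scored sites that
are lane-polymorphic (H ≠ M within the individual). Band sites whose
variation is concordant in both lanes across samples carry no methylation
signal and are excluded — as ordinary AFLP sequence polymorphism for
genome-wide MSAP, or as transposition presence/absence polymorphism for
TE-anchored TMD.

Population structure is then tested on binary marker matrices (one marker
per retained site and lane):

* **Resemblance** — binary Bray-Curtis (Sørensen) similarity
  `2a/(2a+b+c)` and Jaccard `a/(a+b+c)`;
* **Clustering** — group-average (UPGMA) agglomeration on `1 − S`, with
  the **SIMPROF** permutation test attaching a significance verdict to
  every node (statistic `π = Σ|observed_k − mean_k|` over the sorted
  similarity profile, null from independent column permutations);
* **ANOSIM** — Clarke's rank statistic
  `R = (r̄_between − r̄_within)/(M/2)`, with exhaustive or sampled label
  permutations, global and pairwise;
* **nMDS** — non-metric multidimensional scaling scored by Kruskal
  stress-1.

A forward simulator generates band matrices with planted
population-specific methylation distributions, genetic (AFLP-like) sites,
band-call error and generation-to-generation transmission, so the whole
pipeline is testable against known truth.

## Worked example

```python
from msapop import RunConfig, SimulationConfig, analyze, generate

bands, metadata, truth = generate(SimulationConfig(seed=1))
result = analyze(bands, metadata, RunConfig(
    seed=1, simprof_n_perm_mean=199, simprof_n_perm_test=199,
    anosim_n_perm=999, nmds_restarts=8,
))
print(result.report["context_fractions"]["chg_pct"])
print(result.anosim.global_r, result.anosim.global_p)
```

Running `python examples/population_structure.py` (the same analysis)
prints:

```
bands: 447 in, 13 excluded as purely genetic polymorphism
  Hermon   mean methylation level 61.7%
  Amiad    mean methylation level 62.9%
  Tabgha   mean methylation level 63.4%
  Jaba     mean methylation level 66.3%
  Amasa    mean methylation level 60.6%
context: 61.2% CHG vs 38.8% CG
SIMPROF: 7 significant nodes (alpha=0.05)
ANOSIM: global R = 0.919, p = 0.001
nMDS: 2-D stress = 0.265
```

Roughly 62–66% of scored CCGG sites per accession are methylated, mostly
in CHG context; ANOSIM's global R near 1 with p < 0.05 says
between-population dissimilarities rank almost entirely above
within-population ones, i.e. the populations carry distinct heritable
methylation patterns. The other examples show direct scoring of a small
hand-written band table and two-generation transmission of methylation
levels.

A thin CLI wraps the same library:

```sh
msapop simulate --out-dir sim --seed 1
msapop score --bands sim/bands_gen1.tsv --out levels.tsv
msapop run-all --out-dir run1 --seed 1
```

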