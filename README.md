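# hibernaseq

A tested, reusable pipeline for seasonal transcriptome studies of
hibernating mammals sequenced with long single-end pyrosequencing reads:
from multiplexed cDNA reads through demultiplexing, trimming, emulsion-PCR
artificial-replicate removal, greedy contig assembly, gene annotation,
upper-quartile count normalization, and six-way exact differential-
expression testing at a stringent FDR — plus reconstruction of the circular
mitochondrial genome from transcript reads and a closed-form read-density
model.  A synthetic-data generator emulates the study design (3 tissues ×
6 time points, trimmed read lengths ≈ Normal(335, 133), tissue-dependent
mitochondrial read fractions, planted fold changes, duplicate artifacts),
so every stage is testable offline against known ground truth.

It is aimed at researchers working on non-model organisms who need the
classical tag-count analysis stack — exact tests on integer counts rather
than dispersion-model fits — in a form whose every stage is scoreable.

## The statistics at the core

**Differential expression.**  For each gene in a tissue, a 2×k table
(k = 6 time points) holds the gene's read count per sample over the
sample's remaining assigned reads.  Under the null of constant expression
the table is multivariate hypergeometric with all margins fixed,

P(a₁…a₆) = ∏ⱼ C(cⱼ, aⱼ) / C(N, n),

and the two-sided p-value generalizes Fisher's exact test by probability
ordering: p = Σ P(T) over tables with P(T) ≤ P(obs)(1+ε).  Two independent
exact algorithms (meet-in-the-middle enumeration; a network dynamic program
with longest/shortest-path pruning and closed-form terminal columns) are
cross-checked to relative 1e-6, all in log space so p-values far below
1e-13 never underflow.  Benjamini–Hochberg FDR is applied per tissue and
genes are flagged at q ≤ 1.0×10⁻¹¹.

**Normalization.**  Within each tissue, each sample's counts are scaled by
its 75th-percentile gene count (zero-in-tissue genes excluded, linear
interpolation) relative to the tissue-mean upper quartile, then rounded
half-up back to integers.  No transcript-length correction is applied.

**Read density.**  Under uniform fragmentation a read of length J on a
transcript of length L overlaps position I with probability

p(I, J, L) = min(I, J, L−I+1, L−J+1) / (L−J+1),

piecewise linear in I with Σ_I p = J exactly; averaging over the observed
read-length distribution gives an expected density that is compared to
observed coverage by a coefficient of determination R² = 1 − SS_res/SS_tot.

## Worked example

```python
from hibernaseq import SimulationConfig, PlantedEffect
from hibernaseq.simulate import generate_reference, sample_count_matrix
from hibernaseq.destats import de_gene_list

cfg = SimulationConfig(
    seed=42, n_tissues=1, n_timepoints=6, n_genes=120,
    transcript_length_range=(1000, 1001), mito_fraction={"heart": 0.0},
    abundance_sigma=0.0,
    planted_effects=(PlantedEffect("G0007", "heart", "Torpor", 8.0),),
)
truth = generate_reference(cfg)
counts = sample_count_matrix(truth, cfg, total_reads=20_000, tissue="heart")
results, summary = de_gene_list(counts, cutoff=1e-11)
print(f"{summary.n_pass} of {summary.n_genes} genes pass q <= {summary.cutoff:g}")
top = results[0]
print(f"top gene {top.gene}: p={top.p_value:.3g} q={top.q_value:.3g} "
      f"peak={top.peak_timepoint} fold={top.fold_change:.1f} [{top.method}]")
```

prints

```
1 of 135 genes pass q <= 1e-11
top gene G0007: p=1e-300 q=1.35e-298 peak=Torpor fold=8.8 [exact-bound]
```

One gene was planted at 8-fold in torpor in a 120-gene heart tissue at
20,000 reads per sample (the matrix also carries the 15 mitochondrial
transcript units, here at zero abundance); it is the only gene passing the
stringent cutoff, its peak is located at torpor, and the fold change of
its normalized peak over its smallest normalized count (8.8, sampling
noise around the planted 8) is reported.  The method tag records how the
p-value was certified — here by a rigorous closed-form upper bound, which
for a signal this strong sits at the 1e-300 reporting floor, hundreds of
orders of magnitude below the cutoff.

The same machinery is available from the shell:

```bash
hibernaseq simulate --seed 3 --genes 100 --tissues 1 --out sim/
hibernaseq run --seed 3 --out run_out/         # full pipeline + manifest
hibernaseq detest run_out/counts.tsv --design run_out/design.tsv \
    --tissue heart --out de.tsv
```

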