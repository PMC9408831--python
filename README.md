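# founderscan

Founder analysis for non-recombining genome phylogenies — identifying,
dating and geographically attributing migration events from the lineage
structure of a rooted mutation-count tree.

## The problem

When a migration carries lineages from a *source* population into a
*sink*, each founding lineage leaves a signature: a clade of sink
samples nested inside source diversity, whose accumulated mutations
record the time since arrival. Founder analysis formalises this for
non-recombining loci such as the mitochondrial genome. It is the
standard tool for questions like "when did sub-Saharan mitogenome
lineages arrive in North Africa, Europe, or the Americas, and from
which part of Africa did each wave come?" — cases where ancient DNA is
sparse and contemporary genomes must carry the inference.

`founderscan` implements the complete inference chain on a rooted
phylogeny whose branch lengths are integer substitution counts:

1. **Founder detection** — for every sink sample, find the most recent
   ancestor whose haplotype is attested in the source (an identical
   sampled haplotype at zero mutational distance, or an inferred
   ancestral node with source descendants).
2. **The f-criterion** — require derived diversity in the source at the
   founder node (≥ *f* mutated source-leading branches; *f* = 1, the
   classical "f1" rule, is the default) to guard against back-migration
   and erroneous matches; sink lineages under failing nodes are
   re-assigned rootward.
3. **rho dating** — each founder cluster is dated with the rho
   statistic, the mean number of mutations from the founder node to its
   sink descendants,

   ρ = (1/n) Σᵢ mᵢ,   σ²_ρ = Σ_b (n_b/n)² m_b   (Saillard estimator),

   converted to years with a linear clock of 1 substitution per 2565
   years (the purifying-selection-corrected mitogenome rate near the
   present).
4. **Migration scan** — each founder's age ± error defines a Gaussian
   over candidate migration times; these are evaluated on a 0–25 ka
   grid at 200-year steps and aggregated (weighted by cluster size)
   into a probability mass whose peaks are the most probable migration
   periods.
5. **Epoch allocation** — a fixed two-migration model (8 ka
   "prehistoric", 0.5 ka "historical" by default) statistically
   partitions every founder between the events and reports the
   lineage proportions of each.
6. **Source attribution** — each founder is assigned a broad source
   region (North / West / Central / Eastern / Southern Africa in the
   canonical scheme) by majority vote among source leaves under the
   founder node, with mutational-distance and lexicographic
   tie-breaks, yielding region-by-epoch composition tables and
   per-population epoch frequencies.

A seeded synthetic-data generator produces source/sink trees with
founder events injected at known times and regions, so the whole
pipeline is validated by parameter recovery.

## Worked example

Simulate a two-pulse scenario (30 founders arriving 500 years ago from
West Africa, 10 arriving 8000 years ago from Eastern Africa, 10 sink
samples each) and analyse it:

```bash
$ founderscan simulate --seed 42 --outdir demo/sim
40 founders, 540 samples -> demo/sim/tree.nwk

$ founderscan run --tree demo/sim/tree.nwk --metadata demo/sim/metadata.tsv \
    --source "North Africa,West Africa,Central Africa,Eastern Africa,Southern Africa" \
    --sink Sink --outdir demo/out
40 candidate nodes, 40 founder clusters (400 sink lineages) -> demo/out
  peak at 400 y (mass 0.1398)
  peak at 8000 y (mass 0.0120)
  prehistoric: 25.0% of lineages
  historical: 75.0% of lineages
```

The two scan peaks sit at 400 y and 8000 y — within one grid step of
the simulated pulses — and the two-migration model allocates 75%/25%
of sink lineages to the historical/prehistoric events, exactly the
simulated split. Per-founder dates are in `demo/out/dating.tsv`:

```
founder_id  n   rho  sigma_rho     age_years  sigma_years
F001        10  0.2  0.1414213562  513        362.7457787
F002        10  3.1  0.5567764363  7951.5     1428.131559
```

(F002 carried a mean of 3.1 mutations per lineage; at 2565 years per
substitution that is an arrival 7951 ± 1428 years ago.) The output
bundle also contains the scan (`scan.tsv`, `peaks.tsv`), per-founder
epoch posteriors (`allocation.tsv`), source-region attributions and the
region-by-epoch composition (`attribution.tsv`, `composition.tsv`),
per-population epoch frequencies, and a JSON manifest sufficient to
reproduce the run. `founderscan simulate-and-run` performs the loop in
one command and scores the result against the simulation's ground
truth.

The same interface is available from Python:

```python
import founderscan as fs

result, dataset, report = fs.simulate_and_run(fs.SimConfig(seed=42))
print(result.peaks[:2], report["estimated_epoch_proportions"])
```

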