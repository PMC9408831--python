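# Methods

## Model and assumptions

`founderscan` operates on a rooted phylogeny of a non-recombining locus
in which every branch carries an integer count of substitutions, and on
a metadata table binding each leaf to a geographic region and a
sampling population. A run designates disjoint sets of regions as the
migration *source* and *sink*; samples in neither set stay in the tree
but take no part in any tally. The method assumes the tree is correct
as given (it is typically the resolution of a reduced-median network),
that mutation counts on branches are complete (no unresolved recurrent
hits), and that mutations accumulate linearly in time.

### Founder detection

A node's haplotype counts as *attested in the source* if either

* a source leaf is reachable from the node through a path of total
  mutation count zero — the identical haplotype was sampled in the
  source; this is evaluated on connected components of zero-length
  branches, so the zero path may ascend through the tree as well as
  descend; or
* the node is an internal (inferred ancestral) node with at least one
  source-leaf descendant.

Each sink leaf's founder node is its nearest proper ancestor satisfying
either arm. The second arm makes the root attested whenever any source
sample exists, so under this rule every sink leaf has a founder node;
the "no founder" outcome can only arise under stricter screening
(below). The leaf itself is never its own founder: the founder is the
ancestral haplotype from which the sink lineage diverged.

### The f-criterion

A founder match must display diversity in the source population, which
we operationalise as: at least `f` child branches of the founder node
that lead to source leaves and carry one or more mutations. `f = 1` is
the classical f1 rule and the default; `f = 0` disables the screen.
Sink leaves whose nearest attested ancestor fails the criterion are
re-assigned to the next attested ancestor rootward that passes; leaves
with no passing ancestor are dropped with a warning. This re-assignment
matters in practice: a sink-only subclade whose stem carries no
mutations is itself attested through the zero path, but shows no source
diversity and is correctly absorbed into the enclosing founder.

### Dating

For a cluster of `n` sink leaves, rho is the mean mutation count from
the founder node to each leaf (the branch *into* the founder node is
excluded — rho dates the divergence of the sink subtree from the
founder haplotype, not the haplotype's own origin). Its standard error
follows the branch-weighted estimator

    sigma_rho^2 = sum_b (n_b / n)^2 * m_b

over the branches of the sink-restricted subtree, where `n_b` is the
number of cluster leaves below branch `b` and `m_b` its mutation
count; for a star subtree this reduces to sqrt(total)/n. Ages are
`rho * years_per_mutation` with a strictly linear clock. The default
calibration is 2565 years per substitution, the
purifying-selection-corrected whole-mitogenome rate linearised near the
present; over a 0–25 ka window the deviation of the full correction
curve from linearity is small (under about 7%), and the founder
framework requires linearity, so no time-dependent correction is
applied. Back-mutation is not modelled: path counts are simple sums.

### Migration scan

Each dated founder induces a Gaussian sampling distribution over
candidate migration times, mean `age_years` and standard deviation
`max(sigma_years, sigma_floor)`. The density is evaluated on an
inclusive grid — default 0 to 25 000 years in 200-year steps — and
renormalised over the grid support (truncation at the edges, not
reflection; this slightly sharpens peaks near zero and is the intended
behaviour for a timeframe bounded at the present). The floor, one grid
step by default, keeps zero-diversity clusters (rho = 0, sigma = 0)
from degenerating into delta spikes. Founder vectors are averaged with
weights equal to cluster sink-sample counts — the scan then reads as
the probability mass of *lineages* over migration times — with an
equal-weight option. Peaks are strict local maxima (grid ends compared
to their single neighbour).

### Epoch allocation

A fixed-epoch model — default two migrations, 8 ka ("prehistoric", the
Holocene Climate Optimum) and 0.5 ka ("historical", the onset of the
Atlantic slave trade) — partitions each founder by evaluating the same
Gaussian at the epoch times under a uniform prior and normalising. If
every density underflows, the nearest epoch takes all mass. The same
sigma floor as the scan applies, so a founder's two-epoch posterior
equals its scan vector restricted to the epoch grid points and
renormalised whenever the epochs lie on the grid. Aggregated epoch
proportions are sample-count weighted, matching the scan's
lineage-proportion reading; per-founder posteriors are retained so
either weighting can be recomputed.

### Source attribution

Each founder is attributed to the source region holding the majority of
source leaves below the founder node; ties break first by smaller mean
mutation distance to the founder node, then lexicographically with an
`ambiguous` flag. If the founder node has no source descendants (it was
attested through a zero path, or leaves were re-assigned), the vote
falls back to the nearest rootward node that has some. This replaces a
per-founder expert judgement with a deterministic, auditable rule; the
`support` fraction and `ambiguous` flag expose exactly how clear each
call was. Region-by-epoch composition normalises each epoch column to
1; per-population frequencies are relative to the population's full
sample count, so epoch frequencies plus the non-analysed remainder sum
to 1.

## Synthetic data and what recovery tests show

The generator emulates the structure founder analysis consumes rather
than a full coalescent. Each planned founder gets its own source clade:
one source leaf identical to the founder haplotype (zero branch) plus,
by default, two derived source leaves whose branch lengths are
Poisson(depth / clock) forced to at least 1 — so attestation and the f1
criterion hold by construction. Sink subtrees attach at the founder
node as stars (each leaf Poisson(T / clock), making rho and sigma
analytically checkable) or as a cherry-star mix (time split evenly
between stem and tips) that exercises the general variance formula.
Background source cherries and a random binary backbone with
Poisson-mutated join branches supply unrelated source diversity. All
draws come from one seeded generator; identical configurations produce
byte-identical Newick, metadata and truth tables.

Default study conditions are a twin-pulse scenario: 30 founders at
500 y from West Africa and 10 at 8000 y from Eastern Africa, 10 sink
samples per founder (a 75:25 historical:prehistoric lineage split),
clock 2565, star subtrees, 3 source leaves per founder, 10 background
cherries, 5000-year within-clade source depth and 2000-year backbone
branches — desk-scale values chosen to give each founder clade visible
source diversity while keeping a full replicate under 200 ms.

What the generator does *not* emulate: coalescent genealogy within
clusters (stars are optimistic about independence), back-mutation and
sequencing artefacts, rate heterogeneity across sites, haplotypes
shared across several sink regions, and sampling bias. Passing recovery
tests therefore demonstrate the *inverse-problem correctness* of the
pipeline under its own model assumptions — not robustness to the
messiness of real compilations.

### Statistical resolution of peak recovery

The per-founder age estimate at 8 ka with n = 10 star lineages carries
sigma ≈ sqrt(31.2)/10 × 2565 ≈ 1430 y. With 10 such founders the
aggregate scan peak is located with a standard error of roughly
2565 × sqrt(312)/100 ≈ 450 y — and this is the total Poisson
information in the data, so no estimator can do better. A ±400-year
window around 8 ka is therefore hit in only ~60% of replicates of that
scenario; concentrating the peak further requires more founders or
larger clusters, not a different estimator. The allocation and
attribution summaries are far better determined: the 75:25 epoch split
is recovered within ±5 points essentially always (epoch posteriors are
near-0/1 at these time scales), and region attribution is exact when
founder clades carry uncontaminated source leaves.

## Numerical and degenerate-case choices

* Branch lengths within 1e-6 of an integer are rounded; anything else
  is rejected, as are negative lengths, unbound leaves and duplicate
  labels.
* Probability vectors are renormalised after truncation; sums are
  asserted to 1e-9 in tests.
* If all epoch densities underflow, mass collapses to the nearest
  epoch; if a founder's whole scan vector underflows (age far outside
  the grid), mass collapses to the nearest grid point.
* Founder and cluster identifiers are assigned in tree preorder, making
  every table deterministic; the analysis path downstream of parsing
  contains no randomness.
* Polytomies are handled natively throughout; trees are exchanged as
  Newick with integer branch lengths and internal node labels, which
  round-trips exactly.

## Problem sizes

Module tests run on hand-built trees of ≤ 12 leaves plus randomised
small trees; recovery experiments use 100 replicates of the twin-pulse
scenario (~540 leaves each) and a single 1000-founder calibration
dataset (~13 000 leaves). The full suite and the acceptance script each
complete in well under a minute on one CPU.

## Known limitations

* A single sink pool per run: haplotypes founding several sink regions
  must be analysed in separate runs, one model at a time.
* The f-criterion looks only at derived-branch counts at the founder
  node, not deeper clade shape (no f2-style rules).
* Attribution by absence ("not seen elsewhere") is not formalised;
  the support/ambiguity columns are the raw material for such
  judgements.
* The linear clock is a deliberate simplification; analyses extending
  beyond ~25 ka would need the full time-dependent correction, which is
  out of scope.
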