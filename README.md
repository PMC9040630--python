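# ogukit

Taxonomy-free metagenomic feature tables and phylogeny-aware community
ecology.

## The problem

Shotgun metagenomic reads are conventionally summarised into taxonomic
profiles (species or genus tables) before any ecology is done. That step
throws away resolution twice: genomes of one species are pooled, and the
relationships *between* features are reduced to "same rank = equally
related". `ogukit` instead treats each **individual reference genome** as a
feature — an *operational genomic unit* (OGU) — and uses a genome phylogeny
(or, as a coarse fallback, the taxonomy itself turned into a tree) to
structure the features for phylogeny-aware statistics such as UniFrac.

The package is for microbiome researchers who already have read-to-genome
alignments (SAM, BLAST tabular `-outfmt 6`, or a plain query→genome map,
optionally gzip/bzip2/xz-compressed, multiplexed or per-sample) and want
genome-resolved feature tables plus the downstream beta-diversity toolkit.

## The method

For each query sequence aligned to $k$ genomes, every hit genome is counted
$1/k$ times. Per-genome frequencies are summed over the whole alignment and
then rounded half-to-even, so each sample's column sum equals (up to
rounding) its number of aligned reads $m$. On the resulting table the
package provides:

- **Table operations** — per-sample relative-abundance filtering,
  prevalence filtering, genome-size normalisation
  ($c' = c/\mathrm{len}(g)\times s$, converting sequence abundance to
  taxonomic abundance), and rarefaction that models the unaligned read mass:
  a reserved feature of count $n-m$ joins the urn before a multivariate
  hypergeometric draw of the target depth and is removed afterwards.
- **Taxonomy handling** — Greengenes lineage strings, NCBI taxdump and plain
  child→parent maps; collapsing tables to any of the seven standard ranks;
  converting a taxonomy into a tree whose inter-rank branches all have
  length 1 (so equal-rank taxa sit at equal depth); collapsing a genome
  phylogeny to monophyletic taxa at a chosen rank.
- **Community ecology** — Bray-Curtis, Jaccard, unweighted and weighted
  UniFrac (weighted UniFrac
  $d = \sum_b \ell_b\,|p_x(b)-p_y(b)|$ over branches $b$, where $p_s(b)$ is
  the fraction of sample $s$'s counts descending through $b$; a normalised
  variant divides by $\sum_b \ell_b (p_x(b)+p_y(b))$), classical PCoA,
  PERMANOVA with permutation p-values, and a within/between-environment
  distance-ratio statistic.
- **Synthetic data** — deterministic simulators of communities, alignments
  in all three formats, taxonomies in all three dialects, random
  phylogenies, and a small frozen conceptual fixture; everything is testable
  at desk scale with no downloads.

## Worked example

```python
from ogukit import beta_matrix, collapse_table
from ogukit.synthgen import make_conceptual_fixture

fx = make_conceptual_fixture()          # 3 samples x 10 genomes, 12 reads each
genus = collapse_table(fx.table, fx.taxonomy, "genus")
dm_genus = beta_matrix(genus, "braycurtis")
dm_wu = beta_matrix(fx.table, "weighted-unifrac", fx.tree)
```

Running `python examples/conceptual_fixture.py` prints:

```
genus-level Bray-Curtis:
  d(A,B) = 0.333
  d(A,C) = 0.250
  d(B,C) = 0.167
genome-level weighted UniFrac (phylogeny):
  d(A,B) = 0.358
  d(A,C) = 1.058
  d(B,C) = 1.267
```

At genus resolution samples B and C look like the closest pair — a spurious
proximity, since their reads hit disjoint genomes that merely share genera.
At genome resolution with the phylogeny, A and B emerge as the truly most
similar pair (they share genomes O6 and O9 and carry close relatives of each
other's genomes), and B and C separate. The other scripts in `examples/`
walk through alignment ingestion, PERMANOVA on a simulated two-group study,
and unaligned-aware rarefaction.

A command-line interface mirrors the library
(`ogukit classify | collapse | filter | normalize | subsample | beta | pcoa
| permanova | ratio | simulate | fixture`); run `ogukit --help`.

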