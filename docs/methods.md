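# Methods

This note records the model behind `ogukit`, the parameter choices that
matter, what the synthetic generators do and do not emulate, and the
numerical decisions taken where the design was genuinely open.

## Counting model

An alignment is a mapping from query sequences to subject genomes. A query
hitting $k$ genomes contributes $1/k$ of a count to each — no attempt is
made to adjudicate which hit is "right"; averaging over the ambiguity set is
the model. Apportionment guarantees that every aligned query carries total
weight exactly 1, so the pre-rounding column sum of a sample equals its
aligned read count $m$ to floating-point accuracy (asserted at $10^{-9}$).

Rounding happens once, after the full alignment is processed, using
round-half-to-even on each summed frequency. Two readings of "round to the
nearest even integer" exist: banker's rounding of each value, or quantising
every value to the nearest even integer. The second would double-quantise
(map 3 → 2 or 4) and destroy the near-conservation property above, so
half-to-even is the default; the always-even alternative is not offered.
After rounding, the per-sample sum deviates from $m$ by at most half a count
per nonzero entry, and with $k\equiv1$ it is exact.

Counts are **sequence abundance**. Dividing each genome's count by its
length (and multiplying by a scale, default 1.0 since no canonical constant
exists) estimates **taxonomic abundance**; the result is float-valued and is
not re-rounded unless asked.

## Filtering

Per-sample relative-abundance filtering computes each entry's share of its
sample's column sum *before* any removal and zeroes entries strictly below
the threshold; entries exactly at the threshold are kept ("below" removes,
at-or-above stays). Filtering operates on the rounded table — it is a
post-hoc table operation, not part of tallying. Prevalence filtering drops
features nonzero in fewer than a minimum number of samples. Both filters
are idempotent at a fixed threshold.

## Rarefaction with an unaligned mass

Subsampling depth is defined on the scale of the original sequencing run,
not the aligned fraction: with $m$ of $n$ reads aligned, a reserved feature
`__UNALIGNED__` of count $n-m$ is added, `depth` items are drawn without
replacement (multivariate hypergeometric — we model drawing fewer reads from
a finite run, not resampling with replacement), and the reserved feature is
removed again. A collision with the reserved id is an error, never a silent
rename. Draws are deterministic given a seed; the replicate helper defaults
to seeds 0–9, ten replicates.

## Taxonomy and trees

Three taxonomy dialects normalise into one child→parent map with ranks. In
Greengenes lineage strings, an empty middle label with nonempty labels below
it is rejected as malformed — silently bridging the gap would create
ambiguous nodes. Internally, lineage-string nodes are identified by their
full label path, so identical prefixed labels under different parents stay
distinct.

`taxonomy_to_tree` builds a tree in which every branch between adjacent
ranks has length 1.0. Lineages missing an intermediate rank get
deterministic placeholder nodes named `<child>__incertae_<rank>`, so that
all taxa at one rank sit at the same tip-to-root distance — the contract the
tree must satisfy to act as a constant-branch substitute for a phylogeny in
UniFrac. Unranked genome leaves hang one unit below the species slot, so
genome tips are depth-aligned too. Nonstandard ranks ("strain") map to
`none` and are transparent.

`collapse_phylogeny` replaces the clade of each taxonomic unit at a rank by
a single tip. The unit must be monophyletic among the tree's covered tips
(uncovered tips are pruned first); a violation raises an error naming the
unit and the intruding tips rather than silently splitting it. The new tip
carries the clade's stem branch length — a purely topological choice;
alternatives such as mean tip depth would mix path lengths into a single
branch and were rejected. Total branch length therefore never increases.

## Distances, ordination, tests

UniFrac is computed in one postorder pass accumulating per-branch subtree
counts. The unweighted variant is the unique-to-one-sample branch length
over the branch length observed in either sample; the weighted variant is
$\sum_b \ell_b |p_x(b) - p_y(b)|$. "Weighted UniFrac" unqualified means the
unnormalised variant — that is the quantity the surrounding ecosystem
computes under this name — with the normalised form behind a flag. Both are
cross-checked in the tests against a naive per-branch enumeration oracle and
against scikit-bio's implementations.

PCoA double-centers the squared distance matrix and eigendecomposes it.
Negative eigenvalues (non-Euclidean input) are reported untouched and
excluded from axes and from the proportion-explained denominator; no
Cailliez/Lingoes correction is applied, so users can see non-Euclideanness
rather than having it hidden. Eigenvalues below `1e-10 * max|eigenvalue|`
are treated as zero.

PERMANOVA uses the standard pseudo-F from squared distances with
$SS_\text{total} = \frac{1}{N}\sum_{i<j} d_{ij}^2$ and per-group
$SS_\text{within}$. The permutation p-value uses the +1 correction and so
never returns 0; its floor is $1/(\text{permutations}+1)$. The default
permutation count is 999; an exhaustive mode enumerates all distinct
relabelings for small studies. Ties against the observed statistic are
counted as exceedances (tolerance $10^{-12}$). Note that in small designs
(e.g. 3+3) a random relabeling recreates the observed split with
non-negligible probability, so the attainable p-value is bounded well above
the floor — a property, not a bug.

The environment distance-ratio statistic: for each sample of a focal site,
own-site samples are excluded; the ratio is the mean distance to samples of
the *other* focal sites over the mean distance to non-focal samples. The
per-sample ratios are returned; their distribution (not a single pooled
number) is the reported statistic.

## Synthetic data

The simulator emulates the *structure* of alignment output, not sequences:
no bases, qualities, or error models. Community profiles are log-normal;
planted group structure multiplies a per-group log-normal shift onto a
shared base profile. Each read draws its true genome from the sample
profile, aligns with a fixed probability, and receives $k$ reported hits
with default law $P(k{=}1)=0.8$, $P(k{=}2)=0.15$, $P(k{=}4)=0.05$; the
$k-1$ co-hits are the true genome's nearest phylogenetic neighbours, because
real aligner ambiguity is concentrated among similar genomes rather than
uniform. Read identifiers embed the sample (`S1_r00001`) so multiplexed
demultiplexing is exercised by default.

Scale choices for the shipped experiments (all desk-scale): conservation
checks run 50 scenarios of 3 samples × 200 reads; the depth-robustness
study uses 12 samples in two groups, 150 genomes, 6,000 reads per sample at
90% alignment with heavy-tailed profiles ($\sigma=2$) so the table is
sparse enough for presence/absence metrics to be meaningful, rarefied to
depths 500/1,581/5,000 (a log-spaced order of magnitude) with 3 replicates
each. Under these conditions the PERMANOVA pseudo-F on weighted-UniFrac
distances shifts by well under 25% in median while Jaccard shifts more —
the abundance-versus-presence contrast the method relies on. Passing these
tests shows internal consistency and the direction of the qualitative
effects; it does not certify behaviour on real metagenomes, whose genome
catalogs, contamination and aligner quirks the generator does not model.

The conceptual fixture is a hand-frozen 3-sample × 10-genome table chosen
by constrained search to satisfy a set of structural constraints (equal
sample totals of 12; 5 species / 3 genera / 1 family; one species with
identical totals everywhere; one species whose equal totals in two samples
come from different genomes; two samples sharing two genomes; a phylogeny
that disagrees with the taxonomy about one genome's placement). Tests
assert only those constraints and the qualitative distance orderings, never
the arbitrary exact counts.

## Known limitations

- Dense pandas storage: fine for thousands of features, not for
  repository-scale tables.
- SAM ingestion assumes records of one query are consecutive (aligner
  output order) and verifies it; a shuffled SAM must be grouped first.
  Paired mates are distinguished by a `/1`–`/2` suffix derived from FLAG
  bits 0x40/0x80, so each aligned mate counts once.
- Single-factor PERMANOVA only; no multi-factor or strata support.
- No alpha diversity; no differential-abundance machinery.
- BIOM/HDF5 export is not provided; tables interchange as TSV (dense or
  sparse triplets).
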