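"""Group separation in a simulated study: distances, ordination, PERMANOVA.

Simulates 12 samples in two planted community types, builds the feature
table end to end from the simulated alignments, and tests the separation
with PERMANOVA on weighted-UniFrac distances.
"""

from ogukit import beta_matrix, pcoa, permanova, round_table, tally
from ogukit.aln_io import HitGroup
from ogukit.synthgen import random_scenario, simulate_reads

scenario = random_scenario(seed=42, n_samples=12, n_genomes=150,
                           reads_per_sample=6000, aligned_fraction=0.9,
                           n_groups=2, group_separation=1.5, lognormal_sigma=2.0)
hits, _, ledger = simulate_reads(scenario)
groups = [HitGroup(query_id=r, sample_id=s, subjects=frozenset(subs))
          for s, items in hits.items() for r, subs in items]
table = round_table(tally(groups, total_sequences=ledger.n)[0])

dm = beta_matrix(table, "weighted-unifrac", scenario.tree)
ordination = pcoa(dm)
explained = ordination.proportion_explained[:3].sum()
result = permanova(dm, scenario.group_of, n_permutations=999, seed=0)

print(f"table: {table.shape[0]} genomes x {table.shape[1]} samples")
print(f"PCoA: first three axes explain {100 * explained:.1f}% of variance")
print(f"PERMANOVA: pseudo-F = {result.pseudo_F:.2f}, p = {result.p_value:.3f} "
      f"({result.n_permutations} permutations)")

# A pseudo-F far above 1 with p below 0.01 says between-group distances dwarf
# within-group ones: the two planted community types are cleanly recovered
# from the read-level data.  (With only 6+6 samples a permuted labelling
# occasionally reproduces an extreme split, so p does not always reach the
# 0.001 floor of 999 permutations.)
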