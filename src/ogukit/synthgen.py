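"""Deterministic generators of synthetic inputs.

Everything every other module consumes can be produced here at desk scale:
random rooted phylogenies, random taxonomies (written in all three input
dialects), simulated communities with multi-mapping alignment files in all
three formats, and a small frozen conceptual fixture of three communities
over ten reference genomes that illustrates how feature resolution changes
apparent sample relationships.

No sequence bases are simulated — only the query-to-subject structure of an
alignment, which is all the downstream tallying consumes.  Multi-mapped
reads co-hit the true genome's nearest phylogenetic neighbours, mimicking
the ambiguity real aligners exhibit among similar genomes (rather than
uniform noise).
"""

from __future__ import annotations

import bz2
import gzip
import lzma
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables import FeatureTable, SampleDepthLedger
from .taxotree import TaxonomyMap, read_lineages, read_newick

__all__ = [
    "ConceptualFixture",
    "make_conceptual_fixture",
    "random_phylogeny",
    "random_taxonomy",
    "SyntheticScenario",
    "random_scenario",
    "simulate_reads",
    "write_alignments",
    "write_taxonomy_lineages",
    "write_taxonomy_taxdump",
    "write_taxonomy_parent_map",
]


# --------------------------------------------------------------------------
# conceptual three-community fixture
# --------------------------------------------------------------------------

# Frozen by constrained search: three samples of 12 read hits each over ten
# genomes classified into five species, three genera and one family.  The
# constraints encoded (and asserted in tests): equal per-sample totals of 12;
# species S1 has identical summed counts in all samples; species S3's total
# is the same in samples B and C but carried by O5 in B and O7 in C; samples
# A and B share nonzero counts at O6 and O9 while C has neither; genome O5
# is taxonomically in genus G2 but phylogenetically sister to O4 of genus G1.
_FIXTURE_COUNTS = {
    #        A  B  C
    "O1": (3, 0, 0),
    "O2": (0, 3, 0),
    "O3": (0, 0, 3),
    "O4": (3, 0, 0),
    "O5": (0, 4, 0),
    "O6": (2, 2, 0),
    "O7": (0, 0, 4),
    "O8": (1, 0, 2),
    "O9": (2, 2, 0),
    "O10": (1, 1, 3),
}

_FIXTURE_LINEAGES = [
    "O1\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G1; s__S1",
    "O2\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G1; s__S1",
    "O3\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G1; s__S1",
    "O4\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G1; s__S2",
    "O5\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G2; s__S3",
    "O7\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G2; s__S3",
    "O6\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G2; s__S4",
    "O8\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G3; s__S5",
    "O9\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G3; s__S5",
    "O10\tk__K1; p__P1; c__C1; o__O1o; f__F1; g__G3; s__S5",
]

# O1 and O2 are sisters with O3 their next-closest relative; O4 and O5 form
# a cherry although taxonomy puts them in different genera.
_FIXTURE_NEWICK = (
    "((((O1:0.1,O2:0.1):0.4,O3:0.5):0.5,(O4:0.2,O5:0.2):0.8):0.4,"
    "((O6:0.3,O7:0.3):0.5,(O8:0.3,(O9:0.2,O10:0.2):0.1):0.4):0.4):0.0;"
)


@dataclass
class ConceptualFixture:
    """The frozen conceptual fixture: table, taxonomy and phylogeny."""

    table: FeatureTable
    taxonomy: TaxonomyMap
    tree: TreeNode


def make_conceptual_fixture() -> ConceptualFixture:
    """Build the three-community, ten-genome conceptual fixture.

    Deterministic and self-contained; the qualitative behaviour it encodes
    is that genus-level Bray-Curtis draws samples B and C spuriously close,
    while genome-level (OGU) distances separate them and phylogeny-weighted
    UniFrac reveals A and B as the most similar pair.
    """
    df = pd.DataFrame(
        {s: [counts[i] for counts in _FIXTURE_COUNTS.values()] for i, s in enumerate("ABC")},
        index=list(_FIXTURE_COUNTS),
        dtype=float,
    )
    table = FeatureTable(df, "rounded_int")
    taxonomy = read_lineages(line + "\n" for line in _FIXTURE_LINEAGES)
    tree = read_newick(_FIXTURE_NEWICK)
    return ConceptualFixture(table=table, taxonomy=taxonomy, tree=tree)




# --------------------------------------------------------------------------
# random structures
# --------------------------------------------------------------------------


def random_phylogeny(n_tips: int, seed: int, rate: float = 1.0) -> TreeNode:
    """Random rooted binary tree over tips ``t1..tn``.

    Built by repeatedly joining two uniformly chosen subtrees; branch
    lengths are exponential with the given rate.  Deterministic by seed.
    """
    if n_tips < 2:
        raise ValueError("a phylogeny needs at least 2 tips")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i + 1}", length=float(rng.exponential(1 / rate))) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        joint = TreeNode(length=float(rng.exponential(1 / rate)), children=[left, right])
        nodes.append(joint)
    root = nodes[0]
    root.length = None
    return root


def random_taxonomy(
    n_genomes: int,
    seed: int,
    n_per_rank: tuple[int, ...] = (1, 2, 3, 4, 6, 8, 12),
) -> tuple[TaxonomyMap, list[str]]:
    """Random seven-rank taxonomy over genomes ``g1..gn``.

    ``n_per_rank`` gives the number of taxa at each rank, kingdom to
    species; each taxon's parent is drawn uniformly from the rank above, and
    each genome attaches below a uniformly chosen species.  Returns the
    taxonomy and the genome ids (which carry rank ``none``).
    """
    rng = np.random.default_rng(seed)
    lineages = []
    rank_letters = ["k", "p", "c", "o", "f", "g", "s"]
    parents: dict[str, str | None] = {}
    per_rank_names: list[list[str]] = []
    for level, count in enumerate(n_per_rank):
        names = [f"{rank_letters[level]}__{rank_letters[level].upper()}{i + 1}" for i in range(count)]
        for nm in names:
            parents[nm] = per_rank_names[-1][rng.integers(len(per_rank_names[-1]))] if per_rank_names else None
        per_rank_names.append(names)
    genomes = [f"g{i + 1}" for i in range(n_genomes)]
    for genome in genomes:
        species = per_rank_names[-1][rng.integers(len(per_rank_names[-1]))]
        chain = [species]
        while parents[chain[-1]] is not None:
            chain.append(parents[chain[-1]])
        lineages.append(genome + "\t" + "; ".join(reversed(chain)))
    return read_lineages(line + "\n" for line in lineages), genomes


# --------------------------------------------------------------------------
# community / alignment simulation
# --------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    """A fully specified synthetic study.

    ``abundances`` holds true per-sample relative abundances (genomes x
    samples, columns summing to 1); ``k_law`` is the multi-mapping law, a
    probability over the number of reported hits per aligned read, with
    co-hits drawn from the true genome's nearest phylogenetic neighbours.
    """

    seed: int
    genomes: list[str]
    sample_ids: list[str]
    abundances: pd.DataFrame
    tree: TreeNode
    taxonomy: TaxonomyMap
    reads_per_sample: int = 1000
    aligned_fraction: float = 0.9
    k_law: dict[int, float] = field(default_factory=lambda: {1: 0.8, 2: 0.15, 4: 0.05})
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.aligned_fraction <= 1:
            raise ValueError("aligned_fraction must be in (0, 1]")
        probs = np.array(list(self.k_law.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("k_law probabilities must be nonnegative and sum to 1")
        if any(k < 1 for k in self.k_law):
            raise ValueError("multi-mapping multiplicities must be >= 1")
        sums = self.abundances.sum(axis=0)
        if not np.allclose(sums, 1.0):
            raise ValueError("per-sample abundances must sum to 1")


def random_scenario(
    seed: int,
    n_samples: int = 6,
    n_genomes: int = 24,
    reads_per_sample: int = 1000,
    aligned_fraction: float = 0.9,
    k_law: dict[int, float] | None = None,
    n_groups: int = 1,
    group_separation: float = 2.0,
    lognormal_sigma: float = 1.0,
) -> SyntheticScenario:
    """Draw a random scenario with optional planted group structure.

    Each group gets a log-normal base abundance profile; samples jitter the
    base multiplicatively, and ``group_separation`` scales how far group
    base profiles diverge (0 = identical groups).  Defaults emulate a small
    shallow-sequencing study: ~1,000 reads per sample, 90% alignable, and a
    multi-mapping law of P(k=1)=0.8, P(k=2)=0.15, P(k=4)=0.05.
    """
    rng = np.random.default_rng(seed)
    tree = random_phylogeny(n_genomes, seed=int(rng.integers(2**31)))
    genomes = [t.name for t in tree.tips()]
    taxonomy, tax_genomes = random_taxonomy(n_genomes, seed=int(rng.integers(2**31)))
    # rename taxonomy genomes to the tree tip names
    renames = dict(zip(tax_genomes, genomes))
    taxonomy.parent = {renames.get(k, k): v for k, v in taxonomy.parent.items()}
    taxonomy.rank = {renames.get(k, k): v for k, v in taxonomy.rank.items()}
    taxonomy.name = {renames.get(k, k): renames.get(v, v) for k, v in taxonomy.name.items()}

    base = rng.lognormal(0.0, lognormal_sigma, size=n_genomes)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    group_of = {}
    cols = {}
    group_shift = {
        g: rng.lognormal(0.0, lognormal_sigma * group_separation, size=n_genomes)
        for g in range(max(n_groups, 1))
    }
    for i, sample in enumerate(sample_ids):
        g = i % max(n_groups, 1)
        group_of[sample] = f"grp{g + 1}"
        profile = base * group_shift[g] * rng.lognormal(0.0, 0.3, size=n_genomes)
        cols[sample] = profile / profile.sum()
    abundances = pd.DataFrame(cols, index=genomes)
    return SyntheticScenario(
        seed=seed,
        genomes=genomes,
        sample_ids=sample_ids,
        abundances=abundances,
        tree=tree,
        taxonomy=taxonomy,
        reads_per_sample=reads_per_sample,
        aligned_fraction=aligned_fraction,
        k_law=dict(k_law or {1: 0.8, 2: 0.15, 4: 0.05}),
        group_of=group_of,
    )


def _neighbor_table(tree: TreeNode, genomes: list[str]) -> dict[str, list[str]]:
    td = tree.tip_tip_distances()
    order = {}
    for g in genomes:
        row = pd.Series(td[g], index=list(td.ids)).drop(g)
        order[g] = list(row.sort_values(kind="stable").index)
    return order


def simulate_reads(
    scenario: SyntheticScenario,
) -> tuple[dict[str, list[tuple[str, list[str]]]], FeatureTable, SampleDepthLedger]:
    """Simulate per-sample reads and their alignment hit sets.

    Returns ``(hits, truth, ledger)`` where ``hits[sample]`` is a list of
    ``(read_id, subject_genomes)``, ``truth`` counts each aligned read once
    under its genome of origin, and the ledger records per-sample totals
    ``n`` and aligned counts ``m``.  Reproducible from the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    neighbors = _neighbor_table(scenario.tree, scenario.genomes)
    ks = np.array(sorted(scenario.k_law))
    kp = np.array([scenario.k_law[k] for k in ks])
    hits: dict[str, list[tuple[str, list[str]]]] = {}
    truth_cols: dict[str, np.ndarray] = {}
    n_led, m_led = {}, {}
    gidx = {g: i for i, g in enumerate(scenario.genomes)}
    for sample in scenario.sample_ids:
        p = scenario.abundances[sample].to_numpy()
        origins = rng.choice(len(scenario.genomes), size=scenario.reads_per_sample, p=p)
        aligned = rng.random(scenario.reads_per_sample) < scenario.aligned_fraction
        kvals = ks[rng.choice(len(ks), size=scenario.reads_per_sample, p=kp)]
        sample_hits = []
        truth = np.zeros(len(scenario.genomes))
        for j in range(scenario.reads_per_sample):
            if not aligned[j]:
                continue
            true_g = scenario.genomes[origins[j]]
            k = int(kvals[j])
            subjects = [true_g] + neighbors[true_g][: k - 1]
            sample_hits.append((f"{sample}_r{j + 1:05d}", subjects))
            truth[gidx[true_g]] += 1
        hits[sample] = sample_hits
        truth_cols[sample] = truth
        n_led[sample] = scenario.reads_per_sample
        m_led[sample] = float(len(sample_hits))
    truth_df = pd.DataFrame(truth_cols, index=scenario.genomes)
    truth_table = FeatureTable(truth_df, "rounded_int").drop_empty_features()
    return hits, truth_table, SampleDepthLedger(n=n_led, m=m_led)


_WRITERS = {"none": open, "gzip": gzip.open, "bzip2": bz2.open, "lzma": lzma.open}
_COMP_EXT = {"none": "", "gzip": ".gz", "bzip2": ".bz2", "lzma": ".xz"}
_FMT_EXT = {"sam": ".sam", "blast6": ".b6", "map": ".map"}


def _sam_lines(read_id: str, subjects: list[str]):
    for rank, subject in enumerate(subjects):
        flag = 0 if rank == 0 else 256
        yield f"{read_id}\t{flag}\t{subject}\t1\t30\t50M\t*\t0\t0\t*\t*\n"


def _blast6_lines(read_id: str, subjects: list[str]):
    for subject in subjects:
        yield (
            f"{read_id}\t{subject}\t98.0\t50\t1\t0\t1\t50\t101\t150\t1e-20\t90.0\n"
        )


def _map_lines(read_id: str, subjects: list[str]):
    for subject in subjects:
        yield f"{read_id}\t{subject}\n"


_LINEMAKERS = {"sam": _sam_lines, "blast6": _blast6_lines, "map": _map_lines}


def write_alignments(
    hits: dict[str, list[tuple[str, list[str]]]],
    out_dir: str,
    fmt: str = "map",
    compression: str = "none",
    multiplexed: bool = False,
    stem: str = "alignments",
) -> list[str]:
    """Write simulated hits as alignment files; returns the paths written.

    Multiplexed mode writes one file with the sample encoded in each read id
    (``S1_r00001``); per-sample mode writes one file per sample named after
    the sample.  SAM output gets a minimal header.
    """
    if fmt not in _LINEMAKERS:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if compression not in _WRITERS:
        raise ValueError(f"unknown compression {compression!r}")
    os.makedirs(out_dir, exist_ok=True)
    suffix = _FMT_EXT[fmt] + _COMP_EXT[compression]
    opener = _WRITERS[compression]
    linemaker = _LINEMAKERS[fmt]
    paths = []

    def write_one(path: str, items):
        with opener(path, "wt") as fh:
            if fmt == "sam":
                fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for read_id, subjects in items:
                for line in linemaker(read_id, subjects):
                    fh.write(line)

    if multiplexed:
        path = os.path.join(out_dir, stem + suffix)
        write_one(path, (item for sample in hits for item in hits[sample]))
        paths.append(path)
    else:
        for sample, items in hits.items():
            path = os.path.join(out_dir, sample + suffix)
            # strip the sample prefix so per-sample files carry bare read ids
            bare = ((rid.partition("_")[2] or rid, subs) for rid, subs in items)
            write_one(path, bare)
            paths.append(path)
    return paths


# --------------------------------------------------------------------------
# taxonomy writers (three dialects)
# --------------------------------------------------------------------------


def write_taxonomy_lineages(taxonomy: TaxonomyMap, genomes: list[str], path: str) -> None:
    """Write genome lineages in the Greengenes string dialect."""
    with open(path, "w") as fh:
        for genome in genomes:
            chain = taxonomy.lineage(genome)
            labels = [taxonomy.name_of(n) for n in chain if taxonomy.rank_of(n) != "none" and n != taxonomy.root]
            fh.write(genome + "\t" + "; ".join(labels) + "\n")


def write_taxonomy_taxdump(taxonomy: TaxonomyMap, nodes_path: str, names_path: str) -> None:
    """Write the taxonomy in the NCBI taxdump dialect (nodes.dmp/names.dmp)."""
    with open(nodes_path, "w") as fh:
        for node, par in taxonomy.parent.items():
            rank = taxonomy.rank_of(node)
            fh.write(f"{node}\t|\t{par}\t|\t{rank if rank != 'none' else 'no rank'}\t|\n")
    with open(names_path, "w") as fh:
        for node in taxonomy.parent:
            fh.write(f"{node}\t|\t{taxonomy.name_of(node)}\t|\t\t|\tscientific name\t|\n")


def write_taxonomy_parent_map(taxonomy: TaxonomyMap, path: str) -> None:
    """Write the taxonomy as a plain child<TAB>parent map."""
    with open(path, "w") as fh:
        for node, par in taxonomy.parent.items():
            if node != par:
                fh.write(f"{node}\t{par}\n")
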