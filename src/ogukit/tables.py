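"""Feature tables of operational genomic units (OGUs).

An OGU is an individual reference genome used directly as a community
feature, with no taxonomic label attached.  A read aligned to ``k`` genomes
contributes ``1/k`` of a count to each of them ("fractional apportionment");
per-genome frequencies are summed over the whole alignment and only then
rounded half-to-even, so each sample's column sum stays (up to rounding)
equal to its number of aligned reads.

Tables are stored dense as a pandas DataFrame (features x samples), which is
ample at the scales this package targets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aln_io import HitGroup

__all__ = [
    "FeatureTable",
    "SampleDepthLedger",
    "UNALIGNED_ID",
    "tally",
    "round_table",
    "filter_rel_abund",
    "filter_prevalence",
    "normalize_by_size",
    "subsample",
    "subsample_replicates",
    "merge_tables",
    "read_table",
    "write_table",
    "read_genome_sizes",
]

#: reserved feature id standing for the unaligned fraction during subsampling
UNALIGNED_ID = "__UNALIGNED__"

_VALUE_KINDS = ("raw_float", "rounded_int", "normalized_float")


@dataclass
class FeatureTable:
    """Samples-by-features count matrix.

    ``data`` has feature ids as the index and sample ids as columns.
    ``value_kind`` records where the table sits in the pipeline:
    ``raw_float`` (fractional tallies), ``rounded_int`` (integer counts) or
    ``normalized_float`` (genome-size normalized).
    """

    data: pd.DataFrame
    value_kind: str = "raw_float"

    def __post_init__(self) -> None:
        if self.value_kind not in _VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if not self.data.index.is_unique:
            raise ValueError("duplicate feature ids")
        if not self.data.columns.is_unique:
            raise ValueError("duplicate sample ids")
        if self.data.size and (self.data.to_numpy() < 0).any():
            raise ValueError("feature table contains negative values")
        if self.value_kind == "rounded_int" and self.data.size:
            vals = self.data.to_numpy()
            if not np.array_equal(vals, np.floor(vals)):
                raise ValueError("rounded_int table contains non-integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def drop_empty_features(self) -> "FeatureTable":
        keep = self.data.ne(0).any(axis=1)
        return FeatureTable(self.data.loc[keep].copy(), self.value_kind)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self.data.sum(axis=0)
        sums = sums.replace(0, np.nan)
        return self.data.div(sums, axis=1).fillna(0.0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.value_kind)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.value_kind == other.value_kind and self.data.equals(other.data)


@dataclass
class SampleDepthLedger:
    """Per-sample sequencing bookkeeping.

    ``n`` is the total number of sequences in the original dataset and ``m``
    the number that aligned to at least one genome (the pre-rounding column
    sum).  ``n - m`` is the unaligned mass restored during subsampling.
    """

    n: dict[str, int] = field(default_factory=dict)
    m: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, m in self.m.items():
            n = self.n.get(sample, None)
            if n is not None and not (0 <= m <= n + 1e-9):
                raise ValueError(
                    f"sample {sample!r}: aligned count m={m} outside [0, n={n}]"
                )


def tally(
    hitgroups: Iterable[HitGroup], total_sequences: Mapping[str, int] | None = None
) -> tuple[FeatureTable, SampleDepthLedger]:
    """Tally hit groups into a fractional-count OGU table.

    Each query adds exactly ``1/k`` to each of its ``k`` subject genomes in
    its sample's column, so each column sums to the number of tallied
    queries.  ``total_sequences`` optionally supplies the original per-sample
    read counts ``n`` for the ledger; when absent, ``n`` defaults to the
    aligned count.
    """
    counts: dict[str, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    m: dict[str, float] = defaultdict(float)
    for hg in hitgroups:
        w = 1.0 / hg.k
        col = counts[hg.sample_id]
        for subject in hg.subjects:
            col[subject] += w
        m[hg.sample_id] += 1.0
    df = pd.DataFrame(counts).fillna(0.0).sort_index()
    df.columns.name = None
    # column order: first appearance
    df = df[[s for s in counts]] if len(counts) else df
    table = FeatureTable(df, "raw_float")
    n: dict[str, int] = {}
    for sample in counts:
        if total_sequences is not None and sample in total_sequences:
            n[sample] = int(total_sequences[sample])
        else:
            n[sample] = int(round(m[sample]))
    ledger = SampleDepthLedger(n=n, m=dict(m))
    return table, ledger


def round_table(table: FeatureTable, *, drop_zeros: bool = True) -> FeatureTable:
    """Round fractional counts half-to-even to integer counts.

    Entries that round to zero are dropped from storage.  Because ties are
    broken to the even integer, the per-sample sum stays within half a count
    per nonzero entry of the pre-rounding sum.
    """
    rounded = pd.DataFrame(
        np.rint(table.data.to_numpy()),
        index=table.data.index,
        columns=table.data.columns,
    )
    out = FeatureTable(rounded, "rounded_int")
    if drop_zeros:
        out = out.drop_empty_features()
    return out


def filter_rel_abund(table: FeatureTable, threshold: float) -> FeatureTable:
    """Zero out entries below a per-sample relative-abundance threshold.

    ``threshold`` is a fraction (0.0001 means 0.01%).  Relative abundance is
    computed per sample from that sample's column sum before any removal;
    entries strictly below the threshold are zeroed in that sample only, and
    features left with all-zero rows are dropped.  A zero threshold is the
    identity.  Columns with zero sum are left untouched.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if threshold == 0:
        return table.copy()
    data = table.data.copy()
    sums = data.sum(axis=0)
    for sample in data.columns:
        total = sums[sample]
        if total <= 0:
            continue
        col = data[sample]
        data[sample] = col.where(col / total >= threshold, 0)
    return FeatureTable(data, table.value_kind).drop_empty_features()


def filter_prevalence(table: FeatureTable, min_samples: int) -> FeatureTable:
    """Drop features that are nonzero in fewer than ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = table.data.ne(0).sum(axis=1)
    keep = prevalence >= min_samples
    return FeatureTable(table.data.loc[keep].copy(), table.value_kind)


def read_genome_sizes(path: str) -> dict[str, int]:
    """Read a two-column TSV of genome id and length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"genome size line {lineno}: expected 2 columns")
            length = int(fields[1])
            if length <= 0:
                raise ValueError(f"genome {fields[0]!r} has non-positive size {length}")
            sizes[fields[0]] = length
    return sizes


def normalize_by_size(
    table: FeatureTable,
    sizes: Mapping[str, int],
    scale: float = 1.0,
    *,
    re_round: bool = False,
) -> FeatureTable:
    """Convert sequence abundance to taxonomic abundance by genome size.

    Each entry becomes ``count / genome_length * scale``.  Sequence counts
    are proportional to genome length at equal organism abundance, so this
    division estimates the relative number of organisms.  With ``re_round``
    the result is rounded half-to-even back to integers.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    missing = [f for f in table.feature_ids if f not in sizes]
    if missing:
        raise KeyError(
            "no genome size for feature(s): " + ", ".join(sorted(missing))
        )
    divisor = pd.Series({f: sizes[f] for f in table.feature_ids}, dtype=float)
    data = table.data.div(divisor, axis=0) * scale
    out = FeatureTable(data, "normalized_float")
    if re_round:
        out = round_table(out)
    return out


def subsample(
    table: FeatureTable,
    ledger: SampleDepthLedger,
    depth: int,
    seed: int,
) -> FeatureTable:
    """Rarefy a table to a fixed sequencing depth, without replacement.

    For each sample with ``m`` aligned of ``n`` total sequences, a reserved
    unaligned feature of count ``n - m`` is added, ``depth`` items are drawn
    from the resulting ``n``-item urn (multivariate hypergeometric), and the
    reserved feature is removed again.  ``depth`` is therefore on the scale
    of the *original* sequencing depth, not the aligned depth.  Deterministic
    given ``seed``.
    """
    if table.value_kind != "rounded_int":
        raise ValueError("subsampling requires a rounded_int table")
    if depth <= 0:
        raise ValueError("subsampling depth must be a positive integer")
    if UNALIGNED_ID in table.data.index:
        raise ValueError(f"reserved feature id {UNALIGNED_ID!r} already present")
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.sample_ids:
        col = table.data[sample].to_numpy().astype(np.int64)
        m = int(col.sum())
        n = int(ledger.n.get(sample, m))
        if depth > n:
            raise ValueError(
                f"sample {sample!r}: depth {depth} exceeds total sequences n={n}"
            )
        unaligned = n - m
        urn = np.concatenate([col, [unaligned]])
        drawn = rng.multivariate_hypergeometric(urn, depth)
        out[sample] = drawn[:-1].astype(float)
    data = pd.DataFrame(out, index=table.data.index)
    return FeatureTable(data, "rounded_int").drop_empty_features()


def subsample_replicates(
    table: FeatureTable,
    ledger: SampleDepthLedger,
    depth: int,
    seeds: Sequence[int] = tuple(range(10)),
) -> list[FeatureTable]:
    """Replicate rarefaction; by default 10 replicates with seeds 0 to 9."""
    return [subsample(table, ledger, depth, seed) for seed in seeds]


def merge_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Union of axes; overlapping (feature, sample) cells are summed."""
    if not tables:
        return FeatureTable(pd.DataFrame(), "raw_float")
    kinds = {t.value_kind for t in tables}
    if len(kinds) > 1:
        raise ValueError(f"cannot merge tables of mixed value kinds: {sorted(kinds)}")
    frames = [t.data for t in tables if t.data.size]
    if not frames:
        return FeatureTable(tables[0].data.copy(), tables[0].value_kind)
    merged = frames[0]
    for frame in frames[1:]:
        merged = merged.add(frame, fill_value=0)
    return FeatureTable(merged, tables[0].value_kind)


def write_table(table: FeatureTable, path: str, *, sparse: bool = False) -> None:
    """Write a table as TSV, features as rows, header cell ``#FeatureID``.

    With ``sparse=True`` a three-column triplet format
    (feature, sample, value) is written instead.
    """
    integral = table.value_kind == "rounded_int"

    def fmt(v: float) -> str:
        return str(int(v)) if integral else repr(float(v))

    with open(path, "w") as fh:
        if sparse:
            fh.write("#FeatureID\tSampleID\tValue\n")
            for feature in table.feature_ids:
                row = table.data.loc[feature]
                for sample in table.sample_ids:
                    v = row[sample]
                    if v != 0:
                        fh.write(f"{feature}\t{sample}\t{fmt(v)}\n")
        else:
            fh.write("#FeatureID\t" + "\t".join(table.sample_ids) + "\n")
            for feature in table.feature_ids:
                row = table.data.loc[feature]
                fh.write(
                    feature + "\t" + "\t".join(fmt(row[s]) for s in table.sample_ids) + "\n"
                )


def read_table(path: str, value_kind: str | None = None) -> FeatureTable:
    """Read a TSV feature table (dense or sparse triplet dialect).

    Integer-valued tables come back as ``rounded_int`` unless ``value_kind``
    overrides the guess.  Duplicate ids and negative values are errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#FeatureID"):
            raise ValueError(f"{path!r}: missing '#FeatureID' header")
        cols = header.split("\t")
        sparse = cols[1:3] == ["SampleID", "Value"] and len(cols) == 3
        if sparse:
            cells: dict[str, dict[str, float]] = defaultdict(dict)
            order: dict[str, None] = {}
            feat_order: dict[str, None] = {}
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                feature, sample, value = line.rstrip("\n").split("\t")
                if sample in cells and feature in cells[sample]:
                    raise ValueError(f"{path!r} line {lineno}: duplicate cell")
                cells[sample][feature] = float(value)
                order.setdefault(sample)
                feat_order.setdefault(feature)
            df = pd.DataFrame(
                {s: cells[s] for s in order}, index=list(feat_order)
            ).fillna(0.0)
        else:
            samples = cols[1:]
            if len(set(samples)) != len(samples):
                raise ValueError(f"{path!r}: duplicate sample ids")
            features = []
            rows = []
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(samples) + 1:
                    raise ValueError(
                        f"{path!r} line {lineno}: expected {len(samples) + 1} columns"
                    )
                features.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
            if len(set(features)) != len(features):
                raise ValueError(f"{path!r}: duplicate feature ids")
            df = pd.DataFrame(rows, index=features, columns=samples)
    if df.size and (df.to_numpy() < 0).any():
        raise ValueError(f"{path!r}: negative values in feature table")
    if value_kind is None:
        vals = df.to_numpy()
        value_kind = (
            "rounded_int" if df.size == 0 or np.array_equal(vals, np.floor(vals)) else "raw_float"
        )
    return FeatureTable(df, value_kind)
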