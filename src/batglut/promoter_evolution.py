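"""Group-structured comparative analysis of aligned promoter sequences.

Operates on a gapped multiple alignment whose rows are partitioned
into named groups (e.g. New World fruit bats, Old World fruit bats,
non-frugivorous bats).  Provides column-conservation profiling,
discovery of group-shared deletions, classification of bases
homologous to human promoter SNPs, Tajima's relative rate test, and a
neighbor-joining tree as a quick phylogeny surrogate.

All alignment coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

ALPHABET = set("ACGTN-")
BASES = set("ACGT")
PURINES = set("AG")


@dataclass
class GroupedAlignment:
    """Equal-length gapped sequences with a group label per row."""

    ids: list[str]
    seqs: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(self.ids) < 2:
            raise ValueError("alignment needs at least two rows")
        self.seqs = [s.upper() for s in self.seqs]
        length = len(self.seqs[0])
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise ValueError(f"row {sid!r} length {len(seq)} != {length}")
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"row {sid!r} has invalid symbols {sorted(bad)}")
        missing = [sid for sid in self.ids if sid not in self.groups]
        if missing:
            raise ValueError(f"rows without a group label: {missing}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def row(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def members(self, group: str | Iterable[str]) -> list[str]:
        labels = {group} if isinstance(group, str) else set(group)
        return [sid for sid in self.ids if self.groups[sid] in labels]

    def subset(self, keep: Iterable[str]) -> "GroupedAlignment":
        keep = set(keep)
        ids = [sid for sid in self.ids if sid in keep]
        seqs = [self.seqs[self.ids.index(sid)] for sid in ids]
        return GroupedAlignment(ids, seqs, {sid: self.groups[sid] for sid in ids})

    @classmethod
    def from_fasta(cls, fasta_path, groups: Mapping[str, str] | str) -> "GroupedAlignment":
        """Load from an aligned FASTA plus a group map.

        ``groups`` is either an id -> label mapping or the path of a
        two-column CSV ``id,group``.
        """
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if isinstance(groups, (str, bytes)) or hasattr(groups, "read_text"):
            table = pd.read_csv(groups)
            groups = dict(zip(table["id"].astype(str), table["group"].astype(str)))
        return cls(
            ids=[r.id for r in records],
            seqs=[str(r.seq) for r in records],
            groups=dict(groups),
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# conservation profiling


@dataclass(frozen=True)
class ConservationProfile:
    classes: list[str]  # per column: "universal", "group:<g>", "variable"
    universal_count: int
    group_counts: dict[str, int]  # additional group-specific conserved columns
    levels: dict[str, float]  # per-group conservation percentage
    length: int


def conservation_percent(universal: int, group_specific: int, length: int) -> float:
    """A group's conservation level: percentage of columns that are
    conserved either in every row or within the group, to one decimal."""
    if length <= 0:
        raise ValueError("length must be positive")
    return round(100.0 * (universal + group_specific) / length, 1)


def _column_conserved(column: Iterable[str], shared_gap_ok: bool) -> bool:
    symbols = set(column)
    if len(symbols) != 1:
        return False
    sym = next(iter(symbols))
    if sym in BASES:
        return True
    return sym == "-" and shared_gap_ok


def conservation_profile(
    aln: GroupedAlignment,
    groups: Sequence[str],
    shared_gap_conserves_group: bool = True,
) -> ConservationProfile:
    """Classify every column as universally conserved, conserved only
    within one or more groups, or variable.

    A column is *universal* when every row of the alignment carries the
    same base (a gap or N never counts).  A non-universal column is
    *group-specific* for group g when all of g's members agree; by
    default a gap shared by the whole group counts as conserved there
    (a shared deletion is shared history), switchable via
    ``shared_gap_conserves_group``.  Outgroup rows must be removed by
    the caller before profiling.
    """
    for g in groups:
        if not aln.members(g):
            raise ValueError(f"group {g!r} has no members")
    cols = list(zip(*aln.seqs))
    group_rows = {g: [aln.seqs[aln.ids.index(s)] for s in aln.members(g)] for g in groups}
    classes: list[str] = []
    group_counts = {g: 0 for g in groups}
    universal = 0
    for j, col in enumerate(cols):
        if _column_conserved(col, shared_gap_ok=False):
            classes.append("universal")
            universal += 1
            continue
        conserved_in = [
            g
            for g in groups
            if _column_conserved(
                (row[j] for row in group_rows[g]),
                shared_gap_ok=shared_gap_conserves_group,
            )
        ]
        if conserved_in:
            for g in conserved_in:
                group_counts[g] += 1
            classes.append("group:" + ",".join(conserved_in))
        else:
            classes.append("variable")
    levels = {
        g: conservation_percent(universal, group_counts[g], aln.length) for g in groups
    }
    return ConservationProfile(classes, universal, group_counts, levels, aln.length)


# ---------------------------------------------------------------------------
# shared indels


@dataclass(frozen=True)
class IndelEvent:
    group: str
    start: int  # 1-based alignment column
    length: int
    carriers: tuple[str, ...]


def find_shared_indels(
    aln: GroupedAlignment, group: str | Iterable[str]
) -> list[IndelEvent]:
    """Maximal column runs gapped in every member of ``group`` and
    ungapped in every other row, sorted by start.

    ``group`` may be a single label or several labels whose union forms
    the carrier set (e.g. both fruit-bat groups sharing one deletion).
    """
    carriers = aln.members(group)
    if not carriers:
        raise ValueError(f"group {group!r} has no members")
    others = [sid for sid in aln.ids if sid not in set(carriers)]
    carrier_rows = [aln.row(s) for s in carriers]
    other_rows = [aln.row(s) for s in others]
    label = group if isinstance(group, str) else "+".join(sorted(group))

    events: list[IndelEvent] = []
    run_start = None
    for j in range(aln.length + 1):
        is_shared_gap = j < aln.length and all(r[j] == "-" for r in carrier_rows) and all(
            r[j] != "-" for r in other_rows
        )
        if is_shared_gap and run_start is None:
            run_start = j
        elif not is_shared_gap and run_start is not None:
            events.append(
                IndelEvent(label, run_start + 1, j - run_start, tuple(carriers))
            )
            run_start = None
    return events


# ---------------------------------------------------------------------------
# SNP-homologous sites


@dataclass(frozen=True)
class SnpSite:
    name: str
    column: int  # 1-based
    susceptible: str
    normal: str

    def __post_init__(self) -> None:
        if self.susceptible not in BASES or self.normal not in BASES:
            raise ValueError("alleles must be A/C/G/T")
        if self.susceptible == self.normal:
            raise ValueError("alleles must differ")


def classify_snp_alleles(aln: GroupedAlignment, site: SnpSite) -> dict[str, str]:
    """Label each row's base at a SNP-homologous column as carrying the
    susceptible allele, the normal allele, another base, or a gap."""
    if not 1 <= site.column <= aln.length:
        raise ValueError(
            f"column {site.column} outside alignment of length {aln.length}"
        )
    out = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        base = seq[site.column - 1]
        if base == site.susceptible:
            out[sid] = "susceptible"
        elif base == site.normal:
            out[sid] = "normal"
        elif base == "-":
            out[sid] = "gap"
        else:
            out[sid] = "other"
    return out


def read_snp_sites(path) -> list[SnpSite]:
    table = pd.read_csv(path)
    return [
        SnpSite(str(r["name"]), int(r["column"]), str(r["susceptible"]), str(r["normal"]))
        for _, r in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# Tajima's relative rate test


@dataclass(frozen=True)
class RateTestResult:
    taxon_a: str
    taxon_b: str
    outgroup: str
    m1: int  # substitutions unique to taxon A
    m2: int  # substitutions unique to taxon B
    chi2: float
    p: float
    usable_sites: int


def tajima_relative_rate(
    seq_a: str,
    seq_b: str,
    outgroup: str,
    labels: tuple[str, str, str] = ("A", "B", "outgroup"),
) -> RateTestResult:
    """Tajima's relative rate test on an aligned triplet.

    Counts sites where one ingroup taxon differs while the other
    matches the outgroup (m1 for the first taxon, m2 for the second)
    and tests m1 = m2 with chi2 = (m1-m2)^2/(m1+m2) on 1 df.  Columns
    containing a gap, an N or any non-ACGT symbol in any of the three
    rows are excluded (complete deletion within the triplet).
    """
    seq_a, seq_b, outgroup = seq_a.upper(), seq_b.upper(), outgroup.upper()
    if not len(seq_a) == len(seq_b) == len(outgroup):
        raise ValueError("triplet rows must have equal aligned length")
    m1 = m2 = usable = 0
    for a, b, o in zip(seq_a, seq_b, outgroup):
        if a not in BASES or b not in BASES or o not in BASES:
            continue
        usable += 1
        if a != b:
            if b == o:
                m1 += 1
            elif a == o:
                m2 += 1
            # a != b != o: substitution unassignable, ignored
    if usable < 1:
        raise ValueError("no usable (gap/N-free) sites in triplet")
    if m1 + m2 == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (m1 - m2) ** 2 / (m1 + m2)
        p = float(stats.chi2.sf(chi2, df=1))
    return RateTestResult(labels[0], labels[1], labels[2], m1, m2, float(chi2), p, usable)


def tajima_from_alignment(
    aln: GroupedAlignment, id_a: str, id_b: str, outgroup_id: str
) -> RateTestResult:
    return tajima_relative_rate(
        aln.row(id_a), aln.row(id_b), aln.row(outgroup_id), labels=(id_a, id_b, outgroup_id)
    )


# ---------------------------------------------------------------------------
# neighbor-joining surrogate tree


def _pair_distance(s1: str, s2: str, model: str) -> float:
    pairs = [
        (a, b) for a, b in zip(s1, s2) if a in BASES and b in BASES
    ]
    if not pairs:
        raise ValueError("no comparable (gap/N-free) sites between pair")
    n = len(pairs)
    diffs = sum(a != b for a, b in pairs)
    if model == "p":
        return diffs / n
    if model == "k2p":
        transitions = sum(
            a != b and ((a in PURINES) == (b in PURINES)) for a, b in pairs
        )
        p = transitions / n
        q = (diffs - transitions) / n
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        if w1 <= 0 or w2 <= 0:
            raise ValueError("K2P distance saturated")
        return -0.5 * np.log(w1) - 0.25 * np.log(w2)
    raise ValueError(f"unknown distance model {model!r}")


def pairwise_distances(aln: GroupedAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise p or Kimura two-parameter distances with pairwise
    deletion of gap/N columns."""
    n = len(aln.ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = _pair_distance(aln.seqs[i], aln.seqs[j], model)
            except ValueError as exc:
                raise ValueError(
                    f"{exc} ({aln.ids[i]} vs {aln.ids[j]})"
                ) from None
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=aln.ids)


def nj_tree(aln: GroupedAlignment, distance: str = "p") -> str:
    """Neighbor-joining tree (Newick text) from pairwise distances.

    A fast distance-based surrogate for a model-based phylogeny;
    negative branch lengths arising from the NJ algebra are clamped to
    zero.
    """
    if len(aln.ids) < 3:
        raise ValueError("NJ needs at least three sequences")
    dm = pairwise_distances(aln, model=distance)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
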