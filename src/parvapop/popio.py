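"""Sequence/metadata IO, haplotype collapsing and divergence screening.

The locus is a single aligned mtDNA fragment (~700 bp of cytochrome *b*),
one sequence per individual.  Individuals are mapped to populations and to
the native/invasive group through a 5-column TSV.  Identical sequences (over
the columns retained after complete deletion of gapped/ambiguous columns)
are collapsed into haplotypes; a fold-threshold screen flags haplotypes so
divergent from the rest of the sample that they are better explained by
introgression from another species than by within-species variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from parvapop.errors import (
    AlignmentError,
    DegenerateAlignmentError,
    InputError,
)

#: IUPAC nucleotide codes plus alignment gap.
IUPAC = set("ACGTRYSWKMBDHVN-")
#: Unambiguous bases; only columns where every sequence has one of these survive
#: complete deletion.
UNAMBIGUOUS = set("ACGT")


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An aligned set of equal-length nucleotide sequences.

    Attributes
    ----------
    ids :
        Unique sequence identifiers, in input order.
    seqs :
        Upper-case sequences over the IUPAC alphabet plus ``-``.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise InputError("empty alignment: no sequences")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicate sequence identifiers")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.L == 0:
            raise AlignmentError("alignment has zero columns")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - IUPAC
            if bad:
                raise InputError(f"non-IUPAC characters {sorted(bad)} in {sid!r}")

    @property
    def L(self) -> int:
        """Alignment length in columns."""
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Iterable[str]) -> "AlignedSequenceSet":
        wanted = list(ids)
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [w for w in wanted if w not in index]
        if missing:
            raise InputError(f"ids not in alignment: {missing}")
        return AlignedSequenceSet(
            ids=tuple(wanted), seqs=tuple(self.seqs[index[w]] for w in wanted)
        )


@dataclass(frozen=True)
class PopulationMap:
    """Per-individual population code, group and coordinates.

    ``table`` is indexed by sequence id with columns ``population``, ``group``
    (``native`` or ``invasive``), ``lat`` and ``lon`` in signed decimal
    degrees.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"population", "group", "lat", "lon"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"population map missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise InputError(f"duplicate ids in population map: {dupes}")
        bad_group = set(self.table["group"]) - {"native", "invasive"}
        if bad_group:
            raise InputError(f"unknown group labels: {sorted(bad_group)}")
        if (self.table["lat"].abs() > 90).any() or (self.table["lon"].abs() > 180).any():
            raise InputError("coordinates out of range (|lat|<=90, |lon|<=180)")

    @property
    def populations(self) -> list[str]:
        """Population codes in order of first appearance."""
        return list(dict.fromkeys(self.table["population"]))

    def group_of(self, population: str) -> str:
        rows = self.table[self.table["population"] == population]
        if rows.empty:
            raise InputError(f"unknown population {population!r}")
        return str(rows["group"].iloc[0])

    def ids_of(self, population: str) -> list[str]:
        return list(self.table.index[self.table["population"] == population])

    def coords_of(self, population: str) -> tuple[float, float]:
        rows = self.table[self.table["population"] == population]
        if rows.empty:
            raise InputError(f"unknown population {population!r}")
        return float(rows["lat"].iloc[0]), float(rows["lon"].iloc[0])

    def check_covers(self, aln: AlignedSequenceSet) -> None:
        missing = [sid for sid in aln.ids if sid not in self.table.index]
        if missing:
            raise InputError(f"population map does not cover ids: {missing[:5]}")


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with per-population counts.

    Attributes
    ----------
    hap_ids :
        ``H1, H2, ...`` numbered by first appearance in the input alignment.
    representatives :
        One sequence per haplotype over the retained columns.
    counts :
        haplotype x population integer matrix; column sums equal sample sizes.
    retained_columns :
        0-based indices (into the source alignment) of columns kept after
        complete deletion.  For simulated tables these may simply be
        ``range(site_span)``.
    site_span :
        Number of sites the per-site statistics are scaled by.  Equals
        ``len(retained_columns)`` for collapsed empirical alignments; a
        simulator may retain only segregating sites and set the full locus
        length here.
    flagged :
        Haplotype ids marked "exclude from pi comparisons" by the divergence
        screen.
    assignments :
        Individual id -> haplotype id.
    """

    hap_ids: list[str]
    representatives: list[str]
    counts: pd.DataFrame
    retained_columns: list[int]
    site_span: int
    flagged: set[str] = field(default_factory=set)
    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    def sample_size(self, population: str) -> int:
        return int(self.counts[population].sum())

    def population_counts(self, population: str) -> np.ndarray:
        """Nonzero haplotype counts for one population."""
        col = self.counts[population].to_numpy()
        return col[col > 0]

    def population_profile(self, population: str) -> list[tuple[str, int]]:
        """(representative sequence, count) pairs present in a population."""
        col = self.counts[population]
        return [
            (self.representatives[i], int(c))
            for i, c in enumerate(col.to_numpy())
            if c > 0
        ]

    def representative_of(self, hap_id: str) -> str:
        return self.representatives[self.hap_ids.index(hap_id)]

    def drop_haplotypes(self, hap_ids: Iterable[str]) -> "HaplotypeTable":
        """Return a table with the given haplotypes (and their carriers) removed."""
        drop = set(hap_ids)
        keep = [i for i, h in enumerate(self.hap_ids) if h not in drop]
        return HaplotypeTable(
            hap_ids=[self.hap_ids[i] for i in keep],
            representatives=[self.representatives[i] for i in keep],
            counts=self.counts.iloc[keep],
            retained_columns=list(self.retained_columns),
            site_span=self.site_span,
            flagged={h for h in self.flagged if h not in drop},
            assignments={k: v for k, v in self.assignments.items() if v not in drop},
        )


def read_alignment(path: str | Path, format: str = "fasta") -> AlignedSequenceSet:
    """Read an aligned FASTA file into an :class:`AlignedSequenceSet`.

    Raises
    ------
    InputError
        Empty file or non-IUPAC characters.
    AlignmentError
        Records of unequal length.
    """
    if format != "fasta":
        raise InputError(f"unsupported format {format!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return AlignedSequenceSet(
        ids=tuple(r.id for r in records),
        seqs=tuple(str(r.seq).upper() for r in records),
    )


def write_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a 5-column TSV (id, population, group, lat, lon) with header."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "population": str, "group": str})
    expected = ["id", "population", "group", "lat", "lon"]
    if list(df.columns) != expected:
        raise InputError(f"population map columns must be {expected}, got {list(df.columns)}")
    return PopulationMap(table=df.set_index("id"))


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    popmap.table.reset_index(names="id").to_csv(path, sep="\t", index=False)


def retained_column_indices(aln: AlignedSequenceSet) -> list[int]:
    """Columns where every sequence carries an unambiguous base (complete deletion)."""
    arr = np.frombuffer("".join(aln.seqs).encode(), dtype="S1").reshape(len(aln), aln.L)
    ok = np.isin(arr, [b"A", b"C", b"G", b"T"]).all(axis=0)
    return [int(i) for i in np.flatnonzero(ok)]


def collapse_haplotypes(
    aln: AlignedSequenceSet,
    popmap: PopulationMap,
    missing_policy: str = "complete_deletion",
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes after complete deletion.

    Columns containing a gap or ambiguity code in *any* sequence are removed
    dataset-wide before collapsing, so every downstream pairwise statistic is
    computed on one common site set.  Haplotypes are numbered ``H1, H2, ...``
    by first appearance in input order, making the table order-stable.
    """
    if missing_policy != "complete_deletion":
        raise InputError(f"unsupported missing_policy {missing_policy!r}")
    popmap.check_covers(aln)
    retained = retained_column_indices(aln)
    if not retained:
        raise DegenerateAlignmentError("complete deletion removed every column")
    trimmed = ["".join(s[i] for i in retained) for s in aln.seqs]

    hap_of: dict[str, int] = {}
    hap_ids: list[str] = []
    representatives: list[str] = []
    assignments: dict[str, str] = {}
    populations = popmap.populations
    counts = np.zeros((0, len(populations)), dtype=int)
    pop_index = {p: j for j, p in enumerate(populations)}
    rows: list[np.ndarray] = []
    for sid, seq in zip(aln.ids, trimmed):
        if seq not in hap_of:
            hap_of[seq] = len(hap_ids)
            hap_ids.append(f"H{len(hap_ids) + 1}")
            representatives.append(seq)
            rows.append(np.zeros(len(populations), dtype=int))
        h = hap_of[seq]
        rows[h][pop_index[str(popmap.table.loc[sid, "population"])]] += 1
        assignments[sid] = hap_ids[h]
    counts = pd.DataFrame(np.vstack(rows), index=hap_ids, columns=populations)
    return HaplotypeTable(
        hap_ids=hap_ids,
        representatives=representatives,
        counts=counts,
        retained_columns=retained,
        site_span=len(retained),
        assignments=assignments,
    )


def screen_divergent_haplotypes(
    hap: HaplotypeTable, fold_threshold: float = 5.0
) -> set[str]:
    """Flag haplotypes far outside the sample's own divergence scale.

    A haplotype is flagged when its *minimum* K2P distance to every other
    haplotype exceeds ``fold_threshold`` times the median of all per-haplotype
    minimum distances — the signature of a sequence introgressed from a
    diverged donor (e.g. a *Gobio gobio* mitochondrion riding in a
    misidentified individual) rather than of within-species variation.
    Flags are recorded on the table (``excluded from pi comparisons``).
    """
    from parvapop.diversity import k2p_matrix  # local import to avoid a cycle

    if fold_threshold <= 0:
        raise InputError("fold_threshold must be positive")
    n = len(hap.hap_ids)
    if n < 3:
        warnings.warn("fewer than 3 haplotypes: divergence screen skipped")
        return set()
    d = k2p_matrix(hap.representatives, site_span=hap.site_span)
    np.fill_diagonal(d, np.inf)
    mins = d.min(axis=1)
    med = float(np.median(mins))
    if med == 0.0:
        # Degenerate scale (most haplotypes one step apart after rounding):
        # fall back to the mean of nonzero minima; if all zero, nothing to flag.
        nonzero = mins[mins > 0]
        if nonzero.size == 0:
            return set()
        med = float(np.mean(nonzero))
    flagged = {hap.hap_ids[i] for i in range(n) if mins[i] > fold_threshold * med}
    hap.flagged |= flagged
    return flagged


def write_haplotype_table(hap: HaplotypeTable, counts_path: str | Path, fasta_path: str | Path) -> None:
    """Serialize counts as TSV and representatives as FASTA."""
    hap.counts.rename_axis("haplotype").to_csv(counts_path, sep="\t")
    records = [
        SeqRecord(Seq(s), id=h, description="")
        for h, s in zip(hap.hap_ids, hap.representatives)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def table_from_records(
    ids: Sequence[str],
    seqs: Sequence[str],
    pops: Sequence[str],
    site_span: int | None = None,
) -> HaplotypeTable:
    """Build a :class:`HaplotypeTable` directly from per-individual records.

    Used by simulators whose sequences are already clean (no gaps or
    ambiguity codes); no column filtering is applied.  ``site_span`` lets a
    simulator that tracks only segregating sites declare the true locus
    length for per-site scaling.
    """
    L = len(seqs[0]) if seqs else 0
    hap_of: dict[str, int] = {}
    hap_ids: list[str] = []
    reps: list[str] = []
    populations = list(dict.fromkeys(pops))
    rows: list[np.ndarray] = []
    pop_index = {p: j for j, p in enumerate(populations)}
    assignments: dict[str, str] = {}
    for sid, seq, pop in zip(ids, seqs, pops):
        if len(seq) != L:
            raise AlignmentError("ragged simulated records")
        if seq not in hap_of:
            hap_of[seq] = len(hap_ids)
            hap_ids.append(f"H{len(hap_ids) + 1}")
            reps.append(seq)
            rows.append(np.zeros(len(populations), dtype=int))
        rows[hap_of[seq]][pop_index[pop]] += 1
        assignments[sid] = hap_ids[hap_of[seq]]
    counts = pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, len(populations)), dtype=int),
        index=hap_ids,
        columns=populations,
    )
    return HaplotypeTable(
        hap_ids=hap_ids,
        representatives=reps,
        counts=counts,
        retained_columns=list(range(L)),
        site_span=site_span if site_span is not None else L,
        assignments=assignments,
    )
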