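"""Aligned mtDNA sequence data: reading, validation, site filtering,
haplotype collapsing.

The unit of analysis is an aligned multi-FASTA of control-region (HVI)
haplotype sequences plus a tab-separated label table assigning every
sequence to a sampled habitat patch with its lon/lat. Diversity statistics
downstream operate on *retained sites* only: the default policy removes
every alignment column containing a gap or an IUPAC ambiguity code in any
record (complete deletion, the convention of standard diversity software).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = frozenset("ACGT")
AMBIGUITY = frozenset("RYSWKMBDHVN")
GAP = "-"
ALPHABET = BASES | AMBIGUITY | {GAP}


class AlignmentError(ValueError):
    """Invalid alignment, label table, or filter outcome."""


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with patch labels.

    ``matrix`` is an (n, L) array of single uppercase characters; ``ids``
    and ``patches`` run parallel to its rows. ``retained_sites`` maps the
    current columns back to the original alignment coordinates (identity on
    a freshly read alignment, a subset after :func:`filter_sites`).
    """

    ids: list[str]
    patches: list[str]
    matrix: np.ndarray
    retained_sites: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0] or len(self.patches) != len(self.ids):
            raise AlignmentError("ids/patches/matrix row counts disagree")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if self.retained_sites is None:
            self.retained_sites = np.arange(self.matrix.shape[1])
        bad = ~np.isin(self.matrix, sorted(ALPHABET))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise AlignmentError(
                f"record {self.ids[i]!r}: invalid character "
                f"{str(self.matrix[i, j])!r} at alignment position {j + 1}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.matrix]

    def subset(self, indices) -> "Alignment":
        indices = np.asarray(indices)
        return Alignment([self.ids[i] for i in indices],
                         [self.patches[i] for i in indices],
                         self.matrix[indices],
                         self.retained_sites.copy())


@dataclass
class PatchTable:
    """Sampled patches: label, centroid lon/lat, member sequence ids."""

    table: pd.DataFrame  # index: patch label; columns lon, lat
    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise AlignmentError("duplicate patch labels")
        if not np.isfinite(self.table[["lon", "lat"]].to_numpy()).all():
            raise AlignmentError("non-finite patch coordinates")

    @property
    def labels(self) -> list[str]:
        return list(self.table.index)

    @property
    def k(self) -> int:
        return len(self.table)

    def coords(self) -> np.ndarray:
        return self.table[["lon", "lat"]].to_numpy()


@dataclass
class HaplotypeAssignment:
    """Partition of sequences into haplotypes with per-patch frequencies.

    Identity is exact equality over retained sites; indices follow first
    occurrence in the alignment. ``counts`` is a (haplotype x patch) table
    whose column sums are the patch sample sizes.
    """

    indices: np.ndarray          # haplotype index per record
    counts: pd.DataFrame         # rows: haplotype index, cols: patch label

    @property
    def n_haplotypes(self) -> int:
        return self.counts.shape[0]

    @property
    def patch_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def proportions(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1).to_numpy()


def read_alignment(fasta_path, labels_path) -> tuple[Alignment, PatchTable]:
    """Read and validate an aligned FASTA plus its ``id patch lon lat`` TSV.

    Sequences are case-normalized to uppercase; ambiguity codes are
    preserved. Errors name the offending records: ragged alignments list
    every id of deviant length, unknown characters are reported with their
    position, and any FASTA id absent from the label table is fatal.
    """
    labels = pd.read_csv(labels_path, sep="\t", dtype={"id": str, "patch": str})
    required = {"id", "patch", "lon", "lat"}
    if not required.issubset(labels.columns):
        raise AlignmentError(
            f"label table must have columns {sorted(required)}, "
            f"got {list(labels.columns)}")
    if labels["id"].duplicated().any():
        dups = labels.loc[labels["id"].duplicated(), "id"].tolist()
        raise AlignmentError(f"duplicate ids in label table: {dups}")
    by_id = labels.set_index("id")

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        mode_len = max(lengths, key=lambda L: sum(len(r.seq) == L for r in records))
        bad = [r.id for r in records if len(r.seq) != mode_len]
        raise AlignmentError(f"ragged alignment: records {bad} differ from "
                             f"the majority length {mode_len}")
    missing = [r.id for r in records if r.id not in by_id.index]
    if missing:
        raise AlignmentError(f"ids missing from label table: {missing}")

    ids = [r.id for r in records]
    patches = [by_id.loc[r.id, "patch"] for r in records]
    matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="U1")
    aln = Alignment(ids, patches, matrix)

    # patch centroid = mean of its members' coordinates
    sub = by_id.loc[ids]
    centroids = sub.groupby("patch")[["lon", "lat"]].mean()
    members = {p: sub.index[sub["patch"] == p].tolist() for p in centroids.index}
    return aln, PatchTable(centroids, members)


def write_alignment(aln: Alignment, patches: PatchTable,
                    fasta_path, labels_path, wrap: int = 70) -> None:
    """Write FASTA (fixed line wrap) and the matching label TSV."""
    recs = [SeqRecord(Seq(s), id=i, description="")
            for i, s in zip(aln.ids, aln.sequences())]
    with open(fasta_path, "w") as fh:
        for rec in recs:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for start in range(0, len(s), wrap):
                fh.write(s[start:start + wrap] + "\n")
    coord = patches.table
    rows = [(i, p, coord.loc[p, "lon"], coord.loc[p, "lat"])
            for i, p in zip(aln.ids, aln.patches)]
    pd.DataFrame(rows, columns=["id", "patch", "lon", "lat"]).to_csv(
        labels_path, sep="\t", index=False)


def filter_sites(aln: Alignment, policy: str = "complete") -> Alignment:
    """Apply the site-filter policy; returns a new alignment.

    ``complete`` (default) drops every column containing a gap or ambiguity
    code in any record, recording the retained-column map. ``none`` is the
    identity (used when π is later computed with pairwise deletion).
    """
    if policy == "none":
        return Alignment(list(aln.ids), list(aln.patches), aln.matrix.copy(),
                         aln.retained_sites.copy())
    if policy != "complete":
        raise AlignmentError(f"unknown site-filter policy {policy!r}")
    clean = np.isin(aln.matrix, list("ACGT")).all(axis=0)
    if not clean.any():
        raise AlignmentError("no analyzable sites: every column has a gap "
                             "or ambiguity code")
    return Alignment(list(aln.ids), list(aln.patches),
                     aln.matrix[:, clean], aln.retained_sites[clean])


def collapse_haplotypes(aln: Alignment) -> HaplotypeAssignment:
    """Group sequences identical over retained sites into haplotypes."""
    seqs = aln.sequences()
    first_seen: dict[str, int] = {}
    indices = np.empty(aln.n, dtype=int)
    for i, s in enumerate(seqs):
        indices[i] = first_seen.setdefault(s, len(first_seen))
    patch_labels = sorted(set(aln.patches))
    counts = pd.DataFrame(0, index=range(len(first_seen)), columns=patch_labels)
    for idx, patch in zip(indices, aln.patches):
        counts.loc[idx, patch] += 1
    return HaplotypeAssignment(indices, counts)
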