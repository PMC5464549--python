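"""Aligned haploid sequence I/O, validation, and haplotype bookkeeping.

The central containers are :class:`Alignment` (a fixed-length nucleotide
matrix with per-sequence identifiers), :class:`SampleMetadata` (sample →
location → biogeographical-area mapping with optional coordinates),
:class:`HaplotypeTable` (distinct sequences × location count matrix) and
:class:`DistanceMatrix`.

Distances between sequences use pairwise deletion: a site enters a pair's
comparison only when both sequences carry an unambiguous base (A/C/G/T);
sites with N or an alignment gap in either member are skipped for that pair.
This choice differs between the classical programs in the field and is
therefore recorded in output provenance by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGTN-"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
#: codes 0..3 are unambiguous bases; 4 = N, 5 = gap
N_BASES = 4

METADATA_COLUMNS = ("sample_id", "location", "area", "lat", "lon")


class AlignmentError(ValueError):
    """Sequences violate the alignment contract (length, alphabet)."""


class MetadataError(ValueError):
    """Metadata rows and alignment records do not match up."""


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase nucleotide string as a uint8 code vector."""
    try:
        return np.fromiter((_CODE[c] for c in seq.upper()), np.uint8, len(seq))
    except KeyError as exc:
        raise AlignmentError(
            f"illegal character {exc.args[0]!r}; allowed alphabet is {ALPHABET}"
        ) from None


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass
class Alignment:
    """Equal-length haploid nucleotide sequences with unique identifiers."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence identifiers are not unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]
        self._matrix = (
            np.vstack([encode(s) for s in self.seqs])
            if self.seqs
            else np.empty((0, 0), np.uint8)
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        """Alignment length in bp."""
        return self._matrix.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """(n, L) uint8 code matrix; read-only view."""
        return self._matrix

    def subset(self, indices) -> "Alignment":
        indices = list(indices)
        return Alignment([self.ids[i] for i in indices], [self.seqs[i] for i in indices])

    def n_polymorphic(self) -> int:
        """Sites with >= 2 distinct unambiguous bases across sequences."""
        m = self._matrix
        if m.size == 0:
            return 0
        n_states = np.zeros(m.shape[1], int)
        for b in range(N_BASES):
            n_states += (m == b).any(axis=0)
        return int((n_states >= 2).sum())


@dataclass
class SampleMetadata:
    """Per-sample location/area labels with optional coordinates.

    Wraps a DataFrame with columns sample_id, location, area, lat, lon.
    Every location must map to exactly one area.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS[:3] if c not in self.table.columns]
        if missing:
            raise MetadataError(f"metadata missing required columns: {missing}")
        for c in ("lat", "lon"):
            if c not in self.table.columns:
                self.table[c] = np.nan
        if self.table["sample_id"].duplicated().any():
            raise MetadataError("duplicate sample_id in metadata")
        loc_area = self.table.groupby("location")["area"].nunique()
        bad = loc_area[loc_area > 1]
        if len(bad):
            raise MetadataError(
                f"locations mapped to more than one area: {list(bad.index)}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def locations(self) -> list[str]:
        """Distinct locations in order of first appearance."""
        return list(dict.fromkeys(self.table["location"]))

    @property
    def areas(self) -> list[str]:
        return list(dict.fromkeys(self.table["area"]))

    def location_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["location"]))

    def area_of_location(self) -> dict[str, str]:
        return dict(zip(self.table["location"], self.table["area"]))

    def aligned_to(self, aln: Alignment) -> "SampleMetadata":
        """Reorder rows to the alignment's id order; error on missing ids."""
        idx = self.table.set_index("sample_id")
        missing = [i for i in aln.ids if i not in idx.index]
        if missing:
            raise MetadataError(f"samples absent from metadata: {missing[:5]}")
        return SampleMetadata(idx.loc[aln.ids].reset_index())


@dataclass
class HaplotypeTable:
    """Distinct sequences × location matrix of individual counts."""

    hap_seqs: list[str]
    counts: pd.DataFrame  # index = haplotype id, columns = locations
    hap_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.hap_seqs) != len(self.counts):
            raise ValueError("hap_seqs and count rows differ in number")
        if len(set(self.hap_seqs)) != len(self.hap_seqs):
            raise ValueError("haplotype sequences are not pairwise distinct")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative haplotype count")
        if len(self.counts) and (self.counts.sum(axis=1) < 1).any():
            raise ValueError("haplotype with zero total count")
        if not self.hap_ids:
            self.hap_ids = [f"H{i + 1}" for i in range(len(self.hap_seqs))]
        self.counts.index = pd.Index(self.hap_ids, name="haplotype")

    @property
    def N(self) -> int:
        """Total number of individuals."""
        return int(self.counts.to_numpy().sum())

    @property
    def Nh(self) -> int:
        """Number of distinct haplotypes."""
        return len(self.hap_seqs)

    @property
    def Np(self) -> int:
        """Number of polymorphic sites among the observed haplotypes."""
        return Alignment(self.hap_ids, list(self.hap_seqs)).n_polymorphic()

    def singletons(self) -> int:
        return int((self.counts.sum(axis=1) == 1).sum())

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "sequence", self.hap_seqs)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        seqs = list(df.pop("sequence"))
        return cls(seqs, df.astype(int), hap_ids=list(df.index))


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal, with labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) values in row-major order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]


def read_alignment(fasta_path, metadata_path) -> tuple[Alignment, SampleMetadata]:
    """Read a FASTA alignment plus its tab-separated metadata.

    Metadata must have a header line ``sample_id	location	area	lat	lon``
    (lat/lon may be empty). Rows are returned re-ordered to FASTA order.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    aln = Alignment([r.id for r in records], [str(r.seq) for r in records])
    meta = SampleMetadata(pd.read_csv(metadata_path, sep="\t"))
    return aln, meta.aligned_to(aln)


def write_alignment(aln: Alignment, fasta_path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)]
    SeqIO.write(recs, str(fasta_path), "fasta")


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False, columns=list(METADATA_COLUMNS))


def collapse_haplotypes(aln: Alignment, meta: SampleMetadata) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes, counted per location.

    Identity is exact string equality after uppercasing; sequences containing
    N or gaps join a haplotype only when the full strings match. Haplotypes
    are ordered by first appearance in the alignment.
    """
    if aln.n == 0:
        raise ValueError("empty alignment")
    meta = meta.aligned_to(aln)
    loc_of = meta.location_of()
    locations = meta.locations
    hap_index: dict[str, int] = {}
    hap_seqs: list[str] = []
    rows: list[dict[str, int]] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        j = hap_index.get(seq)
        if j is None:
            j = hap_index[seq] = len(hap_seqs)
            hap_seqs.append(seq)
            rows.append({})
        loc = loc_of[sid]
        rows[j][loc] = rows[j].get(loc, 0) + 1
    counts = pd.DataFrame(rows, dtype=float).reindex(columns=locations).fillna(0)
    return HaplotypeTable(hap_seqs, counts.astype(int))


def expand_from_counts(
    ht: HaplotypeTable, area_of_location: dict[str, str] | None = None
) -> tuple[Alignment, SampleMetadata]:
    """Reconstruct individual-level records from a haplotype-count table.

    Inverse of :func:`collapse_haplotypes` up to row/column order. When
    ``area_of_location`` is omitted every location is assigned to a single
    area ``"all"``.
    """
    if ht.N == 0:
        raise ValueError("count matrix is all zero")
    ids, seqs, rows = [], [], []
    for loc in ht.counts.columns:
        area = (area_of_location or {}).get(loc, "all")
        k = 0
        for hap_id, seq, c in zip(ht.hap_ids, ht.hap_seqs, ht.counts[loc]):
            for _ in range(int(c)):
                k += 1
                sid = f"{loc}_{k:03d}"
                ids.append(sid)
                seqs.append(seq)
                rows.append(
                    {"sample_id": sid, "location": loc, "area": area,
                     "lat": np.nan, "lon": np.nan}
                )
    return Alignment(ids, seqs), SampleMetadata(pd.DataFrame(rows))


def pairwise_differences(aln: Alignment) -> DistanceMatrix:
    """Pairwise nucleotide-difference counts under pairwise deletion.

    Entry (i, j) counts sites where both sequences carry an unambiguous base
    and the bases differ.
    """
    m = aln.matrix
    valid = m < N_BASES
    n = aln.n
    d = np.zeros((n, n), float)
    for i in range(n - 1):
        neq = m[i + 1 :] != m[i]
        ok = valid[i + 1 :] & valid[i]
        d[i, i + 1 :] = (neq & ok).sum(axis=1)
    d += d.T
    return DistanceMatrix(list(aln.ids), d)


def compared_sites(aln: Alignment) -> np.ndarray:
    """(n, n) matrix of the number of sites compared per pair (pairwise deletion)."""
    valid = (aln.matrix < N_BASES).astype(np.int32)
    return valid @ valid.T
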