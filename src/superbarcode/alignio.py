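"""Core data objects and file I/O for organellar super-barcoding.

The substrate of every downstream statistic is a gapped multiple-sequence
alignment (one record per specimen) together with a specimen-to-species map
and, optionally, a table of annotated regions (CDS, spacer, intron,
pseudogene, rRNA, tRNA) partitioning the alignment columns.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: canonical residue encoding used by the numeric alignment matrix
ALPHABET = "ACGTN-"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
A, C, G, T, N_CODE, GAP_CODE = range(6)

#: region categories; only CDS counts as coding
REGION_CATEGORIES = ("CDS", "spacer", "intron", "pseudogene", "rRNA", "tRNA")
NONCODING_CATEGORIES = ("spacer", "intron", "pseudogene",)


class AlignmentError(ValueError):
    """Raised when alignment invariants are violated."""


@dataclass(frozen=True)
class Region:
    """A named, categorized half-open interval on alignment columns."""

    name: str
    start: int
    end: int
    category: str

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionTable:
    """Non-overlapping named regions partitioning (part of) an alignment.

    Parameters
    ----------
    regions
        Iterable of :class:`Region` (or ``(name, start, end, category)``
        tuples). Regions must not overlap and names must be unique.
    """

    def __init__(self, regions: Iterable[Region | tuple]):
        regs = []
        for r in regions:
            if not isinstance(r, Region):
                r = Region(str(r[0]), int(r[1]), int(r[2]), str(r[3]))
            regs.append(r)
        names = [r.name for r in regs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AlignmentError(f"duplicate region names: {dup}")
        for r in regs:
            if not 0 <= r.start < r.end:
                raise AlignmentError(f"region {r.name!r}: need 0 <= start < end, got [{r.start},{r.end})")
            if r.category not in REGION_CATEGORIES:
                raise AlignmentError(f"region {r.name!r}: unknown category {r.category!r}")
        for a, b in zip(sorted(regs, key=lambda r: r.start), sorted(regs, key=lambda r: r.start)[1:]):
            if b.start < a.end:
                raise AlignmentError(f"regions overlap: {a.name!r} and {b.name!r}")
        self.regions: list[Region] = regs

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i) -> Region:
        return self.regions[i]

    def validate_for(self, aln: "Alignment") -> None:
        for r in self.regions:
            if r.end > aln.length:
                raise AlignmentError(
                    f"region {r.name!r} end {r.end} exceeds alignment length {aln.length}"
                )

    def by_category(self, *categories: str) -> list[Region]:
        return [r for r in self.regions if r.category in categories]


class Alignment:
    """An equal-length gapped alignment with species labels.

    Sequences are stored uppercase over ``{A,C,G,T,N,-}``; any IUPAC
    ambiguity code is collapsed to ``N`` on construction (the downstream
    statistics only need a valid/invalid site classification).

    Attributes
    ----------
    ids : list of str
        Ordered specimen identifiers (unique).
    seqs : list of str
        Aligned sequences, one per specimen.
    species_of : dict
        Specimen id -> species label; every id must be present.
    """

    def __init__(self, ids: Sequence[str], seqs: Sequence[str], species_of: Mapping[str, str]):
        ids = list(ids)
        if len(ids) != len(set(ids)):
            raise AlignmentError("specimen ids are not unique")
        if len(ids) < 2:
            raise AlignmentError("alignment needs >= 2 specimens")
        if len(seqs) != len(ids):
            raise AlignmentError("ids and seqs differ in length")
        cleaned, n_unknown = [], 0
        length = None
        for sid, s in zip(ids, seqs):
            s = str(s).upper()
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise AlignmentError(
                    f"unequal alignment lengths: record {sid!r} has {len(s)}, expected {length}"
                )
            filtered = []
            for ch in s:
                if ch in _CODE:
                    filtered.append(ch)
                else:
                    filtered.append("N")
                    n_unknown += 1
            cleaned.append("".join(filtered))
        if length is None or length < 1:
            raise AlignmentError("empty alignment")
        missing = [sid for sid in ids if sid not in species_of]
        if missing:
            raise AlignmentError(f"specimens without species label: {missing}")
        if n_unknown:
            logger.warning("mapped %d unknown characters to N", n_unknown)
        self.ids = ids
        self.seqs = cleaned
        self.length = length
        self.species_of = {sid: species_of[sid] for sid in ids}
        self._matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_specimens(self) -> int:
        return len(self.ids)

    @property
    def species(self) -> list[str]:
        """Distinct species labels in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.ids:
            seen.setdefault(self.species_of[sid], None)
        return list(seen)

    @property
    def matrix(self) -> np.ndarray:
        """(n_specimens, length) uint8 matrix over codes A=0,C=1,G=2,T=3,N=4,-=5."""
        if self._matrix is None:
            m = np.empty((len(self.ids), self.length), dtype=np.uint8)
            for i, s in enumerate(self.seqs):
                m[i] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            lut = np.full(128, N_CODE, dtype=np.uint8)
            for ch, code in _CODE.items():
                lut[ord(ch)] = code
            self._matrix = lut[m]
            self._matrix.setflags(write=False)
        return self._matrix

    @classmethod
    def from_matrix(cls, ids: Sequence[str], matrix: np.ndarray, species_of: Mapping[str, str]) -> "Alignment":
        seqs = ["".join(ALPHABET[c] for c in row) for row in np.asarray(matrix, dtype=np.uint8)]
        return cls(ids, seqs, species_of)

    def species_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid in self.ids:
            out.setdefault(self.species_of[sid], []).append(sid)
        return out


_LUT = np.full(128, N_CODE, dtype=np.uint8)
for _ch, _code in _CODE.items():
    _LUT[ord(_ch)] = _code


def encode_seq(seq: str) -> np.ndarray:
    """Encode one sequence string to the numeric alphabet (unknowns -> N)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _LUT[np.minimum(raw, 127)]


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a TSV with columns ``specimen_id`` and ``species`` (header required)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("specimen_id", "species"):
        if col not in df.columns:
            raise AlignmentError(f"species map {path}: missing column {col!r}")
    return dict(zip(df["specimen_id"], df["species"]))


def read_alignment(path: str | Path, species_map_path: str | Path) -> Alignment:
    """Read an aligned FASTA plus a specimen->species TSV.

    Species labels come from the TSV only; FASTA headers are treated as
    opaque specimen identifiers (herbarium-style IDs carry no species
    information).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    species_of = read_species_map(species_map_path)
    return Alignment([r.id for r in records], [str(r.seq) for r in records], species_of)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=sid, description="") for sid, s in zip(aln.ids, aln.seqs)]
    SeqIO.write(recs, str(path), "fasta")


def write_species_map(species_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("specimen_id\tspecies\n")
        for sid, sp in species_of.items():
            fh.write(f"{sid}\t{sp}\n")


def read_regions(path: str | Path) -> RegionTable:
    """Read a region TSV with columns name, start, end, category (0-based half-open)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("name", "start", "end", "category"):
        if col not in df.columns:
            raise AlignmentError(f"region table {path}: missing column {col!r}")
    return RegionTable(
        Region(str(r["name"]), int(r["start"]), int(r["end"]), str(r["category"]))
        for _, r in df.iterrows()
    )


def write_regions(regions: RegionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\tcategory\n")
        for r in regions:
            fh.write(f"{r.name}\t{r.start}\t{r.end}\t{r.category}\n")


def _check_intervals(intervals: Sequence[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    for a, b in ivs:
        if not (0 <= a < b <= length):
            raise AlignmentError(f"interval [{a},{b}) out of range for length {length}")
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 < b1:
            raise AlignmentError(f"overlapping intervals [{a1},{b1}) and [{a2},{b2})")
    return ivs


def drop_columns(aln: Alignment, intervals: Sequence[tuple[int, int]]) -> Alignment:
    """Remove half-open column intervals (e.g. the second inverted-repeat copy).

    Returns a new alignment; specimen order is preserved.  Dropping all
    columns is an error.
    """
    if not intervals:
        return Alignment(aln.ids, aln.seqs, aln.species_of)
    ivs = _check_intervals(intervals, aln.length)
    keep = np.ones(aln.length, dtype=bool)
    for a, b in ivs:
        keep[a:b] = False
    if not keep.any():
        raise AlignmentError("empty alignment: all columns dropped")
    idx = np.flatnonzero(keep)
    seqs = ["".join(s[i] for i in idx) for s in aln.seqs]
    return Alignment(aln.ids, seqs, aln.species_of)
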