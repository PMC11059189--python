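"""Genome model, megabase binning, and I/O for per-cell contact files.

Contacts are exchanged as plain-text "pairs"-dialect files (one per cell):
``#``-prefixed header lines carrying cell metadata, then one contact per
body line with at least four whitespace-separated columns
``chrom1 pos1 chrom2 pos2`` (extra columns are ignored).  Positions are
1-based, following the dominant pairs-file convention; bins are 0-based
half-open internally, with :func:`assign_bin` defining the bridge.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "Contact",
    "ContactSet",
    "BinIndex",
    "CompartmentTrack",
    "read_chrom_sizes",
    "load_packaged_genome",
    "read_pairs",
    "write_pairs",
    "make_bins",
    "assign_bin",
    "read_track",
    "write_track",
]

DAYS_PER_YEAR = 365.0


class FormatError(ValueError):
    """Malformed input table or pairs file."""


@dataclass(frozen=True)
class Genome:
    """An ordered set of chromosomes with lengths in bp.

    The X chromosome is identified by name ("chrX" or "X"); every other
    chromosome is treated as an autosome.  Chromosome order as given
    defines the canonical sort order for contacts.
    """

    species: str
    names: tuple[str, ...]
    lengths: tuple[int, ...]
    x_name: str | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise FormatError("duplicate chromosome name")
        if any(l <= 0 for l in self.lengths):
            raise FormatError("non-positive chromosome length")
        if len(self.names) != len(self.lengths):
            raise FormatError("names/lengths mismatch")

    @property
    def n_chroms(self) -> int:
        return len(self.names)

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n != self.x_name)

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.names)}

    @property
    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=np.int64)

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.index[chrom]]

    @property
    def x_index(self) -> int | None:
        return self.index[self.x_name] if self.x_name is not None else None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


class Contact(NamedTuple):
    """One chromatin contact: a pair of genomic loci (chrom, pos in bp)."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


@dataclass
class ContactSet:
    """All chromatin contacts of one cell, plus cell metadata.

    Contacts are stored column-wise as numpy arrays (chromosome indices
    into ``genome.names`` and 1-based positions) and are kept in
    canonical order: chrom_a <= chrom_b by genome order, and
    pos_a <= pos_b for intra-chromosomal contacts.
    """

    cell_id: str
    genome: Genome
    chrom1: np.ndarray  # int32 indices into genome.names
    pos1: np.ndarray  # int64, 1-based
    chrom2: np.ndarray
    pos2: np.ndarray
    donor: str | None = None
    age: float | None = None
    age_unit: str = "years"  # "years" | "days" (postnatal days)
    sex: str | None = None  # "M" | "F" | None
    species: str | None = None
    truth: dict = field(default_factory=dict)  # ground-truth labels if synthetic
    n_rejected: int = 0  # records dropped at read time

    def __post_init__(self) -> None:
        for name in ("chrom1", "chrom2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int32))
        for name in ("pos1", "pos2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if len(self) < 1:
            raise ValueError(f"cell {self.cell_id!r}: a ContactSet needs >= 1 contact")
        lens = self.genome.lengths_array
        for c, p in ((self.chrom1, self.pos1), (self.chrom2, self.pos2)):
            if c.min() < 0 or c.max() >= self.genome.n_chroms:
                raise ValueError("contact references chromosome outside genome")
            if p.min() < 1 or np.any(p > lens[c]):
                raise ValueError("contact position outside chromosome bounds")
        self.canonicalize()

    def __len__(self) -> int:
        return int(self.chrom1.shape[0])

    @property
    def n_contacts(self) -> int:
        return len(self)

    @property
    def age_years(self) -> float | None:
        """Age converted to years (1 postnatal day = 1/365 yr)."""
        if self.age is None:
            return None
        return self.age / DAYS_PER_YEAR if self.age_unit == "days" else self.age

    def canonicalize(self) -> None:
        """Order endpoints in place; idempotent."""
        swap = (self.chrom1 > self.chrom2) | (
            (self.chrom1 == self.chrom2) & (self.pos1 > self.pos2)
        )
        if swap.any():
            c1, p1 = self.chrom1.copy(), self.pos1.copy()
            self.chrom1[swap], self.pos1[swap] = self.chrom2[swap], self.pos2[swap]
            self.chrom2[swap], self.pos2[swap] = c1[swap], p1[swap]

    @property
    def is_intra(self) -> np.ndarray:
        return self.chrom1 == self.chrom2

    def iter_contacts(self) -> Iterator[Contact]:
        names = self.genome.names
        for c1, p1, c2, p2 in zip(self.chrom1, self.pos1, self.chrom2, self.pos2):
            yield Contact(names[c1], int(p1), names[c2], int(p2))

    @classmethod
    def from_contacts(
        cls, cell_id: str, genome: Genome, contacts: Iterable[tuple], **meta
    ) -> "ContactSet":
        idx = genome.index
        rows = list(contacts)
        if not rows:
            raise ValueError(f"cell {cell_id!r}: a ContactSet needs >= 1 contact")
        c1 = np.array([idx[r[0]] for r in rows], dtype=np.int32)
        p1 = np.array([r[1] for r in rows], dtype=np.int64)
        c2 = np.array([idx[r[2]] for r in rows], dtype=np.int32)
        p2 = np.array([r[3] for r in rows], dtype=np.int64)
        return cls(cell_id, genome, c1, p1, c2, p2, **meta)

    def equals(self, other: "ContactSet") -> bool:
        return (
            self.cell_id == other.cell_id
            and self.donor == other.donor
            and self.age == other.age
            and self.age_unit == other.age_unit
            and self.sex == other.sex
            and self.species == other.species
            and self.truth == other.truth
            and np.array_equal(self.chrom1, other.chrom1)
            and np.array_equal(self.pos1, other.pos1)
            and np.array_equal(self.chrom2, other.chrom2)
            and np.array_equal(self.pos2, other.pos2)
        )


@dataclass(frozen=True)
class BinIndex:
    """Bijection between (chromosome, bin ordinal) and a global bin id.

    Chromosomes are tiled left to right with fixed-size bins (the last
    bin of each chromosome may be short); global ids are consecutive in
    genome order.
    """

    genome: Genome
    bin_size: int
    n_bins_per_chrom: tuple[int, ...]
    offsets: tuple[int, ...]  # global id of bin 0 of each chromosome

    @property
    def n_bins(self) -> int:
        return self.offsets[-1] + self.n_bins_per_chrom[-1]

    @property
    def offsets_array(self) -> np.ndarray:
        return np.asarray(self.offsets, dtype=np.int64)

    def global_id(self, chrom: str, ordinal: int) -> int:
        ci = self.genome.index[chrom]
        if not 0 <= ordinal < self.n_bins_per_chrom[ci]:
            raise IndexError(f"bin ordinal {ordinal} out of range for {chrom}")
        return self.offsets[ci] + ordinal

    def decompose(self, gid: int) -> tuple[str, int]:
        if not 0 <= gid < self.n_bins:
            raise IndexError(f"global bin id {gid} out of range")
        ci = int(np.searchsorted(self.offsets_array, gid, side="right") - 1)
        return self.genome.names[ci], gid - self.offsets[ci]

    def chrom_of_bins(self, gids: np.ndarray) -> np.ndarray:
        """Chromosome index for each global bin id (vectorized)."""
        return np.searchsorted(self.offsets_array, np.asarray(gids), side="right") - 1

    def bin_start(self, gid: int) -> tuple[str, int]:
        """(chrom, 0-based bp start) of a global bin."""
        chrom, ordinal = self.decompose(gid)
        return chrom, ordinal * self.bin_size

    def bins_of_positions(self, chrom_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorized (chrom index, 1-based pos) -> global bin id."""
        return self.offsets_array[chrom_idx] + (np.asarray(pos, dtype=np.int64) - 1) // self.bin_size


@dataclass
class CompartmentTrack:
    """Per-bin reference A/B compartment value in [0, 1] (A-like high).

    ``values`` has one entry per global bin; missing bins are NaN.
    ``truth_labels`` ("A"/"B" per bin) is populated by the synthetic
    generator and absent for real tracks.
    """

    bin_index: BinIndex
    values: np.ndarray  # float, NaN = missing
    truth_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.bin_index.n_bins:
            raise FormatError("track length does not match bin index")
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise FormatError("track values must lie in [0, 1]")

    @property
    def bin_size(self) -> int:
        return self.bin_index.bin_size

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


# ---------------------------------------------------------------------------
# readers / writers


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_chrom_sizes(path, species: str = "unknown") -> Genome:
    """Parse a two-column chromosome-sizes table into a :class:`Genome`.

    The stated chromosome order is preserved; the X chromosome is
    recognized by the names "chrX" or "X".
    """
    names: list[str] = []
    lengths: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name length'")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from e
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for {name}")
            if name in names:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name}")
            names.append(name)
            lengths.append(length)
    if not names:
        raise FormatError(f"{path}: empty chromosome-sizes file")
    x = next((n for n in names if n in ("chrX", "X")), None)
    return Genome(species=species, names=tuple(names), lengths=tuple(lengths), x_name=x)


def load_packaged_genome(species: str) -> Genome:
    """Load the packaged human ("human"/"hg38") or mouse ("mouse"/"mm10")
    chromosome-sizes fixture (chr1..chr22/chr19 + chrX, real assembly sizes)."""
    key = {"human": "hg38", "hg38": "hg38", "mouse": "mm10", "mm10": "mm10"}[species]
    ref = resources.files("cbg3d.data") / f"{key}.chrom.sizes"
    with resources.as_file(ref) as path:
        return read_chrom_sizes(path, species="human" if key == "hg38" else "mouse")


_META_KEYS = ("cell_id", "donor", "age", "age_unit", "sex", "species")


def write_pairs(cells, path) -> list[Path]:
    """Write one pairs file per cell.

    ``cells`` may be a single :class:`ContactSet` with ``path`` a file, or
    a sequence of cells with ``path`` a directory (files named
    ``<cell_id>.pairs``).  Output is deterministic: canonical contact
    order, metadata in a fixed header-key order.
    """
    if isinstance(cells, ContactSet):
        targets = [(cells, Path(path))]
    else:
        cells = list(cells)
        if not cells:
            raise ValueError("no cells to write")
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        targets = [(c, outdir / f"{c.cell_id}.pairs") for c in cells]
    written = []
    for cell, target in targets:
        order = np.lexsort((cell.pos2, cell.chrom2, cell.pos1, cell.chrom1))
        with _open_text(target, "wt") as fh:
            fh.write("## pairs-dialect v1 (cbg3d)\n")
            fh.write("#columns: chrom1 pos1 chrom2 pos2\n")
            for key in _META_KEYS:
                val = getattr(cell, key)
                if val is not None:
                    fh.write(f"#{key}: {val}\n")
            for key in sorted(cell.truth):
                fh.write(f"#truth_{key}: {cell.truth[key]}\n")
            names = cell.genome.names
            c1, p1 = cell.chrom1[order], cell.pos1[order]
            c2, p2 = cell.chrom2[order], cell.pos2[order]
            for i in range(len(cell)):
                fh.write(f"{names[c1[i]]}\t{p1[i]}\t{names[c2[i]]}\t{p2[i]}\n")
        written.append(Path(target))
    return written


def read_pairs(path, genome: Genome) -> ContactSet:
    """Read one cell's pairs file.

    Records on chromosomes absent from ``genome`` or with out-of-range
    positions are skipped (counted in ``n_rejected``, logged); lines that
    do not parse at all raise :class:`FormatError`.
    """
    meta: dict = {}
    truth: dict = {}
    idx = genome.index
    lens = genome.lengths
    c1, p1, c2, p2 = [], [], [], []
    rejected = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key, val = key.strip(), val.strip()
                    if key in _META_KEYS:
                        meta[key] = val
                    elif key.startswith("truth_"):
                        truth[key[len("truth_"):]] = val
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            ca, cb = parts[0], parts[2]
            try:
                pa, pb = int(parts[1]), int(parts[3])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad position") from e
            if ca not in idx or cb not in idx:
                rejected += 1
                continue
            ia, ib = idx[ca], idx[cb]
            if not (1 <= pa <= lens[ia]) or not (1 <= pb <= lens[ib]):
                rejected += 1
                continue
            c1.append(ia)
            p1.append(pa)
            c2.append(ib)
            p2.append(pb)
    if rejected:
        logger.warning("%s: skipped %d unmappable record(s)", path, rejected)
    age = meta.get("age")
    return ContactSet(
        cell_id=meta.get("cell_id", Path(path).stem),
        genome=genome,
        chrom1=np.array(c1, dtype=np.int32),
        pos1=np.array(p1, dtype=np.int64),
        chrom2=np.array(c2, dtype=np.int32),
        pos2=np.array(p2, dtype=np.int64),
        donor=meta.get("donor"),
        age=float(age) if age is not None else None,
        age_unit=meta.get("age_unit", "years"),
        sex=meta.get("sex"),
        species=meta.get("species"),
        truth=truth,
        n_rejected=rejected,
    )


# ---------------------------------------------------------------------------
# binning


def make_bins(genome: Genome, bin_size: int) -> BinIndex:
    """Tile every chromosome with fixed-size bins (last bin may be short)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    counts = [int(-(-l // bin_size)) for l in genome.lengths]  # ceil div
    offsets = list(np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(int))
    return BinIndex(genome, bin_size, tuple(counts), tuple(int(o) for o in offsets))


def assign_bin(pos: int, chrom: str, bin_index: BinIndex) -> int:
    """Global bin id of a 1-based position; ordinal = (pos - 1) // bin_size."""
    ci = bin_index.genome.index[chrom]
    if not 1 <= pos <= bin_index.genome.lengths[ci]:
        raise ValueError(f"position {pos} outside {chrom}")
    return bin_index.offsets[ci] + (pos - 1) // bin_index.bin_size


# ---------------------------------------------------------------------------
# compartment track I/O (tab-separated: chrom, 0-based bin start, value)


def write_track(track: CompartmentTrack, path) -> Path:
    bi = track.bin_index
    rows = []
    for gid in range(bi.n_bins):
        chrom, start = bi.bin_start(gid)
        v = track.values[gid]
        rows.append((chrom, start, "" if np.isnan(v) else repr(float(v))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "value"])
    with _open_text(path, "wt") as fh:
        fh.write(f"# bin_size: {bi.bin_size}\n")
        df.to_csv(fh, sep="\t", index=False)
    return Path(path)


def read_track(path, bin_index: BinIndex) -> CompartmentTrack:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    values = np.full(bin_index.n_bins, np.nan)
    idx = bin_index.genome.index
    for chrom, start, val in zip(df["chrom"], df["start"], df["value"]):
        if chrom not in idx or pd.isna(val):
            continue
        gid = bin_index.offsets[idx[chrom]] + int(start) // bin_index.bin_size
        values[gid] = float(val)
    return CompartmentTrack(bin_index, values)
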