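"""Histone catalog I/O, curation filters, and reference-based residue numbering.

Archaeal histones are short (~69 aa) single-fold proteins. A catalog is the
set of candidate histone sequences for an analysis; curation applies a length
window, removes sequence-identical redundancy, and — on the aligned catalog —
drops gap-rich columns. Residues are numbered by positional orthology to a
designated reference row (HMfB numbering, 1..69; core histone fold 2..65),
so that "position 49" means the same structural site in every sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = STANDARD_AA | {"X"}

DEFAULT_MIN_LEN = 60
DEFAULT_MAX_LEN = 80
DEFAULT_MAX_GAP_FRAC = 0.05
CORE_FOLD_RANGE = (2, 65)


class CatalogError(ValueError):
    """Raised for malformed catalogs, alignments, or FASTA input."""


@dataclass(frozen=True)
class HistoneRecord:
    """One histone protein sequence with species and paralog identity."""

    id: str
    species_id: str
    sequence: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise CatalogError("record id must be non-empty")
        if not self.sequence:
            raise CatalogError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise CatalogError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}; "
                "expected uppercase one-letter amino acids or X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HistoneCatalog:
    """An ordered collection of histone records with unique ids."""

    records: tuple[HistoneRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise CatalogError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> HistoneRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def paralog_counts(self) -> dict[str, int]:
        """Number of histone records per species."""
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.species_id] = counts.get(rec.species_id, 0) + 1
        return counts

    def species_groups(self) -> dict[str, str]:
        """Label each species 'single' or 'multi' by paralog count."""
        return {
            sp: ("multi" if n > 1 else "single")
            for sp, n in self.paralog_counts().items()
        }


@dataclass(frozen=True)
class RemovalRecord:
    """Why a record was dropped during curation."""

    id: str
    reason: str


def _parse_header(header: str) -> tuple[str, str]:
    # Convention: "id|species_id"; fallback: whole header is both id and species.
    if "|" in header:
        rec_id, species = header.split("|", 1)
        return rec_id.strip(), species.strip()
    return header, header


def _precheck_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise CatalogError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                return


def read_fasta(path: str | Path) -> HistoneCatalog:
    """Read an (ungapped) histone FASTA into a catalog.

    Headers follow ``id|species_id``; a header without ``|`` is used as both
    id and species. Sequences are uppercased. Order is preserved.
    """
    path = Path(path)
    _precheck_fasta(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id, species = _parse_header(entry.description)
        seq = str(entry.seq).upper().replace(".", GAP)
        if GAP in seq:
            raise CatalogError(
                f"{path}: record {rec_id!r} contains gap characters; "
                "use read_alignment for aligned FASTA"
            )
        records.append(HistoneRecord(rec_id, species, seq, source_tag=str(path)))
    if not records:
        logger.warning("%s: empty FASTA, returning empty catalog", path)
    return HistoneCatalog(tuple(records))


def write_fasta(catalog: HistoneCatalog, path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(rec.sequence), id=f"{rec.id}|{rec.species_id}", description="")
        for rec in catalog
    ]
    SeqIO.write(entries, str(path), "fasta")


def filter_by_length(
    catalog: HistoneCatalog,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[HistoneCatalog, list[RemovalRecord]]:
    """Keep records with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise CatalogError(f"min_len {min_len} > max_len {max_len}")
    kept, removed = [], []
    for rec in catalog:
        n = len(rec)
        if n < min_len:
            removed.append(RemovalRecord(rec.id, f"too_short:{n}<{min_len}"))
        elif n > max_len:
            removed.append(RemovalRecord(rec.id, f"too_long:{n}>{max_len}"))
        else:
            kept.append(rec)
    return HistoneCatalog(tuple(kept)), removed


def dedupe_identical(
    catalog: HistoneCatalog, seed: int
) -> tuple[HistoneCatalog, list[RemovalRecord]]:
    """Remove sequence-identical redundancy, keeping one random survivor.

    Within each class of identical sequences exactly one record survives,
    chosen by a seeded uniform draw; deterministic given the seed and
    independent of input record order.
    """
    classes: dict[str, list[str]] = {}
    for rec in catalog:
        classes.setdefault(rec.sequence, []).append(rec.id)
    rng = np.random.default_rng(seed)
    survivors: set[str] = set()
    # iterate classes in a canonical order so the draw ignores input order
    for seq in sorted(classes):
        members = sorted(classes[seq])
        survivors.add(members[int(rng.integers(len(members)))])
    kept, removed = [], []
    for rec in catalog:
        if rec.id in survivors:
            kept.append(rec)
        else:
            removed.append(RemovalRecord(rec.id, "duplicate_sequence"))
    return HistoneCatalog(tuple(kept)), removed


@dataclass(frozen=True)
class AlignedCatalog:
    """A fixed-width alignment of catalog rows plus a kept-column mask.

    ``column_kept_mask`` records which columns survive gap filtering; the
    matrix itself is never rewritten, so original column indices stay valid.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    species_of: Mapping[str, str]
    column_kept_mask: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise CatalogError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise CatalogError("duplicate row ids in alignment")
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise CatalogError("alignment rows have unequal lengths")
            if self.column_kept_mask.shape != (width,):
                raise CatalogError("column_kept_mask length != alignment width")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rec_id: str) -> str:
        try:
            return self.rows[self.ids.index(rec_id)]
        except ValueError:
            raise KeyError(rec_id) from None

    def kept_columns(self) -> np.ndarray:
        return np.flatnonzero(self.column_kept_mask)

    def gap_fractions(self) -> np.ndarray:
        """Per-column fraction of rows carrying a gap (over all columns)."""
        mat = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(self.n_rows, self.n_cols)
        return (mat == GAP.encode()).mean(axis=0)

    def degapped(self, rec_id: str) -> str:
        return self.row(rec_id).replace(GAP, "")


def read_alignment(path: str | Path) -> AlignedCatalog:
    """Read an aligned FASTA ('.' normalized to '-'); all columns start kept."""
    path = Path(path)
    _precheck_fasta(path)
    ids, rows, species = [], [], {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id, sp = _parse_header(entry.description)
        if rec_id in species:
            raise CatalogError(f"{path}: duplicate id {rec_id!r}")
        ids.append(rec_id)
        species[rec_id] = sp
        rows.append(str(entry.seq).upper().replace(".", GAP))
    if not rows:
        raise CatalogError(f"{path}: empty alignment")
    mask = np.ones(len(rows[0]), dtype=bool)
    return AlignedCatalog(tuple(ids), tuple(rows), species, mask)


def write_alignment(aligned: AlignedCatalog, path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(row), id=f"{rid}|{aligned.species_of.get(rid, rid)}",
                  description="")
        for rid, row in zip(aligned.ids, aligned.rows)
    ]
    SeqIO.write(entries, str(path), "fasta")


def remove_gappy_columns(
    aligned: AlignedCatalog, max_gap_frac: float = DEFAULT_MAX_GAP_FRAC
) -> AlignedCatalog:
    """Mask out columns whose gap fraction strictly exceeds ``max_gap_frac``.

    The 5% rule is strict: a column with exactly 5% gaps is kept. Idempotent;
    the mask is ANDed with any previous mask so original indices remain
    recoverable.
    """
    if aligned.n_rows == 0:
        raise CatalogError("empty alignment")
    frac = aligned.gap_fractions()
    new_mask = aligned.column_kept_mask & (frac <= max_gap_frac)
    return replace(aligned, column_kept_mask=new_mask)


@dataclass(frozen=True)
class PositionMap:
    """Bijection between alignment columns and reference residue numbers.

    The k-th ungapped residue of the reference row gets number k (1-based);
    columns where the reference has a gap are unmapped. The default core-fold
    interval is residues 2..65 in HMfB numbering.
    """

    reference_id: str
    column_to_position: Mapping[int, int]
    core_fold_range: tuple[int, int] = CORE_FOLD_RANGE

    def __post_init__(self) -> None:
        cols = sorted(self.column_to_position)
        positions = [self.column_to_position[c] for c in cols]
        if positions != sorted(set(positions)):
            raise CatalogError("position map must be injective and increasing")

    @property
    def position_to_column(self) -> dict[int, int]:
        return {p: c for c, p in self.column_to_position.items()}

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.position_to_column))

    def column_of(self, position: int) -> int:
        try:
            return self.position_to_column[position]
        except KeyError:
            raise CatalogError(
                f"position {position} is not mapped to any alignment column"
            ) from None

    def residue_at(self, row: str, position: int) -> str:
        """Residue (or gap) of an aligned row at a reference position."""
        return row[self.column_of(position)]


def build_position_map(
    aligned: AlignedCatalog,
    reference_id: str,
    core_fold_range: tuple[int, int] = CORE_FOLD_RANGE,
) -> PositionMap:
    """Number columns by positional orthology to the reference row."""
    ref = aligned.row(reference_id)  # raises KeyError if absent
    mapping: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(ref):
        if ch != GAP:
            k += 1
            mapping[col] = k
    return PositionMap(reference_id, mapping, core_fold_range)


def core_fold_complete(row: str, posmap: PositionMap) -> bool:
    """True iff the row has no gap at any mapped core-fold position."""
    lo, hi = posmap.core_fold_range
    p2c = posmap.position_to_column
    for pos in range(lo, hi + 1):
        col = p2c.get(pos)
        if col is not None and row[col] == GAP:
            return False
    return True


def write_removal_log(removed: Iterable[RemovalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for rec in removed:
            fh.write(f"{rec.id}\t{rec.reason}\n")


def write_position_map(posmap: PositionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tposition\n")
        for col in sorted(posmap.column_to_position):
            fh.write(f"{col}\t{posmap.column_to_position[col]}\n")
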