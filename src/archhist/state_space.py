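"""Tetramer state space: enumeration, symmetry reduction, classification.

An archaeal histone tetramer is an ordered 4-tuple of monomers partitioned
into two dimers, (m1,m2)+(m3,m4), joined at a single dimer:dimer interface.
A species with n paralogs has n^4 ordered combinations; because complex
energies are invariant to swapping partners within a dimer and to swapping
the two dimers, the ordered tuples fall into symmetry classes whose
multiplicities sum to n^4.

Capstone detection is a sequence-level classifier on residue 49 (HMfB
numbering): a negatively charged or hydrophobic residue at the dimer:dimer
interface marks a paralog predicted to block tetramer extension, whereas the
ancestral state is a positively charged histidine.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GAP, PositionMap

if TYPE_CHECKING:  # pragma: no cover
    from .energetics import ComplexEnergy, EnergyBackend

MIXED = "MIXED"
CAPSTONE_POSITION = 49
NEGATIVE_RESIDUES = frozenset({"D", "E"})
DEFAULT_HYDROPHOBIC = frozenset({"A", "I", "L", "M", "F", "V", "W"})


class StateSpaceError(ValueError):
    pass


@dataclass(frozen=True)
class TetramerComplex:
    """Ordered 4-tuple of monomer ids; dimers are (m1,m2) and (m3,m4)."""

    monomers: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.monomers) != 4:
            raise StateSpaceError("a tetramer has exactly 4 monomers")

    @property
    def dimers(self) -> tuple[tuple[str, str], tuple[str, str]]:
        m = self.monomers
        return (m[0], m[1]), (m[2], m[3])

    @property
    def key(self) -> str:
        return "+".join(self.monomers)

    @property
    def composition(self) -> Counter:
        return Counter(self.monomers)

    @classmethod
    def from_key(cls, key: str) -> "TetramerComplex":
        parts = tuple(key.split("+"))
        if len(parts) != 4:
            raise StateSpaceError(f"bad complex key {key!r}")
        return cls(parts)  # type: ignore[arg-type]


def canonical_form(monomers: Sequence[str]) -> tuple[str, str, str, str]:
    """Canonical representative under within-dimer and dimer-pair swaps."""
    d1 = tuple(sorted(monomers[:2]))
    d2 = tuple(sorted(monomers[2:]))
    return tuple(sorted([d1, d2])[0] + sorted([d1, d2])[1])  # type: ignore[return-value]


@dataclass(frozen=True)
class CanonicalClass:
    representative: TetramerComplex
    multiplicity: int


def enumerate_tetramers(
    paralog_ids: Sequence[str], mode: str = "ORDERED"
) -> list[TetramerComplex] | list[CanonicalClass]:
    """All tetramer combinations of the given paralogs.

    ORDERED: all n^4 ordered tuples in lexicographic order of monomer index —
    the counting convention of the full combinatorial state space (7 paralogs
    give 2,401 complexes). CANONICAL: one representative per symmetry class
    (within-dimer swap, dimer-pair swap) with its class multiplicity;
    multiplicities sum to n^4.
    """
    ids = list(paralog_ids)
    if len(set(ids)) != len(ids):
        raise StateSpaceError("paralog ids must be distinct")
    if not ids:
        raise StateSpaceError("need at least one paralog")
    ordered = [TetramerComplex(t) for t in itertools.product(ids, repeat=4)]
    if mode == "ORDERED":
        return ordered
    if mode == "CANONICAL":
        classes: dict[tuple[str, str, str, str], int] = {}
        for t in ordered:
            classes[canonical_form(t.monomers)] = (
                classes.get(canonical_form(t.monomers), 0) + 1
            )
        return [
            CanonicalClass(TetramerComplex(rep), mult)
            for rep, mult in sorted(classes.items())
        ]
    raise StateSpaceError(f"unknown enumeration mode {mode!r}")


@dataclass(frozen=True)
class DominanceCall:
    dominant: str  # paralog id or MIXED
    homo: bool


def classify_dominant(complex_: TetramerComplex) -> DominanceCall:
    """Dominant paralog = id occurring >= 3 of 4 times; else MIXED.

    Homotetramers (4 of 4) carry an additional flag so they can be grouped
    separately from 3-of-4 complexes.
    """
    (pid, count), = complex_.composition.most_common(1) or [(MIXED, 0)]
    if count >= 3:
        return DominanceCall(pid, homo=(count == 4))
    return DominanceCall(MIXED, homo=False)


@dataclass(frozen=True)
class CapstoneCall:
    monomer_id: str
    residue49: str  # one-letter code or "GAP"
    clazz: str  # CAPSTONE | STANDARD | UNKNOWN
    basis: str  # NEGATIVE | HYDROPHOBIC | NONE


def capstone_call(
    monomer_id: str,
    row: str,
    posmap: PositionMap,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
) -> CapstoneCall:
    """Classify a monomer by the chemistry of its residue-49 site.

    Negatively charged (D/E) or hydrophobic residues at the dimer:dimer
    interface mark capstones; a gap or X is UNKNOWN; anything else (including
    the ancestral histidine) is STANDARD.
    """
    residue = posmap.residue_at(row, CAPSTONE_POSITION)
    if residue == GAP or residue == "X":
        return CapstoneCall(monomer_id, "GAP" if residue == GAP else "X",
                            "UNKNOWN", "NONE")
    if residue in NEGATIVE_RESIDUES:
        return CapstoneCall(monomer_id, residue, "CAPSTONE", "NEGATIVE")
    if residue in hydrophobic_set:
        return CapstoneCall(monomer_id, residue, "CAPSTONE", "HYDROPHOBIC")
    return CapstoneCall(monomer_id, residue, "STANDARD", "NONE")


def summarize_state_space(
    complexes: Iterable[TetramerComplex],
    energies: Mapping[str, "ComplexEnergy"],
) -> pd.DataFrame:
    """Energy-range statistics per dominant-paralog grouping.

    One row per dominant label (paralog id or MIXED) plus per-paralog
    homotetramer rows, with min/max/mean of ddG_bind and ddG_tet and range
    widths. Raises if any complex lacks an energy.
    """
    rows = []
    for cx in complexes:
        if cx.key not in energies:
            raise StateSpaceError(f"missing energy for complex {cx.key!r}")
        e = energies[cx.key]
        call = classify_dominant(cx)
        rows.append((cx.key, call.dominant, call.homo, e.ddg_bind, e.ddg_tet))
    df = pd.DataFrame(
        rows, columns=["complex_key", "dominant", "homo", "ddg_bind", "ddg_tet"]
    )
    if df.empty:
        raise StateSpaceError("no complexes to summarize")

    def _agg(sub: pd.DataFrame, label: str, homo: bool) -> dict:
        return dict(
            group=label,
            homotetramer=homo,
            n=len(sub),
            bind_min=sub.ddg_bind.min(), bind_max=sub.ddg_bind.max(),
            bind_mean=sub.ddg_bind.mean(),
            bind_range=sub.ddg_bind.max() - sub.ddg_bind.min(),
            tet_min=sub.ddg_tet.min(), tet_max=sub.ddg_tet.max(),
            tet_mean=sub.ddg_tet.mean(),
            tet_range=sub.ddg_tet.max() - sub.ddg_tet.min(),
        )

    out = [_agg(df, "ALL", False)]
    for label, sub in df.groupby("dominant", sort=True):
        out.append(_agg(sub, str(label), False))
    for label, sub in df[df.homo].groupby("dominant", sort=True):
        out.append(_agg(sub, f"{label}:homotetramer", True))
    return pd.DataFrame(out)


def complex_table(
    complexes: Iterable[TetramerComplex],
    energies: Mapping[str, "ComplexEnergy"],
) -> pd.DataFrame:
    """Flat per-complex table: key, dominant, homo flag, energies."""
    rows = []
    for cx in complexes:
        call = classify_dominant(cx)
        e = energies[cx.key]
        rows.append((cx.key, call.dominant, call.homo, e.ddg_bind, e.ddg_tet))
    return pd.DataFrame(
        rows, columns=["complex_key", "dominant", "homo", "ddg_bind", "ddg_tet"]
    )


def dosage_series(
    paralog_a: str,
    paralog_b: str,
    backend: "EnergyBackend",
) -> pd.DataFrame:
    """Energy coordinates as a function of paralog-b dosage k = 0..4.

    For each k, statistics are taken over all ordered complexes with
    composition {(4-k) a, k b}; under additive energies the mean is exactly
    linear in k and the endpoints are the two homotetramers.
    """
    rows = []
    for k in range(5):
        pattern = [paralog_a] * (4 - k) + [paralog_b] * k
        binds, tets = [], []
        for perm in set(itertools.permutations(pattern)):
            e = backend.energy(TetramerComplex(perm))
            binds.append(e.ddg_bind)
            tets.append(e.ddg_tet)
        binds, tets = np.array(binds), np.array(tets)
        rows.append(
            dict(dosage_b=k, n_complexes=len(binds),
                 bind_mean=binds.mean(), bind_sd=binds.std(),
                 tet_mean=tets.mean(), tet_sd=tets.std())
        )
    return pd.DataFrame(rows)
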