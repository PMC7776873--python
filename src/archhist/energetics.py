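"""Free-energy bookkeeping for tetrameric histone-DNA complexes.

Implements the thermodynamic identities used throughout the analysis —
relative stability ddG = dG_mutant - dG_wildtype (positive = destabilized),
DNA binding dG_bind = dG_complex - dG_DNA - dG_histone, and tetramerization
dG_tet = dG_tetramer - dG_dimer1 - dG_dimer2 — together with pluggable
backends that assign each tetramer a (ddG_bind, ddG_tet) coordinate relative
to a named reference complex.

Two backend families exist:

* Table backends ingest externally computed energies (e.g. exported from
  structure-based mutational scanning runs), either keyed per complex or as
  additive per-monomer terms. Values pass through untouched, in the file's
  units. This is the only route to quantitatively meaningful energies.
* A built-in coarse-grained charge surrogate scores the cross-dimer interface
  and DNA-contacting loop residues from sequence alone. It reproduces
  orderings (capstone-driven interface destabilization, charge-driven DNA
  binding), never absolute energies, and exists so every downstream stage is
  testable without external structure calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import pandas as pd

from .catalog import GAP, PositionMap
from .state_space import TetramerComplex


class EnergyError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyTerms:
    """Raw free-energy components of one complex (any consistent unit).

    Enthalpic/entropic and gas/solvation splits are carried as optional
    metadata only; the bookkeeping here never decomposes them.
    """

    dG_complex: float = 0.0
    dG_DNA: float = 0.0
    dG_histone: float = 0.0
    dG_tetramer: float = 0.0
    dG_dimer1: float = 0.0
    dG_dimer2: float = 0.0
    dH: float | None = None
    TdS: float | None = None
    E_gas: float | None = None
    E_solv: float | None = None


@dataclass(frozen=True)
class ComplexEnergy:
    """(ddG_bind, ddG_tet) of a complex relative to a reference complex."""

    ddg_bind: float
    ddg_tet: float
    reference_id: str
    backend_tag: str = ""


def relative_ddg(dG_mutant: float, dG_wildtype: float) -> float:
    """ddG = dG_mutant - dG_wildtype; positive means destabilized."""
    return dG_mutant - dG_wildtype


def binding_energy(dG_complex: float, dG_DNA: float, dG_histone: float) -> float:
    """dG_bind = dG_complex - dG_DNA - dG_histone."""
    return dG_complex - dG_DNA - dG_histone


def tetramerization_energy(
    dG_tetramer: float, dG_dimer1: float, dG_dimer2: float
) -> float:
    """dG_tet = dG_tetramer - dG_dimer1 - dG_dimer2."""
    return dG_tetramer - dG_dimer1 - dG_dimer2


#: unit charges per residue at neutral pH; His partially protonated so that
#: H/H and E/E interface pairs score differently
DEFAULT_CHARGES: Mapping[str, float] = {
    "D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0, "H": +0.5,
}

#: positions critical for stable tetramerization (dimer:dimer interface)
DEFAULT_TET_POSITIONS = frozenset({46, 49, 59, 62})
#: loop positions making large contributions to DNA binding
DEFAULT_DNA_POSITIONS = frozenset({10, 19, 53, 54})


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the coarse-grained charge surrogate."""

    charge_of: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHARGES)
    )
    tet_positions: frozenset[int] = DEFAULT_TET_POSITIONS
    dna_positions: frozenset[int] = DEFAULT_DNA_POSITIONS
    kappa_tet: float = 1.0
    kappa_dna: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa_tet <= 0 or self.kappa_dna <= 0:
            raise EnergyError("kappa parameters must be positive")
        for pos in self.tet_positions | self.dna_positions:
            if not 2 <= pos <= 65:
                raise EnergyError(f"surrogate position {pos} outside core fold 2..65")

    def charge(self, residue: str) -> float:
        if residue == GAP:
            return 0.0
        return float(self.charge_of.get(residue, 0.0))


def surrogate_raw_terms(
    complex_: TetramerComplex,
    rows: Mapping[str, str],
    posmap: PositionMap,
    params: SurrogateParams | None = None,
) -> tuple[float, float]:
    """Raw (dG_bind_raw, dG_tet_raw) of a tetramer under the charge surrogate.

    The tetramer has a single dimer:dimer interface carried by the two inner
    monomers (monomer 2 of dimer 1 and monomer 3 of dimer 2):

        dG_tet_raw  = kappa_tet * sum_{p in tet_positions} q(inner1,p)*q(inner2,p)
        dG_bind_raw = -kappa_dna * sum_{monomers m} sum_{p in dna_positions} q(m,p)

    Positive dG_tet_raw means a repulsive interface; positively charged loop
    residues strengthen (lower) DNA binding. Gaps contribute zero charge.
    """
    params = params or SurrogateParams()
    try:
        seqs = [rows[m] for m in complex_.monomers]
    except KeyError as exc:
        raise EnergyError(f"unknown monomer id {exc.args[0]!r}") from None
    inner1, inner2 = seqs[1], seqs[2]
    tet = sum(
        params.charge(posmap.residue_at(inner1, p))
        * params.charge(posmap.residue_at(inner2, p))
        for p in sorted(params.tet_positions)
    )
    bind = -sum(
        params.charge(posmap.residue_at(seq, p))
        for seq in seqs
        for p in sorted(params.dna_positions)
    )
    return params.kappa_dna * bind, params.kappa_tet * tet


class EnergyBackend(Protocol):
    """Anything that maps a tetramer to a ComplexEnergy."""

    reference_id: str
    backend_tag: str

    def energy(self, complex_: TetramerComplex) -> ComplexEnergy: ...


class SurrogateBackend:
    """Charge-surrogate backend; ddG values relative to a reference complex."""

    backend_tag = "surrogate"

    def __init__(
        self,
        rows: Mapping[str, str],
        posmap: PositionMap,
        reference: TetramerComplex,
        params: SurrogateParams | None = None,
    ) -> None:
        self.rows = rows
        self.posmap = posmap
        self.params = params or SurrogateParams()
        self.reference = reference
        self.reference_id = reference.key
        self._ref_bind, self._ref_tet = surrogate_raw_terms(
            reference, rows, posmap, self.params
        )

    def energy(self, complex_: TetramerComplex) -> ComplexEnergy:
        bind, tet = surrogate_raw_terms(
            complex_, self.rows, self.posmap, self.params
        )
        return ComplexEnergy(
            ddg_bind=relative_ddg(bind, self._ref_bind),
            ddg_tet=relative_ddg(tet, self._ref_tet),
            reference_id=self.reference_id,
            backend_tag=self.backend_tag,
        )


class TableBackend:
    """Exact-key lookup of precomputed (ddG_bind, ddG_tet) per complex."""

    backend_tag = "table"

    def __init__(self, table: Mapping[str, tuple[float, float]],
                 reference_id: str = "") -> None:
        self._table = dict(table)
        self.reference_id = reference_id

    def energy(self, complex_: TetramerComplex) -> ComplexEnergy:
        try:
            bind, tet = self._table[complex_.key]
        except KeyError:
            raise EnergyError(
                f"no energy entry for complex {complex_.key!r}"
            ) from None
        return ComplexEnergy(bind, tet, self.reference_id, self.backend_tag)


class AdditiveTableBackend:
    """Per-monomer additive terms; complex energy is the sum over monomers."""

    backend_tag = "additive"

    def __init__(self, terms: Mapping[str, tuple[float, float]],
                 reference_id: str = "") -> None:
        self._terms = dict(terms)
        self.reference_id = reference_id

    @property
    def monomer_ids(self) -> tuple[str, ...]:
        return tuple(self._terms)

    def monomer_terms(self, monomer_id: str) -> tuple[float, float]:
        try:
            return self._terms[monomer_id]
        except KeyError:
            raise EnergyError(f"unknown monomer id {monomer_id!r}") from None

    def energy(self, complex_: TetramerComplex) -> ComplexEnergy:
        bind = tet = 0.0
        for m in complex_.monomers:
            b, t = self.monomer_terms(m)
            bind += b
            tet += t
        return ComplexEnergy(bind, tet, self.reference_id, self.backend_tag)


def load_energy_table(path: str | Path, reference_id: str = "") -> EnergyBackend:
    """Load a TSV energy table, auto-detecting its dialect from the header.

    "complex" dialect: columns complex_key (four '+'-joined monomer ids),
    ddG_bind, ddG_tet — exact-key lookup. "additive" dialect: columns
    monomer_id, bind_term, tet_term — complex energies are per-monomer sums.
    Values are carried through unconverted, in the file's stated unit.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = set(df.columns)
    if {"complex_key", "ddG_bind", "ddG_tet"} <= cols:
        keys = df["complex_key"]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise EnergyError(f"{path}: duplicate complex_key {dup!r}")
        table = {
            str(k): (float(b), float(t))
            for k, b, t in zip(keys, df["ddG_bind"], df["ddG_tet"])
        }
        return TableBackend(table, reference_id)
    if {"monomer_id", "bind_term", "tet_term"} <= cols:
        ids = df["monomer_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise EnergyError(f"{path}: duplicate monomer_id {dup!r}")
        terms = {
            str(m): (float(b), float(t))
            for m, b, t in zip(ids, df["bind_term"], df["tet_term"])
        }
        return AdditiveTableBackend(terms, reference_id)
    raise EnergyError(
        f"{path}: unrecognized energy-table header {sorted(cols)!r}; expected "
        "complex dialect (complex_key, ddG_bind, ddG_tet) or additive dialect "
        "(monomer_id, bind_term, tet_term)"
    )


def write_additive_table(
    terms: Mapping[str, tuple[float, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("monomer_id\tbind_term\ttet_term\n")
        for m, (b, t) in terms.items():
            fh.write(f"{m}\t{b!r}\t{t!r}\n")


def homotetramer_stability(
    backend: EnergyBackend, paralog_ids: Sequence[str]
) -> dict[str, float]:
    """ddG_tet of each paralog's homotetramer (stability ranking input)."""
    out = {}
    for pid in paralog_ids:
        homo = TetramerComplex((pid, pid, pid, pid))
        out[pid] = backend.energy(homo).ddg_tet
    return out
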