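"""Synthetic histone catalogs, abundance tables, and energy tables.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised and scored without external data:

* a 69-residue scaffold ("HMfB-like") with species carrying 1..7 paralogs;
* group-structured per-column diversity — designated "hot" positions mutate
  at a multiplied rate, but only in multi-paralog species, planting an
  elevated multi/single diversity ratio at those sites;
* residues 19 and 49 held invariant (R and H) in single-histone species,
  mirroring their conservation in single-histone archaea;
* planted capstones: a fraction of multi-paralog species get one paralog
  with glutamate at position 49;
* LFQ-like abundance tables over two growth conditions spanning a
  configurable fold range, with a planted Spearman rank correlation between
  paralog abundance and homotetramer stability, and a condition shift that
  up-weights the least stable paralogs;
* additive per-monomer energy tables in which capstone paralogs carry a
  large positive tetramerization penalty.

All outputs are deterministic functions of (spec, seed). A truth record
accompanies each artifact so recovery tests can be scored without
re-deriving ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (
    AlignedCatalog,
    HistoneCatalog,
    HistoneRecord,
    PositionMap,
    build_position_map,
)
from .diversity import GroupLabeling, spearman_exact

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
REFERENCE_ID = "HMF_REF"
REFERENCE_SPECIES = "reference"


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    Defaults mirror the curated-study regime: 143 single-histone and 139
    multi-histone species, 2-7 paralogs per multi species, a 69-residue
    scaffold, hot positions {10,19,49,53,54} diversified at 10x the
    background rate in multi species only, a 27-fold abundance range, and a
    planted abundance-stability Spearman correlation of -0.8.
    """

    seed: int = 0
    n_single_species: int = 143
    n_multi_species: int = 139
    paralogs_per_multi: int | tuple[int, int] = (2, 7)
    scaffold_length: int = 69
    background_mutation_rate: float = 0.08
    hot_positions: tuple[int, ...] = (10, 19, 49, 53, 54)
    hot_rate_multiplier: float = 10.0
    capstone_fraction: float = 0.3
    abundance_fold_range: float = 27.0
    planted_rho: float = -0.8
    conditions: tuple[str, str] = ("exponential", "stationary")
    n_replicates: int = 3
    replicate_cv: float = 0.2
    shift_n_up: int = 2
    shift_upweight_factor: float = 4.0
    energy_sigma_bind: float = 2.0
    energy_sigma_tet: float = 2.0
    capstone_tet_penalty: float = 5.0

    def __post_init__(self) -> None:
        if self.n_single_species + self.n_multi_species < 1:
            raise SyntheticError("need at least one species")
        if not 0.0 <= self.background_mutation_rate <= 1.0:
            raise SyntheticError("background_mutation_rate must be in [0,1]")
        if not 0.0 <= self.capstone_fraction <= 1.0:
            raise SyntheticError("capstone_fraction must be in [0,1]")
        if self.abundance_fold_range < 1.0:
            raise SyntheticError("abundance_fold_range must be >= 1")
        if abs(self.planted_rho) > 1.0:
            raise SyntheticError("|planted_rho| must be <= 1")
        for p in self.hot_positions:
            if not 1 <= p <= self.scaffold_length:
                raise SyntheticError(f"hot position {p} outside scaffold")

    def paralog_range(self) -> tuple[int, int]:
        if isinstance(self.paralogs_per_multi, int):
            k = self.paralogs_per_multi
            return k, k
        lo, hi = self.paralogs_per_multi
        return lo, hi


@dataclass(frozen=True)
class SyntheticCatalog:
    catalog: HistoneCatalog
    aligned: AlignedCatalog
    posmap: PositionMap
    labeling: GroupLabeling
    truth: dict


def _mutate(
    scaffold: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute positions with Bernoulli(rate), uniformly among the 19
    non-scaffold residues."""
    seq = scaffold.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rates)
    for j in hit:
        offset = 1 + int(rng.integers(len(AMINO_ACIDS) - 1))
        seq[j] = (seq[j] + offset) % len(AMINO_ACIDS)
    return seq


def gen_catalog(spec: SyntheticSpec) -> SyntheticCatalog:
    """Generate a catalog + trivial alignment with planted diversity structure.

    The alignment has no indels, so the position map is the identity on the
    reference scaffold row (which is included in the alignment under the id
    ``HMF_REF`` and left out of the group labeling).
    """
    rng = np.random.default_rng([spec.seed, 0])
    L = spec.scaffold_length
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    scaffold = rng.integers(len(AMINO_ACIDS), size=L)
    # paper-consistent anchors: R19 / H49 are the conserved states
    if L >= 19:
        scaffold[18] = aa_index["R"]
    if L >= 49:
        scaffold[48] = aa_index["H"]

    hot = np.zeros(L, dtype=bool)
    for p in spec.hot_positions:
        hot[p - 1] = True
    base = spec.background_mutation_rate
    rate_single = np.full(L, base)
    if L >= 19:
        rate_single[18] = 0.0  # invariant R in single-histone species
    if L >= 49:
        rate_single[48] = 0.0  # invariant H in single-histone species
    rate_multi = np.full(L, base)
    rate_multi[hot] = np.minimum(1.0, base * spec.hot_rate_multiplier)

    records: list[HistoneRecord] = []
    group_of: dict[str, str] = {}

    def _to_str(idx: np.ndarray) -> str:
        return "".join(AMINO_ACIDS[i] for i in idx)

    for i in range(spec.n_single_species):
        sp = f"sing{i:03d}"
        rid = f"{sp}_h1"
        seq = _mutate(scaffold, rate_single, rng)
        records.append(HistoneRecord(rid, sp, _to_str(seq), "synthetic"))
        group_of[rid] = "single"

    lo, hi = spec.paralog_range()
    multi_ids_by_species: list[list[str]] = []
    for i in range(spec.n_multi_species):
        sp = f"mult{i:03d}"
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        ids = []
        for j in range(k):
            rid = f"{sp}_h{j + 1}"
            seq = _mutate(scaffold, rate_multi, rng)
            records.append(HistoneRecord(rid, sp, _to_str(seq), "synthetic"))
            group_of[rid] = "multi"
            ids.append(rid)
        multi_ids_by_species.append(ids)

    # plant capstones: one E49 paralog in a fixed fraction of multi species
    capstone_ids: list[str] = []
    n_cap = int(round(spec.capstone_fraction * spec.n_multi_species))
    if n_cap > 0 and spec.n_multi_species > 0 and L >= 49:
        chosen = rng.choice(spec.n_multi_species, size=n_cap, replace=False)
        rec_by_id = {r.id: r for r in records}
        for si in sorted(int(s) for s in chosen):
            ids = multi_ids_by_species[si]
            rid = ids[int(rng.integers(len(ids)))]
            rec = rec_by_id[rid]
            seq = rec.sequence[:48] + "E" + rec.sequence[49:]
            rec_by_id[rid] = HistoneRecord(rid, rec.species_id, seq, rec.source_tag)
            capstone_ids.append(rid)
        records = [rec_by_id[r.id] for r in records]

    reference = HistoneRecord(
        REFERENCE_ID, REFERENCE_SPECIES, _to_str(scaffold), "synthetic-scaffold"
    )
    all_records = (reference, *records)
    catalog = HistoneCatalog(all_records)
    aligned = AlignedCatalog(
        ids=tuple(r.id for r in all_records),
        rows=tuple(r.sequence for r in all_records),
        species_of={r.id: r.species_id for r in all_records},
        column_kept_mask=np.ones(L, dtype=bool),
    )
    posmap = build_position_map(aligned, REFERENCE_ID)
    truth = dict(
        scaffold=reference.sequence,
        hot_positions=list(spec.hot_positions),
        capstone_ids=capstone_ids,
        reference_id=REFERENCE_ID,
        group_of=dict(group_of),
    )
    return SyntheticCatalog(catalog, aligned, posmap, GroupLabeling(group_of), truth)


def gen_abundance(
    spec: SyntheticSpec,
    stability: Mapping[str, float],
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """LFQ-like abundance table with a planted abundance-stability correlation.

    ``stability`` maps paralog id to homotetramer ddG_tet (higher = less
    stable). Condition-1 mean intensities are placed on a geometric ladder
    spanning ``abundance_fold_range`` and rank-coupled to stability through a
    Gaussian copula so the expected Spearman correlation is ``planted_rho``.
    Condition 2 additionally up-weights the ``shift_n_up`` least stable
    paralogs by ``shift_upweight_factor``. Replicates carry lognormal jitter
    rescaled so each (paralog, condition) arithmetic mean equals its designed
    intensity exactly.
    """
    ids = list(stability)
    n = len(ids)
    if n < 3:
        raise SyntheticError("correlation planting needs at least 3 paralogs")
    rng = np.random.default_rng([spec.seed if seed is None else seed, 1])
    stab = np.array([stability[i] for i in ids], dtype=float)

    # Gaussian-copula coupling: Spearman rho_s ~ (6/pi) asin(rho_p/2)
    rho_p = 2.0 * math.sin(math.pi * spec.planted_rho / 6.0)
    u = stats.norm.ppf((stats.rankdata(stab) - 0.375) / (n + 0.25))
    if abs(spec.planted_rho) >= 1.0:
        y = math.copysign(1.0, spec.planted_rho) * u
    else:
        y = rho_p * u + math.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    ranks_y = stats.rankdata(y, method="ordinal")

    base = 1e6
    designed = base * spec.abundance_fold_range ** ((ranks_y - 1) / max(n - 1, 1))
    cond_a, cond_b = spec.conditions
    up_idx = np.argsort(stab)[-spec.shift_n_up:] if spec.shift_n_up > 0 else []
    designed_b = designed.copy()
    designed_b[list(up_idx)] *= spec.shift_upweight_factor

    rows = []
    for cond, intens in ((cond_a, designed), (cond_b, designed_b)):
        for pid, val in zip(ids, intens):
            mult = np.exp(rng.normal(0.0, spec.replicate_cv, spec.n_replicates))
            mult /= mult.mean()
            for r, m in enumerate(mult, start=1):
                rows.append((pid, cond, r, float(val * m)))
    table = pd.DataFrame(rows, columns=["paralog_id", "condition", "replicate",
                                        "intensity"])
    realized = spearman_exact(designed, stab)
    truth = dict(
        designed_intensity={cond_a: dict(zip(ids, designed)),
                            cond_b: dict(zip(ids, designed_b))},
        realized_rho=realized.rho,
        planted_rho=spec.planted_rho,
        upweighted_ids=[ids[int(i)] for i in up_idx],
    )
    return table, truth


def gen_energy_table(
    spec: SyntheticSpec,
    paralog_ids: Sequence[str],
    capstone_ids: Sequence[str] = (),
    reference_id: str | None = None,
    seed: int | None = None,
) -> tuple[dict[str, tuple[float, float]], dict]:
    """Additive per-monomer (bind_term, tet_term) energy table.

    Terms are drawn from centered normals; capstone paralogs get a large
    positive tetramerization penalty; the reference paralog's row is zeroed
    so its homotetramer sits at the origin of state space.
    """
    ids = list(paralog_ids)
    if not ids:
        raise SyntheticError("no paralogs")
    rng = np.random.default_rng([spec.seed if seed is None else seed, 2])
    ref = reference_id if reference_id is not None else ids[0]
    terms: dict[str, tuple[float, float]] = {}
    for pid in ids:
        b = float(rng.normal(0.0, spec.energy_sigma_bind))
        t = float(rng.normal(0.0, spec.energy_sigma_tet))
        if pid in set(capstone_ids):
            t += spec.capstone_tet_penalty
        if pid == ref:
            b, t = 0.0, 0.0
        terms[pid] = (b, t)
    truth = dict(reference_id=ref, capstone_ids=list(capstone_ids))
    return terms, truth
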