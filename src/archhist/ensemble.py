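"""Abundance-weighted Monte-Carlo sampling of tetramer ensembles.

Given per-paralog protein abundances (LFQ-like intensities), monomers are
recruited into complexes independently at random with probability
proportional to mean abundance ("random dimerization"). Ensembles drawn
under two growth conditions are compared in (ddG_bind, ddG_tet) energy space
as a binned density-shift map, emulating the condition-versus-condition
chromatin state-space comparison.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .energetics import EnergyBackend
from .state_space import TetramerComplex

ABUNDANCE_COLUMNS = ("paralog_id", "condition", "replicate", "intensity")


class EnsembleError(ValueError):
    pass


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    """Read an abundance table (paralog_id, condition, replicate, intensity)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ABUNDANCE_COLUMNS) - set(df.columns)
    if missing:
        raise EnsembleError(f"{path}: missing columns {sorted(missing)}")
    if (df["intensity"] < 0).any():
        raise EnsembleError(f"{path}: negative intensities")
    return df


def write_abundance_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def normalize_abundance(
    table: pd.DataFrame,
    condition: str,
    paralog_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Monomer recruitment probabilities from mean replicate intensity.

    p_i = mean intensity of paralog i / sum over paralogs; paralogs listed in
    ``paralog_ids`` but absent from the table get probability zero.
    """
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise EnsembleError(f"condition {condition!r} not present")
    means = sub.groupby("paralog_id")["intensity"].mean()
    if paralog_ids is not None:
        means = means.reindex(list(paralog_ids), fill_value=0.0)
    total = means.sum()
    if total <= 0:
        raise EnsembleError(f"condition {condition!r} has zero total intensity")
    return means / total


@dataclass(frozen=True)
class SampledEnsemble:
    """A Monte-Carlo ensemble of tetramers drawn for one condition."""

    condition: str
    paralog_ids: tuple[str, ...]
    draws: np.ndarray  # (n_draws, 4) int indices into paralog_ids
    probabilities: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return int(self.draws.shape[0])

    def complex_counts(self) -> Counter:
        """Counts of ordered complex keys in the ensemble."""
        keys, counts = np.unique(self.draws, axis=0, return_counts=True)
        ids = np.array(self.paralog_ids)
        return Counter(
            {"+".join(ids[row]): int(c) for row, c in zip(keys, counts)}
        )

    def slot_frequencies(self) -> np.ndarray:
        """(4, n_paralogs) empirical monomer frequency per tetramer slot."""
        k = len(self.paralog_ids)
        out = np.zeros((4, k))
        for slot in range(4):
            counts = np.bincount(self.draws[:, slot], minlength=k)
            out[slot] = counts / self.n_draws
        return out


def sample_ensemble(
    probabilities: pd.Series | Mapping[str, float],
    n_draws: int = 100_000,
    seed: int = 0,
    condition: str = "",
) -> SampledEnsemble:
    """Draw an ensemble of tetramers by four iid categorical monomer draws.

    Monomer-level iid recruitment implements random dimerization; the draw is
    deterministic given the seed. The default ensemble size is 100,000.
    """
    if n_draws <= 0:
        raise EnsembleError("n_draws must be positive")
    probs = pd.Series(probabilities, dtype=float)
    p = probs.to_numpy()
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
        raise EnsembleError("probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(p), size=(n_draws, 4), p=p / p.sum())
    return SampledEnsemble(
        condition=condition,
        paralog_ids=tuple(str(i) for i in probs.index),
        draws=draws,
        probabilities=p,
        seed=seed,
    )


def expected_frequency(
    probabilities: pd.Series | Mapping[str, float],
    complex_or_composition: TetramerComplex | Mapping[str, int],
) -> float:
    """Closed-form probability of a complex under iid monomer recruitment.

    For an ordered complex the probability is the product of its monomer
    probabilities; for an unordered composition it is the multinomial
    coefficient times that product.
    """
    probs = dict(pd.Series(probabilities, dtype=float))
    if isinstance(complex_or_composition, TetramerComplex):
        out = 1.0
        for m in complex_or_composition.monomers:
            out *= probs.get(m, 0.0)
        return out
    comp = dict(complex_or_composition)
    if sum(comp.values()) != 4:
        raise EnsembleError("composition must total 4 monomers")
    coef = math.factorial(4)
    out = 1.0
    for m, k in comp.items():
        coef //= math.factorial(k)
        out *= probs.get(m, 0.0) ** k
    return coef * out


def ensemble_energies(
    ensemble: SampledEnsemble, backend: EnergyBackend
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw (ddG_bind, ddG_tet) arrays, via lookup on unique complexes."""
    uniq, inverse = np.unique(ensemble.draws, axis=0, return_inverse=True)
    ids = np.array(ensemble.paralog_ids)
    binds = np.empty(len(uniq))
    tets = np.empty(len(uniq))
    for i, row in enumerate(uniq):
        e = backend.energy(TetramerComplex(tuple(ids[row])))
        binds[i] = e.ddg_bind
        tets[i] = e.ddg_tet
    return binds[inverse], tets[inverse]


@dataclass(frozen=True)
class DensityShiftGrid:
    """Binned two-condition comparison in (ddG_bind, ddG_tet) space.

    ``log2_ratio`` is log2((counts_b + pseudocount)/(counts_a + pseudocount))
    per bin: positive bins are enriched in condition B. ``summary`` holds the
    ensemble-mean energy coordinates and their B-A differences.
    """

    condition_a: str
    condition_b: str
    x_edges: np.ndarray  # ddG_bind bin edges
    y_edges: np.ndarray  # ddG_tet bin edges
    counts_a: np.ndarray
    counts_b: np.ndarray
    pseudocount: float
    summary: dict[str, float]

    @property
    def log2_ratio(self) -> np.ndarray:
        return np.log2(
            (self.counts_b + self.pseudocount)
            / (self.counts_a + self.pseudocount)
        )

    def to_tsv(self, path: str | Path) -> None:
        nx, ny = self.counts_a.shape
        with open(path, "w") as fh:
            fh.write("bin_x\tbin_y\tcount_a\tcount_b\tlog2_ratio\n")
            lr = self.log2_ratio
            for i in range(nx):
                for j in range(ny):
                    fh.write(
                        f"{i}\t{j}\t{self.counts_a[i, j]:g}\t"
                        f"{self.counts_b[i, j]:g}\t{lr[i, j]:.6g}\n"
                    )


def density_shift(
    ensemble_a: SampledEnsemble,
    ensemble_b: SampledEnsemble,
    backend: EnergyBackend,
    n_bins: int = 50,
    pseudocount: float = 1.0,
) -> DensityShiftGrid:
    """Density-shift map between two sampled ensembles on shared bin edges.

    Bin edges span the pooled ensembles. If the ensembles differ in size,
    counts are normalized to frequencies before the ratio.
    """
    if ensemble_a.n_draws == 0 or ensemble_b.n_draws == 0:
        raise EnsembleError("empty ensemble")
    ba, ta = ensemble_energies(ensemble_a, backend)
    bb, tb = ensemble_energies(ensemble_b, backend)
    all_b = np.concatenate([ba, bb])
    all_t = np.concatenate([ta, tb])
    x_edges = np.linspace(all_b.min(), all_b.max() + 1e-12, n_bins + 1)
    y_edges = np.linspace(all_t.min(), all_t.max() + 1e-12, n_bins + 1)
    counts_a, _, _ = np.histogram2d(ba, ta, bins=(x_edges, y_edges))
    counts_b, _, _ = np.histogram2d(bb, tb, bins=(x_edges, y_edges))
    if ensemble_a.n_draws != ensemble_b.n_draws:
        counts_a = counts_a / ensemble_a.n_draws
        counts_b = counts_b / ensemble_b.n_draws
    summary = dict(
        mean_bind_a=float(ba.mean()), mean_bind_b=float(bb.mean()),
        mean_tet_a=float(ta.mean()), mean_tet_b=float(tb.mean()),
        delta_mean_bind=float(bb.mean() - ba.mean()),
        delta_mean_tet=float(tb.mean() - ta.mean()),
        se_delta_bind=float(
            math.hypot(ba.std() / math.sqrt(len(ba)), bb.std() / math.sqrt(len(bb)))
        ),
        se_delta_tet=float(
            math.hypot(ta.std() / math.sqrt(len(ta)), tb.std() / math.sqrt(len(tb)))
        ),
    )
    return DensityShiftGrid(
        ensemble_a.condition, ensemble_b.condition,
        x_edges, y_edges, counts_a, counts_b, pseudocount, summary
    )


def ensemble_counts_tsv(
    ensembles: Sequence[SampledEnsemble], path: str | Path
) -> None:
    """Write ordered-complex counts per condition as TSV."""
    counters = {e.condition or f"cond{i}": e.complex_counts()
                for i, e in enumerate(ensembles)}
    keys = sorted(set().union(*[set(c) for c in counters.values()]))
    with open(path, "w") as fh:
        fh.write("complex_key\t" + "\t".join(counters) + "\n")
        for k in keys:
            fh.write(k + "\t" + "\t".join(str(c.get(k, 0)) for c in counters.values()) + "\n")
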