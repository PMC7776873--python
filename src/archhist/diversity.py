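"""Per-position diversity statistics on aligned histone groups.

Shannon diversity H (in nats) per alignment column and sequence group, the
between-group diversity ratio H_A/H_B, Jaccard overlap of the residue sets
observed in two groups, and an exact small-n Spearman rank correlation.

The ratio is reported as an explicit UNDEFINED value whenever the denominator
group has zero diversity (e.g. a residue perfectly conserved in single-histone
archaea), rather than as an infinity or NaN that silently propagates.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GAP, AlignedCatalog, PositionMap

#: characters never counted as residues in diversity statistics
EXCLUDED_CHARS = frozenset({GAP, "X"})

#: largest n for which the exact permutation p-value is enumerated (8! = 40320)
EXACT_P_MAX_N = 8


class DiversityError(ValueError):
    pass


@dataclass(frozen=True)
class GroupLabeling:
    """Map record id -> group label; ids missing from the map are unlabeled."""

    group_of: Mapping[str, str]

    def members(self, group: str) -> tuple[str, ...]:
        ids = tuple(i for i, g in self.group_of.items() if g == group)
        if not ids:
            raise DiversityError(f"unknown or empty group {group!r}")
        return ids


def shannon_index(residue_counts: Mapping[str, int | float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i over residues with count > 0.

    Counts must already exclude gaps/unknowns; an all-zero count is an error
    (the caller should skip such positions).
    """
    counts = np.array([c for c in residue_counts.values() if c > 0], dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise DiversityError("shannon_index requires a positive total count")
    return float(stats.entropy(counts))  # natural log


def min_positive_entropy(n: int) -> float:
    """Smallest nonzero H achievable in a column of n sequences.

    Attained by a single deviant residue among n: H(n-1, 1). Used as a
    regularization floor when ranking positions whose denominator group is
    perfectly conserved (H = 0, ratio formally undefined).
    """
    if n < 2:
        return float("nan")
    return float(stats.entropy([n - 1, 1]))


def _column_counts(
    aligned: AlignedCatalog, member_ids: Sequence[str], col: int
) -> Counter:
    counts: Counter = Counter()
    idx = {rid: i for i, rid in enumerate(aligned.ids)}
    for rid in member_ids:
        ch = aligned.rows[idx[rid]][col]
        if ch not in EXCLUDED_CHARS:
            counts[ch] += 1
    return counts


@dataclass(frozen=True)
class DiversityProfile:
    """Per-position diversity table for a pair of groups.

    ``table`` columns: position, n_a, n_b, H_a, H_b, ratio, ratio_defined,
    both_zero, jaccard, jaccard_defined. ``ratio`` is NaN wherever
    ``ratio_defined`` is False (H_b = 0); ``both_zero`` marks the 0/0 subcase.
    """

    group_a: str
    group_b: str
    table: pd.DataFrame

    def ranked_positions(self) -> list[int]:
        """Positions ordered most- to least-diversified in group A vs B.

        Defined ratios sort by their value. Positions with H_b = 0 but
        H_a > 0 (the residue-19-style case) are ranked by the regularized
        ratio H_a / H_min(n_b), which always places them above any column
        with comparable H_a and observed diversity in B. 0/0 positions rank
        last.
        """
        t = self.table
        key = np.empty(len(t), dtype=float)
        for i, row in enumerate(t.itertuples(index=False)):
            if row.both_zero:
                key[i] = -np.inf
            elif row.ratio_defined:
                key[i] = row.ratio
            else:  # H_b == 0, H_a > 0
                key[i] = row.H_a / min_positive_entropy(int(row.n_b))
        order = np.argsort(-key, kind="stable")
        return [int(t["position"].iloc[i]) for i in order]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(1, "group_a", self.group_a)
        out.insert(2, "group_b", self.group_b)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _profile_positions(aligned: AlignedCatalog, posmap: PositionMap) -> list[tuple[int, int]]:
    kept = set(aligned.kept_columns().tolist())
    return [
        (pos, col)
        for col, pos in sorted(posmap.column_to_position.items())
        if col in kept
    ]


def diversity_ratio_profile(
    aligned: AlignedCatalog,
    posmap: PositionMap,
    labeling: GroupLabeling,
    group_a: str,
    group_b: str,
) -> DiversityProfile:
    """Shannon H per group and the ratio H_A/H_B at every kept, mapped position.

    Gaps and X are excluded from counts. The ratio is UNDEFINED (NaN +
    ``ratio_defined`` False) when H_B = 0; ``both_zero`` additionally flags
    positions where H_A = 0 too. Jaccard overlap of the observed residue sets
    is computed alongside.
    """
    ids_a = labeling.members(group_a)
    ids_b = labeling.members(group_b)
    records = []
    for pos, col in _profile_positions(aligned, posmap):
        ca = _column_counts(aligned, ids_a, col)
        cb = _column_counts(aligned, ids_b, col)
        na, nb = sum(ca.values()), sum(cb.values())
        if na == 0 or nb == 0:
            continue  # no observable residues in one group
        ha = shannon_index(ca)
        hb = shannon_index(cb)
        defined = hb > 0.0
        both_zero = (ha == 0.0) and (hb == 0.0)
        ratio = ha / hb if defined else float("nan")
        set_a, set_b = set(ca), set(cb)
        union = set_a | set_b
        jac = len(set_a & set_b) / len(union) if union else float("nan")
        records.append(
            dict(position=pos, n_a=na, n_b=nb, H_a=ha, H_b=hb, ratio=ratio,
                 ratio_defined=defined, both_zero=both_zero,
                 jaccard=jac, jaccard_defined=bool(union))
        )
    table = pd.DataFrame.from_records(records)
    return DiversityProfile(group_a, group_b, table)


def jaccard_profile(
    aligned: AlignedCatalog,
    posmap: PositionMap,
    labeling: GroupLabeling,
    group_a: str,
    group_b: str,
) -> pd.Series:
    """Per-position Jaccard index |A∩B|/|A∪B| of observed residue sets."""
    ids_a = labeling.members(group_a)
    ids_b = labeling.members(group_b)
    out = {}
    for pos, col in _profile_positions(aligned, posmap):
        set_a = set(_column_counts(aligned, ids_a, col))
        set_b = set(_column_counts(aligned, ids_b, col))
        union = set_a | set_b
        out[pos] = len(set_a & set_b) / len(union) if union else float("nan")
    return pd.Series(out, name="jaccard").sort_index()


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    mode: str  # "exact" | "t-approx" | "undefined"
    n: int

    @property
    def defined(self) -> bool:
        return self.mode != "undefined"


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman_exact(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman correlation with an exact permutation p-value at small n.

    rho is the Pearson correlation of average ranks (ties get average ranks).
    For n <= 8 the two-sided p-value is exact, by full enumeration of all n!
    rank permutations; for larger n a t-approximation is used. A constant
    input vector makes rho undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DiversityError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise DiversityError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), "undefined", n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    if n <= EXACT_P_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc ** 2).sum() * (pc ** 2).sum(axis=1))
        rhos = (pc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho, p, "exact", n)
    t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, min(p, 1.0), "t-approx", n)
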