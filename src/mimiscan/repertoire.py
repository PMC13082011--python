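"""Antibody-repertoire summaries from an epitope-binding-signal (EBS) matrix.

The EBS matrix holds non-negative enrichment Z-scores (individuals x peptides)
from phage-immunoprecipitation sequencing.  This module computes

* per-group mean EBS per individual,
* the antibody repertoire breadth (ARB): the normalized Shannon entropy

      ARB = -sum_i P_i ln(P_i) / ln(S)

  where ``P_i`` is the proportion of the individual's total group EBS on
  peptide ``i`` and ``S`` the number of peptides in the group.  ARB is 1 for
  perfectly even reactivity, 0 when a single peptide carries all signal, and
  undefined (NaN) when the group has no signal or fewer than two peptides;
* the CE1 seroreactivity score: mean EBS over a fixed panel of CE1 peptides
  (default panel size 40), with a configurable seropositivity cutoff.

``0 * ln 0`` is taken as 0 by continuity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import PeptideGroup

logger = logging.getLogger(__name__)

__all__ = [
    "ARBResult",
    "SeroreactivityScore",
    "group_ebs_summary",
    "compute_arb",
    "arb_category",
    "arb_above_half",
    "ce1_seroreactivity",
]

DEFAULT_CATEGORY_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_PANEL_SIZE = 40


@dataclass(frozen=True)
class ARBResult:
    individual_id: str
    group: str
    arb: float           # NaN when undefined
    n_peptides: int      # S
    total_signal: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.arb)


@dataclass(frozen=True)
class SeroreactivityScore:
    individual_id: str
    score: float
    k_used: int
    seropositive: bool


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("EBS matrix has duplicate individual or peptide ids")
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("EBS matrix contains NaN values")
    if (vals < 0).any():
        raise ValueError("EBS values must be non-negative enrichment Z-scores")


def _group_columns(
    matrix: pd.DataFrame,
    assignment: Mapping[str, PeptideGroup | str],
    *,
    strict: bool,
) -> dict[str, list[str]]:
    """Map group label -> matrix peptide columns; handles missing assignments."""
    assigned = {p: (g.value if isinstance(g, PeptideGroup) else str(g))
                for p, g in assignment.items()}
    missing = [p for p in matrix.columns if p not in assigned]
    if missing:
        if strict:
            raise ValueError(
                f"{len(missing)} matrix peptides lack a group assignment "
                f"(first: {missing[0]!r})"
            )
        logger.warning(
            "excluding %d matrix peptides with no group assignment", len(missing)
        )
    extra = set(assigned) - set(matrix.columns)
    if extra:
        logger.warning("ignoring %d assignments for peptides absent from matrix",
                       len(extra))
    cols: dict[str, list[str]] = {}
    for pep in matrix.columns:
        if pep in assigned:
            cols.setdefault(assigned[pep], []).append(pep)
    return cols


def group_ebs_summary(
    matrix: pd.DataFrame,
    assignment: Mapping[str, PeptideGroup | str],
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Mean EBS per individual per peptide group.

    Returns a DataFrame (individuals x groups).  Groups with no peptides in
    the matrix yield NaN columns.  In strict mode (default) a matrix peptide
    absent from the assignment raises; in lenient mode it is excluded with a
    logged count.
    """
    _check_matrix(matrix)
    cols = _group_columns(matrix, assignment, strict=strict)
    out = pd.DataFrame(index=matrix.index)
    for group in sorted(cols):
        out[group] = matrix[cols[group]].mean(axis=1)
    return out


def compute_arb(
    matrix: pd.DataFrame,
    assignment: Mapping[str, PeptideGroup | str],
    group: PeptideGroup | str,
    *,
    strict: bool = True,
) -> list[ARBResult]:
    """Antibody repertoire breadth per individual for one peptide group.

    ARB = -sum P_i ln P_i / ln S over the group's peptides, with
    P_i = EBS_i / sum_j EBS_j.  NaN (undefined) when the individual's total
    group signal is zero or the group has S < 2 peptides.
    """
    _check_matrix(matrix)
    label = group.value if isinstance(group, PeptideGroup) else str(group)
    cols = _group_columns(matrix, assignment, strict=strict).get(label, [])
    if not cols:
        raise ValueError(f"group {label!r} has no peptides in the matrix")

    sub = matrix[cols].to_numpy(dtype=float)
    s = len(cols)
    totals = sub.sum(axis=1)
    results: list[ARBResult] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sub / totals[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        entropy = np.maximum(-plogp.sum(axis=1), 0.0)  # avoid -0.0
        arb = entropy / np.log(s) if s >= 2 else np.full(len(totals), np.nan)
    for i, ind in enumerate(matrix.index):
        undefined = totals[i] == 0 or s < 2
        results.append(
            ARBResult(
                individual_id=str(ind),
                group=label,
                arb=float("nan") if undefined else float(arb[i]),
                n_peptides=s,
                total_signal=float(totals[i]),
            )
        )
    return results


def arb_category(
    arb: float,
    *,
    edges: Sequence[float] = DEFAULT_CATEGORY_EDGES,
) -> int:
    """Bin a defined ARB value into categories delimited by ``edges``.

    Default edges quarter the unit interval: bin 1 = [0, 0.25],
    bin 2 = (0.25, 0.5], bin 3 = (0.5, 0.75], bin 4 = (0.75, 1].  The lowest
    bin is closed on the left so ARB = 0 is category 1.  Returns the 1-based
    bin index.
    """
    if np.isnan(arb):
        raise ValueError("ARB is undefined; cannot categorize")
    edges = list(edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    if not (edges[0] <= arb <= edges[-1]):
        raise ValueError(f"ARB {arb} outside [{edges[0]}, {edges[-1]}]")
    for k in range(1, len(edges)):
        if arb <= edges[k]:
            return k
    return len(edges) - 1  # pragma: no cover - unreachable


def arb_above_half(arb: float, *, threshold: float = 0.5) -> bool:
    """Binary breadth indicator: strictly ARB > threshold (default 0.5)."""
    if np.isnan(arb):
        raise ValueError("ARB is undefined; cannot threshold")
    return arb > threshold


def ce1_seroreactivity(
    matrix: pd.DataFrame,
    ce1_peptides: Sequence[str],
    *,
    k: int = DEFAULT_PANEL_SIZE,
    positivity_threshold: float = 0.0,
    data_driven: bool = False,
) -> list[SeroreactivityScore]:
    """CE1 seroreactivity: mean EBS over a CE1 peptide panel, per individual.

    In fixed-panel mode (default) the supplied ``ce1_peptides`` list IS the
    reactive panel and ``k`` is ignored for selection.  In data-driven mode
    the ``k`` peptides with highest cohort-mean EBS among ``ce1_peptides`` are
    selected (ties broken by lexicographic peptide id) and averaged per
    individual.  ``seropositive`` is score > ``positivity_threshold``
    (strict; default threshold 0 marks any detectable panel reactivity).
    """
    _check_matrix(matrix)
    panel = list(ce1_peptides)
    if not panel:
        raise ValueError("CE1 peptide list is empty")
    unknown = [p for p in panel if p not in matrix.columns]
    if unknown:
        raise KeyError(f"CE1 peptides absent from matrix (first: {unknown[0]!r})")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")

    if data_driven:
        if k > len(panel):
            warnings.warn(
                f"k={k} exceeds available CE1 peptides ({len(panel)}); using all",
                stacklevel=2,
            )
            k = len(panel)
        cohort_mean = matrix[panel].mean(axis=0)
        # sort by (-mean, id): highest mean first, lexicographic id on ties
        ranked = sorted(panel, key=lambda p: (-cohort_mean[p], p))
        panel = ranked[:k]

    scores = matrix[panel].mean(axis=1)
    return [
        SeroreactivityScore(
            individual_id=str(ind),
            score=float(scores[ind]),
            k_used=len(panel),
            seropositive=bool(scores[ind] > positivity_threshold),
        )
        for ind in matrix.index
    ]
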