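"""Molecular-mimicry target discovery from IP-MS intensity tables.

The screening funnel mirrors an immunoprecipitation / mass-spectrometry
experiment with anti-epitope antibodies on tumor cell lysates:

1. per-protein fold changes of target-antibody over control-antibody
   intensity, with a pseudocount for missing/zero intensities;
2. enrichment calls at a strict fold-change cutoff (> 100 by default) and
   intersection across cell lines;
3. cross-reference against a surface-proteome membership list;
4. local alignment of each surviving candidate against the query epitope
   (BLOSUM62 Smith-Waterman) and ranking by expect value.

The funnel is monotone: enriched >= surface-filtered >= ranked.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .alignment import CANONICAL_AA, AlignmentReport, smith_waterman

logger = logging.getLogger(__name__)

__all__ = [
    "EpitopeQuery",
    "EnrichmentInputs",
    "FOLD_CHANGE_CUTOFF",
    "compute_fold_changes",
    "intersect_enriched",
    "filter_surface",
    "align_query",
    "rank_candidates",
    "run_mimicry_funnel",
    "competition_summary",
]

FOLD_CHANGE_CUTOFF = 100.0
DEFAULT_PSEUDOCOUNT = 1.0

# Printed query peptide used for antibody panning; the leading Cys is a
# conjugation handle and may optionally be stripped (config strip_leading_cys).
CE1_QUERY_SEQUENCE = "CSESVPALTAVETGHTS"


@dataclass(frozen=True)
class EpitopeQuery:
    """An amino-acid query epitope (uppercase canonical residues)."""

    sequence: str
    name: str = "query"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("query sequence is empty")
        bad = [c for c in self.sequence if c not in CANONICAL_AA]
        if bad:
            raise ValueError(
                f"query {self.name!r}: non-canonical residue {bad[0]!r}"
            )

    def stripped(self) -> "EpitopeQuery":
        """Drop a leading conjugation cysteine, if present."""
        if self.sequence.startswith("C") and len(self.sequence) > 1:
            return EpitopeQuery(self.sequence[1:], self.name)
        return self


@dataclass
class EnrichmentInputs:
    """Per-cell-line IP-MS intensities.

    ``tables`` maps cell line -> DataFrame indexed by protein id with a
    ``control`` column and one column per target antibody.  Protein universes
    may differ between tables; absences count as intensity 0 (union taken).
    """

    tables: dict[str, pd.DataFrame]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError(f"pseudocount must be > 0, got {self.pseudocount}")
        if not self.tables:
            raise ValueError("need at least one cell-line table")
        for line, tab in self.tables.items():
            if "control" not in tab.columns:
                raise ValueError(f"cell line {line!r}: missing 'control' column")
            if tab.shape[1] < 2:
                raise ValueError(f"cell line {line!r}: no target antibody column")
            if (tab.to_numpy(dtype=float) < 0).any():
                raise ValueError(f"cell line {line!r}: negative intensity")

    @property
    def antibodies(self) -> list[str]:
        names: list[str] = []
        for tab in self.tables.values():
            for c in tab.columns:
                if c != "control" and c not in names:
                    names.append(c)
        return names

    @property
    def proteins(self) -> list[str]:
        universe: set[str] = set()
        for tab in self.tables.values():
            universe.update(map(str, tab.index))
        return sorted(universe)


def compute_fold_changes(inputs: EnrichmentInputs) -> pd.DataFrame:
    """Tidy fold-change table: one row per (protein, cell line, antibody).

    FC = (target + pseudocount) / (control + pseudocount); ``passes`` is the
    strict >100 enrichment verdict for that table.  Proteins absent from a
    table contribute intensity 0.
    """
    rows = []
    universe = inputs.proteins
    for line, tab in inputs.tables.items():
        targets = [c for c in tab.columns if c != "control"]
        reindexed = tab.reindex(universe).fillna(0.0)
        for ab in targets:
            fc = (reindexed[ab] + inputs.pseudocount) / (
                reindexed["control"] + inputs.pseudocount
            )
            for prot in universe:
                rows.append(
                    {
                        "protein": prot,
                        "cell_line": line,
                        "antibody": ab,
                        "target_intensity": float(reindexed.at[prot, ab]),
                        "control_intensity": float(reindexed.at[prot, "control"]),
                        "fold_change": float(fc[prot]),
                        "passes": bool(fc[prot] > FOLD_CHANGE_CUTOFF),
                    }
                )
    return pd.DataFrame(rows)


def intersect_enriched(
    fold_changes: pd.DataFrame,
    *,
    cell_line_mode: str = "all",
    antibody_mode: str = "any",
    cutoff: float = FOLD_CHANGE_CUTOFF,
) -> set[str]:
    """Proteins enriched across cell lines.

    Within a cell line a protein passes when its fold change exceeds
    ``cutoff`` for ``antibody_mode`` = "any" (either antibody; default,
    matching enrichment by one antibody or the other) or "all" antibodies.
    Across cell lines, ``cell_line_mode`` = "all" (default: enriched in every
    line) or "any".
    """
    if cell_line_mode not in {"all", "any"}:
        raise ValueError(f"cell_line_mode must be all|any, got {cell_line_mode!r}")
    if antibody_mode not in {"all", "any"}:
        raise ValueError(f"antibody_mode must be all|any, got {antibody_mode!r}")
    passed = fold_changes.assign(ok=fold_changes["fold_change"] > cutoff)
    per_line = (
        passed.groupby(["protein", "cell_line"])["ok"]
        .agg("all" if antibody_mode == "all" else "any")
        .reset_index()
    )
    per_protein = per_line.groupby("protein")["ok"].agg(
        "all" if cell_line_mode == "all" else "any"
    )
    return set(per_protein[per_protein].index.astype(str))


_ISOFORM_SUFFIX = re.compile(r"-\d+$")


def normalize_protein_id(pid: str, *, strip_isoform: bool = True) -> str:
    pid = pid.strip().upper()
    if strip_isoform:
        pid = _ISOFORM_SUFFIX.sub("", pid)
    return pid


def filter_surface(
    enriched: Iterable[str],
    surface_list: Iterable[str],
    *,
    strip_isoform: bool = True,
) -> set[str]:
    """Intersect enriched proteins with a surface-proteome membership list.

    Identifiers are case-folded and isoform suffixes ("-2") stripped before
    comparison (configurable).  Returns the original enriched ids that match.
    """
    surface_norm = {
        normalize_protein_id(s, strip_isoform=strip_isoform) for s in surface_list
    }
    if not surface_norm:
        logger.warning("surface list is empty; no candidates retained")
        return set()
    return {
        pid
        for pid in enriched
        if normalize_protein_id(pid, strip_isoform=strip_isoform) in surface_norm
    }


def align_query(
    query: EpitopeQuery,
    subject: str,
    *,
    candidate_id: str = "",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentReport:
    """Local alignment of the query epitope against one candidate sequence."""
    return smith_waterman(
        query.sequence,
        subject,
        candidate_id=candidate_id,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def rank_candidates(
    candidates: Iterable[str],
    sequences: Mapping[str, str],
    query: EpitopeQuery,
    *,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> pd.DataFrame:
    """Align each candidate to the query and rank by homology.

    Sort key: ascending expect value, ties by descending raw score, then
    lexicographic candidate id.  Returns a DataFrame with one row per
    candidate and the full AlignmentReport in the ``report`` column.
    """
    rows = []
    for cid in sorted(set(map(str, candidates))):
        if cid not in sequences:
            raise KeyError(f"no sequence for candidate {cid!r}")
        rep = align_query(
            query, sequences[cid], candidate_id=cid,
            gap_open=gap_open, gap_extend=gap_extend,
        )
        rows.append(
            {
                "candidate": cid,
                "raw_score": rep.raw_score,
                "bit_score": rep.bit_score,
                "expect": rep.expect,
                "n_identity": rep.n_identity,
                "n_conserved": rep.n_conserved,
                "subject_start": rep.subject_interval[0],
                "subject_end": rep.subject_interval[1],
                "report": rep,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["candidate", "raw_score", "bit_score", "expect",
                     "n_identity", "n_conserved", "subject_start",
                     "subject_end", "report", "rank"]
        )
    df = df.sort_values(
        ["expect", "raw_score", "candidate"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class FunnelResult:
    fold_changes: pd.DataFrame = field(repr=False)
    enriched: set[str]
    surface: set[str]
    ranking: pd.DataFrame = field(repr=False)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "proteins": int(self.fold_changes["protein"].nunique()),
            "enriched": len(self.enriched),
            "surface": len(self.surface),
            "ranked": len(self.ranking),
        }


def run_mimicry_funnel(
    inputs: EnrichmentInputs,
    surface_list: Iterable[str],
    sequences: Mapping[str, str],
    query: EpitopeQuery,
    *,
    cutoff: float = FOLD_CHANGE_CUTOFF,
    cell_line_mode: str = "all",
    antibody_mode: str = "any",
    strip_isoform: bool = True,
) -> FunnelResult:
    """End-to-end screen: fold changes -> enrichment -> surface -> ranking."""
    fc = compute_fold_changes(inputs)
    enriched = intersect_enriched(
        fc, cell_line_mode=cell_line_mode, antibody_mode=antibody_mode,
        cutoff=cutoff,
    )
    surface = filter_surface(enriched, surface_list, strip_isoform=strip_isoform)
    ranking = rank_candidates(surface, sequences, query)
    res = FunnelResult(fold_changes=fc, enriched=enriched, surface=surface,
                       ranking=ranking)
    logger.info("mimicry funnel counts: %s", res.stage_counts)
    return res


def competition_summary(
    data: pd.DataFrame,
    *,
    response: str = "readout",
    condition: str = "condition",
    dose: str = "dose",
    ss_type: int = 2,
) -> pd.DataFrame:
    """Two-way ANOVA on a tidy dose-response (or time-course) readout table.

    Expects replicate rows with columns for the response, the condition
    (e.g. competing antigen) and the dose or time level.  Reports main-effect
    and interaction F statistics and p-values; Type-II sums of squares by
    default (robust to unbalanced designs), Type-I available via ``ss_type``.
    """
    for col in (response, condition, dose):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from readout table")
    df = data.rename(columns={response: "y", condition: "cond", dose: "dose"})
    df = df.assign(cond=df["cond"].astype(str), dose=df["dose"].astype(str))
    model = smf.ols("y ~ C(cond) * C(dose)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    table = table.rename(
        index={
            "C(cond)": "condition",
            "C(dose)": "dose",
            "C(cond):C(dose)": "interaction",
            "Residual": "residual",
        }
    )
    return table
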