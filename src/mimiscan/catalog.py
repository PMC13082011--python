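"""Peptide catalog, polyprotein chain annotations, and the three-way epitope partition.

Enterovirus/rhinovirus genomes encode a single polyprotein that is cleaved into
the capsid proteins VP1-VP4 and several non-structural proteins.  Peptides in a
phage-display catalog are located by 1-based closed residue intervals on their
source polyprotein.  Each peptide is assigned to exactly one of three groups:

* ``CE1_VP1``      — overlaps the VP1 chain AND the CE1 consensus-epitope window,
* ``NON_CE1_VP1``  — overlaps VP1 but not the CE1 window,
* ``NON_VP1``      — everything else.

Overlap means >= ``min_ce1_overlap`` shared residues (default 1).  All
coordinates follow the UniProt chain convention: 1-based, both ends inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PeptideGroup",
    "ChainName",
    "ChainAnnotation",
    "PeptideRecord",
    "assign_groups",
    "read_catalog_tsv",
    "read_annotations_tsv",
    "write_assignments_tsv",
]


class PeptideGroup(str, enum.Enum):
    CE1_VP1 = "CE1_VP1"
    NON_CE1_VP1 = "NON_CE1_VP1"
    NON_VP1 = "NON_VP1"


class ChainName(str, enum.Enum):
    VP1 = "VP1"
    VP2 = "VP2"
    VP3 = "VP3"
    VP4 = "VP4"
    NONSTRUCTURAL = "NONSTRUCTURAL"


@dataclass(frozen=True)
class ChainAnnotation:
    """One chain interval of a polyprotein, optionally carrying the CE1 window.

    The CE1 window may only be present on VP1 chains and must lie inside the
    chain interval.
    """

    accession: str
    chain_name: ChainName
    start: int
    end: int
    ce1_start: int | None = None
    ce1_end: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"chain {self.accession}/{self.chain_name.value}: "
                f"require 1 <= start <= end, got [{self.start}, {self.end}]"
            )
        has_ce1 = self.ce1_start is not None or self.ce1_end is not None
        if has_ce1:
            if self.chain_name is not ChainName.VP1:
                raise ValueError(
                    f"chain {self.accession}/{self.chain_name.value}: "
                    "CE1 window only allowed on VP1 chains"
                )
            if self.ce1_start is None or self.ce1_end is None:
                raise ValueError("ce1_start and ce1_end must both be given")
            if not (self.start <= self.ce1_start <= self.ce1_end <= self.end):
                raise ValueError(
                    f"CE1 window [{self.ce1_start}, {self.ce1_end}] not inside "
                    f"VP1 chain [{self.start}, {self.end}]"
                )


@dataclass(frozen=True)
class PeptideRecord:
    """A displayed peptide located on its source polyprotein (1-based closed)."""

    peptide_id: str
    accession: str
    start: int
    end: int
    strain: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"peptide {self.peptide_id}: require 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )


def _overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Number of residues shared by two 1-based closed intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _validate_annotations(
    annotations: Iterable[ChainAnnotation],
) -> dict[str, list[ChainAnnotation]]:
    by_acc: dict[str, list[ChainAnnotation]] = {}
    for ann in annotations:
        by_acc.setdefault(ann.accession, []).append(ann)
    for acc, chains in by_acc.items():
        chains_sorted = sorted(chains, key=lambda c: c.start)
        for prev, nxt in zip(chains_sorted, chains_sorted[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"accession {acc}: overlapping chains "
                    f"[{prev.start},{prev.end}] and [{nxt.start},{nxt.end}]"
                )
    return by_acc


def assign_groups(
    catalog: Iterable[PeptideRecord],
    annotations: Iterable[ChainAnnotation],
    *,
    min_ce1_overlap: int = 1,
) -> dict[str, PeptideGroup]:
    """Partition catalog peptides into CE1-VP1 / non-CE1 VP1 / non-VP1 groups.

    A peptide is VP1-intersecting when it shares at least one residue with a
    VP1 chain of its accession (peptides spanning a chain boundary count);
    among VP1-intersecting peptides, those sharing >= ``min_ce1_overlap``
    residues with the CE1 window are ``CE1_VP1``, the rest ``NON_CE1_VP1``.

    Parameters
    ----------
    catalog
        Peptide records; every accession must appear in ``annotations``.
    annotations
        Chain annotations; chains of one accession must not overlap.
    min_ce1_overlap
        Minimum shared-residue count with the CE1 window for a CE1-VP1 call.

    Returns
    -------
    dict mapping peptide_id -> PeptideGroup (a partition of the catalog).

    Raises
    ------
    KeyError
        If a peptide references an unannotated accession.
    ValueError
        If a peptide extends beyond its polyprotein's annotated range, or
        ``min_ce1_overlap`` < 1.
    """
    if min_ce1_overlap < 1:
        raise ValueError(f"min_ce1_overlap must be >= 1, got {min_ce1_overlap}")
    by_acc = _validate_annotations(annotations)

    out: dict[str, PeptideGroup] = {}
    for pep in catalog:
        chains = by_acc.get(pep.accession)
        if chains is None:
            raise KeyError(
                f"peptide {pep.peptide_id}: unknown accession {pep.accession!r}"
            )
        acc_end = max(c.end for c in chains)
        if pep.end > acc_end:
            raise ValueError(
                f"peptide {pep.peptide_id}: interval [{pep.start}, {pep.end}] "
                f"extends beyond annotated polyprotein end {acc_end} "
                f"of {pep.accession}"
            )
        in_vp1 = False
        in_ce1 = False
        for chain in chains:
            if chain.chain_name is not ChainName.VP1:
                continue
            if _overlap_len(pep.start, pep.end, chain.start, chain.end) >= 1:
                in_vp1 = True
            if chain.ce1_start is not None and chain.ce1_end is not None:
                if (
                    _overlap_len(pep.start, pep.end, chain.ce1_start, chain.ce1_end)
                    >= min_ce1_overlap
                ):
                    in_ce1 = True
        if in_vp1 and in_ce1:
            out[pep.peptide_id] = PeptideGroup.CE1_VP1
        elif in_vp1:
            out[pep.peptide_id] = PeptideGroup.NON_CE1_VP1
        else:
            out[pep.peptide_id] = PeptideGroup.NON_VP1
    return out


# ---------------------------------------------------------------------------
# TSV I/O (coordinates in all files are 1-based closed intervals)
# ---------------------------------------------------------------------------

def read_catalog_tsv(path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "accession": str})
    return [
        PeptideRecord(
            peptide_id=row.peptide_id,
            accession=row.accession,
            start=int(row.start),
            end=int(row.end),
            strain=str(getattr(row, "strain", "")),
        )
        for row in df.itertuples(index=False)
    ]


def read_annotations_tsv(path) -> list[ChainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "chain_name": str})
    out = []
    for row in df.itertuples(index=False):
        ce1_start = getattr(row, "ce1_start", None)
        ce1_end = getattr(row, "ce1_end", None)
        ce1_start = None if pd.isna(ce1_start) else int(ce1_start)
        ce1_end = None if pd.isna(ce1_end) else int(ce1_end)
        out.append(
            ChainAnnotation(
                accession=row.accession,
                chain_name=ChainName(row.chain_name),
                start=int(row.start),
                end=int(row.end),
                ce1_start=ce1_start,
                ce1_end=ce1_end,
            )
        )
    return out


def write_assignments_tsv(assignments: Mapping[str, PeptideGroup], path) -> None:
    df = pd.DataFrame(
        {
            "peptide_id": list(assignments.keys()),
            "group": [g.value for g in assignments.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)
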