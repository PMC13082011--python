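"""Tumor-transcriptome analyses: ADCC signature scoring, NK-infiltration
stratification, and serostatus-stratified correlation and survival.

Expression is assumed log-scale, genes x samples, with a dataset-of-origin
label per sample.  Normalization is Z-scoring per gene WITHIN each dataset
(sample sd, n-1), so cohorts profiled on different platforms can be pooled.
ADCC (antibody-dependent cellular cytotoxicity) activity is operationalized
as the unweighted mean of the within-dataset Z-scores of a 20-gene signature;
NK infiltration scores (e.g. from xCell deconvolution) are consumed
precomputed and dichotomized at a strict cutoff (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import association
from .association import ChiSquareResult, SpearmanResult, SurvivalStratumResult

logger = logging.getLogger(__name__)

__all__ = [
    "ADCC_SIGNATURE_GENES",
    "NK_CUTOFF",
    "ExpressionBundle",
    "zscore_within_dataset",
    "adcc_score",
    "nk_stratify",
    "serostatus_nk_chisq",
    "stratified_asph_adcc",
    "asph_sero_survival",
]

# 20-gene transcriptomic ADCC-activity signature
ADCC_SIGNATURE_GENES = (
    "TNFRSF9", "TNF", "BCL2", "IL21R", "BIRC3", "IKZF2", "CCR7", "CD69",
    "MKI67", "CD226", "CLEC2B", "CXCR4", "TIA1", "TNFSF10", "GZMA", "TLR6",
    "TLR1", "CD244", "CD38", "TLR3",
)
NK_CUTOFF = 0.01
TARGET_GENE = "ASPH"


@dataclass
class ExpressionBundle:
    """Genes x samples expression with per-sample metadata.

    ``metadata`` is indexed by sample id and carries ``dataset`` (required),
    and optionally ``nk_score``, ``ce1_seroreactivity``, ``seropositive``,
    ``survival_time``, ``event``.
    """

    expression: pd.DataFrame
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if "dataset" not in self.metadata.columns:
            raise ValueError("metadata must carry a 'dataset' label per sample")
        missing = set(self.expression.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(
                f"{len(missing)} samples lack metadata "
                f"(first: {sorted(missing)[0]!r})"
            )

    @property
    def samples(self) -> list[str]:
        return list(map(str, self.expression.columns))


def zscore_within_dataset(
    bundle: ExpressionBundle,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Z-score within each dataset (sample sd, denominator n-1).

    Returns genes x samples in the bundle's sample order.  A zero-variance
    gene within a dataset becomes an all-zero row there, with a warning.
    Requesting a gene absent from the matrix raises.
    """
    expr = bundle.expression
    if genes is not None:
        absent = [g for g in genes if g not in expr.index]
        if absent:
            raise KeyError(f"genes absent from expression (first: {absent[0]!r})")
        expr = expr.loc[list(genes)]
    datasets = bundle.metadata.loc[expr.columns, "dataset"]
    out = pd.DataFrame(index=expr.index, columns=expr.columns, dtype=float)
    for ds in datasets.unique():
        cols = expr.columns[(datasets == ds).to_numpy()]
        if len(cols) < 2:
            raise ValueError(f"dataset {ds!r} has < 2 samples; cannot Z-score")
        block = expr[cols].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            logger.warning(
                "dataset %s: %d zero-variance genes set to 0", ds, int(flat.sum())
            )
        sd = np.where(sd == 0, 1.0, sd)
        out.loc[:, cols] = (block - mu) / sd
    return out


def adcc_score(
    normalized: pd.DataFrame,
    signature: Sequence[str] = ADCC_SIGNATURE_GENES,
) -> pd.Series:
    """Per-sample ADCC signature score: mean normalized expression of the
    signature genes.  Signature genes missing from the matrix are dropped
    with a logged count; gene order never changes the score."""
    sig = list(dict.fromkeys(signature))
    if not sig:
        raise ValueError("empty signature gene list")
    present = [g for g in sig if g in normalized.index]
    if not present:
        raise KeyError("no signature genes present in the expression matrix")
    if len(present) < len(sig):
        logger.warning("dropping %d signature genes absent from matrix",
                       len(sig) - len(present))
    return normalized.loc[present].mean(axis=0)


def nk_stratify(nk_scores, *, cutoff: float = NK_CUTOFF) -> pd.Series:
    """Dichotomize NK-infiltration scores: 'high' iff score > cutoff (strict;
    a score exactly at the cutoff is 'low')."""
    s = pd.Series(nk_scores, dtype=float)
    if (s < 0).any():
        raise ValueError("NK scores must be >= 0")
    return pd.Series(np.where(s > cutoff, "high", "low"), index=s.index)


def serostatus_nk_chisq(nk_labels, sero_labels) -> ChiSquareResult:
    """Chi-square association between NK high/low and CE1 serostatus (2x2)."""
    tab = pd.crosstab(pd.Series(list(nk_labels)), pd.Series(list(sero_labels)))
    return association.arb_category_chisq(tab.to_numpy())


def stratified_asph_adcc(
    bundle: ExpressionBundle,
    serostatus,
    *,
    target_gene: str = TARGET_GENE,
    signature: Sequence[str] = ADCC_SIGNATURE_GENES,
) -> list[SpearmanResult]:
    """Spearman correlation of target-gene expression vs ADCC score, within
    each serostatus stratum (normalized within dataset first)."""
    genes = [target_gene] + [g for g in signature if g != target_gene]
    normalized = zscore_within_dataset(bundle, genes)
    score = adcc_score(normalized, [g for g in genes if g != target_gene])
    target = normalized.loc[target_gene]
    return association.stratified_spearman(
        target.to_numpy(), score.to_numpy(), list(serostatus)
    )


def asph_sero_survival(
    bundle: ExpressionBundle,
    serostatus,
    *,
    target_gene: str = TARGET_GENE,
) -> dict[str, SurvivalStratumResult]:
    """Serostatus survival contrast within target-gene-high and -low tumors.

    Samples are split at the within-cohort median of normalized target-gene
    expression (values equal to the median go to the low stratum); within
    each stratum, Kaplan-Meier curves and a log-rank test compare
    seropositive vs seronegative patients.  Requires ``survival_time`` and
    ``event`` columns in the bundle metadata.
    """
    for col in ("survival_time", "event"):
        if col not in bundle.metadata.columns:
            raise ValueError(f"metadata missing {col!r} for survival analysis")
    normalized = zscore_within_dataset(bundle, [target_gene])
    target = normalized.loc[target_gene]
    median = float(target.median())
    stratum = np.where(target.to_numpy() > median, "high", "low")
    sero = pd.Series(list(serostatus), index=bundle.expression.columns)
    meta = bundle.metadata.loc[bundle.expression.columns]

    out: dict[str, SurvivalStratumResult] = {}
    for lab in ("high", "low"):
        mask = stratum == lab
        out[lab] = association.km_logrank(
            meta.loc[mask, "survival_time"],
            meta.loc[mask, "event"],
            sero[mask],
        )
    return out
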