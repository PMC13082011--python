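"""Synthetic cohorts with the statistical structure the downstream analyses
assume, under a fixed seed.

Three generators cover the pipeline's inputs:

* :func:`generate_serology_cohort` — a peptide catalog tiling synthetic
  enterovirus/rhinovirus polyproteins (exact three-way partition sizes), an
  epitope-binding-signal matrix (zero-inflated log-normal), diagnosis labels
  from a logistic model with a user-encoded odds ratio per unit of mean
  CE1-VP1 EBS, and exponential survival whose hazard depends on whether the
  individual's CE1-VP1 antibody repertoire breadth exceeds 0.5;
* :func:`generate_ipms_tables` — IP-MS intensity tables for two cell lines
  with background proteins concentrated below the >100 fold-change cutoff and
  spiked surface mimics carrying a query-derived subsequence;
* :func:`generate_expression_cohort` — a tumor expression bundle whose
  target-gene / ADCC-signature rank correlation is controlled per serostatus
  stratum through a Gaussian copula, with NK scores, seroreactivity, and
  stratum-dependent survival.

Identical specs (including seed) give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .alignment import CANONICAL_AA
from .catalog import ChainAnnotation, ChainName, PeptideRecord, assign_groups
from .mimicry import EnrichmentInputs, EpitopeQuery
from .signatures import ADCC_SIGNATURE_GENES, ExpressionBundle

__all__ = [
    "CohortSpec",
    "MimicrySpec",
    "ExpressionSpec",
    "SerologyCohort",
    "IpmsBundle",
    "generate_serology_cohort",
    "generate_ipms_tables",
    "generate_expression_cohort",
]

AA = np.array(list(CANONICAL_AA))
PEPTIDE_LEN = 56          # phage-display tile length
DAYS_HALF_LIFE = 730.0    # baseline median survival ~2 years
BASELINE_HAZARD = math.log(2.0) / DAYS_HALF_LIFE


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


# ---------------------------------------------------------------------------
# Serology cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic serology cohort.

    ``n_peptides_per_group`` are the exact partition sizes
    (CE1-VP1, non-CE1 VP1, non-VP1); defaults follow the published catalog
    (59, 281, 1671) and the three-way split of a ~1,900-subject cohort.
    ``diagnosis_or_per_ebs_unit`` is the odds ratio of HCC per unit of mean
    CE1-VP1 EBS encoded into diagnosis sampling; ``arb_hazard_ratio`` is the
    hazard multiplier for CE1-VP1 ARB <= 0.5 relative to > 0.5.
    ``ebs_location_shift`` is added to the nonzero CE1-VP1 signals of healthy
    individuals after diagnosis sampling.
    """

    n_healthy: int = 640
    n_cld: int = 640
    n_hcc: int = 637
    n_peptides_per_group: tuple[int, int, int] = (59, 281, 1671)
    ebs_location_shift: float = 0.5
    diagnosis_or_per_ebs_unit: float = 0.9
    arb_hazard_ratio: float = 2.0
    censor_rate: float = 0.3
    seed: int = 0
    # responder-structure knobs (see docs/methods.md)
    broad_fraction_ce1: float = 0.6
    broad_fraction_other: float = 0.1
    p_reactive_broad: float = 0.8
    p_reactive_restricted: float = 0.08
    log_mu: float = 1.0
    log_sigma: float = 1.0
    baseline_hazard: float = BASELINE_HAZARD

    def validate(self) -> None:
        _require(self.n_healthy > 0, "n_healthy", "must be > 0")
        _require(self.n_cld > 0, "n_cld", "must be > 0")
        _require(self.n_hcc > 0, "n_hcc", "must be > 0")
        _require(
            len(self.n_peptides_per_group) == 3
            and all(k > 0 for k in self.n_peptides_per_group),
            "n_peptides_per_group", "must be three positive counts",
        )
        _require(self.diagnosis_or_per_ebs_unit > 0,
                 "diagnosis_or_per_ebs_unit", "must be > 0")
        _require(self.arb_hazard_ratio > 0, "arb_hazard_ratio", "must be > 0")
        _require(0.0 <= self.censor_rate <= 1.0, "censor_rate",
                 "must be in [0, 1]")
        _require(0.0 < self.p_reactive_broad <= 1.0, "p_reactive_broad",
                 "must be in (0, 1]")
        _require(0.0 < self.p_reactive_restricted <= 1.0,
                 "p_reactive_restricted", "must be in (0, 1]")
        _require(self.baseline_hazard > 0, "baseline_hazard", "must be > 0")


@dataclass
class SerologyCohort:
    catalog: list[PeptideRecord]
    annotations: list[ChainAnnotation]
    ebs: pd.DataFrame = field(repr=False)           # individuals x peptides
    metadata: pd.DataFrame = field(repr=False)      # diagnosis, survival
    assignments: dict[str, str] = field(repr=False) # peptide -> group label
    spec: CohortSpec | None = None


# synthetic polyprotein architecture (1-based closed intervals)
_CHAIN_LAYOUT = (
    (ChainName.VP4, 1, 69),
    (ChainName.VP2, 70, 330),
    (ChainName.VP3, 331, 568),
    (ChainName.VP1, 569, 869),
    (ChainName.NONSTRUCTURAL, 870, 2190),
)
_CE1_WINDOW = (700, 760)
_N_STRAINS = 5


def _make_annotations() -> list[ChainAnnotation]:
    anns = []
    for s in range(_N_STRAINS):
        acc = f"SYNEV{s + 1:02d}"
        for name, start, end in _CHAIN_LAYOUT:
            if name is ChainName.VP1:
                anns.append(ChainAnnotation(acc, name, start, end,
                                            ce1_start=_CE1_WINDOW[0],
                                            ce1_end=_CE1_WINDOW[1]))
            else:
                anns.append(ChainAnnotation(acc, name, start, end))
    return anns


def _sample_starts(rng, ranges: list[tuple[int, int]], n: int) -> np.ndarray:
    """Uniformly sample n start coordinates from a union of closed ranges."""
    pool = np.concatenate([np.arange(a, b + 1) for a, b in ranges if a <= b])
    return rng.choice(pool, size=n, replace=True)


def _make_catalog(rng, sizes: tuple[int, int, int]) -> list[PeptideRecord]:
    vp1_s, vp1_e = 569, 869
    ce1_s, ce1_e = _CE1_WINDOW
    acc_end = 2190
    L = PEPTIDE_LEN
    specs = [
        # CE1-VP1: start anywhere the tile overlaps the CE1 window
        ("CE1", [(ce1_s - L + 1, ce1_e)]),
        # non-CE1 VP1: overlaps VP1 but misses the CE1 window entirely
        ("VP1", [(vp1_s - L + 1, ce1_s - L), (ce1_e + 1, vp1_e)]),
        # non-VP1: wholly before or after VP1
        ("NSP", [(1, vp1_s - L - 1), (vp1_e + 1, acc_end - L + 1)]),
    ]
    peptides: list[PeptideRecord] = []
    idx = 0
    for (tag, ranges), n in zip(specs, sizes):
        starts = _sample_starts(rng, ranges, n)
        accs = rng.integers(0, _N_STRAINS, size=n)
        for k in range(n):
            idx += 1
            acc = f"SYNEV{accs[k] + 1:02d}"
            peptides.append(
                PeptideRecord(
                    peptide_id=f"EVRV_{idx:06d}",
                    accession=acc,
                    start=int(starts[k]),
                    end=int(starts[k]) + L - 1,
                    strain=f"strain_{acc}",
                )
            )
    return peptides


def _zero_inflated_lognormal(rng, shape, p_reactive, mu, sigma):
    mask = rng.random(shape) < p_reactive
    vals = rng.lognormal(mean=mu, sigma=sigma, size=shape)
    return np.where(mask, vals, 0.0)


def _solve_intercept(x: np.ndarray, beta: float, prevalence: float) -> float:
    def mean_prob(a):
        return float(expit(a + beta * x).mean()) - prevalence

    return brentq(mean_prob, -50.0, 50.0)


def _normalized_entropy(block: np.ndarray) -> np.ndarray:
    """Row-wise ARB of a non-negative matrix; NaN when a row sums to 0."""
    totals = block.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = block / totals[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        arb = -plogp.sum(axis=1) / math.log(block.shape[1])
    arb[totals == 0] = np.nan
    return arb


def _censor(rng, t_event: np.ndarray, hazard: np.ndarray,
            censor_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Independent exponential censoring calibrated to the target rate."""
    if censor_rate <= 0:
        return t_event, np.ones_like(t_event)
    if censor_rate >= 1:
        c = rng.exponential(scale=1.0 / hazard.mean() * 1e-6, size=len(t_event))
        return np.minimum(t_event, c), (t_event <= c).astype(float)
    lam = float(hazard.mean())
    mu = lam * censor_rate / (1.0 - censor_rate)
    c = rng.exponential(scale=1.0 / mu, size=len(t_event))
    return np.minimum(t_event, c), (t_event <= c).astype(float)


def generate_serology_cohort(spec: CohortSpec) -> SerologyCohort:
    """Generate a peptide catalog plus EBS matrix with encoded effects.

    The returned catalog partitions exactly into ``spec.n_peptides_per_group``
    under :func:`mimiscan.catalog.assign_groups`.  Diagnosis labels follow a
    logistic model in mean CE1-VP1 EBS whose slope encodes
    ``diagnosis_or_per_ebs_unit`` (intercept solved to hit the requested HCC
    prevalence); among non-HCC subjects, healthy vs chronic-liver-disease
    labels follow the requested ratio.  Survival (HCC subjects only) is
    exponential with hazard ``baseline_hazard * arb_hazard_ratio`` when the
    realized CE1-VP1 ARB is <= 0.5 (or undefined) and ``baseline_hazard``
    otherwise, with independent exponential censoring.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    annotations = _make_annotations()
    catalog = _make_catalog(rng, tuple(spec.n_peptides_per_group))
    assignments = {
        pid: grp.value
        for pid, grp in assign_groups(catalog, annotations).items()
    }

    n = spec.n_healthy + spec.n_cld + spec.n_hcc
    n_ce1, n_vp1, n_nsp = spec.n_peptides_per_group
    individuals = [f"IND_{i + 1:05d}" for i in range(n)]

    # responder types: broad responders react to most peptides of a group
    broad_ce1 = rng.random(n) < spec.broad_fraction_ce1
    broad_other = rng.random(n) < spec.broad_fraction_other
    p_ce1 = np.where(broad_ce1, spec.p_reactive_broad,
                     spec.p_reactive_restricted)
    p_oth = np.where(broad_other, spec.p_reactive_broad,
                     spec.p_reactive_restricted)

    ce1_block = _zero_inflated_lognormal(
        rng, (n, n_ce1), p_ce1[:, None], spec.log_mu, spec.log_sigma)
    vp1_block = _zero_inflated_lognormal(
        rng, (n, n_vp1), p_oth[:, None], spec.log_mu, spec.log_sigma)
    nsp_block = _zero_inflated_lognormal(
        rng, (n, n_nsp), p_oth[:, None], spec.log_mu, spec.log_sigma)

    # diagnosis from logistic model on mean CE1-VP1 EBS (pre-shift)
    x = ce1_block.mean(axis=1)
    beta = math.log(spec.diagnosis_or_per_ebs_unit)
    prevalence = spec.n_hcc / n
    alpha = _solve_intercept(x, beta, prevalence)
    is_hcc = rng.random(n) < expit(alpha + beta * x)
    p_healthy = spec.n_healthy / (spec.n_healthy + spec.n_cld)
    is_healthy = (~is_hcc) & (rng.random(n) < p_healthy)
    diagnosis = np.where(is_hcc, "HCC", np.where(is_healthy, "healthy", "CLD"))

    # healthy individuals' CE1 reactivity is location-shifted (nonzero mass)
    if spec.ebs_location_shift != 0.0:
        shift_rows = diagnosis == "healthy"
        block = ce1_block[shift_rows]
        ce1_block[shift_rows] = np.where(
            block > 0, np.maximum(block + spec.ebs_location_shift, 0.0), 0.0)

    # survival for HCC subjects, hazard keyed to realized CE1-VP1 ARB > 0.5
    arb = _normalized_entropy(ce1_block)
    low_breadth = ~(arb > 0.5)  # undefined ARB counts as low breadth
    hazard = np.where(low_breadth,
                      spec.baseline_hazard * spec.arb_hazard_ratio,
                      spec.baseline_hazard)
    t_event = rng.exponential(scale=1.0 / hazard, size=n)
    time, event = _censor(rng, t_event, hazard, spec.censor_rate)
    time = np.where(is_hcc, time, np.nan)
    event = np.where(is_hcc, event, np.nan)

    peptide_ids = [p.peptide_id for p in catalog]
    ebs = pd.DataFrame(
        np.hstack([ce1_block, vp1_block, nsp_block]),
        index=pd.Index(individuals, name="individual_id"),
        columns=peptide_ids,
    )
    metadata = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "survival_time": time,
            "event": event,
        },
        index=pd.Index(individuals, name="individual_id"),
    )
    return SerologyCohort(
        catalog=catalog,
        annotations=annotations,
        ebs=ebs,
        metadata=metadata,
        assignments=assignments,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# IP-MS tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MimicrySpec:
    """Parameters of a synthetic IP-MS screen.

    Background proteins carry fold changes concentrated below the >100
    enrichment cutoff; ``n_spiked_surface_mimics`` proteins carry a planted
    query-derived subsequence (``mimic_identity_fraction`` of query residues
    identical), appear in the surface list, and are enriched at
    ``enrichment_fold_spiked`` in every table.
    """

    n_background_proteins: int = 250
    n_spiked_surface_mimics: int = 1
    mimic_identity_fraction: float = 0.8
    enrichment_fold_spiked: float = 500.0
    intensity_noise_cv: float = 0.1
    seed: int = 0
    background_surface_fraction: float = 0.1
    sticky_background_fraction: float = 0.05
    protein_length_range: tuple[int, int] = (300, 800)

    def validate(self) -> None:
        _require(self.n_background_proteins > 0, "n_background_proteins",
                 "must be > 0")
        _require(self.n_spiked_surface_mimics >= 0, "n_spiked_surface_mimics",
                 "must be >= 0")
        _require(0.0 < self.mimic_identity_fraction <= 1.0,
                 "mimic_identity_fraction", "must be in (0, 1]")
        _require(self.enrichment_fold_spiked > 0, "enrichment_fold_spiked",
                 "must be > 0")
        _require(self.intensity_noise_cv >= 0, "intensity_noise_cv",
                 "must be >= 0")
        _require(0.0 <= self.background_surface_fraction <= 1.0,
                 "background_surface_fraction", "must be in [0, 1]")
        _require(0.0 <= self.sticky_background_fraction <= 1.0,
                 "sticky_background_fraction", "must be in [0, 1]")


@dataclass
class IpmsBundle:
    inputs: EnrichmentInputs
    sequences: dict[str, str] = field(repr=False)
    surface_list: list[str] = field(default_factory=list)
    mimic_ids: list[str] = field(default_factory=list)
    spec: MimicrySpec | None = None


def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def _plant_mimic(rng, protein: str, query: str, identity_fraction: float) -> str:
    """Embed a query-derived subsequence at a uniform internal offset."""
    L = len(query)
    n_keep = int(round(identity_fraction * L))
    if n_keep == 0:
        raise ValueError(
            "mimic_identity_fraction: produces an empty mimic subsequence"
        )
    mutate = rng.choice(L, size=L - n_keep, replace=False)
    planted = list(query)
    for pos in mutate:
        choices = [a for a in CANONICAL_AA if a != query[pos]]
        planted[pos] = choices[rng.integers(0, len(choices))]
    offset = int(rng.integers(1, len(protein) - L))  # internal placement
    return protein[:offset] + "".join(planted) + protein[offset + L:]


def generate_ipms_tables(
    spec: MimicrySpec,
    query: EpitopeQuery,
    *,
    cell_lines: Sequence[str] = ("Huh7", "HLE"),
    antibodies: Sequence[str] = ("rB9", "rB10"),
) -> IpmsBundle:
    """Generate IP-MS intensity tables, FASTA-ready sequences, surface list.

    Control intensities are log-normal around 1e5; target intensity is
    control x fold-change x multiplicative log-normal noise (CV
    ``intensity_noise_cv``).  Background fold changes are log-normal with
    median ~2 (a small "sticky" fraction is enriched in all tables,
    emulating non-surface high binders); spiked mimics use
    ``enrichment_fold_spiked`` everywhere.
    """
    spec.validate()
    if len(query.sequence) >= min(spec.protein_length_range):
        raise ValueError("protein_length_range: proteins shorter than query")
    rng = np.random.default_rng(spec.seed)

    n_bg = spec.n_background_proteins
    n_mim = spec.n_spiked_surface_mimics
    bg_ids = [f"B{k + 1:05d}" for k in range(n_bg)]
    mim_ids = [f"M{k + 1:05d}" for k in range(n_mim)]
    all_ids = bg_ids + mim_ids

    lengths = rng.integers(spec.protein_length_range[0],
                           spec.protein_length_range[1] + 1,
                           size=len(all_ids))
    sequences = {pid: _random_protein(rng, int(lng))
                 for pid, lng in zip(all_ids, lengths)}
    for pid in mim_ids:
        sequences[pid] = _plant_mimic(
            rng, sequences[pid], query.sequence, spec.mimic_identity_fraction)

    sticky = rng.random(n_bg) < spec.sticky_background_fraction
    surface_bg = [pid for pid in bg_ids
                  if rng.random() < spec.background_surface_fraction]
    surface_list = sorted(surface_bg + mim_ids)

    sigma_noise = math.sqrt(math.log(1.0 + spec.intensity_noise_cv**2))
    tables: dict[str, pd.DataFrame] = {}
    for line in cell_lines:
        control = rng.lognormal(mean=math.log(1e5), sigma=1.0,
                                size=len(all_ids))
        cols = {"control": control}
        for ab in antibodies:
            fc_bg = rng.lognormal(mean=math.log(2.0), sigma=1.0, size=n_bg)
            fc_bg = np.where(sticky,
                             rng.lognormal(mean=math.log(500.0), sigma=0.3,
                                           size=n_bg),
                             fc_bg)
            fc = np.concatenate(
                [fc_bg, np.full(n_mim, spec.enrichment_fold_spiked)])
            noise = (rng.lognormal(mean=0.0, sigma=sigma_noise,
                                   size=len(all_ids))
                     if sigma_noise > 0 else np.ones(len(all_ids)))
            cols[ab] = control * fc * noise
        tables[line] = pd.DataFrame(cols, index=pd.Index(all_ids,
                                                         name="protein"))
    return IpmsBundle(
        inputs=EnrichmentInputs(tables=tables),
        sequences=sequences,
        surface_list=surface_list,
        mimic_ids=mim_ids,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Expression cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSpec:
    """Parameters of a synthetic tumor-expression cohort.

    ``adcc_asph_rho_pos`` / ``adcc_asph_rho_neg`` are the target Spearman
    correlations between the target gene and the ADCC signature score in the
    seropositive / seronegative strata (Gaussian copula).
    ``sero_benefit_hr_high`` multiplies the hazard of seronegative patients
    within the target-gene-high stratum (``sero_benefit_hr_low`` likewise in
    the low stratum; 1.0 = no benefit).
    """

    n_tumors: int = 97
    n_seropositive: int = 48
    adcc_asph_rho_pos: float = 0.5
    adcc_asph_rho_neg: float = 0.0
    nk_high_fraction_pos: float = 0.5
    nk_high_fraction_neg: float = 0.2
    seed: int = 0
    n_datasets: int = 2
    n_background_genes: int = 30
    signature_noise_sd: float = 0.5
    sero_benefit_hr_high: float = 2.0
    sero_benefit_hr_low: float = 1.0
    censor_rate: float = 0.3
    baseline_hazard: float = BASELINE_HAZARD

    def validate(self) -> None:
        _require(self.n_tumors > 1, "n_tumors", "must be > 1")
        _require(0 <= self.n_seropositive <= self.n_tumors, "n_seropositive",
                 f"must be in [0, n_tumors={self.n_tumors}]")
        _require(-1.0 <= self.adcc_asph_rho_pos <= 1.0, "adcc_asph_rho_pos",
                 "must be in [-1, 1]")
        _require(-1.0 <= self.adcc_asph_rho_neg <= 1.0, "adcc_asph_rho_neg",
                 "must be in [-1, 1]")
        _require(0.0 <= self.nk_high_fraction_pos <= 1.0,
                 "nk_high_fraction_pos", "must be in [0, 1]")
        _require(0.0 <= self.nk_high_fraction_neg <= 1.0,
                 "nk_high_fraction_neg", "must be in [0, 1]")
        _require(self.n_datasets >= 1, "n_datasets", "must be >= 1")
        _require(0.0 <= self.censor_rate <= 1.0, "censor_rate",
                 "must be in [0, 1]")
        _require(self.sero_benefit_hr_high > 0, "sero_benefit_hr_high",
                 "must be > 0")
        _require(self.sero_benefit_hr_low > 0, "sero_benefit_hr_low",
                 "must be > 0")


def _pearson_for_spearman(rho_s: float) -> float:
    """Bivariate-normal Pearson r achieving Spearman rho_s (Pearson 1907)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_expression_cohort(spec: ExpressionSpec) -> ExpressionBundle:
    """Generate an expression bundle with controlled stratified correlation.

    The target gene (ASPH) and a latent ADCC axis are drawn from a Gaussian
    copula whose Pearson parameter is chosen so the population Spearman
    correlation equals the requested value within each serostatus stratum;
    each signature gene is the latent axis plus independent noise.  Raw
    expression receives dataset-specific location/scale so within-dataset
    Z-scoring is exercised.  NK scores straddle the 0.01 cutoff with
    stratum-specific high fractions; survival hazards implement a
    serostatus benefit confined to the requested target-gene stratum.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tumors
    n_pos = spec.n_seropositive
    samples = [f"TUM_{i + 1:04d}" for i in range(n)]
    seropositive = np.zeros(n, dtype=bool)
    seropositive[:n_pos] = True
    order = rng.permutation(n)
    seropositive = seropositive[order]

    # copula draw per stratum
    z_target = np.empty(n)
    z_latent = np.empty(n)
    for mask, rho_s in ((seropositive, spec.adcc_asph_rho_pos),
                        (~seropositive, spec.adcc_asph_rho_neg)):
        k = int(mask.sum())
        if k == 0:
            continue
        r = _pearson_for_spearman(rho_s)
        z1 = rng.standard_normal(k)
        if abs(r) >= 1.0 - 1e-12:
            z2 = math.copysign(1.0, r) * z1
        else:
            z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.standard_normal(k)
        z_target[mask] = z1
        z_latent[mask] = z2

    genes = [ "ASPH", *ADCC_SIGNATURE_GENES,
              *[f"BGGENE{k + 1:03d}" for k in range(spec.n_background_genes)] ]
    raw = np.empty((len(genes), n))
    raw[0] = z_target
    for g in range(len(ADCC_SIGNATURE_GENES)):
        raw[1 + g] = z_latent + rng.normal(0.0, spec.signature_noise_sd, size=n)
    for g in range(spec.n_background_genes):
        raw[1 + len(ADCC_SIGNATURE_GENES) + g] = rng.normal(0.0, 1.0, size=n)

    # dataset-of-origin labels and per-(gene, dataset) affine distortions
    ds_labels = np.array(
        [f"set{(i % spec.n_datasets) + 1}" for i in range(n)])
    for d in range(spec.n_datasets):
        cols = ds_labels == f"set{d + 1}"
        shift = rng.normal(0.0, 2.0, size=(len(genes), 1))
        scale = rng.lognormal(0.0, 0.3, size=(len(genes), 1))
        raw[:, cols] = raw[:, cols] * scale + shift

    # NK scores straddling the 0.01 cutoff
    p_high = np.where(seropositive, spec.nk_high_fraction_pos,
                      spec.nk_high_fraction_neg)
    nk_high = rng.random(n) < p_high
    nk = np.where(nk_high,
                  rng.uniform(0.015, 0.3, size=n),
                  rng.uniform(0.0, 0.009, size=n))

    sero_score = np.where(seropositive,
                          rng.lognormal(0.0, 0.5, size=n) + 0.5, 0.0)

    # survival: serostatus benefit confined to one target-gene stratum;
    # the split matches the downstream within-dataset-Z median rule
    z_within = np.empty(n)
    for d in range(spec.n_datasets):
        cols = ds_labels == f"set{d + 1}"
        vals = raw[0, cols]
        z_within[cols] = (vals - vals.mean()) / vals.std(ddof=1)
    high = z_within > np.median(z_within)
    hr = np.where(high,
                  np.where(seropositive, 1.0, spec.sero_benefit_hr_high),
                  np.where(seropositive, 1.0, spec.sero_benefit_hr_low))
    hazard = spec.baseline_hazard * hr
    t_event = rng.exponential(scale=1.0 / hazard, size=n)
    time, event = _censor(rng, t_event, hazard, spec.censor_rate)

    expression = pd.DataFrame(raw, index=pd.Index(genes, name="gene"),
                              columns=samples)
    metadata = pd.DataFrame(
        {
            "dataset": ds_labels,
            "nk_score": nk,
            "ce1_seroreactivity": sero_score,
            "seropositive": seropositive,
            "survival_time": time,
            "event": event,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionBundle(expression=expression, metadata=metadata)


def spec_to_dict(spec) -> dict:
    """JSON-serializable record of a generator spec (for sidecar files)."""
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
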