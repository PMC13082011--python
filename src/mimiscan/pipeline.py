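"""End-to-end orchestration: simulate (or load) -> partition -> repertoire ->
association -> mimicry -> signatures, from a single YAML/JSON config.

The config has one block per data stream; each stream carries exactly one of
a ``simulate`` spec or a ``paths`` mapping.  Unknown keys are rejected before
any stage runs.  With fixed seeds, reruns reproduce every output file
byte-identically (the run log, which records wall-clock times, is the one
exception; the machine-readable ``run_report.json`` omits timings for this
reason — they are logged instead).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, io, mimicry, repertoire, signatures, synthdata
from .catalog import (PeptideGroup, assign_groups, read_annotations_tsv,
                      read_catalog_tsv, write_assignments_tsv)
from .mimicry import CE1_QUERY_SEQUENCE, EpitopeQuery

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "StageRecord", "run_pipeline",
           "load_config", "default_demo_config"]

_TOP_KEYS = {"seed", "outdir", "serology", "mimicry", "expression",
             "repertoire", "association"}
_STREAM_KEYS = {"simulate", "paths"}


@dataclass
class StageRecord:
    name: str
    parameters: dict
    n_in: int
    n_out: int
    warnings: list[str] = field(default_factory=list)
    elapsed_seconds: float = 0.0
    status: str = "ok"


@dataclass
class RunReport:
    stages: list[StageRecord] = field(default_factory=list)
    exit_status: str = "ok"

    def to_dict(self, *, include_elapsed: bool = True) -> dict:
        stages = []
        for s in self.stages:
            d = dataclasses.asdict(s)
            if not include_elapsed:
                d.pop("elapsed_seconds")
            stages.append(d)
        return {"stages": stages, "exit_status": self.exit_status}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    raw: dict
    outdir: Path
    seed: int

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        unknown = set(cfg) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in cfg:
            raise ValueError("config missing required key 'outdir'")
        for stream in ("serology", "mimicry", "expression"):
            block = cfg.get(stream)
            if block is None:
                continue
            stream_keys = set(block) & _STREAM_KEYS
            if len(stream_keys) != 1:
                raise ValueError(
                    f"stream {stream!r}: exactly one of 'simulate' or "
                    f"'paths' required, got {sorted(stream_keys) or 'neither'}"
                )
            extra = set(block) - _STREAM_KEYS - _STREAM_EXTRA.get(stream, set())
            if extra:
                raise ValueError(f"stream {stream!r}: unknown keys {sorted(extra)}")
        return cls(raw=cfg, outdir=Path(cfg["outdir"]),
                   seed=int(cfg.get("seed", 0)))


_STREAM_EXTRA = {
    "mimicry": {"query", "cutoff", "antibody_mode", "cell_line_mode",
                "strip_leading_cys"},
}


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config file (YAML parses JSON as a subset)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path}: expected a mapping at top level")
    return RunConfig.from_dict(cfg)


def default_demo_config(outdir, seed: int = 7) -> RunConfig:
    """A small pure-simulation demo config exercising all six stages."""
    return RunConfig.from_dict(
        {
            "seed": seed,
            "outdir": str(outdir),
            "serology": {
                "simulate": {
                    "n_healthy": 60, "n_cld": 60, "n_hcc": 80,
                    "n_peptides_per_group": [20, 40, 100],
                    "censor_rate": 0.2,
                }
            },
            "mimicry": {
                "simulate": {"n_background_proteins": 60,
                             "n_spiked_surface_mimics": 1},
            },
            "expression": {
                "simulate": {"n_tumors": 120, "n_seropositive": 60,
                             "adcc_asph_rho_pos": 0.7},
            },
            "repertoire": {"panel_k": 10, "seropositivity_threshold": 0.0},
        }
    )


def _stage(report: RunReport, name: str, params: dict):
    record = StageRecord(name=name, parameters=params, n_in=0, n_out=0)

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return record

        def __exit__(self, exc_type, exc, tb):
            record.elapsed_seconds = time.perf_counter() - self.t0
            if exc_type is not None:
                record.status = f"failed: {exc}"
                report.exit_status = "failed"
            report.stages.append(record)
            logger.info("stage %s: %s (%.2fs, %d -> %d records)",
                        name, record.status, record.elapsed_seconds,
                        record.n_in, record.n_out)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all configured stages in dependency order.

    A stage failure aborts downstream stages, is recorded in the report, and
    re-raised after the report is written.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("mimiscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    report = RunReport()
    try:
        _run_stages(config, outdir, report)
    finally:
        (outdir / "run_report.json").write_text(
            json.dumps(report.to_dict(include_elapsed=False), indent=2) + "\n")
        root.removeHandler(handler)
        handler.close()
    return report


def _run_stages(config: RunConfig, outdir: Path, report: RunReport) -> None:
    cfg = config.raw
    rep_cfg = cfg.get("repertoire", {})
    panel_k = int(rep_cfg.get("panel_k", repertoire.DEFAULT_PANEL_SIZE))
    sero_thresh = float(rep_cfg.get("seropositivity_threshold", 0.0))

    # ---- stage 1: serology inputs -------------------------------------
    sero_block = cfg.get("serology")
    cohort = None
    with _stage(report, "serology_inputs", sero_block or {}) as rec:
        if sero_block is None:
            raise ValueError("config missing 'serology' stream")
        if "simulate" in sero_block:
            params = dict(sero_block["simulate"])
            params.setdefault("seed", config.seed)
            if "n_peptides_per_group" in params:
                params["n_peptides_per_group"] = tuple(
                    params["n_peptides_per_group"])
            spec = synthdata.CohortSpec(**params)
            cohort = synthdata.generate_serology_cohort(spec)
            io.write_serology_cohort(cohort, outdir / "inputs")
            catalog, annotations = cohort.catalog, cohort.annotations
            ebs, meta = cohort.ebs, cohort.metadata
        else:
            paths = sero_block["paths"]
            catalog = read_catalog_tsv(_expect_path(paths, "catalog"))
            annotations = read_annotations_tsv(_expect_path(paths, "annotations"))
            ebs = io.read_ebs_tsv(_expect_path(paths, "ebs"))
            meta = pd.read_csv(_expect_path(paths, "metadata"), sep="\t",
                               index_col=0)
        rec.n_in = 0
        rec.n_out = len(ebs)

    # ---- stage 2: partition -------------------------------------------
    with _stage(report, "partition", {}) as rec:
        rec.n_in = len(catalog)
        groups = assign_groups(catalog, annotations)
        write_assignments_tsv(groups, outdir / "peptide_groups.tsv")
        rec.n_out = len(groups)
        sizes = pd.Series([g.value for g in groups.values()]).value_counts()
        logger.info("partition sizes: %s", sizes.to_dict())

    # ---- stage 3: repertoire ------------------------------------------
    with _stage(report, "repertoire", {"panel_k": panel_k,
                                       "seropositivity_threshold": sero_thresh}) as rec:
        rec.n_in = len(ebs)
        summary = repertoire.group_ebs_summary(ebs, groups)
        arb_results = repertoire.compute_arb(ebs, groups, PeptideGroup.CE1_VP1)
        arb = pd.Series({r.individual_id: r.arb for r in arb_results})
        n_undef = int(arb.isna().sum())
        if n_undef:
            rec.warnings.append(f"{n_undef} individuals with undefined ARB")
        ce1_peps = [p for p, g in groups.items()
                    if g is PeptideGroup.CE1_VP1]
        sero = repertoire.ce1_seroreactivity(
            ebs, ce1_peps, k=panel_k, positivity_threshold=sero_thresh,
            data_driven=True)
        rep_table = summary.copy()
        rep_table["arb_ce1_vp1"] = arb
        rep_table["arb_above_0.5"] = arb > 0.5
        rep_table["ce1_seroreactivity"] = pd.Series(
            {s.individual_id: s.score for s in sero})
        rep_table["seropositive"] = pd.Series(
            {s.individual_id: s.seropositive for s in sero})
        rep_table.to_csv(outdir / "repertoire.tsv", sep="\t",
                         float_format="%.6g")
        rec.n_out = len(rep_table)

    # ---- stage 4: association -----------------------------------------
    with _stage(report, "association", {}) as rec:
        rec.n_in = len(rep_table)
        results: dict[str, object] = {}
        is_hcc = (meta["diagnosis"] == "HCC").astype(float)
        fit = association.fit_diagnosis_logistic(
            rep_table["CE1_VP1"].to_numpy(), is_hcc.to_numpy())
        results["diagnosis_logistic"] = {
            "odds_ratio_per_unit": fit.odds_ratio,
            "odds_ratio_per_sd": fit.odds_ratio_per_sd,
            "p_value": fit.p_value,
            "converged": fit.converged,
            "n_used": fit.n_used,
        }
        t = association.compare_group_means(
            rep_table["CE1_VP1"].to_numpy(), rep_table["NON_CE1_VP1"].to_numpy())
        results["ce1_vs_nonce1_ttest"] = {
            "t": t.statistic, "p_value": t.p_value, "mean_diff": t.mean_diff}
        defined = rep_table["arb_ce1_vp1"].notna()
        cats = rep_table.loc[defined, "arb_ce1_vp1"].map(repertoire.arb_category)
        tab = pd.crosstab(meta.loc[defined.index[defined], "diagnosis"], cats)
        chi = association.arb_category_chisq(tab.to_numpy())
        results["arb_category_chisq"] = {
            "statistic": chi.statistic, "df": chi.df, "p_value": chi.p_value}
        hcc_mask = (meta["diagnosis"] == "HCC") & defined
        surv = association.km_logrank(
            meta.loc[hcc_mask, "survival_time"],
            meta.loc[hcc_mask, "event"],
            np.where(rep_table.loc[hcc_mask, "arb_ce1_vp1"] > 0.5,
                     "ARB>0.5", "ARB<=0.5"))
        results["arb_survival_logrank"] = {
            "statistic": surv.logrank_statistic, "p_value": surv.logrank_p,
            "n_per_stratum": surv.n_per_stratum}
        (outdir / "association_results.json").write_text(
            json.dumps(results, indent=2, default=float) + "\n")
        rec.n_out = len(results)

    # ---- stage 5: mimicry ---------------------------------------------
    mim_block = cfg.get("mimicry")
    with _stage(report, "mimicry", mim_block or {}) as rec:
        if mim_block is None:
            raise ValueError("config missing 'mimicry' stream")
        query = EpitopeQuery(mim_block.get("query", CE1_QUERY_SEQUENCE),
                             name="CE1")
        if mim_block.get("strip_leading_cys", False):
            query = query.stripped()
        if "simulate" in mim_block:
            params = dict(mim_block["simulate"])
            params.setdefault("seed", config.seed)
            mspec = synthdata.MimicrySpec(**params)
            bundle = synthdata.generate_ipms_tables(mspec, query)
            io.write_ipms_bundle(bundle, outdir / "inputs" / "ipms")
            inputs, sequences, surface = (bundle.inputs, bundle.sequences,
                                          bundle.surface_list)
        else:
            paths = mim_block["paths"]
            inputs = mimicry.EnrichmentInputs(
                tables=io.read_intensity_tables(
                    _expect_path(paths, "intensities_dir")))
            sequences = io.read_fasta(_expect_path(paths, "fasta"))
            surface = io.read_surface_list(_expect_path(paths, "surface"))
        rec.n_in = len(inputs.proteins)
        funnel = mimicry.run_mimicry_funnel(
            inputs, surface, sequences, query,
            cutoff=float(mim_block.get("cutoff", mimicry.FOLD_CHANGE_CUTOFF)),
            cell_line_mode=mim_block.get("cell_line_mode", "all"),
            antibody_mode=mim_block.get("antibody_mode", "any"))
        ranked = funnel.ranking.drop(columns=["report"])
        ranked.to_csv(outdir / "mimicry_ranking.tsv", sep="\t", index=False,
                      float_format="%.6g")
        with open(outdir / "mimicry_alignments.txt", "w") as fh:
            for rep_ in funnel.ranking["report"]:
                fh.write(f"> {rep_.candidate_id} raw={rep_.raw_score} "
                         f"E={rep_.expect:.3g}\n{rep_.pretty()}\n\n")
        rec.parameters = {**rec.parameters,
                          "stage_counts": funnel.stage_counts}
        rec.n_out = len(ranked)

    # ---- stage 6: signatures ------------------------------------------
    expr_block = cfg.get("expression")
    with _stage(report, "signatures", expr_block or {}) as rec:
        if expr_block is None:
            raise ValueError("config missing 'expression' stream")
        if "simulate" in expr_block:
            params = dict(expr_block["simulate"])
            params.setdefault("seed", config.seed)
            espec = synthdata.ExpressionSpec(**params)
            bundle = synthdata.generate_expression_cohort(espec)
            (outdir / "inputs").mkdir(exist_ok=True)
            bundle.expression.to_csv(outdir / "inputs" / "expression.tsv",
                                     sep="\t", float_format="%.6g")
            bundle.metadata.to_csv(outdir / "inputs" / "expression_meta.tsv",
                                   sep="\t", float_format="%.6g")
        else:
            paths = expr_block["paths"]
            bundle = signatures.ExpressionBundle(
                expression=pd.read_csv(_expect_path(paths, "expression"),
                                       sep="\t", index_col=0),
                metadata=pd.read_csv(_expect_path(paths, "metadata"),
                                     sep="\t", index_col=0))
        rec.n_in = len(bundle.samples)
        sero_labels = np.where(bundle.metadata["seropositive"].astype(bool),
                               "seropositive", "seronegative")
        nk_labels = signatures.nk_stratify(bundle.metadata["nk_score"])
        chi = signatures.serostatus_nk_chisq(nk_labels.to_numpy(), sero_labels)
        spearman = signatures.stratified_asph_adcc(bundle, sero_labels)
        surv = signatures.asph_sero_survival(bundle, sero_labels)
        sig_results = {
            "nk_serostatus_chisq": {"statistic": chi.statistic,
                                    "p_value": chi.p_value},
            "asph_adcc_spearman": {
                r.stratum: {"rho": r.rho, "p_value": r.p_value, "n": r.n}
                for r in spearman},
            "asph_sero_survival": {
                lab: {"logrank_p": res.logrank_p,
                      "n_per_stratum": res.n_per_stratum}
                for lab, res in surv.items()},
        }
        (outdir / "signature_results.json").write_text(
            json.dumps(sig_results, indent=2, default=float) + "\n")
        rec.n_out = len(sig_results)


def _expect_path(paths: dict, key: str) -> Path:
    if key not in paths:
        raise ValueError(f"paths block missing required key {key!r}")
    p = Path(paths[key])
    if not p.exists():
        raise FileNotFoundError(f"input path for {key!r} not found: {p}")
    return p
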