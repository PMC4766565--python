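"""Configured, logged, reproducible orchestration of the full analysis.

Stages: acquire (simulate or load) → phenotype derivation → genotype QC →
ancestry PCA → GRS construction → model fitting (three tiers + pleiotropy
check) → reports. Identical config + seed produces byte-identical tabular
artifacts; timestamps are confined to the run manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import genetics as gen
from . import models as mod
from . import phenotypes as ph
from .simulate import SimConfig, SnpSpec, simulate_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

STAGES = ("acquire", "derive", "qc", "pca", "grs", "fit", "report")

EXPOSURES = ("sbp", "dbp", "map")
PLEIO_CONFOUNDERS = ("total_cholesterol", "glucose", "creatinine")


class PipelineError(RuntimeError):
    """A stage failure with a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = "") -> None:
        self.stage = stage
        self.hint = hint
        text = f"[stage {stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)


@dataclass
class RunConfig:
    """Declarative run configuration.

    Exactly one of the simulation block or the input paths must be given.
    Every protocol threshold is a named key defaulting to the study value:
    QC (call rate 0.95, MAF 0.001, HWE p 1e-6), candidate window ±100 kb,
    5 ancestry PCs, β per 10 mmHg, diabetes glucose 11.1 mmol/L, repeat-
    reading thresholds 10/5 mmHg.
    """

    simulate: SimConfig | None = None
    phenotype_csv: str | None = None
    genotype_path: str | None = None
    panel_path: str | None = None
    qc_call_rate: float = 0.95
    qc_maf: float = 0.001
    qc_hwe_p: float = 1e-6
    hwe_method: str = "chisq"
    grs_window_kb: float = 100.0
    grs_missing_policy: str = "impute"
    grs_weight_mode: str = "in_sample"  # in_sample | split_sample
    n_pcs: int = 5
    scale_per: float = 10.0
    model3_mode: str = "meta"  # meta | pooled
    model2_covariates: str = "methods"  # methods | footnote
    meta_method: str = "fixed"
    weak_f_threshold: float = 10.0
    knudtson_arteriole: float = ph.KNUDTSON_ARTERIOLE
    knudtson_venule: float = ph.KNUDTSON_VENULE
    diabetes_glucose: float = ph.DIABETES_GLUCOSE_MMOL
    out_dir: str = "bpmr_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = any((self.phenotype_csv, self.genotype_path))
        if self.simulate is not None and has_paths:
            raise ValueError("config must give either a simulation block or "
                             "input paths, not both")
        if self.simulate is None and not (self.phenotype_csv and self.genotype_path):
            raise ValueError("config needs a simulation block or both "
                             "phenotype_csv and genotype_path")
        if not 0 < self.qc_call_rate <= 1:
            raise ValueError("qc_call_rate must be in (0,1]")
        if not 0 <= self.qc_maf < 0.5:
            raise ValueError("qc_maf must be in [0,0.5)")
        if not 0 < self.qc_hwe_p < 1:
            raise ValueError("qc_hwe_p must be in (0,1)")
        if self.grs_weight_mode not in ("in_sample", "split_sample"):
            raise ValueError(f"unknown grs_weight_mode {self.grs_weight_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            sim = dict(sim)
            panel = sim.pop("snp_panel", None)
            if panel is not None:
                sim["snp_panel"] = tuple(
                    SnpSpec(**{**e, "freq": dict(e["freq"])}) for e in panel
                )
            for tup_key in ("strata", "unmeasured_loadings"):
                if tup_key in sim:
                    sim[tup_key] = tuple(sim[tup_key])
            if "confounder_effects" in sim:
                sim["confounder_effects"] = {
                    k: tuple(v) for k, v in sim["confounder_effects"].items()
                }
            cfg.simulate = SimConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _acquire(config: RunConfig) -> tuple[pd.DataFrame, gen.GenotypeMatrix, dict | None]:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        bundle = simulate_cohort(sim)
        return bundle.participants, bundle.genotypes, bundle.truth
    try:
        raw = pd.read_csv(config.phenotype_csv)
    except OSError as e:
        raise PipelineError("acquire", f"cannot read phenotype CSV: {e}",
                            "check phenotype_csv path") from e
    panel = gen.read_panel(config.panel_path) if config.panel_path else None
    try:
        g = gen.read_genotypes(config.genotype_path, panel=panel)
    except OSError as e:
        raise PipelineError("acquire", f"cannot read genotypes: {e}",
                            "check genotype_path") from e
    ids = raw["participant_id"].astype(str).tolist()
    if set(ids) != set(g.participant_ids):
        raise PipelineError(
            "acquire", "participant IDs differ between phenotype and genotype files",
            "both files must cover the identical participant set",
        )
    order = [g.participant_ids.index(i) for i in ids]
    g = gen.GenotypeMatrix(
        [g.participant_ids[i] for i in order], g.snps, g.dosages[order]
    )
    return raw, g, None


def _make_grs(
    config: RunConfig, data: pd.DataFrame, g: gen.GenotypeMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach grs_sbp/dbp/map columns; returns (analysis data, weight table)."""
    panel_index = [s for s in g.snps if s.locus == s.snp_id]
    stratum_dummies = pd.get_dummies(
        data["stratum"], prefix="stratum", drop_first=True, dtype=float
    )
    window = int(config.grs_window_kb * 1000)
    weight_rows = []
    if config.grs_weight_mode == "split_sample":
        rng = np.random.default_rng(config.seed + 104729)
        train = rng.random(len(data)) < 0.5
        analysis_mask = ~train
    else:
        train = np.ones(len(data), dtype=bool)
        analysis_mask = np.ones(len(data), dtype=bool)
    g_train = gen.GenotypeMatrix(
        [p for p, t in zip(g.participant_ids, train) if t], g.snps, g.dosages[train]
    )
    out = data.copy()
    for exposure in EXPOSURES:
        weights = gen.select_locus_snps(
            g_train,
            data.loc[train, exposure].to_numpy(dtype=float),
            panel_index,
            window_bp=window,
            phenotype=exposure,
            covariates=stratum_dummies.loc[train] if len(stratum_dummies.columns) else None,
        )
        if not weights.entries:
            raise PipelineError(
                "grs", f"no instruments available for {exposure}",
                "relax QC thresholds or provide more candidate SNPs",
            )
        score = gen.compute_grs(g, weights, missing_policy=config.grs_missing_policy)
        out[f"grs_{exposure}"] = score.to_numpy()
        for e in weights.entries:
            weight_rows.append(
                {"phenotype": exposure, "locus": e.locus, "snp_id": e.snp_id,
                 "weight": e.weight, "p_value": e.p_value}
            )
        for locus in weights.dropped_loci:
            weight_rows.append(
                {"phenotype": exposure, "locus": locus, "snp_id": "",
                 "weight": np.nan, "p_value": np.nan}
            )
    return out[analysis_mask].reset_index(drop=True), pd.DataFrame(weight_rows)


def run_pipeline(config: RunConfig, until: str = "report") -> dict:
    """Run the pipeline through ``until`` (default: everything).

    Returns a manifest dict including artifact paths and, for simulated
    runs, a truth-vs-estimate comparison.
    """
    t0 = time.time()
    config.validate()
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    stop = STAGES.index(until)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "versions": _versions(),
        "artifacts": artifacts,
    }

    raw, g, truth = _acquire(config)
    log.info("acquired cohort: %d participants, %d SNPs", len(raw), g.n_snps)
    if stop >= STAGES.index("derive"):
        data = ph.derive_participant_table(
            raw,
            arteriole_constant=config.knudtson_arteriole,
            venule_constant=config.knudtson_venule,
            glucose_threshold=config.diabetes_glucose,
        )
    if stop >= STAGES.index("qc"):
        thr = gen.QcThresholds(
            call_rate=config.qc_call_rate, maf=config.qc_maf, hwe_p=config.qc_hwe_p
        )
        g, qc_report = gen.apply_qc(g, thr, hwe_method=config.hwe_method)
        p = outdir / "qc_report.tsv"
        qc_report.to_csv(p, sep="\t", index=False)
        artifacts["qc_report"] = str(p)
        log.info("QC kept %d SNPs (%d removed)", g.n_snps, int(qc_report.removed.sum()))
        if g.n_snps == 0:
            raise PipelineError(
                "grs", "no instruments: all SNPs removed by QC",
                "inspect qc_report.tsv and relax thresholds if appropriate",
            )
    if stop >= STAGES.index("pca"):
        if g.n_snps < config.n_pcs:
            raise PipelineError(
                "pca", f"{g.n_snps} SNPs cannot support {config.n_pcs} PCs",
                "lower n_pcs or supply more SNPs",
            )
        pca = gen.genotype_pca(g, n_components=config.n_pcs)
        data = pd.concat([data, pca.scores.reset_index(drop=True)], axis=1)
    if stop >= STAGES.index("grs"):
        data, weight_table = _make_grs(config, data, g)
        p = outdir / "grs_weights.tsv"
        weight_table.to_csv(p, sep="\t", index=False)
        artifacts["grs_weights"] = str(p)
        p = outdir / "grs.csv"
        data[["participant_id"] + [f"grs_{e}" for e in EXPOSURES]].to_csv(p, index=False)
        artifacts["grs"] = str(p)
    if stop >= STAGES.index("fit"):
        try:
            results = mod.build_table2(
                data,
                model3_mode=config.model3_mode,
                model2_covariates=config.model2_covariates,
                scale_per=config.scale_per,
                weak_f_threshold=config.weak_f_threshold,
                meta_method=config.meta_method,
            )
        except (ValueError, KeyError) as e:
            raise PipelineError("fit", str(e),
                                "check covariate columns and sample size") from e
        pleio = mod.pleiotropy_check(
            data, [f"grs_{e}" for e in EXPOSURES], list(PLEIO_CONFOUNDERS)
        )
        rt = mod.results_table(results)
        p = outdir / "results.tsv"
        rt.to_csv(p, sep="\t", index=False)
        artifacts["results"] = str(p)
        p = outdir / "pleiotropy.tsv"
        pleio.to_csv(p, sep="\t", index=False)
        artifacts["pleiotropy"] = str(p)
    if stop >= STAGES.index("report"):
        p = outdir / "table2.txt"
        p.write_text(mod.format_table2(results, scale_per=config.scale_per))
        artifacts["table2"] = str(p)
        p = outdir / "table3.txt"
        p.write_text(mod.format_table3(pleio))
        artifacts["table3"] = str(p)
        if truth is not None:
            comparison = _truth_comparison(truth, results, config.scale_per)
            p = outdir / "truth_vs_estimate.json"
            p.write_text(json.dumps(comparison, indent=2, sort_keys=True) + "\n")
            artifacts["truth_vs_estimate"] = str(p)
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = str(p)
    return manifest


def _truth_comparison(truth: dict, results, scale_per: float) -> dict:
    causal_bp = truth["causal_bp"]
    out = {"causal_bp": causal_bp, "scale_per": scale_per}
    for outcome in ("crae", "crve"):
        true_val = truth[f"causal_effect_{outcome}"] * scale_per
        est = [
            r for r in results
            if r.outcome == outcome and r.exposure == causal_bp
            and r.tier == "model3" and r.stratum in ("meta", "pooled")
        ]
        out[outcome] = {
            "true_effect": true_val,
            "mr_estimate": est[0].beta if est else None,
            "mr_ci": [est[0].ci_low, est[0].ci_high] if est else None,
            "covered": bool(est and est[0].ci_low <= true_val <= est[0].ci_high),
        }
    return out


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "bpmr": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
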