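"""Synthetic multi-ethnic cohort generator with known causal ground truth.

Emulates the statistical structure the downstream analysis assumes: three
ethnic strata with distinct allele frequencies at ten biallelic blood-
pressure SNPs acting additively on latent SBP/DBP; measured confounders
(age, BMI, smoking) and a single unmeasured standard-normal confounder
loading on both BP and retinal caliber; a linear causal effect of one BP
phenotype on CRAE/CRVE; repeated noisy BP readings following the clinical
repeat-reading protocol; six arteriolar and six venular vessel widths whose
Knudtson summary equals the latent caliber; and optional direct
(pleiotropic) GRS→caliber and GRS→confounder paths.

Vessel widths are produced by inverting the Knudtson chain for six equal
widths and then applying a pairing-preserving angular jitter, so the
phenotypes module — not the generator — defines the caliber computation.
The per-SNP effect sizes of the default panel are illustrative (no
per-ethnicity effects are published for these loci); they are sized so the
10-SNP score is a usable instrument at simulated sample sizes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import phenotypes as ph
from .genetics import GenotypeMatrix, SnpInfo, write_dosage_tsv, write_panel, write_vcf

__all__ = [
    "SnpSpec",
    "SimConfig",
    "CohortBundle",
    "DEFAULT_SNP_PANEL",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SnpSpec:
    """Generative spec for one index SNP: location, alleles, per-stratum
    risk-allele frequency and additive effects on SBP/DBP (mmHg/allele)."""

    snp_id: str
    chromosome: str
    position: int
    risk_allele: str
    other_allele: str
    freq: Mapping[str, float]  # stratum -> risk-allele frequency
    beta_sbp: float
    beta_dbp: float
    nearby_gene: str = ""
    source_ethnicity: str = ""
    region_start: int | None = None
    region_end: int | None = None

    def beta_for(self, phenotype: str) -> float:
        if phenotype == "sbp":
            return self.beta_sbp
        if phenotype == "dbp":
            return self.beta_dbp
        if phenotype == "map":
            return self.beta_sbp / 3.0 + 2.0 * self.beta_dbp / 3.0
        raise ValueError(f"unknown BP phenotype {phenotype!r}")

    def to_snp_info(self) -> SnpInfo:
        return SnpInfo(
            snp_id=self.snp_id,
            chromosome=self.chromosome,
            position=self.position,
            risk_allele=self.risk_allele,
            other_allele=self.other_allele,
            nearby_gene=self.nearby_gene,
            source_ethnicity=self.source_ethnicity,
            region_start=self.region_start,
            region_end=self.region_end,
        )


def _snp(sid, chrom, pos, risk, other, gene, eth, fm, fi, fc, bs, bd, r0, r1):
    return SnpSpec(
        snp_id=sid, chromosome=chrom, position=pos, risk_allele=risk,
        other_allele=other, nearby_gene=gene, source_ethnicity=eth,
        freq={"malay": fm, "indian": fi, "chinese": fc},
        beta_sbp=bs, beta_dbp=bd, region_start=r0, region_end=r1,
    )


# Ten index SNPs at established BP loci (positions are the locus region
# starts; risk alleles and per-stratum frequencies are illustrative).
DEFAULT_SNP_PANEL: tuple[SnpSpec, ...] = (
    _snp("rs17030613", "1", 112767664, "C", "A", "ST7L-CAPZA1", "Asians",
         0.55, 0.45, 0.62, 1.2, 0.7, 112767664, 113115764),
    _snp("rs880315", "1", 10596666, "C", "T", "CASZ1", "Europeans",
         0.60, 0.52, 0.68, 1.0, 0.6, 10596666, 10956733),
    _snp("rs16849225", "2", 164074308, "C", "T", "FIGN-GRB14", "Asians",
         0.70, 0.62, 0.75, 1.4, 0.8, 164074308, 165286606),
    _snp("rs16998073", "4", 81084091, "T", "A", "FGF5", "Europeans",
         0.30, 0.38, 0.25, 1.6, 0.9, 81084091, 81312171),
    _snp("rs6825911", "4", 111516678, "C", "T", "ENPEP", "Asians",
         0.50, 0.42, 0.58, 1.1, 0.7, 111516678, 111803942),
    _snp("rs1173766", "5", 32610743, "C", "T", "NPR3", "Asians",
         0.58, 0.50, 0.64, 1.0, 0.6, 32610743, 32904778),
    _snp("rs11191548", "10", 104490288, "T", "C", "CNNM2-NT5C2-CYP17A1",
         "Europeans", 0.72, 0.80, 0.66, 1.8, 1.0, 104490288, 105053064),
    _snp("rs11066280", "12", 112104691, "A", "T", "RPL6-PTPN11-ALDH2", "Asians",
         0.75, 0.85, 0.70, 1.7, 0.9, 112104691, 113024727),
    _snp("rs35444", "12", 115008059, "A", "G", "TBX3", "Asians",
         0.42, 0.35, 0.48, 1.2, 0.7, 115008059, 115652687),
    _snp("rs17249754", "12", 89881826, "G", "A", "ATP2B1", "Europeans",
         0.65, 0.58, 0.72, 1.5, 0.8, 89881826, 90160836),
)

# Fraction of a confounder's SBP effect applied to DBP.
DBP_CONFOUNDER_SHARE = 0.6


@dataclass
class SimConfig:
    """All generative parameters of the synthetic cohort.

    ``confounder_effects`` maps a measured covariate to its
    (effect on SBP mmHg per unit, effect on caliber μm per unit); the DBP
    effect is DBP_CONFOUNDER_SHARE of the SBP effect, and the caliber effect
    applies to both CRAE and CRVE. ``unmeasured_loadings`` are the linear
    loadings of a single standard-normal latent confounder on
    (SBP, DBP, CRAE, CRVE). ``pleiotropy_effect`` is a direct path from the
    standardised true GRS to both calibers (μm per SD), violating the
    exclusion restriction when nonzero. ``grs_to_confounder`` injects direct
    GRS→covariate paths (per SD of true GRS) for pleiotropy-check studies.
    """

    n_per_stratum: int = 600
    strata: tuple[str, ...] = ("malay", "indian", "chinese")
    snp_panel: tuple[SnpSpec, ...] = DEFAULT_SNP_PANEL
    causal_bp: str = "map"
    causal_effect_crae: float = -0.26  # μm per mmHg
    causal_effect_crve: float = -0.09
    confounder_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "age": (0.45, -0.15),
            "bmi": (0.55, -0.30),
            "smoking": (2.0, -1.5),
        }
    )
    unmeasured_confounder_sd: float = 1.0
    unmeasured_loadings: tuple[float, float, float, float] = (8.0, 4.0, 2.5, 3.0)
    pleiotropy_effect: float = 0.0
    grs_to_confounder: dict[str, float] = field(default_factory=dict)
    bp_reading_sd: float = 4.0  # mmHg, per reading, SBP and DBP alike
    sbp_noise_sd: float = 13.0  # latent inter-individual residual
    dbp_noise_sd: float = 7.5
    caliber_noise_sd: float = 9.0  # μm, latent caliber residual
    sbp_base: float = 80.0
    dbp_base: float = 45.0
    stratum_sbp_shift: dict[str, float] = field(
        default_factory=lambda: {"malay": 8.0}
    )
    crae_base: float = 184.0
    crve_base: float = 238.0
    missing_genotype_rate: float = 0.02
    candidates_per_locus: int = 1
    repeat_sbp_threshold: float = 10.0  # mmHg, repeat-reading trigger
    repeat_dbp_threshold: float = 5.0
    repeat_rule: str = "or"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_stratum < 1:
            raise ValueError("n_per_stratum: must be >= 1")
        if not self.strata:
            raise ValueError("strata: must be a non-empty list of labels")
        if len(set(self.strata)) != len(self.strata):
            raise ValueError("strata: labels must be unique")
        if not self.snp_panel:
            raise ValueError("snp_panel: must contain at least one SNP")
        for j, s in enumerate(self.snp_panel):
            for st in self.strata:
                if st not in s.freq:
                    raise ValueError(f"snp_panel[{j}].freq: missing stratum {st!r}")
                if not 0.0 < s.freq[st] < 1.0:
                    raise ValueError(
                        f"snp_panel[{j}].freq[{st!r}]: frequency must be in (0,1), "
                        f"got {s.freq[st]}"
                    )
        if not 0.0 <= self.missing_genotype_rate < 1.0:
            raise ValueError("missing_genotype_rate: must be in [0,1)")
        for name in ("bp_reading_sd", "sbp_noise_sd", "dbp_noise_sd",
                     "caliber_noise_sd", "unmeasured_confounder_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be non-negative")
        if self.causal_bp not in ("sbp", "dbp", "map"):
            raise ValueError("causal_bp: must be one of sbp, dbp, map")
        if self.candidates_per_locus < 1:
            raise ValueError("candidates_per_locus: must be >= 1")


@dataclass
class CohortBundle:
    """Simulated cohort: raw phenotype table, genotypes and the ground truth.

    ``participants`` holds one row per participant (raw measurements, not
    derived summaries); ``latents`` carries the noise-free quantities the
    generator used, for truth-vs-estimate comparisons.
    """

    participants: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: dict
    latents: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.participants["participant_id"].astype(str).tolist()
        if ids != self.genotypes.participant_ids:
            raise ValueError(
                "participant IDs differ between phenotype and genotype components"
            )


INCOME_LEVELS = ("<1000", "1000-3000", ">3000")

# Knudtson chain value for six equal widths w is K(k)·w with K = k²·√(4k²+2).
def _equal_width_chain_constant(k: float) -> float:
    return k * k * np.sqrt(4.0 * k * k + 2.0)


def _widths_from_caliber(
    caliber: np.ndarray, k: float, rng: np.random.Generator
) -> np.ndarray:
    """Six widths whose Knudtson summary equals ``caliber`` exactly.

    Inverts the chain for equal widths, then jitters each of the three
    first-round pairs along an angle θ ≤ π/4 (widths √2·w·cosθ, √2·w·sinθ),
    which preserves both the pairing under the sort-and-pair rule and the
    pair's combined value.
    """
    n = caliber.shape[0]
    w = caliber / _equal_width_chain_constant(k)
    theta = np.sort(np.pi / 4.0 - rng.uniform(0.0, 0.12, size=(n, 3)), axis=1)
    wide = np.sqrt(2.0) * w[:, None] * np.cos(theta)
    narrow = np.sqrt(2.0) * w[:, None] * np.sin(theta)
    widths = np.concatenate([wide, narrow], axis=1)
    return rng.permuted(widths, axis=1)


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate a cohort with the configured causal structure.

    Identical config + seed gives a bit-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    strata = list(config.strata)
    n_s = config.n_per_stratum
    n = n_s * len(strata)
    stratum = np.repeat(strata, n_s)
    ids = [f"S{i:06d}" for i in range(1, n + 1)]

    # --- measured covariates -------------------------------------------------
    age = np.clip(rng.normal(58.1, 10.0, n), 40.0, 95.0)
    gender = rng.integers(0, 2, n)  # 1 = male
    height = np.where(
        gender == 1, rng.normal(168.0, 6.5, n), rng.normal(156.0, 6.0, n)
    )
    bmi_means = {"malay": 26.4, "indian": 26.2, "chinese": 23.8}
    bmi_sds = {"malay": 5.1, "indian": 4.8, "chinese": 3.5}
    bmi = np.empty(n)
    for st in strata:
        m = stratum == st
        bmi[m] = rng.normal(bmi_means.get(st, 25.7), bmi_sds.get(st, 4.7), m.sum())
    bmi = np.clip(bmi, 15.0, 45.0)
    weight = bmi * (height / 100.0) ** 2
    total_cholesterol = np.clip(rng.normal(5.4, 1.1, n), 2.5, None)
    glucose = np.clip(np.exp(rng.normal(np.log(6.2), 0.35, n)), 3.0, 30.0)
    creatinine = np.clip(rng.normal(82.0, 30.0, n), 30.0, None)
    smoking = rng.random(n) < 0.31
    alcohol = rng.random(n) < 0.086
    household_income = np.array(INCOME_LEVELS)[
        rng.choice(3, size=n, p=(0.53, 0.30, 0.17))
    ]
    covariates = {
        "age": age, "gender": gender.astype(float), "bmi": bmi,
        "smoking": smoking.astype(float), "alcohol": alcohol.astype(float),
        "total_cholesterol": total_cholesterol, "glucose": glucose,
        "creatinine": creatinine,
    }

    # --- genotypes -----------------------------------------------------------
    panel_specs: list[SnpSpec] = []
    effect_specs = list(config.snp_panel)
    for s in effect_specs:
        panel_specs.append(s)
        for c in range(1, config.candidates_per_locus):
            # extra null candidates inside the ±100 kb window, no BP effect
            panel_specs.append(
                SnpSpec(
                    snp_id=f"{s.snp_id}_c{c}",
                    chromosome=s.chromosome,
                    position=s.position + 17_000 * c,
                    risk_allele=s.risk_allele,
                    other_allele=s.other_allele,
                    freq=dict(s.freq),
                    beta_sbp=0.0, beta_dbp=0.0,
                    nearby_gene=s.nearby_gene,
                )
            )
    m = len(panel_specs)
    dosage_true = np.empty((n, m))
    for j, s in enumerate(panel_specs):
        for st in strata:
            mask = stratum == st
            dosage_true[mask, j] = rng.binomial(2, s.freq[st], mask.sum())

    # --- latent blood pressure ----------------------------------------------
    u = rng.normal(0.0, config.unmeasured_confounder_sd, n)
    lam_sbp, lam_dbp, lam_crae, lam_crve = config.unmeasured_loadings
    beta_sbp = np.array([s.beta_sbp for s in panel_specs])
    beta_dbp = np.array([s.beta_dbp for s in panel_specs])
    conf_sbp = np.zeros(n)
    conf_cal = np.zeros(n)
    for name, (b_bp, b_cal) in config.confounder_effects.items():
        if name not in covariates:
            raise ValueError(f"confounder_effects: unknown covariate {name!r}")
        conf_sbp += b_bp * covariates[name]
        conf_cal += b_cal * covariates[name]
    sbp_shift = np.array([config.stratum_sbp_shift.get(st, 0.0) for st in stratum])
    latent_sbp = (
        config.sbp_base + sbp_shift + dosage_true @ beta_sbp + conf_sbp
        + lam_sbp * u + rng.normal(0.0, config.sbp_noise_sd, n)
    )
    latent_dbp = (
        config.dbp_base + 0.25 * sbp_shift + dosage_true @ beta_dbp
        + DBP_CONFOUNDER_SHARE * conf_sbp + lam_dbp * u
        + rng.normal(0.0, config.dbp_noise_sd, n)
    )
    latent_dbp = np.minimum(latent_dbp, latent_sbp - 10.0)  # keep sbp > dbp
    latent_map = latent_sbp / 3.0 + 2.0 * latent_dbp / 3.0
    latent_exposure = {"sbp": latent_sbp, "dbp": latent_dbp, "map": latent_map}[
        config.causal_bp
    ]

    # standardised true GRS for the causal phenotype (pleiotropy paths)
    beta_causal = np.array([s.beta_for(config.causal_bp) for s in panel_specs])
    grs_true = dosage_true @ beta_causal
    sd = grs_true.std()
    grs_z = (grs_true - grs_true.mean()) / sd if sd > 0 else np.zeros(n)

    # optional direct GRS→covariate paths (injected pleiotropy via confounders)
    for name, eff in config.grs_to_confounder.items():
        if name not in covariates:
            raise ValueError(f"grs_to_confounder: unknown covariate {name!r}")
        covariates[name] = covariates[name] + eff * grs_z

    # --- latent calibers and vessel widths -----------------------------------
    latent_crae = np.clip(
        config.crae_base + config.causal_effect_crae * latent_exposure + conf_cal
        + lam_crae * u + config.pleiotropy_effect * grs_z
        + rng.normal(0.0, config.caliber_noise_sd, n),
        60.0, None,
    )
    latent_crve = np.clip(
        config.crve_base + config.causal_effect_crve * latent_exposure + conf_cal
        + lam_crve * u + config.pleiotropy_effect * grs_z
        + rng.normal(0.0, config.caliber_noise_sd, n),
        80.0, None,
    )
    art = _widths_from_caliber(latent_crae, ph.KNUDTSON_ARTERIOLE, rng)
    ven = _widths_from_caliber(latent_crve, ph.KNUDTSON_VENULE, rng)

    # --- repeated BP readings (third only when the protocol rule fires) ------
    def _reading():
        s = latent_sbp + rng.normal(0.0, config.bp_reading_sd, n)
        d = latent_dbp + rng.normal(0.0, config.bp_reading_sd, n)
        return s, np.minimum(d, s - 5.0)  # a reading is always SBP > DBP

    s1, d1 = _reading()
    s2, d2 = _reading()
    s3_all, d3_all = _reading()
    third = np.array(
        [
            ph.needs_third_reading(
                (s1[i], d1[i]),
                (s2[i], d2[i]),
                sbp_threshold=config.repeat_sbp_threshold,
                dbp_threshold=config.repeat_dbp_threshold,
                rule=config.repeat_rule,
            )
            for i in range(n)
        ]
    )
    s3 = np.where(third, s3_all, np.nan)
    d3 = np.where(third, d3_all, np.nan)

    # --- disease status -------------------------------------------------------
    htn_dx = ((latent_sbp > 140.0) | (latent_dbp > 90.0)) ^ (rng.random(n) < 0.08)
    htn_med = htn_dx & (rng.random(n) < 0.6)
    dm_dx = (glucose > 10.0) & (rng.random(n) < 0.7)
    dm_med = dm_dx & (rng.random(n) < 0.6)

    # --- observed genotype matrix (missingness applied after latents) --------
    dosage_obs = dosage_true.copy()
    if config.missing_genotype_rate > 0:
        dosage_obs[rng.random((n, m)) < config.missing_genotype_rate] = np.nan
    snps = [s.to_snp_info() for s in panel_specs]
    genotypes = GenotypeMatrix(ids, snps, dosage_obs)

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "stratum": stratum,
            "age": age,
            "gender": gender,
            "height": height,
            "weight": weight,
            "sbp1": s1, "dbp1": d1, "sbp2": s2, "dbp2": d2, "sbp3": s3, "dbp3": d3,
            **{f"art_w{i + 1}": art[:, i] for i in range(6)},
            **{f"ven_w{i + 1}": ven[:, i] for i in range(6)},
            "total_cholesterol": covariates["total_cholesterol"],
            "glucose": covariates["glucose"],
            "creatinine": covariates["creatinine"],
            "hypertension_dx": htn_dx,
            "htn_medication": htn_med,
            "diabetes_dx": dm_dx,
            "dm_medication": dm_med,
            "smoking": smoking,
            "alcohol": alcohol,
            "household_income": household_income,
        }
    )
    truth = {
        "causal_bp": config.causal_bp,
        "causal_effect_crae": config.causal_effect_crae,
        "causal_effect_crve": config.causal_effect_crve,
        "pleiotropy_effect": config.pleiotropy_effect,
        "grs_to_confounder": dict(config.grs_to_confounder),
        "confounder_effects": {
            k: list(v) for k, v in config.confounder_effects.items()
        },
        "unmeasured_loadings": list(config.unmeasured_loadings),
        "unmeasured_confounder_sd": config.unmeasured_confounder_sd,
        "snp_betas": {
            s.snp_id: {"beta_sbp": s.beta_sbp, "beta_dbp": s.beta_dbp,
                       "beta_map": s.beta_for("map")}
            for s in panel_specs
        },
        "seed": config.seed,
        "n": n,
        "strata": strata,
    }
    latents = pd.DataFrame(
        {
            "participant_id": ids,
            "latent_sbp": latent_sbp,
            "latent_dbp": latent_dbp,
            "latent_map": latent_map,
            "latent_crae": latent_crae,
            "latent_crve": latent_crve,
            "grs_true_z": grs_z,
            "u": u,
        }
    )
    return CohortBundle(
        participants=participants, genotypes=genotypes, truth=truth, latents=latents
    )


def write_cohort(bundle: CohortBundle, out_prefix) -> dict[str, Path]:
    """Write the cohort as plain-text artifacts.

    Emits ``<prefix>_phenotypes.csv`` (raw measurements, one row per
    participant), ``<prefix>_genotypes.vcf`` (VCF v4.2, GT only),
    ``<prefix>_dosages.tsv``, ``<prefix>_panel.tsv`` and
    ``<prefix>_truth.json``. Round-trips losslessly through the genetics
    readers.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": prefix.with_name(prefix.name + "_phenotypes.csv"),
        "vcf": prefix.with_name(prefix.name + "_genotypes.vcf"),
        "dosages": prefix.with_name(prefix.name + "_dosages.tsv"),
        "panel": prefix.with_name(prefix.name + "_panel.tsv"),
        "truth": prefix.with_name(prefix.name + "_truth.json"),
    }
    bundle.participants.to_csv(paths["phenotypes"], index=False)
    write_vcf(bundle.genotypes, paths["vcf"])
    write_dosage_tsv(bundle.genotypes, paths["dosages"])
    write_panel(bundle.genotypes.snps, paths["panel"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
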