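"""Genotype handling: I/O, quality control, ancestry PCA and GRS instruments.

Dosages are always oriented to the risk allele of the SNP panel: 0, 1, 2
copies of the risk allele, NaN for missing calls. QC applies the chip-era
filters (call rate < 95%, MAF < 0.1%, Hardy-Weinberg p < 1e-6); ancestry
structure is summarised by PCA of the standardised dosage matrix; the
weighted genetic risk score used as the Mendelian-randomisation instrument
is the effect-size-weighted sum of risk-allele counts over the per-locus
most-associated SNPs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

log = logging.getLogger(__name__)

__all__ = [
    "SnpInfo",
    "GenotypeMatrix",
    "GrsWeights",
    "GrsEntry",
    "PcaResult",
    "QcThresholds",
    "read_panel",
    "write_panel",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "snp_call_rate",
    "minor_allele_frequency",
    "hwe_test",
    "apply_qc",
    "genotype_pca",
    "select_locus_snps",
    "compute_grs",
]

VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpInfo:
    """Metadata for one biallelic SNP, oriented to its risk allele."""

    snp_id: str
    chromosome: str
    position: int  # 1-based bp
    risk_allele: str
    other_allele: str = "N"
    nearby_gene: str = ""
    source_ethnicity: str = ""
    locus: str = ""  # index-SNP id of the locus; defaults to snp_id
    region_start: int | None = None
    region_end: int | None = None

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive")
        if self.risk_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: risk allele must be one of A,C,G,T")
        if not self.locus:
            object.__setattr__(self, "locus", self.snp_id)


class GenotypeMatrix:
    """Participants × SNPs risk-allele dosage matrix with SNP metadata.

    ``dosages`` is a float array with entries in {0, 1, 2} and NaN for
    missing genotype calls.
    """

    def __init__(
        self,
        participant_ids: Sequence[str],
        snps: Sequence[SnpInfo],
        dosages: np.ndarray,
    ) -> None:
        self.participant_ids = [str(p) for p in participant_ids]
        self.snps = list(snps)
        d = np.asarray(dosages, dtype=float)
        if d.shape != (len(self.participant_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {d.shape} inconsistent with "
                f"{len(self.participant_ids)} participants x {len(self.snps)} SNPs"
            )
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        self.dosages = d

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            self.participant_ids, [self.snps[i] for i in idx], self.dosages[:, idx]
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_participants} participants, {self.n_snps} SNPs)"


@dataclass(frozen=True)
class GrsEntry:
    snp_id: str
    weight: float  # β, mmHg per risk allele
    p_value: float
    locus: str


@dataclass(frozen=True)
class GrsWeights:
    """Per-locus selected SNPs with regression-estimated weights."""

    phenotype: str  # sbp | dbp | map
    entries: tuple[GrsEntry, ...]
    dropped_loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        loci = [e.locus for e in self.entries]
        if len(set(loci)) != len(loci):
            raise ValueError("GrsWeights must carry one entry per locus")
        if not all(np.isfinite(e.weight) for e in self.entries):
            raise ValueError("GRS weights must be finite")


# ---------------------------------------------------------------------------
# Panel and genotype I/O

PANEL_COLUMNS = [
    "snp_id",
    "chromosome",
    "position",
    "risk_allele",
    "other_allele",
    "nearby_gene",
    "source_ethnicity",
    "locus",
    "region_start",
    "region_end",
]


def write_panel(snps: Sequence[SnpInfo], path) -> None:
    rows = []
    for s in snps:
        rows.append(
            {
                "snp_id": s.snp_id,
                "chromosome": s.chromosome,
                "position": s.position,
                "risk_allele": s.risk_allele,
                "other_allele": s.other_allele,
                "nearby_gene": s.nearby_gene,
                "source_ethnicity": s.source_ethnicity,
                "locus": s.locus,
                "region_start": "" if s.region_start is None else s.region_start,
                "region_end": "" if s.region_end is None else s.region_end,
            }
        )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path) -> list[SnpInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    snps = []
    for _, r in df.iterrows():
        snps.append(
            SnpInfo(
                snp_id=str(r["snp_id"]),
                chromosome=str(r["chromosome"]),
                position=int(r["position"]),
                risk_allele=str(r["risk_allele"]),
                other_allele=str(r.get("other_allele", "N")),
                nearby_gene=str(r.get("nearby_gene", "") or ""),
                source_ethnicity=str(r.get("source_ethnicity", "") or ""),
                locus=str(r.get("locus", "") or ""),
                region_start=None
                if pd.isna(r.get("region_start"))
                else int(r["region_start"]),
                region_end=None
                if pd.isna(r.get("region_end"))
                else int(r["region_end"]),
            )
        )
    return snps


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    """Allele-dosage TSV: participant_id + one 0/1/2/NA column per SNP."""
    df = pd.DataFrame(g.dosages, columns=g.snp_ids)
    df.insert(0, "participant_id", g.participant_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


_GT_BY_DOSAGE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path, *, ref_is_risk: bool = False) -> None:
    """Write a VCF v4.2 with GT-only genotype fields.

    Default orientation is REF = other allele, ALT = risk allele;
    ``ref_is_risk`` swaps them (the reader must recover identical dosages
    either way). SNPs are emitted in karyotype order.
    """
    order = sorted(
        range(g.n_snps),
        key=lambda i: (_chrom_key(g.snps[i].chromosome), g.snps[i].position),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.snps[i].chromosome for i in order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.participant_ids)
            + "\n"
        )
        for i in order:
            s = g.snps[i]
            other = s.other_allele if s.other_allele in VALID_ALLELES else _fallback_other(s.risk_allele)
            ref, alt = (s.risk_allele, other) if ref_is_risk else (other, s.risk_allele)
            col = g.dosages[:, i]
            alt_dose = (2.0 - col) if ref_is_risk else col
            gts = ["./." if np.isnan(x) else _GT_BY_DOSAGE[x] for x in alt_dose]
            fh.write(
                f"{s.chromosome}\t{s.position}\t{s.snp_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def _chrom_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


def _fallback_other(risk: str) -> str:
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[risk]


def read_genotypes(
    path, fmt: str | None = None, panel: Sequence[SnpInfo] | None = None
) -> GenotypeMatrix:
    """Read genotypes from VCF or allele-dosage TSV.

    With a panel, dosages are oriented to the panel's risk alleles (allele
    flip applied when the VCF REF/ALT orientation differs) and SNP metadata
    is taken from the panel; a VCF record whose alleles match neither panel
    allele is a hard error naming the SNP.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "dosage_tsv"
    if fmt == "vcf":
        return _read_vcf(path, panel)
    if fmt == "dosage_tsv":
        return _read_dosage_tsv(path, panel)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _panel_map(panel: Sequence[SnpInfo] | None) -> dict[str, SnpInfo]:
    return {s.snp_id: s for s in panel} if panel else {}


def _read_vcf(path: Path, panel: Sequence[SnpInfo] | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    pmap = _panel_map(panel)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[SnpInfo] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        alt = var.ALT[0] if var.ALT else "N"
        gts = var.genotypes
        alt_count = np.full(len(samples), np.nan)
        for i, gt in enumerate(gts):
            a = [x for x in gt[:2] if x >= 0]
            if len(a) == 2:
                alt_count[i] = float(sum(1 for x in a if x > 0))
        info = pmap.get(vid)
        if info is not None:
            if alt == info.risk_allele and var.REF == info.other_allele or (
                alt == info.risk_allele and info.other_allele == "N"
            ):
                dose = alt_count
            elif var.REF == info.risk_allele:
                dose = 2.0 - alt_count
            else:
                raise ValueError(
                    f"SNP {vid}: VCF alleles {var.REF}/{alt} do not match panel "
                    f"{info.other_allele}/{info.risk_allele}"
                )
            snps.append(info)
        else:
            if alt not in VALID_ALLELES:
                continue
            dose = alt_count
            snps.append(
                SnpInfo(
                    snp_id=vid,
                    chromosome=str(var.CHROM),
                    position=int(var.POS),
                    risk_allele=alt,
                    other_allele=var.REF,
                )
            )
        cols.append(dose)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    g = GenotypeMatrix(samples, snps, dosages)
    return g.subset_snps([s.snp_id for s in panel if s.snp_id in g.snp_ids]) if panel else g


def _read_dosage_tsv(path: Path, panel: Sequence[SnpInfo] | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    ids = df["participant_id"].astype(str).tolist()
    pmap = _panel_map(panel)
    snp_cols = [c for c in df.columns if c != "participant_id"]
    snps = [
        pmap.get(c, SnpInfo(snp_id=c, chromosome="0", position=1, risk_allele="A"))
        for c in snp_cols
    ]
    return GenotypeMatrix(ids, snps, df[snp_cols].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Quality control


@dataclass(frozen=True)
class QcThresholds:
    """Chip QC thresholds; all comparisons are strict, matching the protocol
    wording (call rate < 0.95 removed, MAF < 0.001 removed, HWE p < 1e-6
    removed)."""

    call_rate: float = 0.95
    maf: float = 0.001
    hwe_p: float = 1e-6


def snp_call_rate(g: GenotypeMatrix, snp_id: str) -> float:
    col = g.column(snp_id)
    return float(np.mean(~np.isnan(col))) if col.size else 0.0


def minor_allele_frequency(g: GenotypeMatrix, snp_id: str) -> float:
    col = g.column(snp_id)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return 0.0
    p = float(obs.sum()) / (2.0 * obs.size)
    return min(p, 1.0 - p)


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[~np.isnan(col)]
    return (int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()))


def hwe_test(g: GenotypeMatrix, snp_id: str, method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium p-value for one SNP.

    ``chisq``: 1-df goodness-of-fit of observed genotype counts against
    p², 2pq, q² expectations. ``exact``: the standard exact test summing
    heterozygote-count probabilities no larger than the observed one.
    Monomorphic SNPs return p = 1 by convention.
    """
    n0, n1, n2 = _genotype_counts(g.column(snp_id))
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    p = (2 * n2 + n1) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    if method == "chisq":
        q = 1.0 - p
        exp = np.array([n * q * q, 2 * n * p * q, n * p * p])
        chi2 = float(np.sum((np.array([n0, n1, n2]) - exp) ** 2 / exp))
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n0, n1, n2)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test: sum P(het count) over counts as or less probable."""
    n = n0 + n1 + n2
    na = n1 + 2 * min(n0, n2)  # minor allele count
    hets = np.arange(na % 2, na + 1, 2)
    homr = (na - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(na + 1)
        + gammaln(2 * n - na + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n1][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(
    g: GenotypeMatrix, thresholds: QcThresholds | None = None, *, hwe_method: str = "chisq"
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove SNPs failing call-rate, MAF or HWE filters.

    Returns the filtered matrix and a per-SNP report with the measured
    metrics, a removed flag and the (first triggering) reason. Idempotent:
    re-applying to the output changes nothing.
    """
    thr = thresholds or QcThresholds()
    rows = []
    keep = []
    for s in g.snps:
        cr = snp_call_rate(g, s.snp_id)
        maf = minor_allele_frequency(g, s.snp_id)
        hp = hwe_test(g, s.snp_id, method=hwe_method)
        reason = ""
        if cr < thr.call_rate:
            reason = "call_rate"
        elif maf < thr.maf:
            reason = "maf"
        elif hp < thr.hwe_p:
            reason = "hwe"
        rows.append(
            {
                "snp_id": s.snp_id,
                "call_rate": cr,
                "maf": maf,
                "hwe_p": hp,
                "removed": bool(reason),
                "reason": reason,
            }
        )
        if not reason:
            keep.append(s.snp_id)
    report = pd.DataFrame(
        rows, columns=["snp_id", "call_rate", "maf", "hwe_p", "removed", "reason"]
    )
    return g.subset_snps(keep), report


# ---------------------------------------------------------------------------
# Ancestry PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame  # participants × PC1..PCk
    loadings: pd.DataFrame  # SNPs × PC1..PCk
    explained_variance_ratio: np.ndarray


def genotype_pca(g: GenotypeMatrix, n_components: int = 5) -> PcaResult:
    """PCA of the column-standardised dosage matrix.

    Missing dosages are mean-imputed per SNP; columns are centred by 2p̂ and
    scaled by sqrt(2p̂(1-p̂)); components are ordered by explained variance
    with the deterministic sign convention that each component's
    largest-magnitude SNP loading is positive.
    """
    if n_components > g.n_snps:
        raise ValueError(
            f"n_components={n_components} exceeds number of SNPs ({g.n_snps})"
        )
    d = g.dosages.copy()
    p_hat = np.nanmean(d, axis=0) / 2.0
    for j in range(d.shape[1]):
        d[np.isnan(d[:, j]), j] = 2.0 * p_hat[j]
    scale = np.sqrt(np.clip(2.0 * p_hat * (1.0 - p_hat), 1e-12, None))
    z = (d - 2.0 * p_hat) / scale
    u, sv, vt = np.linalg.svd(z, full_matrices=False)
    u, sv, vt = u[:, :n_components], sv[:n_components], vt[:n_components]
    sign = np.sign(vt[np.arange(n_components), np.argmax(np.abs(vt), axis=1)])
    sign[sign == 0] = 1.0
    scores = (u * sv) * sign
    cols = [f"pc{i + 1}" for i in range(n_components)]
    total_var = float(np.sum(np.linalg.svd(z, compute_uv=False) ** 2)) or 1.0
    return PcaResult(
        scores=pd.DataFrame(scores, columns=cols, index=g.participant_ids),
        loadings=pd.DataFrame((vt.T * sign), columns=cols, index=g.snp_ids),
        explained_variance_ratio=sv**2 / total_var,
    )


# ---------------------------------------------------------------------------
# GRS construction


def _assoc_lm(y: np.ndarray, x: np.ndarray, covars: np.ndarray | None):
    """Slope, SE and two-tailed t p-value of y ~ x (+ covariates)."""
    mask = ~(np.isnan(y) | np.isnan(x))
    if covars is not None:
        mask &= ~np.isnan(covars).any(axis=1)
    y, x = y[mask], x[mask]
    X = np.column_stack(
        [np.ones_like(x), x] + ([covars[mask]] if covars is not None else [])
    )
    n, k = X.shape
    if n <= k:
        return np.nan, np.nan, 1.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    if se == 0.0:
        return float(beta[1]), 0.0, 0.0
    t = beta[1] / se
    return float(beta[1]), se, float(2.0 * stats.t.sf(abs(t), n - k))


def select_locus_snps(
    g: GenotypeMatrix,
    phenotype_values: np.ndarray | pd.Series,
    panel: Sequence[SnpInfo],
    window_bp: int = 100_000,
    *,
    phenotype: str = "phenotype",
    covariates: pd.DataFrame | None = None,
) -> GrsWeights:
    """Per locus, pick the candidate SNP most associated with the phenotype.

    Loci are the panel's index SNPs; candidates are matrix SNPs on the same
    chromosome within ±``window_bp`` of the index position (1-based,
    inclusive). The weight is the regression β of the phenotype on dosage
    (optionally covariate-adjusted). p-value ties break to the smaller
    position, then snp_id. Loci with no candidate are dropped with a
    warning and recorded in ``dropped_loci``.
    """
    y = np.asarray(phenotype_values, dtype=float)
    if len(y) != g.n_participants:
        raise ValueError("phenotype length does not match genotype matrix")
    cov = covariates.to_numpy(dtype=float) if covariates is not None else None
    entries: list[GrsEntry] = []
    dropped: list[str] = []
    for index in panel:
        cands = [
            s
            for s in g.snps
            if s.chromosome == index.chromosome
            and abs(s.position - index.position) <= window_bp
        ]
        if not cands:
            log.warning("locus %s: no candidate SNPs within ±%d bp; dropped",
                        index.snp_id, window_bp)
            dropped.append(index.snp_id)
            continue
        scored = []
        for s in cands:
            beta, _se, p = _assoc_lm(y, g.column(s.snp_id), cov)
            if np.isnan(beta):
                continue
            scored.append((p, s.position, s.snp_id, beta))
        if not scored:
            dropped.append(index.snp_id)
            continue
        p, _pos, sid, beta = min(scored)
        entries.append(GrsEntry(snp_id=sid, weight=beta, p_value=p, locus=index.snp_id))
    return GrsWeights(
        phenotype=phenotype, entries=tuple(entries), dropped_loci=tuple(dropped)
    )


def compute_grs(
    g: GenotypeMatrix, weights: GrsWeights, missing_policy: str = "impute"
) -> pd.Series:
    """Weighted genetic risk score: Σⱼ βⱼ · dosageᵢⱼ per participant.

    ``impute`` (default) replaces a missing dosage by its SNP's expected
    dosage 2p̂ among observed calls; ``complete_case`` leaves the score NaN
    for any participant with a missing dosage.
    """
    if missing_policy not in ("impute", "complete_case"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    score = np.zeros(g.n_participants)
    nanmask = np.zeros(g.n_participants, dtype=bool)
    for e in weights.entries:
        col = g.column(e.snp_id).copy()  # KeyError if absent, per contract
        miss = np.isnan(col)
        if miss.any():
            if missing_policy == "impute":
                col[miss] = np.nanmean(col) if not miss.all() else 0.0
            else:
                nanmask |= miss
                col[miss] = 0.0
        score += e.weight * col
    out = pd.Series(score, index=g.participant_ids, name=f"grs_{weights.phenotype}")
    if missing_policy == "complete_case":
        out[nanmask] = np.nan
    return out
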