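"""Genotype I/O, QC filters, ancestry PCA and GRS construction."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpmr.genetics import (
    GenotypeMatrix,
    GrsEntry,
    GrsWeights,
    QcThresholds,
    SnpInfo,
    apply_qc,
    compute_grs,
    genotype_pca,
    hwe_test,
    minor_allele_frequency,
    read_genotypes,
    select_locus_snps,
    snp_call_rate,
    write_dosage_tsv,
    write_vcf,
)


def _matrix(dosages, snps=None, ids=None):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    snps = snps or [
        SnpInfo(f"rs{j}", "1", 1000 + j, "A", "G") for j in range(m)
    ]
    ids = ids or [f"P{i}" for i in range(n)]
    return GenotypeMatrix(ids, snps, d)


# --- I/O and allele orientation ---------------------------------------------


def test_vcf_orientation_and_missing(tmp_path):
    panel = [SnpInfo("rs1", "1", 100, "T", "A"), SnpInfo("rs2", "1", 200, "C", "G")]
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t./.\n"  # ALT is risk
        "1\t200\trs2\tC\tG\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1\n"  # REF is risk
    )
    g = read_genotypes(vcf, panel=panel)
    np.testing.assert_array_equal(g.column("rs1"), [1.0, 2.0, np.nan])
    # REF = risk allele: hom-ALT means zero risk alleles
    np.testing.assert_array_equal(g.column("rs2"), [0.0, 2.0, 1.0])


def test_vcf_allele_mismatch_is_hard_error(tmp_path):
    panel = [SnpInfo("rs1", "1", 100, "T", "A")]
    vcf = tmp_path / "bad.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "1\t100\trs1\tC\tG\t.\tPASS\t.\tGT\t0/1\n"
    )
    with pytest.raises(ValueError, match="rs1"):
        read_genotypes(vcf, panel=panel)


def test_risk_allele_flip_invariance(tmp_path, small_bundle):
    """The same genotypes written with swapped REF/ALT read back identically."""
    g = small_bundle.genotypes
    a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_vcf(g, a, ref_is_risk=False)
    write_vcf(g, b, ref_is_risk=True)
    ga = read_genotypes(a, panel=g.snps)
    gb = read_genotypes(b, panel=g.snps)
    np.testing.assert_array_equal(ga.dosages, gb.dosages)
    np.testing.assert_array_equal(ga.dosages, g.dosages)


def test_dosage_tsv_round_trip(tmp_path, small_bundle):
    g = small_bundle.genotypes
    p = tmp_path / "d.tsv"
    write_dosage_tsv(g, p)
    g2 = read_genotypes(p, panel=g.snps)
    assert g2.participant_ids == g.participant_ids
    assert g2.snp_ids == g.snp_ids
    np.testing.assert_array_equal(g2.dosages, g.dosages)


# --- per-SNP QC metrics -----------------------------------------------------


def test_call_rate_cases():
    col = np.array([[0.0]] * 95 + [[np.nan]] * 5)
    g = _matrix(np.hstack([col, np.ones((100, 1))]))
    assert snp_call_rate(g, "rs0") == pytest.approx(0.95)
    assert snp_call_rate(g, "rs1") == 1.0
    g_all_missing = _matrix(np.full((4, 1), np.nan))
    assert snp_call_rate(g_all_missing, "rs0") == 0.0


@pytest.mark.parametrize(
    "dosages,expected",
    [([0, 0, 0, 0], 0.0), ([1, 1, 1, 1], 0.5), ([0, 0, 1, 2], 0.375)],
)
def test_minor_allele_frequency(dosages, expected):
    g = _matrix(np.array(dosages, dtype=float)[:, None])
    assert minor_allele_frequency(g, "rs0") == pytest.approx(expected)


def test_hwe_chisq_cases():
    # perfect equilibrium at p = 0.5
    g = _matrix(np.repeat([0.0, 1.0, 2.0], [25, 50, 25])[:, None])
    assert hwe_test(g, "rs0") == pytest.approx(1.0)
    # no heterozygotes at p = 0.5: chi-square equals n
    g = _matrix(np.repeat([0.0, 2.0], [50, 50])[:, None])
    assert hwe_test(g, "rs0") == pytest.approx(float(stats.chi2.sf(100, 1)), rel=1e-10)
    assert hwe_test(g, "rs0") < 1e-6
    # monomorphic convention
    g = _matrix(np.zeros((30, 1)))
    assert hwe_test(g, "rs0") == 1.0


def test_hwe_exact_agrees_in_direction():
    g_bad = _matrix(np.repeat([0.0, 2.0], [50, 50])[:, None])
    g_ok = _matrix(np.repeat([0.0, 1.0, 2.0], [25, 50, 25])[:, None])
    assert hwe_test(g_bad, "rs0", method="exact") < 1e-6
    assert hwe_test(g_ok, "rs0", method="exact") > 0.5


# --- QC filter --------------------------------------------------------------


def _qc_fixture(rng):
    n = 1000
    clean = rng.binomial(2, 0.3, (n, 2)).astype(float)
    low_call = rng.binomial(2, 0.3, n).astype(float)
    low_call[: int(n * 0.10)] = np.nan  # call rate 0.90
    rare = np.zeros(n)
    rare[0] = 1.0  # MAF = 1/2000 = 0.0005
    hwe_bad = np.repeat([0.0, 2.0], [n // 2, n // 2]).astype(float)
    snps = [
        SnpInfo("clean1", "1", 100, "A", "G"),
        SnpInfo("clean2", "1", 200, "A", "G"),
        SnpInfo("lowcall", "1", 300, "A", "G"),
        SnpInfo("rare", "1", 400, "A", "G"),
        SnpInfo("hwebad", "1", 500, "A", "G"),
    ]
    d = np.column_stack([clean, low_call, rare, hwe_bad])
    return GenotypeMatrix([f"P{i}" for i in range(n)], snps, d)


def test_apply_qc_removes_with_stated_reasons(rng):
    g = _qc_fixture(rng)
    g2, report = apply_qc(g)
    reasons = report.set_index("snp_id")["reason"].to_dict()
    assert reasons["lowcall"] == "call_rate"
    assert reasons["rare"] == "maf"
    assert reasons["hwebad"] == "hwe"
    assert reasons["clean1"] == "" and reasons["clean2"] == ""
    assert g2.snp_ids == ["clean1", "clean2"]


def test_qc_boundary_is_strict(rng):
    # exactly 95% call rate is retained (threshold is strict <)
    n = 100
    col = rng.binomial(2, 0.4, n).astype(float)
    col[:5] = np.nan
    g = _matrix(col[:, None])
    g2, report = apply_qc(g)
    assert not report["removed"].iloc[0]
    assert g2.n_snps == 1


def test_apply_qc_idempotent(rng):
    g = _qc_fixture(rng)
    g1, _ = apply_qc(g)
    g2, report2 = apply_qc(g1)
    assert g2.snp_ids == g1.snp_ids
    assert not report2["removed"].any()


def test_clean_matrix_unchanged(small_bundle):
    g2, report = apply_qc(small_bundle.genotypes)
    assert g2.snp_ids == small_bundle.genotypes.snp_ids
    assert not report["removed"].any()


# --- ancestry PCA -----------------------------------------------------------


def _two_pop_fixture(rng, n_per=200, delta=0.4):
    f1, f2 = 0.3, 0.3 + delta
    d = np.vstack(
        [rng.binomial(2, f1, (n_per, 10)), rng.binomial(2, f2, (n_per, 10))]
    ).astype(float)
    labels = np.repeat([0, 1], n_per)
    return _matrix(d), labels


def test_pca_separates_populations(rng):
    g, labels = _two_pop_fixture(rng)
    res = genotype_pca(g, 5)
    r = np.corrcoef(res.scores["pc1"], labels)[0, 1]
    assert abs(r) > 0.9


def test_pca_orthogonal_and_duplicate_rows(rng):
    g, _ = _two_pop_fixture(rng)
    res = genotype_pca(g, 5)
    s = res.scores.to_numpy()
    gram = s.T @ s
    off = gram - np.diag(np.diag(gram))
    assert np.all(np.abs(off) < 1e-8 * np.abs(np.diag(gram)).max())
    # duplicated participant rows get identical coordinates
    d2 = np.vstack([g.dosages, g.dosages[:1]])
    g2 = _matrix(d2, snps=g.snps, ids=[f"Q{i}" for i in range(d2.shape[0])])
    res2 = genotype_pca(g2, 5)
    np.testing.assert_allclose(
        res2.scores.iloc[-1].to_numpy(), res2.scores.iloc[0].to_numpy(), atol=1e-10
    )


def test_pca_row_order_invariance(rng):
    g, _ = _two_pop_fixture(rng)
    res = genotype_pca(g, 3)
    perm = rng.permutation(g.n_participants)
    gp = _matrix(
        g.dosages[perm], snps=g.snps, ids=[g.participant_ids[i] for i in perm]
    )
    resp = genotype_pca(gp, 3)
    np.testing.assert_allclose(
        resp.scores.to_numpy(), res.scores.to_numpy()[perm], atol=1e-8
    )


def test_pca_too_many_components(rng):
    g, _ = _two_pop_fixture(rng)
    with pytest.raises(ValueError):
        genotype_pca(g, 11)


# --- locus selection and GRS ------------------------------------------------


def test_single_candidate_chosen_regardless_of_p(rng):
    g = _matrix(rng.binomial(2, 0.4, (50, 1)).astype(float),
                snps=[SnpInfo("rs0", "1", 5000, "A", "G")])
    y = rng.normal(size=50)  # pure noise: p-value irrelevant
    w = select_locus_snps(g, y, [g.snps[0]])
    assert [e.snp_id for e in w.entries] == ["rs0"]


def test_tie_breaks_to_smaller_position(rng):
    dos = rng.binomial(2, 0.4, 60).astype(float)
    snps = [
        SnpInfo("rs_far", "1", 6000, "A", "G"),
        SnpInfo("rs_near", "1", 5000, "A", "G"),
    ]
    g = GenotypeMatrix([f"P{i}" for i in range(60)], snps,
                       np.column_stack([dos, dos]))  # identical dosages: tied p
    index = SnpInfo("rs_near", "1", 5000, "A", "G")
    y = 0.5 * dos + rng.normal(size=60)
    w = select_locus_snps(g, y, [index])
    assert w.entries[0].snp_id == "rs_near"


def test_effect_snp_beats_null_candidate():
    hits = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        n = 2000
        eff = r.binomial(2, 0.4, n).astype(float)
        null = r.binomial(2, 0.4, n).astype(float)
        y = 0.8 * eff + r.normal(0, 5, n)
        g = GenotypeMatrix(
            [f"P{i}" for i in range(n)],
            [SnpInfo("eff", "1", 5000, "A", "G"), SnpInfo("null", "1", 6000, "A", "G")],
            np.column_stack([eff, null]),
        )
        w = select_locus_snps(g, y, [SnpInfo("eff", "1", 5000, "A", "G")])
        hits += w.entries[0].snp_id == "eff"
    assert hits >= 95


def test_empty_locus_dropped_with_record(rng):
    g = _matrix(rng.binomial(2, 0.4, (50, 1)).astype(float),
                snps=[SnpInfo("rs0", "1", 5000, "A", "G")])
    far_index = SnpInfo("rs_far", "2", 10_000_000, "A", "G")
    w = select_locus_snps(g, rng.normal(size=50), [g.snps[0], far_index])
    assert w.dropped_loci == ("rs_far",)
    assert len(w.entries) == 1


def test_grs_hand_computation(rng):
    dosages = rng.binomial(2, 0.5, (3, 10)).astype(float)
    g = _matrix(dosages)
    betas = rng.normal(0.5, 0.3, 10)
    w = GrsWeights(
        phenotype="sbp",
        entries=tuple(
            GrsEntry(f"rs{j}", betas[j], 0.01, f"rs{j}") for j in range(10)
        ),
    )
    expected = dosages @ betas  # brute-force dot product
    np.testing.assert_allclose(compute_grs(g, w).to_numpy(), expected, atol=1e-12)


def test_grs_simple_cases():
    g = _matrix(np.array([[0.0], [1.0], [2.0]]))
    w = GrsWeights("sbp", (GrsEntry("rs0", 1.0, 0.5, "rs0"),))
    np.testing.assert_allclose(compute_grs(g, w).to_numpy(), [0, 1, 2])
    g0 = _matrix(np.zeros((4, 2)))
    w2 = GrsWeights(
        "sbp", (GrsEntry("rs0", 1.3, 0.5, "rs0"), GrsEntry("rs1", -0.2, 0.5, "rs1"))
    )
    np.testing.assert_allclose(compute_grs(g0, w2).to_numpy(), np.zeros(4))


def test_grs_missing_policies():
    d = np.array([[0.0, 2.0], [np.nan, 2.0], [2.0, 0.0], [2.0, 0.0]])
    g = _matrix(d)
    w = GrsWeights(
        "sbp", (GrsEntry("rs0", 1.0, 0.5, "rs0"), GrsEntry("rs1", 2.0, 0.5, "rs1"))
    )
    imputed = compute_grs(g, w, missing_policy="impute")
    # expected dosage of rs0 among observed = (0+2+2)/3
    assert imputed.iloc[1] == pytest.approx(4.0 / 3.0 + 4.0)
    cc = compute_grs(g, w, missing_policy="complete_case")
    assert np.isnan(cc.iloc[1]) and cc.iloc[0] == pytest.approx(4.0)
    with pytest.raises(KeyError):
        compute_grs(g, GrsWeights("sbp", (GrsEntry("absent", 1.0, 0.5, "x"),)))


def test_grs_monotone_in_dosage(rng):
    d = rng.binomial(2, 0.5, (20, 5)).astype(float)
    g = _matrix(d)
    w = GrsWeights(
        "sbp",
        tuple(GrsEntry(f"rs{j}", abs(rng.normal()) + 0.1, 0.5, f"rs{j}") for j in range(5)),
    )
    base = compute_grs(g, w)
    bumped = d.copy()
    bumped[bumped[:, 2] < 2, 2] += 1
    g2 = _matrix(bumped)
    assert (compute_grs(g2, w) >= base - 1e-12).all()


def test_grs_weights_one_entry_per_locus():
    with pytest.raises(ValueError):
        GrsWeights(
            "sbp",
            (GrsEntry("a", 1.0, 0.5, "locus1"), GrsEntry("b", 1.0, 0.5, "locus1")),
        )
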