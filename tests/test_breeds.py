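"""Common/breed-specific SNP logic, cohort statistics and genotype PCA."""
import math

import numpy as np
import pytest

from tailvar import (
    BreedPanel,
    GenotypeCall,
    GenotypeMatrix,
    VariantRecord,
    breed_specific_snps,
    common_snps,
    genotype_pca,
    het_hom_ratio,
    snp_density,
    ts_tv_ratio,
)
from tailvar.breeds import ConfigurationError, DegenerateInputError

PANEL_A = BreedPanel("A", ("a1", "a2", "a3", "a4"))
PANEL_B = BreedPanel("B", ("b1", "b2", "b3", "b4"))


def _site(pos, gts, ref="A", alt="G"):
    """gts: dict sample -> GT string; AD is well supported."""
    calls = []
    for s, gt in gts.items():
        if gt == "./.":
            calls.append(GenotypeCall(s, (None, None), None, 0))
        else:
            a, b = (int(x) for x in gt.split("/"))
            ad = (0, 20) if (a, b) == (1, 1) else ((10, 10) if a != b else (20, 0))
            calls.append(GenotypeCall(s, (a, b), ad, 20))
    return VariantRecord("chr1", pos, ref, [alt], genotypes=calls)


def _full(pos, a_gts, b_gts, **kw):
    gts = dict(zip(PANEL_A.sample_ids, a_gts)) | dict(zip(PANEL_B.sample_ids, b_gts))
    return _site(pos, gts, **kw)


class TestCommonSNPs:
    def test_two_carriers_included_one_excluded(self):
        recs = [
            _full(100, ["0/1", "1/1", "0/0", "0/0"], ["0/0"] * 4),
            _full(200, ["0/1", "0/0", "0/0", "0/0"], ["0/0"] * 4),
        ]
        keys = common_snps(recs, PANEL_A)
        assert keys == {recs[0].key}

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigurationError):
            common_snps([], BreedPanel("X", ()))

    def test_invalidated_support_call_excluded(self):
        # two A carriers but one genotype was voided by the support stage
        rec = _full(100, ["0/1", "./.", "0/0", "0/0"], ["0/0"] * 4)
        assert common_snps([rec], PANEL_A) == set()


class TestBreedSpecific:
    def test_divergent_genotypes_are_specific(self):
        rec = _full(100, ["0/1", "1/1", "0/0", "./."], ["0/0"] * 4)
        ca = common_snps([rec], PANEL_A)
        cb = common_snps([rec], PANEL_B)
        sa, sb = breed_specific_snps(ca, cb, [rec], PANEL_A, PANEL_B)
        assert sa == {rec.key} and sb == set()

    def test_segregating_in_both_breeds_is_neither(self):
        rec = _full(100, ["0/1", "1/1", "0/0", "0/0"], ["0/1", "0/1", "0/0", "0/0"])
        ca, cb = common_snps([rec], PANEL_A), common_snps([rec], PANEL_B)
        sa, sb = breed_specific_snps(ca, cb, [rec], PANEL_A, PANEL_B)
        assert sa == set() and sb == set()

    def test_single_other_breed_het_vetoes_specificity(self):
        rec = _full(100, ["0/1", "1/1", "0/0", "0/0"], ["0/1", "0/0", "0/0", "0/0"])
        ca, cb = common_snps([rec], PANEL_A), common_snps([rec], PANEL_B)
        sa, sb = breed_specific_snps(ca, cb, [rec], PANEL_A, PANEL_B)
        assert sa == set() and sb == set()

    def test_strict_mode_vetoes_on_missing(self):
        rec = _full(100, ["0/1", "1/1", "0/0", "0/0"], ["0/0", "0/0", "0/0", "./."])
        ca, cb = common_snps([rec], PANEL_A), common_snps([rec], PANEL_B)
        sa, _ = breed_specific_snps(ca, cb, [rec], PANEL_A, PANEL_B)
        assert sa == {rec.key}
        sa, _ = breed_specific_snps(ca, cb, [rec], PANEL_A, PANEL_B,
                                    require_complete=True)
        assert sa == set()

    def test_overlapping_panels_rejected(self):
        with pytest.raises(ConfigurationError):
            breed_specific_snps(set(), set(), [], PANEL_A,
                                BreedPanel("B", ("a1", "b2")))

    def test_relabelling_breeds_swaps_specific_sets(self, cohort, cascade):
        ca = common_snps(cascade.survivors, cohort.panel_a)
        cb = common_snps(cascade.survivors, cohort.panel_b)
        sa, sb = breed_specific_snps(ca, cb, cascade.survivors,
                                     cohort.panel_a, cohort.panel_b)
        sb2, sa2 = breed_specific_snps(cb, ca, cascade.survivors,
                                       cohort.panel_b, cohort.panel_a)
        assert (sa, sb) == (sa2, sb2)
        assert not sa & sb and sa <= ca and sb <= cb

    def test_matches_exhaustive_per_site_evaluator(self, cohort, cascade):
        recs = cascade.survivors
        pa, pb = cohort.panel_a, cohort.panel_b
        ca, cb = common_snps(recs, pa), common_snps(recs, pb)
        sa, sb = breed_specific_snps(ca, cb, recs, pa, pb)
        brute_ca, brute_cb, brute_sa, brute_sb = set(), set(), set(), set()
        for rec in recs:
            gts = {c.sample_id: c for c in rec.genotypes}
            carr_a = [s for s in pa.sample_ids if gts[s].is_variant]
            carr_b = [s for s in pb.sample_ids if gts[s].is_variant]
            if len(carr_a) >= 2:
                brute_ca.add(rec.key)
            if len(carr_b) >= 2:
                brute_cb.add(rec.key)
            b_hom_ref = all(
                gts[s].is_missing or gts[s].alleles == (0, 0) for s in pb.sample_ids
            )
            a_hom_ref = all(
                gts[s].is_missing or gts[s].alleles == (0, 0) for s in pa.sample_ids
            )
            if len(carr_a) >= 2 and len(carr_b) < 2 and b_hom_ref:
                brute_sa.add(rec.key)
            if len(carr_b) >= 2 and len(carr_a) < 2 and a_hom_ref:
                brute_sb.add(rec.key)
        assert (ca, cb, sa, sb) == (brute_ca, brute_cb, brute_sa, brute_sb)


class TestStatistics:
    def test_ts_tv_hand_count(self):
        sites = {("c", 1, "A", "G"), ("c", 2, "C", "T"), ("c", 3, "G", "A"),
                 ("c", 4, "A", "C")}
        assert ts_tv_ratio(sites) == 3.0

    def test_all_transversions_zero(self):
        assert ts_tv_ratio({("c", 1, "A", "T"), ("c", 2, "C", "G")}) == 0.0

    def test_no_transversion_signals_undefined(self):
        assert math.isnan(ts_tv_ratio({("c", 1, "A", "G")}))
        assert math.isnan(ts_tv_ratio(set()))

    def test_het_hom_definition(self):
        recs = [
            _site(p, {"s": "0/1"}) for p in range(1, 28)
        ] + [_site(p, {"s": "1/1"}) for p in range(100, 150)]
        assert het_hom_ratio(recs, "s") == pytest.approx(27 / 50)
        assert het_hom_ratio([_site(1, {"s": "1/1"})], "s") == 0.0
        assert math.isnan(het_hom_ratio([_site(1, {"s": "0/1"})], "s"))

    def test_density_windows_and_conservation(self, cohort):
        sites = [("chr1", 5, "A", "G"), ("chr1", 15, "A", "G"), ("chr1", 25, "A", "G")]
        df = snp_density(sites, {"chr1": 30}, 10)
        assert df["count"].tolist() == [1, 1, 1]
        keys = {r.key for r in cohort.records if len(r.alt) == 1}
        df = snp_density(keys, cohort.reference.chrom_lengths, 10_000)
        assert df["count"].sum() == len(keys)
        empty = snp_density([], {"chr1": 30}, 10)
        assert empty["count"].sum() == 0

    def test_density_rejects_out_of_range_site(self):
        with pytest.raises(ConfigurationError):
            snp_density([("chr1", 31, "A", "G")], {"chr1": 30}, 10)


class TestPCA:
    def test_normalization_formula_by_hand(self):
        # dosages (0,1,2,1): p = (1+4)/(2+8) = 0.5, mean 1 -> (-2, 0, 2, 0)
        g = np.array([[0.0], [1.0], [2.0], [1.0]])
        mu, p = g.mean(), (1 + g.sum()) / (2 + 2 * 4)
        norm = (g - mu) / np.sqrt(p * (1 - p))
        assert p == 0.5
        assert np.allclose(norm.ravel(), [-2, 0, 2, 0])
        # the PCA path reproduces the same covariance structure
        m = GenotypeMatrix(["s1", "s2", "s3", "s4"],
                           [("c", 1, "A", "G"), ("c", 2, "A", "G")],
                           np.array([[0, 0.0], [1, 1], [2, 2], [1, 1]]))
        res = genotype_pca(m, 2)
        assert np.allclose(np.abs(res.coordinates[:, 0]),
                           np.abs(np.array([-2, 0, 2, 0]) / np.sqrt(8)))

    def test_duplicated_samples_get_identical_coordinates(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(3, 40)).astype(float)
        g = np.vstack([g, g[1]])  # duplicate sample 2
        m = GenotypeMatrix([f"s{i}" for i in range(4)],
                           [("c", j + 1, "A", "G") for j in range(40)], g)
        res = genotype_pca(m, 2)
        assert np.allclose(res.coordinates[1], res.coordinates[3])

    def test_components_orthogonal_and_variance_fractions_bounded(self, cohort, cascade):
        m = GenotypeMatrix.from_records(cascade.survivors, cohort.samples)
        res = genotype_pca(m, 4)
        gram = res.coordinates.T @ res.coordinates
        assert np.allclose(gram, np.eye(4), atol=1e-8)
        assert 0 < res.explained.sum() <= 1.0 + 1e-12

    def test_monomorphic_input_signals_degeneracy(self):
        m = GenotypeMatrix(["a", "b"], [("c", 1, "A", "G"), ("c", 2, "A", "G")],
                           np.ones((2, 2)))
        with pytest.raises(DegenerateInputError):
            genotype_pca(m)

    def test_breed_structure_separates_on_pc1(self, cohort, cascade):
        m = GenotypeMatrix.from_records(cascade.survivors, cohort.samples)
        res = genotype_pca(m, 2)
        pc1 = res.coordinates[:, 0]
        na = len(cohort.panel_a)
        a, b = pc1[:na], pc1[na:]
        assert max(a) < min(b) or max(b) < min(a)  # sign-invariant separation
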