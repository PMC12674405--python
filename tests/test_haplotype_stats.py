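"""EHH profiles, iHH integration, iHS and xpEHH scans."""

import numpy as np
import pytest

from conftest import random_haplotypes
from oracles import ehh_string_oracle
from sweepscan.haplotype_stats import (EHHProfile, ehh_profile, ies_pair,
                                       ihh, ihh_at, ihs_scan,
                                       standardize_by_bin, xpehh_scan)
from sweepscan.variant_io import HaplotypeMatrix


def make_hap(rows, spacing_bp=100_000):
    alleles = np.asarray(rows, dtype=np.uint8)
    n, m = alleles.shape
    assert n % 2 == 0
    pos = np.arange(1, m + 1, dtype=np.int64) * spacing_bp
    return HaplotypeMatrix(alleles, pos, pos * 1e-6,
                           [f"s{i // 2}" for i in range(n)])


class TestEhhProfile:
    def test_identical_carriers_stay_at_one(self):
        hap = make_hap([[1, 1, 0, 1], [1, 1, 0, 1], [0, 0, 1, 0],
                        [0, 0, 1, 0]])
        p = ehh_profile(hap, 1, "derived", "right")
        assert np.allclose(p.ehh, 1.0)
        assert p.truncated_by == "edge"

    def test_four_carriers_split_2_1_1(self):
        # two flanking sites split the 4 carriers into groups {2,1,1}:
        # EHH = C(2,2)/C(4,2) = 1/6
        rows = [[1, 0, 0], [1, 0, 0], [1, 1, 0], [1, 0, 1],
                [0, 0, 0], [0, 0, 0]]
        hap = make_hap(rows)
        p = ehh_profile(hap, 0, "derived", "right")
        assert p.ehh[2] == pytest.approx(1 / 6)

    def test_two_carriers_differ_truncates_at_limehh(self):
        hap = make_hap([[1, 0], [1, 1], [0, 0], [0, 0]])
        p = ehh_profile(hap, 0, "derived", "right")
        assert p.ehh[-1] == 0.0
        assert p.truncated_by == "limehh"

    def test_single_carrier_undefined(self):
        hap = make_hap([[1, 0], [0, 1], [0, 0], [0, 0]])
        assert ehh_profile(hap, 0, "derived", "left") is None

    def test_maxgap_truncation_recorded(self):
        alleles = np.zeros((4, 3), np.uint8)
        alleles[:2, 0] = 1
        pos = np.array([1_000, 2_000, 300_000], np.int64)
        hap = HaplotypeMatrix(alleles, pos, pos * 1e-6, ["a", "a", "b", "b"])
        p = ehh_profile(hap, 0, "derived", "right", maxgap_bp=200_000)
        assert p.truncated_by == "maxgap"
        assert len(p.ehh) == 2  # core + the one reachable site

    def test_nonincreasing_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            hap = random_haplotypes(rng, 16, 30)
            core = rng.integers(0, 30)
            for allele in ("ancestral", "derived", "pooled"):
                for side in ("left", "right"):
                    p = ehh_profile(hap, core, allele, side, limehh=0.0)
                    if p is not None:
                        assert np.all(np.diff(p.ehh) <= 1e-12)
                        assert np.all((p.ehh >= 0) & (p.ehh <= 1))

    def test_matches_string_comparison_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(4, 31)) & ~1
            m = int(rng.integers(5, 51))
            hap = random_haplotypes(rng, n, m)
            core = int(rng.integers(0, m))
            allele = ["ancestral", "derived", "pooled"][rng.integers(3)]
            for side in ("left", "right"):
                p = ehh_profile(hap, core, allele, side, limehh=0.0,
                                maxgap_bp=10**9)
                if p is None:
                    continue
                col = hap.alleles[:, core]
                carriers = np.arange(n) if allele == "pooled" else \
                    np.flatnonzero(col == (1 if allele == "derived" else 0))
                step = -1 if side == "left" else 1
                for k in range(1, len(p.ehh)):
                    target = core + step * k
                    assert p.ehh[k] == pytest.approx(
                        ehh_string_oracle(hap.alleles, core, carriers,
                                          target), abs=1e-12)


class TestIhh:
    def test_constant_ehh_gives_interval_length(self):
        left = EHHProfile(0, "derived", "left", np.array([0.0]),
                          np.array([1.0]), "edge")
        right = EHHProfile(0, "derived", "right",
                           np.array([0.0, 0.1, 0.2]),
                           np.array([1.0, 1.0, 1.0]), "edge")
        assert ihh(left, right) == pytest.approx(0.2)

    @pytest.mark.parametrize("ehh_pts,expected", [
        ((1.0, 0.5), 0.075), ((1.0, 0.0), 0.05)])
    def test_trapezoid_values(self, ehh_pts, expected):
        left = EHHProfile(0, "derived", "left", np.array([0.0]),
                          np.array([1.0]), "edge")
        right = EHHProfile(0, "derived", "right", np.array([0.0, 0.1]),
                           np.array(ehh_pts), "limehh")
        assert ihh(left, right) == pytest.approx(expected)

    def test_invariant_under_non_splitting_site(self):
        rng = np.random.default_rng(4)
        base = random_haplotypes(rng, 12, 20)
        v = ihh_at(base, 5, "pooled", limehh=0.0, maxgap_bp=10**9)
        # duplicate column 10 one bp downstream: no group splits there
        alleles = np.insert(base.alleles, 11, base.alleles[:, 10], axis=1)
        pos = np.insert(base.positions_bp, 11, base.positions_bp[10] + 1)
        hap2 = HaplotypeMatrix(alleles, pos, pos * 1e-6,
                               list(base.sample_of_hap))
        p1 = ehh_profile(base, 5, "pooled", "right", limehh=0.0,
                         maxgap_bp=10**9)
        p2 = ehh_profile(hap2, 5, "pooled", "right", limehh=0.0,
                         maxgap_bp=10**9)
        # EHH at every shared site is untouched by the extra site
        shared = np.isin(p2.distances_cM, p1.distances_cM)
        assert np.allclose(p2.ehh[shared], p1.ehh, atol=1e-12)
        # the integral moves only by the chord-refinement term of the
        # 1 bp insertion: |delta| <= spacing_cM / 2
        v2 = ihh_at(hap2, 5, "pooled", limehh=0.0, maxgap_bp=10**9)
        assert v2 == pytest.approx(v, abs=0.5e-6)


class TestIhsScan:
    def test_bin_standardization_mean0_sd1(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=500)
        ps = rng.uniform(0.05, 0.95, 500)
        z = standardize_by_bin(vals, ps)
        ok = np.isfinite(z)
        # every standardization group has mean 0 and sd 1, so the pooled
        # moments are exact as well
        assert z[ok].mean() == pytest.approx(0.0, abs=1e-9)
        assert z[ok].std() == pytest.approx(1.0, abs=1e-9)

    def test_mirror_profiles_give_zero_unihs(self):
        # ancestral and derived carriers with identical flanking structure
        rows = [[1, 0, 1, 0, 0], [1, 1, 1, 1, 0],
                [0, 0, 0, 0, 0], [0, 1, 0, 1, 0]]
        hap = make_hap(rows)
        a = ihh_at(hap, 2, "ancestral")
        d = ihh_at(hap, 2, "derived")
        assert np.log(a / d) == pytest.approx(0.0, abs=1e-12)

    def test_scan_fields_and_maf_gate(self, tiny_sweep):
        _, _, hap2, _ = tiny_sweep
        df = ihs_scan(hap2)
        assert set(df.columns) >= {"chrom", "pos", "ps", "ihh_a", "ihh_d",
                                   "unihs", "ihs"}
        assert ((df["ps"] >= 0.05) & (df["ps"] <= 0.95)).all()
        z = df["ihs"].to_numpy()
        ok = np.isfinite(z)
        # moment-matched per bin, hence exact pooled moments
        assert z[ok].mean() == pytest.approx(0.0, abs=1e-9)
        assert z[ok].std() == pytest.approx(1.0, abs=1e-9)


def ies_ratio_two_fixture():
    """Two populations on the same 5 sites whose pooled iES ratio is 2.

    Reference: 4 identical haplotypes, EHH = 1 everywhere, iES = full
    span. Test: groups {3, 1} distinct from the first flank on, so pooled
    EHH = C(3,2)/C(4,2) = 1/2; the first flanks sit 1 bp from the core,
    making the profile's descent from its anchor negligible.
    """
    pos = np.array([1, 499_999, 500_000, 500_001, 1_000_000], np.int64)
    ref = np.zeros((4, 5), np.uint8)
    test = np.zeros((4, 5), np.uint8)
    test[3, [0, 1, 3, 4]] = 1  # one haplotype distinct at every flank
    names = ["s0", "s0", "s1", "s1"]
    return (HaplotypeMatrix(ref, pos, pos * 1e-6, names),
            HaplotypeMatrix(test, pos.copy(), pos * 1e-6, names))


class TestXpehh:
    def test_identical_populations_zero(self, tiny_sweep):
        _, hap1, _, _ = tiny_sweep
        df = xpehh_scan(hap1, hap1, standardize=False)
        un = df["unxpehh"].to_numpy()
        assert np.allclose(un[np.isfinite(un)], 0.0, atol=1e-12)

    def test_ies_ratio_two_gives_unxpehh_ln2(self):
        hap_ref, hap_test = ies_ratio_two_fixture()
        i1, i2 = ies_pair(hap_ref, hap_test, 2, limehh=0.0, maxgap_bp=10**9)
        assert i1 / i2 == pytest.approx(2.0, rel=1e-5)
        assert np.log(i1 / i2) == pytest.approx(np.log(2), abs=1e-5)
        assert np.log(2) == pytest.approx(0.6931, abs=5e-5)

    def test_standardized_mean0_sd1(self, tiny_sweep):
        _, hap1, hap2, _ = tiny_sweep
        df = xpehh_scan(hap1, hap2)
        x = df["xpehh"].to_numpy()
        ok = np.isfinite(x)
        assert x[ok].mean() == pytest.approx(0.0, abs=1e-9)
        assert x[ok].std() == pytest.approx(1.0, abs=1e-9)

    def test_swapping_populations_negates_unxpehh(self, tiny_sweep):
        _, hap1, hap2, _ = tiny_sweep
        fwd = xpehh_scan(hap1, hap2, standardize=False)["unxpehh"].to_numpy()
        rev = xpehh_scan(hap2, hap1, standardize=False)["unxpehh"].to_numpy()
        both = np.isfinite(fwd) & np.isfinite(rev)
        assert np.allclose(fwd[both], -rev[both], atol=1e-12)

    def test_site_list_mismatch_rejected(self, tiny_sweep):
        _, hap1, hap2, _ = tiny_sweep
        shifted = HaplotypeMatrix(hap2.alleles[:, 1:],
                                  hap2.positions_bp[1:],
                                  hap2.positions_cM[1:],
                                  list(hap2.sample_of_hap))
        with pytest.raises(ValueError, match="share sites"):
            xpehh_scan(hap1, shifted)
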