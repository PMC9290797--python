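import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixscan.core_io import MISSING, WindowSpec
from admixscan.popstats import (
    AlleleFrequencyTable,
    allele_frequencies,
    joint_sfs,
    pbs,
    window_fst_hudson,
    window_pi,
)
from oracles import pairwise_pi_oracle


def window(start, end, scaffold="scaf1"):
    return WindowSpec(
        scaffold=scaffold, start=start, end=end, snp_start=0, snp_stop=0,
        mode="coordinate",
    )


def freq_table(p_by_pop, n_by_pop, positions=None):
    pops = list(p_by_pop)
    p = np.array([p_by_pop[k] for k in pops], dtype=float)
    n = np.array([n_by_pop[k] for k in pops], dtype=np.int64)
    if positions is None:
        positions = np.arange(p.shape[1])
    return AlleleFrequencyTable(
        scaffold="scaf1", positions=np.asarray(positions), populations=pops, p=p, n=n
    )


# ---------------------------------------------------------------------------
# allele_frequencies
# ---------------------------------------------------------------------------


class TestAlleleFrequencies:
    def test_all_zero_site(self, make_hm, make_popmap):
        hm = make_hm(np.zeros((4, 1), dtype=np.int8))
        pm = make_popmap({"s0": "A", "s1": "A"})
        ft = allele_frequencies(hm, pm, ["A"])
        assert ft.p[0, 0] == 0.0
        assert ft.n[0, 0] == 4

    def test_missing_excluded_from_denominator(self, make_hm, make_popmap):
        hm = make_hm(np.array([[0], [1], [1], [MISSING]], dtype=np.int8))
        pm = make_popmap({"s0": "A", "s1": "A"})
        ft = allele_frequencies(hm, pm, ["A"])
        assert ft.p[0, 0] == pytest.approx(2 / 3)
        assert ft.n[0, 0] == 3

    def test_absent_population_errors(self, make_hm, make_popmap):
        hm = make_hm(np.zeros((4, 1), dtype=np.int8))
        pm = make_popmap({"s0": "A", "s1": "A"})
        with pytest.raises(ValueError, match="B"):
            allele_frequencies(hm, pm, ["B"])


# ---------------------------------------------------------------------------
# window_pi
# ---------------------------------------------------------------------------


class TestWindowPi:
    def test_monomorphic_window_zero(self, make_hm, make_popmap):
        hm = make_hm(np.zeros((4, 5), dtype=np.int8), positions=range(10, 15))
        pm = make_popmap({"s0": "A", "s1": "A"})
        assert window_pi(hm, window(0, 5000), pm, "A") == 0.0

    def test_single_snp_worked_example(self, make_hm, make_popmap):
        # alleles {0,0,1,1}, n=4, window 5000 bp:
        # (2*2*2/(4*3)) / 5000 = 1.3333e-4
        hm = make_hm(np.array([[0], [0], [1], [1]], dtype=np.int8), positions=[100])
        pm = make_popmap({"s0": "A", "s1": "A"})
        got = window_pi(hm, window(0, 5000), pm, "A")
        assert got == pytest.approx(2 * 2 * 2 / (4 * 3) / 5000, rel=1e-12)
        oracle = pairwise_pi_oracle(hm.alleles, 5000)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_length_scaling(self, make_hm, make_popmap):
        hm = make_hm(
            np.array([[0, 1], [1, 0], [1, 1], [0, 0]], dtype=np.int8),
            positions=[10, 20],
        )
        pm = make_popmap({"s0": "A", "s1": "A"})
        pi1 = window_pi(hm, window(0, 5000), pm, "A")
        pi2 = window_pi(hm, window(0, 10000), pm, "A")
        assert pi1 == pytest.approx(2 * pi2, rel=1e-12)

    def test_matches_pairwise_oracle_random(self, make_hm, make_popmap):
        rng = np.random.default_rng(5)
        for _ in range(5):
            alleles = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
            positions = np.sort(rng.choice(4000, 30, replace=False))
            hm = make_hm(alleles, positions=positions)
            pm = make_popmap({f"s{i}": "A" for i in range(4)})
            got = window_pi(hm, window(0, 4000), pm, "A")
            assert got == pytest.approx(pairwise_pi_oracle(alleles, 4000), rel=1e-12)

    def test_zero_length_window_errors(self, make_hm, make_popmap):
        hm = make_hm(np.zeros((4, 1), dtype=np.int8))
        pm = make_popmap({"s0": "A", "s1": "A"})
        with pytest.raises(ValueError):
            WindowSpec("scaf1", 5, 5, 0, 0, "coordinate")


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        ft = freq_table({"A": [1.0], "B": [0.0]}, {"A": [4], "B": [6]})
        raw, clamped, n = window_fst_hudson(ft, "A", "B")
        assert raw == pytest.approx(1.0)
        assert n == 1

    def test_worked_example(self):
        # pA=0.2, pB=0.8, nA=nB=10:
        # N = 0.36 - 0.16/9 - 0.16/9 = 0.324444, D = 0.04 + 0.64 = 0.68
        ft = freq_table({"A": [0.2], "B": [0.8]}, {"A": [10], "B": [10]})
        raw, clamped, _ = window_fst_hudson(ft, "A", "B")
        expect_n = (0.2 - 0.8) ** 2 - 0.2 * 0.8 / 9 - 0.8 * 0.2 / 9
        expect_d = 0.2 * 0.2 + 0.8 * 0.8
        assert expect_n == pytest.approx(0.324444, abs=1e-6)
        assert expect_d == pytest.approx(0.68)
        assert raw == pytest.approx(expect_n / expect_d, rel=1e-12)
        assert raw == pytest.approx(0.47712, abs=1e-5)

    def test_identical_frequencies_clamped_zero(self):
        p = [0.3, 0.5, 0.9]
        ft = freq_table({"A": p, "B": p}, {"A": [10] * 3, "B": [10] * 3})
        raw, clamped, _ = window_fst_hudson(ft, "A", "B")
        assert raw <= 0
        assert clamped == 0.0

    def test_no_usable_sites_is_nan(self):
        ft = freq_table({"A": [0.5], "B": [np.nan]}, {"A": [10], "B": [0]})
        raw, clamped, n = window_fst_hudson(ft, "A", "B")
        assert n == 0
        assert np.isnan(raw) and np.isnan(clamped)

    @settings(max_examples=50, deadline=None)
    @given(
        p=st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=10
        ),
        na=st.integers(2, 20),
        nb=st.integers(2, 20),
    )
    def test_symmetry(self, p, na, nb):
        pa = [x for x, _ in p]
        pb = [y for _, y in p]
        ft = freq_table(
            {"A": pa, "B": pb}, {"A": [na] * len(p), "B": [nb] * len(p)}
        )
        fab = window_fst_hudson(ft, "A", "B")
        fba = window_fst_hudson(ft, "B", "A")
        if np.isnan(fab[0]):
            assert np.isnan(fba[0])
        else:
            assert fab[0] == fba[0]
            assert fab[1] == fba[1]


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------


class TestPbs:
    def test_all_zero(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0

    def test_worked_example(self):
        # T(0.5) = ln 2; (ln2 + ln2 - 0)/2 = ln2 = 0.693147
        got = pbs(0.5, 0.5, 0.0)
        assert got == pytest.approx(np.log(2), rel=1e-9)
        assert got == pytest.approx(0.693147, abs=1e-6)

    def test_symmetric_fst(self):
        for f in (0.1, 0.4, 0.9):
            assert pbs(f, f, f) == pytest.approx(-np.log1p(-f) / 2, rel=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            pbs(1.0, 0.5, 0.2)
        with pytest.raises(ValueError):
            pbs(0.5, -0.1, 0.2)

    @settings(max_examples=100, deadline=None)
    @given(
        fab=st.floats(0, 0.99),
        fac=st.floats(0, 0.99),
        fbc=st.floats(0, 0.99),
    )
    def test_additivity_identity(self, fab, fac, fbc):
        # PBS_A + PBS_B = T_AB
        pbs_a = pbs(fab, fac, fbc)
        pbs_b = pbs(fab, fbc, fac)
        t_ab = -np.log1p(-fab)
        assert pbs_a + pbs_b == pytest.approx(t_ab, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# joint SFS
# ---------------------------------------------------------------------------


class TestJointSfs:
    def build(self, make_hm, make_popmap, cols):
        """cols: list of per-site haplotype columns for samples
        (out, p1, p2), 2 haplotypes each."""
        alleles = np.array(cols, dtype=np.int8).T
        hm = make_hm(alleles, samples=["out", "a1", "b1"])
        pm = make_popmap({"out": "OUT", "a1": "P1", "b1": "P2"})
        return hm, pm

    def test_all_fixed_ancestral(self, make_hm, make_popmap):
        hm, pm = self.build(make_hm, make_popmap, [[0] * 6, [0] * 6, [0] * 6])
        sfs = joint_sfs(hm, pm, ["P1", "P2"], "OUT")
        assert sfs.entries[0, 0] == 3
        assert sfs.excluded_sites == 0

    def test_worked_counts(self, make_hm, make_popmap):
        # derived counts (0,0), (1,1), (2,0) with fixed outgroup
        cols = [
            [0, 0, 0, 0, 0, 0],
            [0, 0, 0, 1, 1, 0],
            [0, 0, 1, 1, 0, 0],
        ]
        hm, pm = self.build(make_hm, make_popmap, cols)
        sfs = joint_sfs(hm, pm, ["P1", "P2"], "OUT")
        assert sfs.entries[0, 0] == 1
        assert sfs.entries[1, 1] == 1
        assert sfs.entries[2, 0] == 1
        assert sfs.excluded_sites == 0
        assert sfs.total_sites == 3

    def test_polymorphic_outgroup_excluded(self, make_hm, make_popmap):
        cols = [[0, 1, 0, 0, 1, 1]]  # outgroup 0/1 -> excluded
        hm, pm = self.build(make_hm, make_popmap, cols)
        sfs = joint_sfs(hm, pm, ["P1", "P2"], "OUT")
        assert sfs.excluded_sites == 1
        assert sfs.entries.sum() == 0

    def test_derived_outgroup_polarizes(self, make_hm, make_popmap):
        # outgroup fixed for allele 1 -> allele 0 is derived
        cols = [[1, 1, 0, 1, 1, 1]]
        hm, pm = self.build(make_hm, make_popmap, cols)
        sfs = joint_sfs(hm, pm, ["P1", "P2"], "OUT")
        assert sfs.entries[1, 0] == 1

    def test_partial_call_excluded(self, make_hm, make_popmap):
        cols = [[0, 0, MISSING, 0, 0, 0]]
        hm, pm = self.build(make_hm, make_popmap, cols)
        sfs = joint_sfs(hm, pm, ["P1", "P2"], "OUT")
        assert sfs.excluded_sites == 1

    def test_outgroup_overlap_errors(self, make_hm, make_popmap):
        hm, pm = self.build(make_hm, make_popmap, [[0] * 6])
        with pytest.raises(ValueError):
            joint_sfs(hm, pm, ["P1", "OUT"], "OUT")

    def test_write_round_trip_counts(self, make_hm, make_popmap, tmp_path):
        cols = [[0, 0, 0, 1, 1, 0], [0, 0, 1, 1, 0, 0]]
        hm, pm = self.build(make_hm, make_popmap, cols)
        sfs = joint_sfs(hm, pm, ["P1", "P2"], "OUT")
        path = tmp_path / "sfs.tsv"
        sfs.write(path)
        text = path.read_text()
        flat = [int(x) for x in text.strip().split("\n")[-1].split("\t")[1].split()]
        assert flat == sfs.entries.ravel(order="C").tolist()
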