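import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from metahet import mmp as M
from metahet.io_core import GeneSet


def make_program(sample, k, factor, genes, coeffs=None):
    genes = list(genes)
    assert len(genes) == 30
    if coeffs is None:
        coeffs = list(np.linspace(3.0, 1.0, 30))
    return M.NMFProgram(sample_id=sample, k=k, factor_index=factor,
                        genes=genes, coefficients=coeffs)


def genes_from(universe, idx):
    return [universe[i] for i in idx]


# ---------------------------------------------------------------------------
# independent brute-force implementations (oracles)
# ---------------------------------------------------------------------------


def brute_force_robust(programs):
    """Re-implementation of the three robustness rules from their definitions."""
    kept = []
    for p in programs:
        crit1 = False
        for q in programs:
            if q is p or q.sample_id != p.sample_id or q.k == p.k:
                continue
            if len(set(p.genes) & set(q.genes)) >= 0.7 * 30:
                crit1 = True
        crit2 = False
        for q in programs:
            if q.sample_id == p.sample_id:
                continue
            if len(set(p.genes) & set(q.genes)) >= 0.2 * 30:
                crit2 = True
        if crit1 and crit2:
            kept.append(p)
    final = []
    for sample in sorted({p.sample_id for p in kept}):
        mine = [p for p in kept if p.sample_id == sample]
        other = [p for p in kept if p.sample_id != sample]

        def max_cross(p):
            return max(
                (len(set(p.genes) & set(q.genes)) for q in other), default=0
            )

        mine_sorted = sorted(mine, key=lambda p: (-max_cross(p), p.k, p.factor_index))
        chosen = []
        for p in mine_sorted:
            redundant = any(
                len(set(p.genes) & set(q.genes)) > 0.2 * 30 for q in chosen
            )
            if not redundant:
                chosen.append(p)
        final.extend(chosen)
    return sorted(final, key=lambda p: (p.sample_id, p.k, p.factor_index))


def exact_hypergeom_sf(k_obs, pop, successes, draws):
    """Upper-tail P(X >= k_obs) by direct summation of the hypergeometric mass."""
    total = 0.0
    for k in range(k_obs, min(successes, draws) + 1):
        total += (
            math.comb(successes, k)
            * math.comb(pop - successes, draws - k)
            / math.comb(pop, draws)
        )
    return min(total, 1.0)


def brute_force_abundance(mmps, prog_types):
    """Independent arithmetic + rule-order implementation."""
    n_robust = len(prog_types)
    all_types = sorted(set(prog_types.values()))
    n_tests = len(mmps) * len(all_types)
    out = {}
    for m in mmps:
        for ct in all_types:
            obs = sum(1 for pid in m.members if prog_types[pid] == ct)
            n_cancer = sum(1 for t in prog_types.values() if t == ct)
            exp = len(m.members) * n_cancer / n_robust
            ab = math.log2((obs + 1) / (exp + 1))
            p = min(1.0, exact_hypergeom_sf(obs, n_robust, len(m.members), n_cancer) * n_tests)
            if obs > 10 or ab > 1:
                cat = "high_significant" if p < 0.05 else "high"
            elif 2 <= obs <= 10 or 0 < ab <= 1:
                cat = "medium"
            elif obs == 1 and -1.5 < ab <= 0:
                cat = "low"
            else:
                cat = "absent"
            out[(m.mmp_id, ct)] = (obs, exp, ab, p, cat)
    return out


def random_instance(rng, max_programs=30):
    """Random small program collection over a small gene universe."""
    universe = [f"g{i}" for i in range(rng.integers(40, 90))]
    n_samples = int(rng.integers(2, 6))
    n_prog = int(rng.integers(2, max_programs + 1))
    programs = []
    for i in range(n_prog):
        sample = f"S{rng.integers(n_samples) + 1}"
        k = int(rng.choice([4, 5, 6]))
        base = rng.choice(len(universe), size=30, replace=False)
        programs.append(
            make_program(sample, k, i, genes_from(universe, base))
        )
    return programs


class TestNMFPrograms:
    def _block_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        n_cells = 60
        genes = [f"g{i:02d}" for i in range(60)]
        vals = rng.random((n_cells, 60)) * 0.05
        vals[:30, :30] += 3.0 + rng.random((30, 30))
        vals[30:, 30:] += 3.0 + rng.random((30, 30))
        return pd.DataFrame(vals, columns=genes)

    def test_default_k_schedule_gives_39_programs(self):
        mat = self._block_matrix()
        progs = M.nmf_programs(mat, "S1", seed=0)
        assert len(progs) == sum(M.DEFAULT_K_VALUES) == 39

    def test_every_program_has_30_genes(self):
        progs = M.nmf_programs(self._block_matrix(), "S1", seed=0)
        assert all(len(p.genes) == 30 for p in progs)
        for p in progs:
            assert np.all(np.diff(p.coefficients) <= 1e-12)

    def test_planted_blocks_recovered_at_k2(self):
        mat = self._block_matrix()
        progs = M.nmf_programs(mat, "S1", k_values=[2], seed=0)
        assert len(progs) == 2
        found = {frozenset(p.genes) for p in progs}
        block_a = frozenset(f"g{i:02d}" for i in range(30))
        block_b = frozenset(f"g{i:02d}" for i in range(30, 60))
        assert found == {block_a, block_b}

    def test_small_sample_skipped(self):
        mat = self._block_matrix().iloc[:10]
        assert M.nmf_programs(mat, "tiny", seed=0) == []

    def test_deterministic(self):
        mat = self._block_matrix()
        a = M.nmf_programs(mat, "S1", seed=3)
        b = M.nmf_programs(mat, "S1", seed=3)
        assert [(p.genes, p.coefficients) for p in a] == [
            (p.genes, p.coefficients) for p in b
        ]


class TestRobustFilter:
    def test_boundary_retained(self):
        universe = [f"g{i}" for i in range(100)]
        # p0: 21/30 shared with a different-K program in S1, 6/30 with S2
        p0 = make_program("S1", 4, 0, genes_from(universe, range(30)))
        p1 = make_program("S1", 5, 0, genes_from(universe, list(range(21)) + list(range(40, 49))))
        p2 = make_program("S2", 4, 0, genes_from(universe, list(range(6)) + list(range(60, 84))))
        # partners need their own robustness: give p1/p2 cross matches
        p3 = make_program("S1", 6, 0, genes_from(universe, list(range(21)) + list(range(40, 49))))
        p4 = make_program("S2", 5, 0, genes_from(universe, list(range(6)) + list(range(60, 84))))
        robust = M.robust_filter([p0, p1, p2, p3, p4])
        assert any(p.program_id == p0.program_id for p in robust)

    def test_isolated_program_removed(self):
        universe = [f"g{i}" for i in range(200)]
        iso = make_program("S1", 4, 0, genes_from(universe, range(30)))
        other = make_program("S2", 4, 0, genes_from(universe, range(60, 90)))
        assert M.robust_filter([iso, other]) == []

    def test_within_tumour_redundancy_keeps_higher_cross_overlap(self):
        universe = [f"g{i}" for i in range(120)]
        shared = list(range(7))  # 7 shared genes -> >20% redundancy
        a = make_program("S1", 4, 0, genes_from(universe, shared + list(range(10, 33))))
        a2 = make_program("S1", 5, 0, genes_from(universe, shared + list(range(10, 33))))
        b = make_program("S1", 4, 1, genes_from(universe, shared + list(range(40, 63))))
        b2 = make_program("S1", 5, 1, genes_from(universe, shared + list(range(40, 63))))
        # cross-tumour: a has full 30-gene twin elsewhere, b only 8 genes
        a_twin = make_program("S2", 4, 0, genes_from(universe, shared + list(range(10, 33))))
        b_weak = make_program("S2", 4, 1, genes_from(universe, shared + [universe.index(g) for g in []] + list(range(62, 85))))
        robust = M.robust_filter([a, a2, b, b2, a_twin, b_weak])
        s1_kept = {p.factor_index for p in robust if p.sample_id == "S1"}
        assert 0 in s1_kept and 1 not in s1_kept

    @pytest.mark.parametrize("trial", range(50))
    def test_agrees_with_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        programs = random_instance(rng)
        got = {p.program_id for p in M.robust_filter(programs)}
        want = {p.program_id for p in brute_force_robust(programs)}
        assert got == want


class TestClusterMMPs:
    def test_identical_programs_one_mmp(self):
        universe = [f"g{i}" for i in range(60)]
        genes = genes_from(universe, range(30))
        progs = [make_program(f"S{i}", 4, 0, genes) for i in range(12)]
        mmps, unassigned = M.cluster_mmps(progs)
        assert len(mmps) == 1
        assert mmps[0].n_members == 12
        assert set(mmps[0].genes) == set(genes)
        assert unassigned == []

    def test_nine_member_cluster_dropped(self):
        universe = [f"g{i}" for i in range(60)]
        genes = genes_from(universe, range(30))
        progs = [make_program(f"S{i}", 4, 0, genes) for i in range(9)]
        mmps, unassigned = M.cluster_mmps(progs)
        assert mmps == []
        assert len(unassigned) == 9

    def test_empty_input(self):
        assert M.cluster_mmps([]) == ([], [])

    def test_two_well_separated_clusters(self):
        universe = [f"g{i}" for i in range(120)]
        g1 = genes_from(universe, range(30))
        g2 = genes_from(universe, range(60, 90))
        progs = [make_program(f"A{i}", 4, 0, g1) for i in range(11)]
        progs += [make_program(f"B{i}", 4, 0, g2) for i in range(10)]
        mmps, _ = M.cluster_mmps(progs)
        assert len(mmps) == 2
        assert {frozenset(m.genes) for m in mmps} == {frozenset(g1), frozenset(g2)}

    def test_members_span_multiple_tumours(self):
        universe = [f"g{i}" for i in range(60)]
        genes = genes_from(universe, range(30))
        progs = [make_program(f"S{i}", 4, 0, genes) for i in range(12)]
        mmps, _ = M.cluster_mmps(progs)
        assert len(mmps[0].tumours) >= 2


class TestAnnotateMMP:
    def _mmp(self, genes):
        return M.MMP(mmp_id="MMP1", genes=list(genes), members=["p1"] * 10)

    def test_fully_contained_pathway_annotated(self):
        bg = [f"g{i}" for i in range(1500)]
        pathway = GeneSet("glyco", bg[:40])
        other = GeneSet("other", bg[200:260])
        m = self._mmp(bg[:30])
        name, p = M.annotate_mmp(m, [pathway, other], bg)
        assert name == "glyco" and p < 0.05

    def test_exact_tail_summation(self):
        bg = [f"g{i}" for i in range(1500)]
        # overlap 5: MMP genes 0..29, pathway = genes 25..74 (overlap 25..29)
        pathway = GeneSet("pw", bg[25:75])
        m = self._mmp(bg[:30])
        M.annotate_mmp(m, [pathway], bg)
        p_direct = exact_hypergeom_sf(5, 1500, 50, 30)
        p_scipy = float(scipy.stats.hypergeom.sf(4, 1500, 50, 30))
        assert p_scipy == pytest.approx(p_direct, rel=1e-9)

    def test_zero_overlap_unannotated(self):
        bg = [f"g{i}" for i in range(500)]
        pathway = GeneSet("pw", bg[400:460])
        m = self._mmp(bg[:30])
        name, _ = M.annotate_mmp(m, [pathway], bg)
        assert name == "unannotated"

    def test_empty_pathways_raise(self):
        bg = [f"g{i}" for i in range(100)]
        with pytest.raises(ValueError):
            M.annotate_mmp(self._mmp(bg[:30]), [], bg)


class TestAbundance:
    def _mmp_with_members(self, mmp_id, member_ids):
        universe = [f"g{i}" for i in range(40)]
        return M.MMP(
            mmp_id=mmp_id, genes=universe[:30], members=list(member_ids)
        )

    def test_worked_example(self):
        # N_MMP=12, N_cancer=39, N_robust=390, observed=4
        prog_types = {}
        members = []
        for i in range(12):
            pid = f"m{i}"
            members.append(pid)
            prog_types[pid] = "CRC" if i < 4 else "OTHER"
        # pad CRC to 39 robust programs and the pool to 390
        for i in range(35):
            prog_types[f"crc_extra{i}"] = "CRC"
        for i in range(390 - len(prog_types)):
            prog_types[f"pad{i}"] = "OTHER"
        assert len(prog_types) == 390
        m = self._mmp_with_members("MMP1", members)
        tab = M.abundance([m], prog_types).set_index("cancer_type")
        row = tab.loc["CRC"]
        assert row["observed"] == 4
        assert row["expected"] == pytest.approx(1.2)
        assert row["abundance"] == pytest.approx(math.log2(5 / 2.2), rel=1e-9)
        assert row["abundance"] == pytest.approx(1.184, abs=1e-3)
        assert row["category"] in ("high", "high_significant")

    def test_observed_eleven_is_high(self):
        prog_types = {f"m{i}": "CRC" for i in range(11)}
        prog_types.update({f"o{i}": "OTHER" for i in range(20)})
        m = self._mmp_with_members("MMP1", [f"m{i}" for i in range(11)])
        tab = M.abundance([m], prog_types).set_index("cancer_type")
        assert tab.loc["CRC", "category"] in ("high", "high_significant")
        assert tab.loc["CRC", "observed"] == 11

    def test_zero_observed_zero_expected_absent(self):
        # a cancer type with no robust programs cannot appear in the table;
        # emulate expected ~ 0 via a tiny type share
        prog_types = {f"m{i}": "A" for i in range(10)}
        prog_types["only_b"] = "B"
        m = self._mmp_with_members("MMP1", [f"m{i}" for i in range(10)])
        tab = M.abundance([m], prog_types).set_index("cancer_type")
        assert tab.loc["B", "observed"] == 0
        assert tab.loc["B", "category"] == "absent"

    def test_conservation_of_members(self):
        rng = np.random.default_rng(0)
        types = ["A", "B", "C"]
        prog_types = {f"p{i}": types[rng.integers(3)] for i in range(40)}
        members = [f"p{i}" for i in range(12)]
        m = self._mmp_with_members("MMP1", members)
        tab = M.abundance([m], prog_types)
        assert tab["observed"].sum() == len(members)

    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        types = [f"T{i}" for i in range(int(rng.integers(2, 5)))]
        n_prog = int(rng.integers(15, 60))
        prog_types = {f"p{i}": types[rng.integers(len(types))] for i in range(n_prog)}
        mmps = []
        cursor = 0
        for j in range(int(rng.integers(1, 4))):
            size = int(rng.integers(10, 14))
            if cursor + size > n_prog:
                break
            mmps.append(
                self._mmp_with_members(f"MMP{j + 1}", [f"p{i}" for i in range(cursor, cursor + size)])
            )
            cursor += size
        if not mmps:
            pytest.skip("instance too small")
        got = M.abundance(mmps, prog_types)
        want = brute_force_abundance(mmps, prog_types)
        for _, row in got.iterrows():
            obs, exp, ab, p, cat = want[(row["mmp_id"], row["cancer_type"])]
            assert row["observed"] == obs
            assert row["expected"] == pytest.approx(exp, rel=1e-12)
            assert row["abundance"] == pytest.approx(ab, rel=1e-12)
            assert row["p_bonferroni"] == pytest.approx(p, rel=1e-9, abs=1e-12)
            assert row["category"] == cat

    def test_no_programs_raises(self):
        with pytest.raises(ValueError):
            M.abundance([], {})


class TestJaccard:
    def test_diagonal_and_symmetry(self):
        universe = [f"g{i}" for i in range(90)]
        p1 = make_program("S1", 4, 0, genes_from(universe, range(30)))
        p2 = make_program("S2", 4, 0, genes_from(universe, range(15, 45)))
        jac = M.jaccard_matrix([p1, p2])
        assert jac.iloc[0, 0] == 1.0
        assert jac.iloc[0, 1] == jac.iloc[1, 0] == pytest.approx(15 / 45)
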