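"""Composite interval mapping: probabilities, scans, thresholds, QTL calls."""

import numpy as np
import pandas as pd
import pytest

from rindqtl import qtl
from rindqtl import simulate as sim
from rindqtl.mapqc import MarkerMatrix
from rindqtl.qtl import QTLInterval
from rindqtl.simulate import haldane_r, ril_expansion


def make_grid(n_lines=200, n_chrom=2, length=100.0, n_markers=51, seed=5, qtl_specs=()):
    cfg = sim.SimConfig(
        n_lines=n_lines,
        chromosomes=(sim.ChromosomeSpec(length, 100_000_000, n_markers),) * n_chrom,
        seed=seed,
        qtl=tuple(qtl_specs),
    )
    gmap = sim.simulate_genetic_map(cfg)
    pop, arch = sim.simulate_ril_population(gmap, n_lines, seed=seed)
    mm = MarkerMatrix(pop.geno, gmap[["marker", "chrom", "pos_bp"]])
    grid = qtl.genotype_probabilities(gmap, mm, step_cM=1.0)
    return cfg, gmap, pop, arch, mm, grid


class TestGenotypeProbabilities:
    def test_observed_marker_probability_one(self):
        _, gmap, pop, _, mm, grid = make_grid(n_lines=50)
        at = grid.positions["at_marker"].to_numpy()
        cm = grid.positions["pos_cM"].to_numpy()
        chrom = grid.positions["chrom"].to_numpy()
        for j in np.nonzero(at)[0][:20]:
            row = gmap[(gmap["chrom"] == chrom[j]) & (np.isclose(gmap["pos_cM"], cm[j]))]
            marker = row["marker"].iloc[0]
            obs = pop.geno[marker].to_numpy()
            p2 = grid.prob2[:, j]
            assert np.allclose(p2[obs == 2.0], 1.0)
            assert np.allclose(p2[obs == 0.0], 0.0)

    def test_probabilities_sum_to_one_in_unit_interval(self):
        _, _, _, _, _, grid = make_grid(n_lines=30)
        assert np.all((grid.prob2 >= 0) & (grid.prob2 <= 1))

    def test_tight_linkage_concordant_flanks(self):
        m = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": [1, 1], "pos_bp": [1, 100],
             "pos_cM": [0.0, 0.02]}
        )
        geno = pd.DataFrame({"a": [0.0, 2.0], "b": [0.0, 2.0]}, index=["L1", "L2"])
        mm = MarkerMatrix(geno, m[["marker", "chrom", "pos_bp"]])
        grid = qtl.genotype_probabilities(m, mm, step_cM=0.01)
        mid = np.argmin(np.abs(grid.positions["pos_cM"].to_numpy() - 0.01))
        assert grid.prob2[0, mid] == pytest.approx(0.0, abs=1e-3)
        assert grid.prob2[1, mid] == pytest.approx(1.0, abs=1e-3)

    def test_discordant_flanks_match_brute_force_enumeration(self):
        # midpoint of a 20 cM interval, flanks 0 / 2: enumerate both paths
        m = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": [1, 1], "pos_bp": [1, 1000],
             "pos_cM": [0.0, 20.0]}
        )
        geno = pd.DataFrame({"a": [0.0], "b": [2.0]}, index=["L1"])
        mm = MarkerMatrix(geno, m[["marker", "chrom", "pos_bp"]])
        grid = qtl.genotype_probabilities(m, mm, step_cM=1.0)
        cm = grid.positions["pos_cM"].to_numpy()
        R10 = float(ril_expansion(haldane_r(10.0)))
        # brute force: P(left=0 -> s -> right=2) over intermediate state s
        paths = {}
        for s, p_l in (("0", 1 - R10), ("2", R10)):  # left transition to state s
            p_r = R10 if s == "0" else 1 - R10  # s to right flank (=2)
            paths[s] = p_l * p_r
        expect = paths["2"] / (paths["0"] + paths["2"])
        mid = np.argmin(np.abs(cm - 10.0))
        assert grid.prob2[0, mid] == pytest.approx(expect, abs=1e-10)

    def test_missing_flank_uses_nearest_informative(self):
        m = pd.DataFrame(
            {"marker": ["a", "b", "c"], "chrom": [1, 1, 1], "pos_bp": [1, 500, 1000],
             "pos_cM": [0.0, 10.0, 20.0]}
        )
        geno = pd.DataFrame({"a": [0.0], "b": [np.nan], "c": [0.0]}, index=["L1"])
        mm = MarkerMatrix(geno, m[["marker", "chrom", "pos_bp"]])
        grid = qtl.genotype_probabilities(m, mm, step_cM=1.0)
        mid = np.argmin(np.abs(grid.positions["pos_cM"].to_numpy() - 10.0))
        assert grid.prob2[0, mid] < 0.5  # pulled toward parent-1 by both flanks


class TestCIMScan:
    def test_noiseless_dosage_phenotype_peaks_at_marker(self):
        _, gmap, pop, _, mm, grid = make_grid(n_lines=120, seed=6)
        target = gmap["marker"].iloc[25]
        x = pop.geno[target].to_numpy() - 1.0
        y = 4.0 + 0.3 * x  # exact additive signal, no noise
        res = qtl.cim_scan(y, grid, n_cofactors=0)
        peak = res.positions.iloc[int(np.argmax(res.lod))]
        assert peak["chrom"] == gmap["chrom"].iloc[25]
        assert peak["pos_cM"] == pytest.approx(gmap["pos_cM"].iloc[25], abs=1e-9)
        assert res.effect[int(np.argmax(res.lod))] == pytest.approx(0.3, abs=1e-8)

    def test_zero_cofactors_equals_simple_interval_mapping(self):
        _, _, pop, _, _, grid = make_grid(n_lines=100, seed=7)
        rng = np.random.default_rng(7)
        y = rng.normal(4, 1, 100)
        res = qtl.cim_scan(y, grid, n_cofactors=0)
        # independent SIM: per position, single-marker regression LOD
        D = grid.dosage
        n = len(y)
        yc = y - y.mean()
        rss0 = float(yc @ yc)
        for j in range(0, grid.n_positions, 17):
            x = D[:, j]
            X = np.column_stack([np.ones(n), x])
            b, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(np.sum((y - X @ b) ** 2))
            lod = n / 2 * np.log10(rss0 / rss1)
            assert res.lod[j] == pytest.approx(lod, abs=1e-8)

    def test_lod_invariant_under_affine_phenotype_transform(self):
        _, _, _, _, _, grid = make_grid(n_lines=80, seed=8)
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, 80)
        r1 = qtl.cim_scan(y, grid, n_cofactors=3)
        r2 = qtl.cim_scan(3.5 * y - 11.0, grid, n_cofactors=3)
        assert np.allclose(r1.lod, r2.lod, atol=1e-8)

    def test_effect_sign_flips_with_parental_labels(self):
        _, gmap, pop, _, mm, grid = make_grid(n_lines=100, seed=9)
        rng = np.random.default_rng(9)
        y = 0.4 * (pop.geno[gmap["marker"].iloc[10]].to_numpy() - 1) + rng.normal(0, 0.5, 100)
        res1 = qtl.cim_scan(y, grid, n_cofactors=0)
        flipped = MarkerMatrix(2.0 - pop.geno, gmap[["marker", "chrom", "pos_bp"]])
        grid2 = qtl.genotype_probabilities(gmap, flipped, step_cM=1.0)
        res2 = qtl.cim_scan(y, grid2, n_cofactors=0)
        assert np.allclose(res1.effect, -res2.effect, atol=1e-8)
        assert np.allclose(res1.lod, res2.lod, atol=1e-8)

    def test_cofactor_absorption_beats_sim_usually(self):
        # two QTL on different chromosomes; cofactoring QTL-2 sharpens QTL-1
        wins = 0
        n_sim = 40
        for s in range(n_sim):
            cfg, gmap, pop, arch, mm, grid = make_grid(
                n_lines=200, seed=100 + s,
                qtl_specs=[
                    sim.QTLSpec(1, 50.0, tuple([0.25] * 7)),
                    sim.QTLSpec(2, 50.0, tuple([0.25] * 7)),
                ],
            )
            table = sim.simulate_phenotypes(pop, arch, cfg)
            y = (
                table[table.stage == "AS30"]
                .groupby("line")["value"].mean().reindex(pop.geno.index).to_numpy()
            )
            cim = qtl.cim_scan(y, grid, n_cofactors=5, window_cM=10.0)
            simres = qtl.cim_scan(y, grid, n_cofactors=0)
            on1 = (grid.positions["chrom"] == 1).to_numpy()
            if cim.lod[on1].max() >= simres.lod[on1].max():
                wins += 1
        assert wins / n_sim >= 0.8

    def test_too_many_cofactors_truncated_with_warning(self):
        _, _, _, _, _, grid = make_grid(n_lines=50, seed=10)
        y = np.random.default_rng(0).normal(size=50)
        with pytest.warns(UserWarning, match="n_cofactors"):
            qtl.cim_scan(y, grid, n_cofactors=20)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self):
        _, _, _, _, _, grid = make_grid(n_lines=60, n_chrom=1, seed=11)
        y = np.random.default_rng(1).normal(size=60)
        with pytest.warns(UserWarning):
            thr = qtl.permutation_threshold(y, grid, n_perm=50, alpha=1.0, seed=2)
        assert thr > 0

    def test_deterministic_given_seed(self):
        _, _, _, _, _, grid = make_grid(n_lines=60, n_chrom=1, seed=12)
        y = np.random.default_rng(2).normal(size=60)
        t1 = qtl.permutation_threshold(y, grid, n_perm=100, seed=3)
        t2 = qtl.permutation_threshold(y, grid, n_perm=100, seed=3)
        assert t1 == t2

    def test_monte_carlo_stability(self):
        _, _, _, _, _, grid = make_grid(n_lines=200, n_chrom=2, seed=13)
        y = np.random.default_rng(3).normal(size=200)
        t1 = qtl.permutation_threshold(y, grid, n_perm=1000, seed=4)
        t2 = qtl.permutation_threshold(y, grid, n_perm=1000, seed=5)
        assert abs(t1 - t2) < 0.3


class TestCallQTL:
    def test_empty_when_nothing_above_threshold(self):
        _, _, _, _, _, grid = make_grid(n_lines=60, n_chrom=1, seed=14)
        y = np.random.default_rng(4).normal(size=60)
        res = qtl.cim_scan(y, grid, n_cofactors=0)
        assert qtl.call_qtl(res, threshold=1e6) == []

    def test_noiseless_qtl_pve_100(self):
        _, gmap, pop, _, mm, grid = make_grid(n_lines=100, seed=15)
        x = pop.geno[gmap["marker"].iloc[30]].to_numpy() - 1.0
        y = 4.0 + 0.5 * x
        res = qtl.cim_scan(y, grid, n_cofactors=0)
        hits = qtl.call_qtl(res, threshold=3.0, phenotype=y, grid=grid)
        assert len(hits) >= 1
        assert hits[0].pve == pytest.approx(100.0, abs=1e-6)

    def test_support_interval_contains_peak(self):
        cfg, gmap, pop, arch, mm, grid = make_grid(
            n_lines=200, seed=16, qtl_specs=[sim.QTLSpec(1, 50.0, tuple([0.3] * 7))]
        )
        table = sim.simulate_phenotypes(pop, arch, cfg)
        y = (
            table[table.stage == "AS30"]
            .groupby("line")["value"].mean().reindex(pop.geno.index).to_numpy()
        )
        res = qtl.cim_scan(y, grid)
        hits = qtl.call_qtl(res, threshold=3.5, phenotype=y, grid=grid)
        for h in hits:
            assert h.ci_lo_cM <= h.peak_cM <= h.ci_hi_cM
            assert h.ci_lo_bp <= h.peak_bp <= h.ci_hi_bp
            assert 0 <= h.pve <= 100

    def test_qtl_name_codes(self):
        # published style: qAhb1 = env A, high-oil population, DTS, chrom 1
        assert qtl.qtl_name("E1", "DTS", "h", 1) == "qAhb1"
        assert qtl.qtl_name("E3", "AS50", "l", 10) == "qClg10"
        assert qtl.qtl_name("E2", "V10", "h", 6, index=2) == "qBha6-2"


class TestMergePleiotropic:
    @staticmethod
    def interval(name, chrom, lo_mb, hi_mb):
        mid = (lo_mb + hi_mb) / 2
        return QTLInterval(
            name=name, chrom=chrom, peak_cM=50.0, peak_bp=int(mid * 1e6), lod=5.0,
            additive_effect=0.1, pve=5.0, ci_lo_cM=40.0, ci_hi_cM=60.0,
            ci_lo_bp=int(lo_mb * 1e6), ci_hi_bp=int(hi_mb * 1e6),
        )

    def test_published_interval_lengths(self):
        # members jointly spanning the two printed pQTL physical ranges
        members6 = [
            self.interval("qAhe6", 6, 158.47, 163.0),
            self.interval("qBhb6", 6, 160.0, 165.5),
            self.interval("qChc6", 6, 162.2, 167.03),
        ]
        members8 = [
            self.interval("qClf8", 8, 118.33, 131.0),
            self.interval("qBlb8", 8, 125.0, 140.75),
        ]
        merged = qtl.merge_pleiotropic(members6 + members8)
        by_chrom = {p.chrom: p for p in merged}
        assert by_chrom[6].length_mb == pytest.approx(8.56)
        assert by_chrom[8].length_mb == pytest.approx(22.42)

    def test_disjoint_intervals_stay_separate(self):
        merged = qtl.merge_pleiotropic(
            [self.interval("a", 1, 10, 20), self.interval("b", 1, 30, 40)]
        )
        assert len(merged) == 2

    def test_transitive_chain_merge(self):
        # A-B overlap, B-C overlap, A-C disjoint -> one pQTL = A u B u C
        a = self.interval("a", 2, 10, 22)
        b = self.interval("b", 2, 20, 32)
        c = self.interval("c", 2, 30, 42)
        merged = qtl.merge_pleiotropic([a, b, c])
        assert len(merged) == 1
        p = merged[0]
        assert (p.start_bp, p.end_bp) == (int(10e6), int(42e6))
        assert set(p.members) == {"a", "b", "c"}
        # brute-force union oracle
        union = np.zeros(50_000_000, dtype=bool)
        for q in (a, b, c):
            union[q.ci_lo_bp : q.ci_hi_bp] = True
        assert union[p.start_bp : p.end_bp].all()

    def test_random_intervals_match_union_oracle(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(deadline=None, derandomize=True, max_examples=30)
        @given(
            st.lists(
                st.tuples(st.integers(0, 90), st.integers(1, 10)), min_size=1, max_size=8
            )
        )
        def check(spans):
            ivs = [
                self.interval(f"q{i}", 1, lo, lo + w) for i, (lo, w) in enumerate(spans)
            ]
            merged = qtl.merge_pleiotropic(ivs)
            # oracle: boolean union on a 0.1 Mb lattice
            lattice = np.zeros(1001, dtype=bool)
            for lo, w in spans:
                lattice[lo * 10 : (lo + w) * 10] = True
            # each merged span must be a maximal run of the union
            runs = []
            i = 0
            while i < len(lattice):
                if lattice[i]:
                    j = i
                    while j < len(lattice) and lattice[j]:
                        j += 1
                    runs.append((i / 10, j / 10))
                    i = j
                else:
                    i += 1
            got = sorted((p.start_bp / 1e6, p.end_bp / 1e6) for p in merged)
            assert len(got) == len(runs)
            for (glo, ghi), (rlo, rhi) in zip(got, runs):
                assert glo == pytest.approx(rlo, abs=0.11)
                assert ghi == pytest.approx(rhi, abs=0.11)

        check()
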