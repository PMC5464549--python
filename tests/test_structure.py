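import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from haplopop import Alignment, SampleMetadata, synth
from haplopop.seqio import DistanceMatrix, pairwise_differences
from haplopop.structure import (
    amova,
    geographic_distances,
    hudson_fst,
    mantel_test,
    nm_from_fst,
    pairwise_fst,
)


def _meta(ids, locs, areas=None, **kw):
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ids,
                "location": locs,
                "area": areas if areas is not None else ["all"] * len(ids),
                **kw,
            }
        )
    )


class TestNmFromFst:
    @pytest.mark.parametrize(
        "fst,expected",
        [(0.757, 0.161), (0.886, 0.064), (0.596, 0.339)],
    )
    def test_island_model_conversions(self, fst, expected):
        assert nm_from_fst(fst) == pytest.approx(expected, abs=5e-4)

    def test_complete_fixation(self):
        assert nm_from_fst(1.0) == 0.0

    def test_nonpositive_gives_infinity(self):
        assert nm_from_fst(0.0) == math.inf
        assert nm_from_fst(-0.02) == math.inf

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            nm_from_fst(1.2)

    def test_strictly_decreasing(self):
        grid = np.linspace(0.01, 1.0, 50)
        vals = [nm_from_fst(f) for f in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestPairwiseFst:
    def test_fixed_difference_gives_one(self):
        aln = Alignment(list("abcd"), ["AAAA", "AAAA", "TTTT", "TTTT"])
        meta = _meta(aln.ids, ["L1", "L1", "L2", "L2"], ["X", "X", "Y", "Y"])
        res = pairwise_fst(aln, meta, level="area", n_perm=20, seed=0)
        assert res.fst[0, 1] == pytest.approx(1.0)
        assert res.nm[0, 1] == pytest.approx(0.0)

    def test_panmictic_split_is_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for s in range(40):
            cfg = synth.SimConfig(
                areas=[("A", ["d"], [30])], theta=5.0, mig_within=0,
                mig_between=0, expansion=None, merge_time=None,
                infinite_sites=True, seed=s,
            )
            aln, _, _ = synth.simulate_study(cfg)
            d = pairwise_differences(aln).values
            idx = rng.permutation(30)
            vals.append(hudson_fst(d, idx[:15], idx[15:]))
        assert abs(np.mean(vals)) < 0.05

    def test_two_island_matches_parametric_and_msprime(self):
        # d=2 demes, per-deme migrant rate M=0.25: exact parametric Hudson
        # FST = 1/(1 + 2M d/(d-1)) = 0.5; ratio-of-means estimator over
        # replicates, with msprime as an independent coalescent oracle.
        import msprime

        reps = 150
        hw_sum = hb_sum = 0.0
        rng = np.random.default_rng(4)
        cfg = synth.SimConfig(
            areas=[("A", ["d1", "d2"], [10, 10])], theta=5.0,
            mig_within=0.25, mig_between=0, expansion=None,
            merge_time=None, infinite_sites=True, seed=0,
        )
        ia, ib = np.arange(10), np.arange(10, 20)
        for _ in range(reps):
            gen = synth.simulate_genealogy(cfg, rng)
            aln = synth.mutate_sequences(gen, cfg, rng)
            d = pairwise_differences(aln).values
            da, db = d[np.ix_(ia, ia)], d[np.ix_(ib, ib)]
            hw_sum += 0.5 * (da.sum() / 90 + db.sum() / 90)
            hb_sum += d[np.ix_(ia, ib)].mean()
        ours = 1 - hw_sum / hb_sum
        assert ours == pytest.approx(0.5, abs=0.07)

        dem = msprime.Demography.island_model([1.0, 1.0], migration_rate=0.25)
        hw_sum = hb_sum = 0.0
        A, B = list(range(10)), list(range(10, 20))
        for s in range(reps):
            ts = msprime.sim_ancestry(
                samples={0: 10, 1: 10}, demography=dem, ploidy=1,
                random_seed=s + 1,
            )
            hw_sum += 0.5 * (
                float(ts.diversity(A, mode="branch"))
                + float(ts.diversity(B, mode="branch"))
            )
            hb_sum += float(ts.divergence([A, B], mode="branch"))
        oracle = 1 - hw_sum / hb_sum
        assert ours == pytest.approx(oracle, abs=0.07)

    def test_insufficient_group_rejected(self):
        aln = Alignment(list("abc"), ["AAAA", "AAAT", "TTTT"])
        meta = _meta(aln.ids, ["L1", "L1", "L2"], ["X", "X", "Y"])
        with pytest.raises(ValueError):
            pairwise_fst(aln, meta, level="area", n_perm=10, seed=0)

    def test_weir_estimator_runs_and_agrees_in_sign(self):
        aln = Alignment(
            list("abcdefgh"),
            ["AAAA"] * 3 + ["AAAT"] + ["TTTT"] * 3 + ["TTTA"],
        )
        meta = _meta(
            aln.ids, ["L1"] * 4 + ["L2"] * 4, ["X"] * 4 + ["Y"] * 4
        )
        h = pairwise_fst(aln, meta, level="area", n_perm=20, seed=0)
        w = pairwise_fst(
            aln, meta, level="area", estimator="weir", n_perm=20, seed=0
        )
        assert h.fst[0, 1] > 0.4 and w.fst[0, 1] > 0.4


def spreadsheet_amova(d2, pops, groups):
    """Independent nested-ANOVA oracle: explicit SS sums and EMS algebra."""
    n = len(pops)
    pop_ids = sorted(set(pops))
    grp_ids = sorted(set(groups))
    grp_of_pop = {p: groups[pops.index(p)] for p in pop_ids}

    def ss(index_sets):
        tot = 0.0
        for idx in index_sets:
            s = 0.0
            for i in idx:
                for j in idx:
                    s += d2[i, j]
            tot += s / (2 * len(idx))
        return tot

    all_idx = [list(range(n))]
    pop_idx = [[i for i in range(n) if pops[i] == p] for p in pop_ids]
    grp_idx = [[i for i in range(n) if groups[i] == g] for g in grp_ids]
    ss_tot, ss_wp, ss_wg = ss(all_idx), ss(pop_idx), ss(grp_idx)
    ssd_ag, ssd_ap, ssd_wp = ss_tot - ss_wg, ss_wg - ss_wp, ss_wp
    G, P = len(grp_ids), len(pop_ids)
    df = [G - 1, P - G, n - P]
    n_p = {p: len(ix) for p, ix in zip(pop_ids, pop_idx)}
    n_g = {g: len(ix) for g, ix in zip(grp_ids, grp_idx)}
    s_np2_ng = sum(
        sum(n_p[p] ** 2 for p in pop_ids if grp_of_pop[p] == g) / n_g[g]
        for g in grp_ids
    )
    s_np2_n = sum(v**2 for v in n_p.values()) / n
    s_ng2_n = sum(v**2 for v in n_g.values()) / n
    ncoef = (n - s_np2_ng) / df[1]
    n1 = (s_np2_ng - s_np2_n) / df[0]
    n2 = (n - s_ng2_n) / df[0]
    ms = [ssd_ag / df[0], ssd_ap / df[1], ssd_wp / df[2]]
    sc = ms[2]
    sb = (ms[1] - sc) / ncoef
    sa = (ms[0] - sc - n1 * sb) / n2
    return sa, sb, sc


class TestAmova:
    def test_fixed_difference_two_level(self):
        aln = Alignment(list("abcd"), ["AAAA", "AAAA", "AATT", "AATT"])
        meta = _meta(aln.ids, ["L1", "L1", "L2", "L2"])
        res = amova(aln, meta, "two-level", n_perm=50, seed=0)
        assert res.phi["Phi_ST"] == pytest.approx(1.0)
        assert res.pct["among_locations"] == pytest.approx(100.0)

    def test_all_identical_flagged(self):
        aln = Alignment(list("abcd"), ["AAAA"] * 4)
        meta = _meta(aln.ids, ["L1", "L1", "L2", "L2"])
        res = amova(aln, meta, "two-level", n_perm=10, seed=0)
        assert res.degenerate
        assert np.isnan(res.phi["Phi_ST"])

    def test_three_level_matches_spreadsheet_oracle(self):
        rng = np.random.default_rng(3)
        seqs = [
            "".join(rng.choice(list("ACGT"), 12)) for _ in range(12)
        ]
        aln = Alignment([f"s{i}" for i in range(12)], seqs)
        pops = ["L1"] * 3 + ["L2"] * 3 + ["L3"] * 3 + ["L4"] * 3
        grps = ["X"] * 6 + ["Y"] * 6
        meta = _meta(aln.ids, pops, grps)
        res = amova(aln, meta, "three-level", n_perm=10, seed=0)
        d2 = pairwise_differences(aln).values
        sa, sb, sc = spreadsheet_amova(d2, pops, grps)
        assert res.sigma["among_areas"] == pytest.approx(sa, abs=1e-9)
        assert res.sigma["among_locations_within_areas"] == pytest.approx(sb, abs=1e-9)
        assert res.sigma["within_locations"] == pytest.approx(sc, abs=1e-9)

    def test_percentages_and_phi_identities(self, small_study):
        aln, meta, _ = small_study
        res = amova(aln, meta, "three-level", n_perm=50, seed=0)
        assert sum(res.pct.values()) == pytest.approx(100.0, abs=0.01)
        tot = sum(res.sigma.values())
        assert res.phi["Phi_CT"] == pytest.approx(
            res.sigma["among_areas"] / tot, abs=1e-9
        )
        assert res.phi["Phi_ST"] == pytest.approx(
            (res.sigma["among_areas"] + res.sigma["among_locations_within_areas"])
            / tot,
            abs=1e-9,
        )
        sb = res.sigma["among_locations_within_areas"]
        sc = res.sigma["within_locations"]
        assert res.phi["Phi_SC"] == pytest.approx(sb / (sb + sc), abs=1e-9)

    def test_two_and_three_level_agree_on_within_component(self, small_study):
        aln, meta, _ = small_study
        r2 = amova(aln, meta, "two-level", n_perm=10, seed=0)
        r3 = amova(aln, meta, "three-level", n_perm=10, seed=0)
        assert r2.sigma["within_locations"] == pytest.approx(
            r3.sigma["within_locations"], abs=1e-9
        )

    def test_phi_st_p_uniform_under_panmixia(self):
        """Type-I error of the Phi_ST permutation test at alpha=0.05."""
        rng = np.random.default_rng(12)
        n_reps = 500
        rejections = 0
        pvals = []
        for rep in range(n_reps):
            cfg = synth.SimConfig(
                areas=[("A", ["d"], [24])], theta=4.0, mig_within=0,
                mig_between=0, expansion=None, merge_time=None,
                infinite_sites=True, seed=1000 + rep,
            )
            aln, _, _ = synth.simulate_study(cfg)
            labels = rng.permutation(["L1"] * 8 + ["L2"] * 8 + ["L3"] * 8)
            meta = _meta(aln.ids, list(labels))
            res = amova(aln, meta, "two-level", n_perm=99, seed=rep)
            pvals.append(res.p["Phi_ST"])
            rejections += res.p["Phi_ST"] <= 0.05
        rate = rejections / n_reps
        # binomial 99.7% band around 0.05 with n=500
        se = math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < 3 * se + 1e-9
        assert 0.35 < np.mean(pvals) < 0.65


class TestMantel:
    def _dm(self, v, labels=None):
        v = np.asarray(v, float)
        return DistanceMatrix(labels or [f"x{i}" for i in range(len(v))], v)

    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        x = self._dm(m)
        res = mantel_test(x, x, n_perm=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 2 / 201 + 1e-9

    def test_permutation_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        a = rng.random((4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((4, 4))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        x, y = self._dm(a), self._dm(b)
        exact = mantel_test(x, y, method="exact")
        # independent oracle: direct enumeration over all 24 relabellings
        iu = np.triu_indices(4, 1)
        z_obs = (a[iu] * b[iu]).sum()
        zs = []
        for p in permutations(range(4)):
            bp = b[np.ix_(p, p)]
            zs.append((a[iu] * bp[iu]).sum())
        p_oracle = np.mean([z >= z_obs - 1e-12 for z in zs])
        assert exact.p == pytest.approx(p_oracle, abs=1e-12)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM, mantel

        rng = np.random.default_rng(2)
        n = 8
        base = rng.random((n, 2))
        a = np.linalg.norm(base[:, None] - base[None, :], axis=2)
        b = a + rng.normal(0, 0.1, (n, n))
        b = np.abs((b + b.T) / 2)
        np.fill_diagonal(b, 0)
        ours = mantel_test(self._dm(a), self._dm(b), n_perm=5000, seed=0)
        r_sk, p_sk, _ = mantel(
            SkDM(a), SkDM(b), method="pearson", permutations=5000,
            alternative="greater",
        )
        assert ours.r == pytest.approx(r_sk, abs=1e-9)
        assert ours.p == pytest.approx(p_sk, abs=0.03)

    def test_label_mismatch_rejected(self):
        a = self._dm(np.zeros((3, 3)), ["a", "b", "c"])
        b = self._dm(np.zeros((3, 3)), ["a", "b", "d"])
        with pytest.raises(ValueError):
            mantel_test(a, b)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for rep in range(100):
            a = rng.random((6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = rng.random((6, 6))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            res = mantel_test(self._dm(a), self._dm(b), n_perm=99, seed=rep)
            pvals.append(res.p)
        from scipy import stats

        # discrete p on {1/100..1}; coarse KS guard against miscalibration
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestGeography:
    def test_great_circle_known_separation(self, toy_metadata):
        dm = geographic_distances(toy_metadata)
        assert dm.values[0, 0] == 0
        # one degree of latitude is ~111 km
        i, j = dm.labels.index("L1"), dm.labels.index("L2")
        assert 150 < dm.values[i, j] < 350
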