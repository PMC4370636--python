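"""MPD/MNTD, standardized effect sizes and the NRI/NTI site table."""

import numpy as np
import pandas as pd
import pytest

import phylostruct as ps
from phylostruct.community import CommunityMatrix


def brute_mpd(sample, D):
    vals = []
    for i, a in enumerate(sample):
        for b in sample[i + 1:]:
            vals.append(D.loc[a, b])
    return np.mean(vals)


def brute_mntd(sample, D):
    vals = []
    for a in sample:
        vals.append(min(D.loc[a, b] for b in sample if b != a))
    return np.mean(vals)


class TestMetrics:
    def test_pair_worked_example(self, worked_dist):
        assert ps.mpd(["A", "B"], worked_dist) == 2.0
        assert ps.mntd(["A", "B"], worked_dist) == 2.0

    def test_triplet_worked_example(self, worked_dist):
        assert ps.mpd(["A", "B", "C"], worked_dist) == pytest.approx(10 / 3)
        assert ps.mntd(["A", "B", "C"], worked_dist) == pytest.approx(8 / 3)

    def test_matches_brute_force_double_loop(self, pool20, pool20_dist):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sample = list(rng.choice(pool20.tip_names, size=6, replace=False))
            assert ps.mpd(sample, pool20_dist) == pytest.approx(
                brute_mpd(sample, pool20_dist), abs=1e-12)
            assert ps.mntd(sample, pool20_dist) == pytest.approx(
                brute_mntd(sample, pool20_dist), abs=1e-12)

    def test_mntd_never_exceeds_mpd(self, pool20, pool20_dist):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            k = int(rng.integers(2, 12))
            sample = list(rng.choice(pool20.tip_names, size=k, replace=False))
            assert (ps.mntd(sample, pool20_dist)
                    <= ps.mpd(sample, pool20_dist) + 1e-12)

    def test_invariant_to_species_order(self, pool20_dist):
        sample = list(pool20_dist.index[:5])
        shuffled = sample[::-1]
        assert ps.mpd(sample, pool20_dist) == ps.mpd(shuffled, pool20_dist)
        assert ps.mntd(sample, pool20_dist) == ps.mntd(shuffled, pool20_dist)

    def test_undefined_below_two_species(self, worked_dist):
        with pytest.raises(ValueError):
            ps.mpd(["A"], worked_dist)
        with pytest.raises(ValueError):
            ps.mntd(["A"], worked_dist)


class TestSES:
    def test_exhaustive_worked_example(self, worked_dist):
        # null over all C(3,2)=3 pairs: {2, 4, 4}; mean 10/3, sd 2/sqrt(3)
        r = ps.ses("MPD", ["A", "B"], worked_dist, exhaustive=True)
        assert r.null_mean == pytest.approx(10 / 3)
        assert r.null_sd == pytest.approx(2 / np.sqrt(3))
        assert r.ses == pytest.approx(-1.1547, abs=1e-4)

    def test_sample_equal_to_pool_is_degenerate(self, worked_dist):
        r = ps.ses("MPD", ["A", "B", "C"], worked_dist, n_perm=100, seed=0)
        assert r.degenerate and r.ses is None

    def test_monte_carlo_agrees_with_exhaustive(self, pool20_dist):
        """Monte-Carlo SES within 3 MC standard errors of the exact null."""
        small = pool20_dist.iloc[:8, :8]
        sample = list(small.index[:4])
        exact = ps.ses("MPD", sample, small, exhaustive=True)
        mc = ps.ses("MPD", sample, small, n_perm=2000, seed=42)
        se_mean = exact.null_sd / np.sqrt(mc.n_perm)
        assert abs(mc.null_mean - exact.null_mean) < 3 * se_mean
        assert abs(mc.ses - exact.ses) < 0.2

    def test_seed_reproducibility(self, pool20_dist):
        sample = list(pool20_dist.index[:5])
        a = ps.ses("MNTD", sample, pool20_dist, n_perm=200, seed=7)
        b = ps.ses("MNTD", sample, pool20_dist, n_perm=200, seed=7)
        assert a == b

    def test_null_calibration_mean_zero(self, pool20, pool20_dist):
        """Random samples from the pool give SES centered on 0 with ~5%
        exceedances at |1.96|."""
        rng = np.random.default_rng(3)
        zs = []
        for i in range(500):
            sample = list(rng.choice(pool20.tip_names, size=6, replace=False))
            r = ps.ses("MPD", sample, pool20_dist, n_perm=200, seed=i)
            zs.append(r.ses)
        zs = np.array(zs)
        assert abs(zs.mean()) < 3 / np.sqrt(len(zs))
        rate = float((np.abs(zs) > 1.96).mean())
        assert 0.02 <= rate <= 0.09


class TestCommunityMatrix:
    def test_long_and_wide_round_trip(self, tmp_path):
        long = pd.DataFrame({
            "site": ["s1", "s1", "s2", "s2", "s2"],
            "species": ["A", "B", "B", "C", "A"],
        })
        cm = CommunityMatrix.from_long(long)
        path = tmp_path / "comm.csv"
        cm.to_csv(path)
        back = CommunityMatrix.from_csv(path)
        assert back.incidence.equals(cm.incidence)
        assert back.species_at("s2") == ["A", "B", "C"]

    def test_validation(self):
        bad = pd.DataFrame({"A": [1, 0], "B": [0, 0]}, index=["s1", "s2"])
        with pytest.raises(ValueError):
            CommunityMatrix(bad)  # empty species and 1-species sites


class TestNriNtiTable:
    def test_whole_clade_site_is_clustered(self):
        """Species drawn from one clade of a two-clade tree have NRI > 0."""
        t = ps.parse_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):8,((E:1,F:1):1,(G:1,H:1):1):8);")
        inc = pd.DataFrame(
            [[1, 1, 1, 1, 0, 0, 0, 0], [1, 0, 0, 1, 0, 1, 1, 0]],
            index=["clade_site", "spread_site"],
            columns=list("ABCDEFGH"))
        inc = inc.loc[:, inc.sum(axis=0) > 0]
        tab = ps.nri_nti_table(CommunityMatrix(inc), t, n_perm=500, seed=0)
        assert tab.loc["clade_site", "NRI"] > 0
        assert tab.loc["spread_site", "NRI"] < 0

    def test_flags_match_indices(self, pool20, pool20_dist):
        rng = np.random.default_rng(4)
        inc = pd.DataFrame(
            rng.integers(0, 2, size=(12, pool20.n_tips)),
            index=[f"s{i}" for i in range(12)], columns=pool20.tip_names)
        inc.iloc[:, 0] = 1  # no empty species/sites
        inc.iloc[:, 1] = 1
        tab = ps.nri_nti_table(CommunityMatrix(inc), pool20_dist,
                               n_perm=100, seed=0)
        assert (tab["NRI_clustered"] == (tab["NRI"] > 1.96)).all()
        assert (tab["NTI_overdispersed"] == (tab["NTI"] < -1.96)).all()
        # definitional: NRI = -SES(MPD), NTI = -SES(MNTD)
        assert np.allclose(tab["NRI"], -tab["SES_MPD"])
        assert np.allclose(tab["NTI"], -tab["SES_MNTD"])

    def test_missing_species_reported(self, worked_tree):
        inc = pd.DataFrame([[1, 1]], index=["s1"], columns=["A", "Zz"])
        with pytest.raises(KeyError, match="Zz"):
            ps.nri_nti_table(CommunityMatrix(inc), worked_tree)

    def test_results_independent_of_site_order(self, pool20_dist):
        inc = pd.DataFrame(0, index=["s1", "s2", "s3"],
                           columns=pool20_dist.index)
        inc.iloc[0, :5] = 1
        inc.iloc[1, 5:11] = 1
        inc.iloc[2, 8:16] = 1
        inc = inc.loc[:, inc.sum(axis=0) > 0]
        cm1 = CommunityMatrix(inc)
        cm2 = CommunityMatrix(inc.iloc[::-1])
        t1 = ps.nri_nti_table(cm1, pool20_dist, n_perm=100, seed=5)
        t2 = ps.nri_nti_table(cm2, pool20_dist, n_perm=100, seed=5)
        assert np.allclose(t1.loc["s2", "NRI"], t2.loc["s2", "NRI"])
        assert np.allclose(t1.loc["s1", "NTI"], t2.loc["s1", "NTI"])


def test_observed_metrics_cross_checked_against_picante(tmp_path, pool20,
                                                        pool20_dist):
    """Independent R oracle: picante's mpd/mntd on the same tree and
    community agree with ours."""
    import shutil
    import subprocess
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    rng = np.random.default_rng(8)
    inc = pd.DataFrame(0, index=["s1", "s2"], columns=pool20.tip_names)
    for row in range(2):
        picks = rng.choice(pool20.n_tips, size=7, replace=False)
        inc.iloc[row, picks] = 1
    tree_path = tmp_path / "t.nwk"
    comm_path = tmp_path / "c.csv"
    ps.write_newick(pool20, tree_path)
    inc.to_csv(comm_path)
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(picante))\n'
        f'tr <- read.tree("{tree_path}")\n'
        f'cm <- as.matrix(read.csv("{comm_path}", row.names=1, check.names=FALSE))\n'
        'd <- cophenetic(tr)\n'
        'cat(mpd(cm, d), mntd(cm, d), sep="\\n")\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True).stdout.split()
    r_mpd = [float(v) for v in out[:2]]
    r_mntd = [float(v) for v in out[2:]]
    for row, site in enumerate(["s1", "s2"]):
        sample = list(inc.columns[inc.loc[site] == 1])
        assert ps.mpd(sample, pool20_dist) == pytest.approx(r_mpd[row], rel=1e-6)
        assert ps.mntd(sample, pool20_dist) == pytest.approx(r_mntd[row], rel=1e-6)
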