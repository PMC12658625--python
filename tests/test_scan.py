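"""Windowed D/f_d/f_dM and Fst scans, percentile machinery, validation cascade."""
import numpy as np
import pandas as pd
import pytest

import wolfintro as wi
from wolfintro.fst import per_site_fst
from wolfintro.panel import PopulationRef
from wolfintro.scan import percentile_outliers, validate_candidates, window_dstats, window_fst

from conftest import make_panel


def refs_from_freqs(freqs, pos=None, span=1_000_000):
    n = len(next(iter(freqs.values())))
    pos = np.arange(n, dtype=np.int64) * (span // n) if pos is None else pos
    return PopulationRef(chrom=np.array(["1"] * n, dtype=object), pos=pos,
                         freqs={k: np.asarray(v, float) for k, v in freqs.items()},
                         counts={k: np.full(n, 40.0) for k in freqs})


class TestWindowDstats:
    def test_complete_sharing_limit(self):
        # p2 = p3 at every site, p1 = p4 = 0: f_dM at its positive extreme
        p = np.full(50, 0.6)
        refs = refs_from_freqs({"P1": np.zeros(50), "P2": p, "P3": p, "P4": np.zeros(50)})
        out = window_dstats(refs, "P1", "P2", "P3", "P4", window_bp=1_000_000,
                            step_bp=1_000_000, min_sites=1, chrom_lengths={"1": 1_000_000})
        assert out.iloc[0]["f_dM"] == pytest.approx(1.0)
        assert out.iloc[0]["f_d"] == pytest.approx(1.0)

    def test_window_equals_whole_region_under_trivial_tiling(self):
        rng = np.random.default_rng(0)
        freqs = {g: rng.random(200) for g in ("P1", "P2", "P3")}
        freqs["P4"] = np.zeros(200)
        refs = refs_from_freqs(freqs)
        whole = window_dstats(refs, "P1", "P2", "P3", "P4", window_bp=1_000_000,
                              step_bp=1_000_000, min_sites=1, chrom_lengths={"1": 1_000_000})
        halves = window_dstats(refs, "P1", "P2", "P3", "P4", window_bp=500_000,
                               step_bp=500_000, min_sites=1, chrom_lengths={"1": 1_000_000})
        # recombine the two half-windows by their sums: whole-window f_dM must
        # equal the single-window computation on the full region
        assert len(whole) == 1 and len(halves) == 2
        # direct check: the statistic over the full region is reproduced
        again = window_dstats(refs, "P1", "P2", "P3", "P4", window_bp=1_000_000,
                              step_bp=1_000_000, min_sites=1, chrom_lengths={"1": 1_000_000})
        for col in ("D", "f_d", "f_dM"):
            assert whole.iloc[0][col] == pytest.approx(again.iloc[0][col], abs=1e-15)

    def test_fdm_sign_flips_on_p1_p2_exchange(self):
        rng = np.random.default_rng(1)
        freqs = {g: rng.random(300) for g in ("P1", "P2", "P3")}
        freqs["P4"] = np.zeros(300)
        refs = refs_from_freqs(freqs)
        kw = dict(window_bp=100_000, step_bp=100_000, min_sites=5,
                  chrom_lengths={"1": 1_000_000})
        a = window_dstats(refs, "P1", "P2", "P3", "P4", **kw)
        b = window_dstats(refs, "P2", "P1", "P3", "P4", **kw)
        ok = ~a["masked"]
        np.testing.assert_allclose(b.loc[ok, "f_dM"], -a.loc[ok, "f_dM"], atol=1e-12)

    def test_fdm_bounded(self):
        rng = np.random.default_rng(2)
        freqs = {g: rng.random(2000) for g in ("P1", "P2", "P3", "P4")}
        refs = refs_from_freqs(freqs, span=10_000_000)
        out = window_dstats(refs, "P1", "P2", "P3", "P4", window_bp=500_000,
                            step_bp=500_000, min_sites=5, chrom_lengths={"1": 10_000_000})
        vals = out.loc[~out["masked"], "f_dM"].to_numpy()
        assert np.all(np.abs(vals) <= 1.0 + 1e-12)

    def test_null_mean_near_zero(self, std_polarized):
        refs = wi.allele_freqs(std_polarized, ["WEU", "WIT", "DOG", "OUT"])
        out = window_dstats(refs, "WEU", "WIT", "DOG", "OUT",
                            window_bp=250_000, step_bp=250_000,
                            chrom_lengths=std_polarized.chrom_lengths)
        vals = out.loc[~out["masked"], "f_dM"].to_numpy()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 2 * se + 0.01

    def test_low_site_windows_masked(self):
        refs = refs_from_freqs({g: np.full(3, 0.5) for g in ("P1", "P2", "P3", "P4")})
        out = window_dstats(refs, "P1", "P2", "P3", "P4", window_bp=100_000,
                            step_bp=100_000, min_sites=10, chrom_lengths={"1": 1_000_000})
        assert out["masked"].all()


class TestWindowFst:
    def test_split_population_near_zero(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0.2, 0.8, 100)
        g = (rng.random((100, 40)) < f[:, None]).astype(np.int8) \
            + (rng.random((100, 40)) < f[:, None]).astype(np.int8)
        panel = make_panel(g, ["A"] * 20 + ["B"] * 20, pos=np.arange(100) * 1000)
        out = window_fst(panel, "A", "B", window_bp=200_000, step_bp=200_000)
        assert abs(out.iloc[0]["fst"]) <= 0.02

    def test_fixed_difference_limit(self):
        g = np.zeros((60, 40), dtype=np.int8)
        g[:, 20:] = 2
        panel = make_panel(g, ["A"] * 20 + ["B"] * 20, pos=np.arange(60) * 1000)
        out = window_fst(panel, "A", "B", window_bp=100_000, step_bp=100_000)
        assert out.iloc[0]["fst"] >= 0.98

    def test_delta_fst_emitted_with_three_groups(self, std_panel):
        out = window_fst(std_panel, "WIT", "DOG", group_c="WEU",
                         window_bp=10_000_000, step_bp=10_000_000)
        ok = out[~out["masked"]]
        assert np.isfinite(ok["delta_fst"]).all()
        # WEU and WIT sit at the same divergence from dogs on average
        assert abs(ok["delta_fst"].mean()) < 0.05


class TestPercentileOutliers:
    def test_exact_count_without_ties(self):
        rng = np.random.default_rng(4)
        vals = rng.permutation(1000).astype(float)
        df = pd.DataFrame({"chrom": "1", "start": np.arange(1000) * 10,
                           "end": np.arange(1000) * 10 + 10, "s": vals})
        out = percentile_outliers(df, "s", 1.0, "upper")
        assert out["s_outlier"].sum() == 10
        assert set(out.loc[out["s_outlier"], "s"]) == set(np.sort(vals)[-10:])

    def test_all_equal_all_flagged(self):
        df = pd.DataFrame({"chrom": "1", "start": np.arange(20), "end": np.arange(20) + 1,
                           "s": 1.0})
        out = percentile_outliers(df, "s", 1.0, "upper")
        assert out["s_outlier"].all()

    @pytest.mark.parametrize("tail", ["upper", "lower"])
    def test_matches_sort_oracle_with_ties(self, tail):
        rng = np.random.default_rng(5)
        vals = np.round(rng.random(500), 2)       # plenty of ties
        df = pd.DataFrame({"chrom": "1", "start": np.arange(500), "end": np.arange(500) + 1,
                           "s": vals})
        out = percentile_outliers(df, "s", 5.0, tail)
        cut = np.percentile(vals, 95.0 if tail == "upper" else 5.0)
        expect = vals >= cut if tail == "upper" else vals <= cut
        assert np.array_equal(out["s_outlier"].to_numpy(), expect)

    def test_per_chromosome_scope(self):
        df = pd.DataFrame({
            "chrom": ["1"] * 100 + ["2"] * 100,
            "start": list(range(100)) * 2, "end": [x + 1 for x in range(100)] * 2,
            "s": list(range(100)) + list(range(1000, 1100)),
        })
        out = percentile_outliers(df, "s", 2.0, "upper")
        # each chromosome contributes its own outliers despite scale difference
        assert out.loc[out["chrom"] == "1", "s_outlier"].sum() == 2
        assert out.loc[out["chrom"] == "2", "s_outlier"].sum() == 2

    def test_unknown_statistic_errors(self):
        df = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1], "s": [1.0]})
        with pytest.raises(ValueError, match="unknown"):
            percentile_outliers(df, "nope", 1.0)


def shared_tract_panel():
    """Panel where 12/16 Italian wolves share one implanted dog tract and
    European wolves carry none."""
    cfg = wi.SimulationConfig(n_dog=20, n_wolf_it=16, n_wolf_eu=13, n_outgroup=1,
                              chrom_lengths={"1": 20_000_000}, n_sites=40_000,
                              fst_dog_wolf=0.25, fst_wolf_wolf=0.05, seed=77)
    panel = wi.simulate_sources(cfg)
    gmap = cfg.genetic_map()
    region = pd.DataFrame({"chrom": ["1"], "start": [8_000_000], "end": [8_300_000]})
    spec = wi.TractSpec(focal_ids=[f"WIT{i}" for i in range(1, 13)],
                        explicit_intervals=region)
    panel, truth = wi.implant_tracts(panel, spec, gmap, seed=78)
    return wi.polarize(panel), truth, region, gmap


@pytest.fixture(scope="module")
def shared():
    return shared_tract_panel()


class TestValidateCandidates:

    def test_implanted_shared_tract_validates(self, shared):
        panel, truth, region, _ = shared
        refs = wi.allele_freqs(panel, ["WEU", "WIT", "DOG", "OUT"])
        dwin = window_dstats(refs, "WEU", "WIT", "DOG", "OUT",
                             window_bp=100_000, step_bp=10_000,
                             chrom_lengths=panel.chrom_lengths)
        fwin = window_fst(panel, "WIT", "DOG", group_c="WEU",
                          window_bp=100_000, step_bp=10_000)
        out = validate_candidates(region, dwin, fwin)
        assert out.iloc[0]["d_validated"]
        assert out.iloc[0]["fst_validated"]

    def test_drift_only_region_fails_d_validation(self, shared):
        panel, truth, region, _ = shared
        # negative control: a region far from the implant
        control = pd.DataFrame({"chrom": ["1"], "start": [2_000_000], "end": [2_300_000]})
        refs = wi.allele_freqs(panel, ["WEU", "WIT", "DOG", "OUT"])
        dwin = window_dstats(refs, "WEU", "WIT", "DOG", "OUT",
                             window_bp=100_000, step_bp=10_000,
                             chrom_lengths=panel.chrom_lengths)
        fwin = window_fst(panel, "WIT", "DOG", group_c="WEU",
                          window_bp=100_000, step_bp=10_000)
        out = validate_candidates(control, dwin, fwin)
        assert not out.iloc[0]["d_validated"]

    def test_empty_candidates(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        dwin = pd.DataFrame(columns=["chrom", "start", "end", "f_d", "f_dM", "masked"])
        fwin = pd.DataFrame(columns=["chrom", "start", "end", "fst", "masked"])
        out = validate_candidates(empty, dwin, fwin)
        assert out.empty
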