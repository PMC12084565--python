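"""Feature grouping, windowed rates, distributions and gene classification."""

import numpy as np
import pandas as pd
import pytest

import damaccess as da
from damaccess.aggregate import WindowMatrix, _mean_signal
from damaccess.kinetics import KineticFit
from damaccess.simulate import ClassKinetics

from test_kinetics import make_track


class TestSitesInFeatures:
    def test_exact_cover_and_halfopen_boundary(self, random_catalog):
        site = random_catalog.usable_sites().iloc[0]
        cut = int(site["cut_pos"])
        covering = da.FeatureSet("f", pd.DataFrame({"chrom": [site["chrom"]], "start": [cut], "end": [cut + 1]}))
        assert list(da.sites_in_features(random_catalog, covering)) == [site.name]
        boundary = da.FeatureSet("f", pd.DataFrame({"chrom": [site["chrom"]], "start": [cut - 10], "end": [cut]}))
        assert len(da.sites_in_features(random_catalog, boundary)) == 0

    def test_empty_features_empty_subset(self, random_catalog):
        fs = da.FeatureSet("empty", pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(da.sites_in_features(random_catalog, fs)) == 0

    def test_matches_all_pairs_oracle(self, random_catalog):
        rng = np.random.default_rng(12)
        starts = rng.integers(0, 19_000, 30)
        iv = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + rng.integers(50, 900, 30)})
        fs = da.FeatureSet("rand", iv)
        got = set(da.sites_in_features(random_catalog, fs))
        expected = set()
        for idx, site in random_catalog.usable_sites().iterrows():
            for _, f in iv.iterrows():
                if f["start"] <= site["cut_pos"] < f["end"]:
                    expected.add(idx)
        assert got == expected


def _simulated_track(blocks, rates, length=60_000, n_mol=120, seed=23, tps=(12.0, 24.0, 48.0)):
    genome, classes = da.generate_genome(length, seed=seed, class_blocks=blocks)
    catalog = da.build_filtered_catalog(genome)
    params = da.KineticsParams(classes={c: ClassKinetics(k=k) for c, k in rates.items()})
    cfg = da.SimConfig(timepoints=list(tps), n_molecules=n_mol, seed=seed + 1)
    frags, _ = da.simulate_fragments(genome, catalog, classes, params, cfg)
    return da.quantify_timecourse(frags, catalog)


class TestWindowRates:
    def test_window_means_match_groupby_oracle(self):
        track = _simulated_track(None, {"euchromatin": 0.03}, n_mol=40)
        wm = da.window_rates(track, window=10_000)
        joined = track.sites.copy()
        joined["win"] = joined["cut_pos"] // 10_000
        joined = joined.join(track.fractions)
        for _, row in wm.table.iterrows():
            grp = joined[(joined["chrom"] == row["chrom"]) & (joined["win"] == row["start"] // 10_000)]
            for t in track.timepoints:
                expected = grp[t].mean()
                np.testing.assert_allclose(row[f"mean_{t:g}"], expected, equal_nan=True)

    def test_uniform_genome_relative_rates_near_one(self):
        track = _simulated_track(None, {"euchromatin": 0.03}, n_mol=150)
        wm = da.window_rates(track, window=10_000)
        assert np.nanmax(np.abs(wm.table["rel_rate"] - 1.0)) < 0.15

    def test_slow_block_has_lowest_window_rate(self):
        blocks = [("euchromatin", 20_000), ("centromere_like", 20_000), ("euchromatin", 20_000)]
        track = _simulated_track(blocks, {"euchromatin": 0.03, "centromere_like": 0.012}, n_mol=150)
        wm = da.window_rates(track, window=20_000)
        rates = wm.table.set_index("start")["rel_rate"]
        assert rates[20_000] < rates[0]
        assert rates[20_000] < rates[40_000]

    def test_small_window_rejected(self):
        track = make_track({0: [0.1, 0.2]}, [12, 24])
        with pytest.raises(ValueError):
            da.window_rates(track, window=500)


def _wm_from_rates(rates_by_chrom: dict) -> WindowMatrix:
    rows = []
    for chrom, rates in rates_by_chrom.items():
        for i, r in enumerate(rates):
            rows.append({"chrom": chrom, "start": i * 100_000, "end": (i + 1) * 100_000,
                         "n_sites": 10, "k": 0.03 * r, "rel_rate": r})
    ref = KineticFit(k=0.03, intercept=0.0, r_squared=1.0, n_points=4)
    return WindowMatrix(window=100_000, table=pd.DataFrame(rows), reference=ref)


class TestChromosomeDistribution:
    def test_uniform_rates_mode_at_one(self):
        wm = _wm_from_rates({"chr1": [1.0] * 20, "chr2": [1.0] * 20})
        _, modes = da.chromosome_rate_distribution(wm)
        for m in modes.values():
            assert abs(m - 1.0) <= 0.025  # within half a bin of 1.0

    def test_histogram_mass_sums_to_one(self):
        rng = np.random.default_rng(2)
        wm = _wm_from_rates({"chr1": rng.uniform(0.5, 1.5, 40)})
        hist, _ = da.chromosome_rate_distribution(wm)
        assert hist.groupby("chrom")["fraction"].sum().iloc[0] == pytest.approx(1.0)

    def test_slow_chromosome_has_lower_mode(self):
        rng = np.random.default_rng(3)
        wm = _wm_from_rates(
            {"chrX": 0.8 + 0.03 * rng.standard_normal(50),
             "chr1": 1.0 + 0.03 * rng.standard_normal(50)}
        )
        _, modes = da.chromosome_rate_distribution(wm)
        assert modes["chrX"] < modes["chr1"]


class TestClassifyGenes:
    def _signal(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def test_constant_signal_above_threshold_active(self, toy_gene_table):
        signal = self._signal([("chr1", 0, 50_000, 0.5)])
        out = da.classify_genes(toy_gene_table, signal, threshold=0.4)
        assert out["active"].all()

    def test_zero_signal_inactive(self, toy_gene_table):
        signal = self._signal([])
        out = da.classify_genes(toy_gene_table, signal, threshold=0.4)
        assert not out["active"].any()

    def test_mean_matches_integration_oracle(self):
        # flank window [900, 2900): 100 bp at 2.0, 1000 bp at 1.0, rest 0
        signal = self._signal([("chr1", 800, 1000, 2.0), ("chr1", 1000, 2000, 1.0)])
        got = _mean_signal(signal, "chr1", 900, 2900)
        assert got == pytest.approx((100 * 2.0 + 1000 * 1.0) / 2000)

    def test_malformed_strand_rejected(self, toy_gene_table):
        bad = toy_gene_table.copy()
        bad.loc[0, "strand"] = "?"
        with pytest.raises(ValueError):
            da.classify_genes(bad, self._signal([]), threshold=0.4)


class TestQuintiles:
    def _classified(self, genes, n_active=None):
        out = genes.copy()
        out["active"] = True if n_active is None else [i < n_active for i in range(len(out))]
        return out

    def test_ten_genes_equal_quintiles(self, toy_gene_table):
        genes = self._classified(toy_gene_table.head(10))
        out = da.assign_quintiles(genes)
        sizes = out["quintile"].value_counts()
        assert all(sizes[f"Q{q}"] == 2 for q in range(1, 6))
        top2 = set(genes.sort_values(["expression", "gene_id"]).tail(2)["gene_id"])
        assert set(out[out["quintile"] == "Q5"]["gene_id"]) == top2

    def test_remainder_goes_to_high_quintiles(self, toy_gene_table):
        out = da.assign_quintiles(self._classified(toy_gene_table))
        sizes = [int((out["quintile"] == f"Q{q}").sum()) for q in range(1, 6)]
        assert sizes == [4, 4, 5, 5, 5]

    def test_quintile_sizes_sum_to_active_count(self, toy_gene_table):
        genes = self._classified(toy_gene_table, n_active=17)
        out = da.assign_quintiles(genes)
        assert int((out["quintile"] != "NoTrans").sum()) == 17
        assert int((out["quintile"] == "NoTrans").sum()) == 6

    def test_ties_broken_deterministically_by_gene_id(self, toy_gene_table):
        genes = self._classified(toy_gene_table)
        genes["expression"] = 1.0
        a = da.assign_quintiles(genes)
        b = da.assign_quintiles(genes.sample(frac=1.0, random_state=1).sort_index())
        pd.testing.assert_series_equal(a["quintile"], b["quintile"])

    def test_permutation_invariance(self, toy_gene_table):
        genes = self._classified(toy_gene_table)
        a = da.assign_quintiles(genes).sort_values("gene_id")["quintile"].to_list()
        shuffled = genes.sample(frac=1.0, random_state=5).reset_index(drop=True)
        b = da.assign_quintiles(shuffled).sort_values("gene_id")["quintile"].to_list()
        assert a == b

    def test_too_few_active_rejected(self, toy_gene_table):
        genes = self._classified(toy_gene_table, n_active=3)
        with pytest.raises(ValueError):
            da.assign_quintiles(genes)
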