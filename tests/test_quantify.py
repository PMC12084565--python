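"""Fragment-end counting and the methylated-fraction estimator."""

import numpy as np
import pandas as pd
import pytest

import damaccess as da
from damaccess.quantify import count_site_ends, estimate_fraction
from damaccess.simulate import ClassKinetics

from conftest import make_genome


def naive_count(fragments: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """All-pairs counting oracle."""
    out = pd.DataFrame(0, index=sites.index, columns=["L", "R", "S"])
    for _, frag in fragments.iterrows():
        for idx, site in sites.iterrows():
            if frag["chrom"] != site["chrom"]:
                continue
            if frag["start"] == site["cut_pos"]:
                out.loc[idx, "L"] += 1
            if frag["end"] == site["cut_pos"]:
                out.loc[idx, "R"] += 1
            if frag["start"] < site["motif_start"] and frag["end"] > site["motif_start"] + 4:
                out.loc[idx, "S"] += 1
    return out


@pytest.fixture(scope="module")
def isolated_site_catalog():
    # one site, cut at 502
    return da.find_gatc_sites(make_genome("A" * 500 + "GATC" + "A" * 500))


class TestCountSiteEnds:
    def test_left_end_at_cut(self, isolated_site_catalog):
        cut = int(isolated_site_catalog.sites.iloc[0]["cut_pos"])
        frags = da.FragmentSet(pd.DataFrame({"chrom": ["chr1"], "start": [cut], "end": [cut + 300]}))
        c = count_site_ends(frags, isolated_site_catalog).iloc[0]
        assert (c["L"], c["R"], c["S"]) == (1, 0, 0)

    def test_spanning_fragment(self, isolated_site_catalog):
        frags = da.FragmentSet(pd.DataFrame({"chrom": ["chr1"], "start": [300], "end": [800]}))
        c = count_site_ends(frags, isolated_site_catalog).iloc[0]
        assert (c["L"], c["R"], c["S"]) == (0, 0, 1)

    def test_fragment_touching_motif_not_spanning(self, isolated_site_catalog):
        # ends exactly at motif_start+4: does not strictly cover the motif
        ms = int(isolated_site_catalog.sites.iloc[0]["motif_start"])
        frags = da.FragmentSet(pd.DataFrame({"chrom": ["chr1"], "start": [300], "end": [ms + 4]}))
        c = count_site_ends(frags, isolated_site_catalog).iloc[0]
        assert (c["L"], c["R"], c["S"]) == (0, 0, 0)

    def test_unknown_chromosome_skipped(self, isolated_site_catalog):
        frags = da.FragmentSet(pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [100]}))
        c = count_site_ends(frags, isolated_site_catalog)
        assert (c.to_numpy() == 0).all()

    def test_matches_all_pairs_oracle_on_simulation(self, random_genome, random_catalog):
        genome, classes = random_genome
        params = da.KineticsParams(classes={"euchromatin": ClassKinetics(k=0.05)})
        cfg = da.SimConfig(timepoints=[24.0], n_molecules=3, seed=17)
        frags, _ = da.simulate_fragments(genome, random_catalog, classes, params, cfg)
        fast = count_site_ends(frags[24.0], random_catalog)
        slow = naive_count(frags[24.0].intervals, random_catalog.sites)
        pd.testing.assert_frame_equal(fast, slow, check_dtype=False)

    def test_invariant_under_fragment_order_permutation(self, random_genome, random_catalog):
        genome, classes = random_genome
        params = da.KineticsParams(classes={"euchromatin": ClassKinetics(k=0.05)})
        cfg = da.SimConfig(timepoints=[24.0], n_molecules=3, seed=18)
        frags, _ = da.simulate_fragments(genome, random_catalog, classes, params, cfg)
        iv = frags[24.0].intervals
        shuffled = da.FragmentSet(iv.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(
            count_site_ends(frags[24.0], random_catalog),
            count_site_ends(shuffled, random_catalog),
        )


def _site(left_ok=True, right_ok=True):
    return pd.Series({"left_ok": left_ok, "right_ok": right_ok, "cpg_overlap": False})


def _counts(L, R, S):
    return pd.Series({"L": L, "R": R, "S": S})


class TestEstimateFraction:
    def test_fully_cut(self):
        assert estimate_fraction(_counts(5, 5, 0), _site()) == 1.0

    def test_fully_protected(self):
        assert estimate_fraction(_counts(0, 0, 10), _site()) == 0.0

    def test_balanced_counts(self):
        # (3+5)/(3+5+2*4) = 0.5
        assert estimate_fraction(_counts(3, 5, 4), _site()) == 0.5

    def test_one_sided_uses_surviving_evidence(self):
        # right half-site filtered: downstream (L) evidence is systematically
        # lost, so the left half-site's upstream (R) evidence is scored
        assert estimate_fraction(_counts(0, 6, 2), _site(right_ok=False)) == 0.75
        assert estimate_fraction(_counts(6, 0, 2), _site(left_ok=False)) == 0.75

    def test_below_informative_threshold_missing(self):
        assert np.isnan(estimate_fraction(_counts(1, 1, 1), _site(), min_informative=5))

    def test_unusable_site_rejected(self):
        with pytest.raises(ValueError):
            estimate_fraction(_counts(1, 1, 1), _site(left_ok=False, right_ok=False))

    def test_per_molecule_unbiasedness_without_shearing(self):
        """Each cut molecule yields one L and one R, each uncut one S, so
        f equals the realized fraction of cut molecules exactly."""
        genome = make_genome("A" * 500 + "GATC" + "A" * 500)
        catalog = da.find_gatc_sites(genome)
        classes = da.RegionClassMap(
            intervals=pd.DataFrame(columns=["chrom", "start", "end", "label"])
        )
        params = da.KineticsParams(classes={"euchromatin": ClassKinetics(k=50.0, A=0.5)})
        cfg = da.SimConfig(timepoints=[10.0], n_molecules=400, shear_mean=None, shear_min=0, seed=4)
        frags, _ = da.simulate_fragments(genome, catalog, classes, params, cfg)
        c = count_site_ends(frags[10.0], catalog).iloc[0]
        assert c["L"] == c["R"]
        assert c["L"] + c["S"] == 400
        f = estimate_fraction(c, catalog.sites.iloc[0])
        assert f == c["L"] / 400


class TestBuildTrack:
    def _track(self, random_genome, random_catalog, timepoints, seed=9, n_mol=60):
        genome, classes = random_genome
        params = da.KineticsParams(classes={"euchromatin": ClassKinetics(k=0.03)})
        cfg = da.SimConfig(timepoints=timepoints, n_molecules=n_mol, seed=seed)
        frags, _ = da.simulate_fragments(genome, random_catalog, classes, params, cfg)
        return da.quantify_timecourse(frags, random_catalog)

    def test_duplicate_timepoint_rejected(self, random_catalog):
        c = pd.DataFrame(0, index=random_catalog.sites.index, columns=["L", "R", "S"])
        with pytest.raises(ValueError):
            da.build_track([(12.0, c), (12.0, c)], random_catalog)

    def test_fractions_in_unit_interval(self, random_genome, random_catalog):
        track = self._track(random_genome, random_catalog, [12.0, 48.0])
        vals = track.fractions.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_missing_sites_absent_from_bedgraph(self, random_genome, random_catalog, tmp_path):
        track = self._track(random_genome, random_catalog, [12.0], n_mol=2)
        path = tmp_path / "t.bedgraph"
        track.to_bedgraph(12.0, path)
        bg = pd.read_csv(path, sep="\t", header=None) if path.stat().st_size else pd.DataFrame()
        n_defined = int(track.fractions[12.0].notna().sum())
        assert len(bg) == n_defined

    def test_tsv_roundtrip(self, random_genome, random_catalog, tmp_path):
        track = self._track(random_genome, random_catalog, [12.0, 48.0])
        path = tmp_path / "track.tsv"
        track.to_tsv(path)
        back = da.MethylationTrack.from_tsv(path)
        assert back.timepoints == track.timepoints
        np.testing.assert_allclose(
            back.fractions.to_numpy(), track.fractions.to_numpy(), equal_nan=True
        )

    def test_estimate_consistency_improves_with_depth(self, random_genome, random_catalog):
        genome, classes = random_genome
        errs = []
        for n_mol in (20, 320):
            params = da.KineticsParams(classes={"euchromatin": ClassKinetics(k=0.03)})
            cfg = da.SimConfig(timepoints=[24.0], n_molecules=n_mol, seed=5)
            frags, truth = da.simulate_fragments(genome, random_catalog, classes, params, cfg)
            track = da.quantify_timecourse(frags, random_catalog)
            merged = track.sites.merge(truth, on=["chrom", "cut_pos"])
            f = track.fractions[24.0].to_numpy()
            ok = np.isfinite(f)
            errs.append(np.mean(np.abs(f[ok] - merged["p_24"].to_numpy()[ok])))
        assert errs[1] < errs[0]
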