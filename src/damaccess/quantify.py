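"""Per-site methylated fractions from DpnI fragment ends.

A molecule in which a GATC site was methylated is cut there and observed
as two daughter fragments — one ending and one starting at the cut
coordinate — while an unmethylated molecule is observed once, as a
fragment spanning the motif. Counting left ends ``L``, right ends ``R``
and spanning fragments ``S`` at each site, the methylated fraction is

    f = (L + R) / (L + R + 2 S)

when both half-sites are usable (each cut molecule contributes two end
observations, each uncut molecule one spanning observation, so this is
the unbiased fraction of cut molecules). When the 150-bp proximity
filter removed a half-site, only the surviving side's evidence is used:
the *right* half-site (downstream side) is evidenced by fragments
starting at the cut (L), the *left* half-site (upstream side) by
fragments ending at the cut (R), so a left-only site uses
``R / (R + S)`` and a right-only site ``L / (L + S)`` — the filtered
side's end count is exactly the evidence the lost small fragments would
have carried. Sites whose denominator falls below ``min_informative``
are reported missing rather than zero.

Shear breakpoints that coincide with a cut coordinate contribute false
end counts at a rate of ~1/shear_mean per site per molecule; this is
accepted as noise and not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sites import SiteCatalog

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["L", "R", "S"]


@dataclass
class FragmentSet:
    """Sequenced fragment intervals of one sample/time point.

    ``intervals``: DataFrame with chrom, start, end (0-based half-open);
    sorted by (chrom, start, end) on construction.
    """

    intervals: pd.DataFrame
    sample_id: str = ""
    timepoint: float | None = None

    def __post_init__(self) -> None:
        iv = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in iv.columns:
                raise ValueError(f"fragment table missing column {col!r}")
        iv = iv.copy()
        iv["start"] = iv["start"].astype(np.int64)
        iv["end"] = iv["end"].astype(np.int64)
        if len(iv) and (iv["start"] >= iv["end"]).any():
            raise ValueError("fragments must satisfy start < end")
        self.intervals = iv.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path, sample_id: str = "", timepoint: float | None = None):
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            comment="#",
        )
        return cls(df, sample_id=sample_id, timepoint=timepoint)

    def to_bed(self, path) -> None:
        self.intervals[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def count_site_ends(fragments: FragmentSet, catalog: SiteCatalog) -> pd.DataFrame:
    """Count L (starts at cut), R (ends at cut) and S (spans the motif)
    per catalog site.

    One linear sweep per chromosome via sorted binary search; fragments
    on chromosomes absent from the catalog are skipped with a logged
    count. Returns a DataFrame indexed like ``catalog.sites`` with
    columns L, R, S.
    """
    sites = catalog.sites
    L = np.zeros(len(sites), dtype=np.int64)
    R = np.zeros(len(sites), dtype=np.int64)
    S = np.zeros(len(sites), dtype=np.int64)

    site_chroms = set(sites["chrom"].unique())
    n_skipped = 0
    for chrom, frag in fragments.intervals.groupby("chrom", sort=False):
        if chrom not in site_chroms:
            n_skipped += len(frag)
            continue
        sub = sites[sites["chrom"] == chrom]
        idx = sub.index.to_numpy()
        cut = sub["cut_pos"].to_numpy()
        motif_start = sub["motif_start"].to_numpy()
        starts = np.sort(frag["start"].to_numpy())
        ends = np.sort(frag["end"].to_numpy())

        L[idx] += np.searchsorted(starts, cut, "right") - np.searchsorted(
            starts, cut, "left"
        )
        R[idx] += np.searchsorted(ends, cut, "right") - np.searchsorted(
            ends, cut, "left"
        )

        # spanning: fragment (a, b) covers motif strictly: a < motif_start, b > motif_start+4
        fs = frag["start"].to_numpy()
        fe = frag["end"].to_numpy()
        lo = np.searchsorted(motif_start, fs, "right")  # first site with ms > a
        hi = np.searchsorted(motif_start, fe - 4, "left")  # sites with ms < b-4
        diff = np.zeros(len(sub) + 1, dtype=np.int64)
        valid = lo < hi
        np.add.at(diff, lo[valid], 1)
        np.add.at(diff, hi[valid], -1)
        S[idx] += np.cumsum(diff[:-1])
    if n_skipped:
        logger.warning("skipped %d fragments on chromosomes absent from catalog", n_skipped)
    return pd.DataFrame({"L": L, "R": R, "S": S}, index=sites.index)


def estimate_fraction(
    counts, site, min_informative: int = 5
) -> float:
    """Methylated fraction of one site from its end/span counts.

    ``counts`` must expose L, R, S; ``site`` must expose left_ok,
    right_ok, cpg_overlap. Returns NaN when the informative denominator
    is below ``min_informative``; raises for sites with no usable
    half-site (they must be excluded upstream).
    """
    left_ok, right_ok = bool(site["left_ok"]), bool(site["right_ok"])
    if not (left_ok or right_ok):
        raise ValueError("site has no usable half-site; exclude it upstream")
    L, R, S = int(counts["L"]), int(counts["R"]), int(counts["S"])
    if left_ok and right_ok:
        denom = L + R + 2 * S
        num = L + R
    elif left_ok:  # upstream evidence only: fragments ending at the cut
        denom = R + S
        num = R
    else:  # downstream evidence only: fragments starting at the cut
        denom = L + S
        num = L
    if denom < min_informative:
        return float("nan")
    return num / denom


def _fractions_vector(
    counts: pd.DataFrame, sites: pd.DataFrame, min_informative: int
) -> np.ndarray:
    L = counts["L"].to_numpy(dtype=float)
    R = counts["R"].to_numpy(dtype=float)
    S = counts["S"].to_numpy(dtype=float)
    left = sites["left_ok"].to_numpy()
    right = sites["right_ok"].to_numpy()
    num = np.where(left & right, L + R, np.where(left, R, L))
    denom = np.where(left & right, L + R + 2 * S, np.where(left, R + S, L + S))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = num / denom
    f[denom < min_informative] = np.nan
    return f


@dataclass
class MethylationTrack:
    """Rectangular site x time point methylated-fraction structure.

    ``sites``: usable-site table (catalog subset, original site ids as
    index). ``fractions``: DataFrame indexed like ``sites`` with one
    float column per time point (NaN = missing). ``counts``: per time
    point, the raw L/R/S table over the same sites.
    """

    sites: pd.DataFrame
    fractions: pd.DataFrame
    counts: dict = field(default_factory=dict)

    @property
    def timepoints(self) -> list[float]:
        return [float(c) for c in self.fractions.columns]

    def to_bedgraph(self, timepoint: float, path) -> None:
        """bedGraph of f at each defined site's cut position (1 bp span);
        missing sites are absent."""
        f = self.fractions[timepoint]
        mask = f.notna()
        out = pd.DataFrame(
            {
                "chrom": self.sites.loc[mask, "chrom"],
                "start": self.sites.loc[mask, "cut_pos"],
                "end": self.sites.loc[mask, "cut_pos"] + 1,
                "value": f[mask],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)

    def to_tsv(self, path) -> None:
        out = self.sites[["chrom", "cut_pos", "left_ok", "right_ok"]].copy()
        out.insert(0, "site_id", out.index)
        for t in self.fractions.columns:
            if float(t) in self.counts:
                c = self.counts[float(t)]
                out[f"L_{t:g}"] = c["L"]
                out[f"R_{t:g}"] = c["R"]
                out[f"S_{t:g}"] = c["S"]
            out[f"f_{t:g}"] = self.fractions[t]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MethylationTrack":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("site_id")
        fcols = [c for c in df.columns if c.startswith("f_")]
        tps = [float(c[2:]) for c in fcols]
        fractions = df[fcols].copy()
        fractions.columns = tps
        sites = df[["chrom", "cut_pos", "left_ok", "right_ok"]].copy()
        counts = {}
        for t in tps:
            lcol = f"L_{t:g}"
            if lcol in df.columns:
                counts[t] = pd.DataFrame(
                    {"L": df[lcol], "R": df[f"R_{t:g}"], "S": df[f"S_{t:g}"]}
                )
        return cls(sites=sites, fractions=fractions, counts=counts)


def build_track(
    counts_by_timepoint,
    catalog: SiteCatalog,
    min_informative: int = 5,
) -> MethylationTrack:
    """Assemble a :class:`MethylationTrack` from per-time-point counts.

    ``counts_by_timepoint``: mapping of time point to L/R/S DataFrame
    (as from :func:`count_site_ends`) or a sequence of (t, counts)
    pairs; duplicate time points are an error. Only usable catalog
    sites are retained.
    """
    if isinstance(counts_by_timepoint, Mapping):
        items = list(counts_by_timepoint.items())
    else:
        items = list(counts_by_timepoint)
    tps = [float(t) for t, _ in items]
    if len(set(tps)) != len(tps):
        raise ValueError(f"duplicate timepoints: {tps}")

    usable = catalog.usable_sites()
    fractions = {}
    counts = {}
    for t, c in items:
        c_usable = c.loc[usable.index]
        fractions[float(t)] = _fractions_vector(c_usable, usable, min_informative)
        counts[float(t)] = c_usable
    frame = pd.DataFrame(fractions, index=usable.index)
    frame = frame[sorted(frame.columns)]
    return MethylationTrack(sites=usable.copy(), fractions=frame, counts=counts)


def quantify_timecourse(
    fragment_sets: Mapping[float, FragmentSet],
    catalog: SiteCatalog,
    min_informative: int = 5,
) -> MethylationTrack:
    """Count ends and build the methylation track for a whole time course."""
    counts = {t: count_site_ends(fs, catalog) for t, fs in fragment_sets.items()}
    return build_track(counts, catalog, min_informative=min_informative)
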