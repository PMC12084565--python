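"""GATC site catalog: discovery and usability filtering.

Dam methylates the adenine of GATC; DpnI then cuts fully methylated sites
between A and T (``GA^TC``), leaving blunt ends. Every downstream
quantification is anchored on the catalog built here: one record per
plus-strand GATC occurrence (the motif is its own reverse complement, so
this enumerates all sites), with the DpnI cut coordinate ``cut_pos =
motif_start + 2`` and three usability flags:

``cpg_overlap``
    The site's own C/G participates in a CpG dinucleotide (5-mer context
    ``GATCG`` on the plus strand or ``CGATC``, its minus-strand mirror).
    CpG methylation (GATm5C) blocks DpnI, so such sites cannot be scored.
``left_ok`` / ``right_ok``
    Whether fragment-end evidence on that side of the cut is trustworthy.
    When two adjacent cuts are closer than ``min_dist`` (default 150 bp)
    the inter-cut fragment is small enough to be lost during purification,
    so the facing half-sites are marked unusable.

A site is *usable* when it is not CpG-flagged and at least one half-site
survives.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSequence

SITE_COLUMNS = ["chrom", "motif_start", "cut_pos", "cpg_overlap", "left_ok", "right_ok"]

MOTIF = "GATC"
CUT_OFFSET = 2  # DpnI cuts GA^TC


@dataclass
class SiteCatalog:
    """All GATC sites of a genome, ordered by (chromosome, position).

    ``sites`` is a DataFrame with columns :data:`SITE_COLUMNS` and a
    0..n-1 integer index that serves as the stable site id.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")

    @property
    def n_total(self) -> int:
        return len(self.sites)

    @property
    def usable_mask(self) -> pd.Series:
        s = self.sites
        return (s["left_ok"] | s["right_ok"]) & ~s["cpg_overlap"]

    @property
    def n_usable(self) -> int:
        return int(self.usable_mask.sum())

    def usable_sites(self) -> pd.DataFrame:
        return self.sites[self.usable_mask]

    def summary(self) -> dict:
        s = self.sites
        return {
            "n_total": self.n_total,
            "n_usable": self.n_usable,
            "n_cpg_overlap": int(s["cpg_overlap"].sum()),
            "n_left_filtered": int((~s["left_ok"]).sum()),
            "n_right_filtered": int((~s["right_ok"]).sum()),
        }

    # -- serialisation -----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write a BED6-like TSV: chrom, motif_start, motif_end, site_id,
        half-site code (L/R/C letters present = usable-left, usable-right,
        CpG-flagged), strand placeholder."""
        s = self.sites
        code = np.where(s["left_ok"], "L", "-")
        code = np.char.add(code.astype(str), np.where(s["right_ok"], "R", "-"))
        code = np.char.add(code, np.where(s["cpg_overlap"], "C", "-"))
        out = pd.DataFrame(
            {
                "chrom": s["chrom"],
                "start": s["motif_start"],
                "end": s["motif_start"] + len(MOTIF),
                "site_id": s.index,
                "code": code,
                "strand": ".",
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)

    def write_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


def find_gatc_sites(genome: GenomeSequence) -> SiteCatalog:
    """Enumerate every plus-strand GATC occurrence of a genome.

    GATC cannot overlap itself, so non-overlapping regex matching is
    exhaustive. Sites are returned with all flags initialised usable and
    unflagged; run :func:`flag_cpg_overlap` and
    :func:`flag_close_halfsites` to apply the standard filters.
    """
    rows: list[tuple[str, int]] = []
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom)
        for m in re.finditer(MOTIF, seq):
            rows.append((chrom, m.start()))
    sites = pd.DataFrame(rows, columns=["chrom", "motif_start"])
    if len(sites) == 0:
        sites = pd.DataFrame(
            {"chrom": pd.Series(dtype=object), "motif_start": pd.Series(dtype=np.int64)}
        )
    sites["cut_pos"] = sites["motif_start"] + CUT_OFFSET
    sites["cpg_overlap"] = False
    sites["left_ok"] = True
    sites["right_ok"] = True
    return SiteCatalog(sites[SITE_COLUMNS].reset_index(drop=True))


def flag_cpg_overlap(catalog: SiteCatalog, genome: GenomeSequence) -> SiteCatalog:
    """Flag sites whose GATC contacts a CpG dinucleotide.

    The motif's own C (or the G on the other strand) forms a CpG exactly
    when the local 5-mer is ``GATCG`` (plus strand) or ``CGATC`` (the
    symmetric minus-strand case). Sites at sequence edges with truncated
    context are left unflagged (no CpG demonstrable).
    """
    sites = catalog.sites.copy()
    flags = np.zeros(len(sites), dtype=bool)
    for chrom, idx in sites.groupby("chrom", sort=False).groups.items():
        seq = genome.sequence(chrom)
        starts = sites.loc[idx, "motif_start"].to_numpy()
        for j, m in zip(idx, starts):
            after_g = m + 4 < len(seq) and seq[m + 4] == "G"
            before_c = m > 0 and seq[m - 1] == "C"
            if after_g or before_c:
                flags[j] = True
    sites["cpg_overlap"] = flags
    return SiteCatalog(sites)


def flag_close_halfsites(catalog: SiteCatalog, min_dist: int = 150) -> SiteCatalog:
    """Mark facing half-sites of cut pairs closer than ``min_dist`` unusable.

    For adjacent sites on a chromosome whose cut positions are less than
    ``min_dist`` apart, the fragment between the two cuts is shorter than
    the size-selection survival limit, so the upstream site loses its
    right half-site and the downstream site its left half-site. Applying
    the filter twice equals applying it once.
    """
    if min_dist <= 0:
        raise ValueError(f"min_dist must be positive, got {min_dist}")
    sites = catalog.sites.copy()
    left_ok = sites["left_ok"].to_numpy().copy()
    right_ok = sites["right_ok"].to_numpy().copy()
    for _, idx in sites.groupby("chrom", sort=False).groups.items():
        pos = sites.loc[idx, "cut_pos"].to_numpy()
        order = np.asarray(idx)
        close = np.diff(pos) < min_dist
        right_ok[order[:-1][close]] = False
        left_ok[order[1:][close]] = False
    sites["left_ok"] = left_ok
    sites["right_ok"] = right_ok
    return SiteCatalog(sites)


def build_filtered_catalog(genome: GenomeSequence, min_dist: int = 150) -> SiteCatalog:
    """Convenience: discovery plus both standard filters."""
    catalog = find_gatc_sites(genome)
    catalog = flag_cpg_overlap(catalog, genome)
    return flag_close_halfsites(catalog, min_dist=min_dist)
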