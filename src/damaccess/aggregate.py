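"""Feature grouping, windowed rates, chromosome distributions, gene classes.

Sites are grouped by the single coordinate ``cut_pos`` (half-open BED
containment), so a motif straddling a feature boundary is never counted
twice; a site may belong to several overlapping feature sets, matching
independent per-mark groupings. Windowed analyses tile each chromosome
with fixed non-overlapping windows anchored at coordinate 0 (last
partial window retained) and fit the log-linear rate to the per-window
*mean* fraction, normalised to the genome-wide rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticFit, TimeCourse, _log_linear
from .quantify import MethylationTrack
from .sites import SiteCatalog

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """Named BED-semantics intervals (chrom, start, end[, label]); may overlap."""

    name: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        iv = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in iv.columns:
                raise ValueError(f"feature table missing column {col!r}")
        if len(iv) and (iv["start"] >= iv["end"]).any():
            raise ValueError("feature intervals must have start < end")

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
        if 3 in df.columns:
            df = df.rename(columns={3: "label"})
        return cls(name=name or str(path), intervals=df)


def sites_in_features(catalog: SiteCatalog, features: FeatureSet) -> pd.Index:
    """Usable sites whose cut position falls in any feature interval.

    Half-open containment (``start <= cut_pos < end``); membership is
    deduplicated. Returns site ids (catalog index values).
    """
    if len(features.intervals) == 0:
        logger.warning("feature set %r is empty", features.name)
        return pd.Index([], dtype=np.int64)
    usable = catalog.usable_sites()
    hit = np.zeros(len(usable), dtype=bool)
    for chrom, iv in features.intervals.groupby("chrom", sort=False):
        sub = usable[usable["chrom"] == chrom]
        if len(sub) == 0:
            continue
        cut = sub["cut_pos"].to_numpy()
        local = np.zeros(len(sub), dtype=bool)
        for s, e in zip(iv["start"].to_numpy(), iv["end"].to_numpy()):
            local |= (cut >= s) & (cut < e)
        hit[usable.index.get_indexer(sub.index)] = local
    return usable.index[hit]


@dataclass
class WindowMatrix:
    """Fixed-window summary: per-window per-timepoint mean fraction,
    fitted rate and relative rate; ``reference`` is the genome-wide fit."""

    window: int
    table: pd.DataFrame
    reference: KineticFit

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def genome_wide_fit(
    track: MethylationTrack, statistic: str = "mean", clip_eps: float = 1e-6
) -> KineticFit:
    """Log-linear rate of the genome-wide summary time course."""
    from .kinetics import summarize_timecourse, fit_log_linear

    tc = summarize_timecourse(track, statistic=statistic)
    return fit_log_linear(tc, clip_eps=clip_eps)


def window_rates(
    track: MethylationTrack,
    window: int = 100_000,
    reference_rate: float | None = None,
    clip_eps: float = 1e-6,
) -> WindowMatrix:
    """Mean methylated fraction and fitted rate per fixed genomic window.

    Windows with no usable sites are missing (absent rows). The relative
    rate divides each window's rate by ``reference_rate`` (default: the
    genome-wide log-linear fit on per-time-point means).
    """
    if window < 1_000:
        raise ValueError(f"window size must be >= 1 kb, got {window}")
    if len(track.fractions) == 0:
        raise ValueError("empty methylation track")
    reference = genome_wide_fit(track, statistic="mean", clip_eps=clip_eps)
    ref_k = reference.k if reference_rate is None else float(reference_rate)

    tps = track.timepoints
    df = track.sites[["chrom", "cut_pos"]].copy()
    df["win"] = df["cut_pos"] // window
    joined = df.join(track.fractions)

    rows = []
    for (chrom, win), grp in joined.groupby(["chrom", "win"], sort=True):
        means = [grp[t].mean() for t in tps]
        n_sites = int(grp[tps[0]].notna().sum() if tps else len(grp))
        t_arr = np.array(tps)
        m_arr = np.array(means, dtype=float)
        try:
            fit = _log_linear(t_arr, m_arr, clip_eps)
            k = fit.k
        except ValueError:
            k = np.nan
        rows.append(
            {
                "chrom": chrom,
                "start": int(win) * window,
                "end": (int(win) + 1) * window,
                "n_sites": n_sites,
                "k": k,
                "rel_rate": k / ref_k if ref_k > 0 else np.nan,
                **{f"mean_{t:g}": m for t, m in zip(tps, means)},
            }
        )
    return WindowMatrix(window=window, table=pd.DataFrame(rows), reference=reference)


def chromosome_rate_distribution(
    wm: WindowMatrix, bin_width: float = 0.05
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-chromosome histogram of window relative rates plus modal rate.

    Fixed bins anchored at 0 with the given width; each chromosome's
    histogram mass sums to 1; the mode is the centre of the most
    populated bin (ties resolved toward the lower bin). Chromosomes with
    no finite windows are skipped with a warning.
    """
    rows = []
    modes: dict[str, float] = {}
    for chrom, grp in wm.table.groupby("chrom", sort=False):
        rates = grp["rel_rate"].to_numpy(dtype=float)
        rates = rates[np.isfinite(rates)]
        if rates.size == 0:
            logger.warning("chromosome %s has no windows with a fitted rate", chrom)
            continue
        n_bins = int(np.floor(rates.max() / bin_width)) + 1
        edges = np.arange(n_bins + 1) * bin_width
        hist, _ = np.histogram(rates, bins=edges)
        frac = hist / hist.sum()
        mode_bin = int(np.argmax(hist))  # argmax returns the first (lowest) max
        modes[chrom] = float(edges[mode_bin] + bin_width / 2.0)
        for b in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_left": float(edges[b]),
                    "bin_right": float(edges[b + 1]),
                    "fraction": float(frac[b]),
                }
            )
    return pd.DataFrame(rows), modes


def _mean_signal(
    signal: pd.DataFrame, chrom: str, start: int, end: int
) -> float:
    """Mean bedGraph value over [start, end); uncovered bases count as 0."""
    sub = signal[signal["chrom"] == chrom]
    if len(sub) == 0:
        return 0.0
    s = np.maximum(sub["start"].to_numpy(), start)
    e = np.minimum(sub["end"].to_numpy(), end)
    overlap = np.maximum(0, e - s)
    total = float(np.sum(overlap * sub["value"].to_numpy()))
    return total / (end - start)


def classify_genes(
    genes: pd.DataFrame,
    signal: pd.DataFrame,
    flank: int = 1000,
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Assign the active flag by mean promoter signal.

    ``genes`` needs gene_id, chrom, tss, strand, expression; ``signal``
    is a bedGraph frame (chrom, start, end, value). A gene is active iff
    the mean signal over [tss - flank, tss + flank) exceeds ``threshold``
    (uncovered positions count as 0).
    """
    bad = set(genes["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"malformed strand values: {sorted(bad)}")
    out = genes.copy()
    means = [
        _mean_signal(signal, row["chrom"], int(row["tss"]) - flank, int(row["tss"]) + flank)
        for _, row in genes.iterrows()
    ]
    out["promoter_signal"] = means
    out["active"] = np.array(means) > threshold
    return out


def assign_quintiles(genes: pd.DataFrame) -> pd.DataFrame:
    """Split active genes into expression quintiles Q1 (lowest) .. Q5
    (highest); inactive genes become 'NoTrans'.

    Active genes are sorted ascending by expression (ties broken stably
    by gene_id) and cut into 5 contiguous groups as equal as possible,
    with the remainder going to the highest quintiles (23 genes ->
    4,4,5,5,5 for Q1..Q5).
    """
    if "active" not in genes.columns:
        raise ValueError("run classify_genes first (missing 'active' column)")
    n_active = int(genes["active"].sum())
    if n_active < 5:
        raise ValueError(f"need >= 5 active genes for quintiles, got {n_active}")
    out = genes.copy()
    out["quintile"] = "NoTrans"
    active = out[out["active"]].sort_values(
        ["expression", "gene_id"], kind="mergesort"
    )
    base, rem = divmod(n_active, 5)
    sizes = [base + (1 if q >= 5 - rem else 0) for q in range(5)]
    labels = np.repeat([f"Q{q + 1}" for q in range(5)], sizes)
    out.loc[active.index, "quintile"] = labels
    return out
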