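"""Synthetic Dam methylation time courses on an annotated genome.

The simulator emulates the statistical structure of an in-vivo Dam
accessibility experiment:

* Per molecule (genome copy), each GATC site is methylated independently
  with probability ``p(t) = A * (1 - exp(-k * t))``, where the rate ``k``
  (per hour) and the accessible fraction ``A`` depend on the annotated
  region class at the site. Hemimethylation is not modelled: DpnI requires
  full methylation, so one Bernoulli per site per molecule suffices.
* DpnI cuts at every methylated site's cut coordinate; each resulting
  stretch is then sheared by recursive binary splitting toward a target
  size of ``shear_mean`` bp — the unimodal fragment-length distribution
  acoustic sonication produces, with essentially no shear-generated
  piece below ~0.45 * shear_mean. Fragments shorter than ``shear_min``
  (typically small inter-cut pieces) are discarded, emulating the loss
  of small fragments during purification.
* A *nuclei* regime reproduces plateau behaviour: nucleosome-protected
  positions are inert (A near 0) while linker positions methylate fast
  (A = 1). For unpositioned chromatin the cell-to-cell variation of
  nucleosome positions is captured by setting A to the linker fraction:
  each molecule has the site in linker with that probability, so the
  population methylated fraction plateaus there.
* Phased nucleosome arrays downstream of anchors (active TSSs, CTCF
  motifs) are laid out as alternating nucleosome/linker blocks behind a
  nucleosome-depleted region, producing phasing signal in nuclei mode.

All outputs are deterministic given the configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .quantify import FragmentSet
from .sites import SiteCatalog

logger = logging.getLogger(__name__)

CLASS_LABELS = (
    "euchromatin",
    "heterochromatin",
    "centromere_like",
    "ndr",
    "linker",
    "nucleosome",
)

NUCLEOSOME_LEN = 147  # bp wrapped around the octamer


@dataclass(frozen=True)
class ClassKinetics:
    """First-order methylation kinetics of one region class.

    ``k`` is the methylation rate in 1/h; ``A`` the accessible fraction,
    i.e. the limit the methylated fraction approaches.
    """

    k: float
    A: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"rate k must be >= 0, got {self.k}")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError(f"accessible fraction A must be in [0,1], got {self.A}")


@dataclass
class KineticsParams:
    """Per-class kinetics plus the experimental regime.

    ``mode`` is ``"live"`` (living cells: A typically 1, rate varies by
    chromatin class) or ``"nuclei"`` (static chromatin: linker fast,
    nucleosome inert, plateaus below 1). The mode is descriptive; the
    behaviour is fully encoded in the per-class (k, A) pairs.
    """

    classes: Mapping[str, ClassKinetics]
    mode: str = "live"

    def __post_init__(self) -> None:
        if self.mode not in ("live", "nuclei"):
            raise ValueError(f"mode must be 'live' or 'nuclei', got {self.mode!r}")

    def for_class(self, label: str) -> ClassKinetics:
        try:
            return self.classes[label]
        except KeyError:
            raise KeyError(f"no kinetics configured for class {label!r}") from None


def nuclei_params(
    linker_fraction: float = 0.35, k_fast: float = 0.3
) -> KineticsParams:
    """Kinetics for unpositioned chromatin in isolated nuclei.

    Each molecule has a given site in accessible linker with probability
    ``linker_fraction`` (nucleosome positions vary cell to cell); linker
    DNA methylates fast, nucleosomal DNA not at all, so every class
    plateaus at the linker fraction.
    """
    kin = ClassKinetics(k=k_fast, A=linker_fraction)
    return KineticsParams(
        classes={c: kin for c in ("euchromatin", "heterochromatin", "centromere_like")},
        mode="nuclei",
    )


def phased_nuclei_params(k_fast: float = 0.3, nucleosome_A: float = 0.0) -> KineticsParams:
    """Kinetics for positioned arrays in nuclei: NDR/linker fast and full,
    nucleosome-protected positions inert."""
    fast = ClassKinetics(k=k_fast, A=1.0)
    return KineticsParams(
        classes={
            "euchromatin": fast,
            "ndr": fast,
            "linker": fast,
            "nucleosome": ClassKinetics(k=k_fast, A=nucleosome_A),
        },
        mode="nuclei",
    )


@dataclass
class RegionClassMap:
    """Labelled genomic intervals with first-match-wins lookup.

    ``intervals`` has columns chrom, start, end, label (0-based half-open);
    positions not covered by any interval default to ``default`` class.
    """

    intervals: pd.DataFrame
    default: str = "euchromatin"

    def __post_init__(self) -> None:
        iv = self.intervals
        for col in ("chrom", "start", "end", "label"):
            if col not in iv.columns:
                raise ValueError(f"class map missing column {col!r}")
        bad = set(iv["label"]) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown region class labels: {sorted(bad)}")
        if len(iv) and (iv["start"] >= iv["end"]).any():
            raise ValueError("class map intervals must have start < end")

    def lookup(self, chrom: str, pos: int) -> str:
        iv = self.intervals
        hits = iv[(iv["chrom"] == chrom) & (iv["start"] <= pos) & (pos < iv["end"])]
        if len(hits):
            return str(hits.iloc[0]["label"])
        return self.default

    def classify(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised lookup: class label for each position (first match wins)."""
        labels = np.full(len(positions), self.default, dtype=object)
        iv = self.intervals[self.intervals["chrom"] == chrom]
        # iterate in reverse so earlier intervals overwrite later ones
        for start, end, label in zip(
            iv["start"].to_numpy()[::-1],
            iv["end"].to_numpy()[::-1],
            iv["label"].to_numpy()[::-1],
        ):
            labels[(positions >= start) & (positions < end)] = label
        return labels

    def to_bed(self, path) -> None:
        self.intervals[["chrom", "start", "end", "label"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class SimConfig:
    """Experiment layout: time points, sequencing depth, shearing.

    ``shear_mean`` is the sonication target fragment size (None disables
    shearing); fragments below ``shear_min`` bp are lost.
    ``nucleosome_spacing``/``linker_len`` configure phased-array layout.
    """

    timepoints: Sequence[float] = (12.0, 24.0, 48.0, 72.0)
    n_molecules: int = 200
    shear_mean: float | None = 350.0
    shear_min: int = 150
    seed: int = 0
    nucleosome_spacing: int = 200
    linker_len: int = 53

    def __post_init__(self) -> None:
        tps = list(self.timepoints)
        if any(t < 0 for t in tps):
            raise ValueError("timepoints must be nonnegative")
        if sorted(tps) != tps:
            raise ValueError("timepoints must be ascending")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.shear_mean is not None and self.shear_min >= self.shear_mean:
            raise ValueError("shear_min must be < shear_mean")


def generate_genome(
    length: int,
    n_chroms: int = 1,
    seed: int = 0,
    class_blocks: Sequence[tuple[str, int]] | None = None,
) -> tuple[GenomeSequence, RegionClassMap]:
    """Random uniform-composition genome with a tiled class annotation.

    Each chromosome is ``length`` bp of i.i.d. uniform A/C/G/T, so GATC
    sites arise at ~1 per 256 bp. ``class_blocks`` is a cycle of
    (label, width) blocks tiled across each chromosome; omitted regions
    default to euchromatin.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb for kinetics to be fittable")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for i in range(n_chroms):
        arr = bases[rng.integers(0, 4, size=length)]
        seqs[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    genome = GenomeSequence(seqs)

    rows = []
    if class_blocks:
        for chrom in genome.chrom_names:
            pos = 0
            bi = 0
            while pos < length:
                label, width = class_blocks[bi % len(class_blocks)]
                end = min(pos + int(width), length)
                rows.append((chrom, pos, end, label))
                pos = end
                bi += 1
    classes = RegionClassMap(
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    )
    return genome, classes


def site_methylation_prob(kin: ClassKinetics, t: float) -> float:
    """Population methylation probability at time ``t`` (hours):
    ``p(t) = A * (1 - exp(-k t))``."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return kin.A * (1.0 - np.exp(-kin.k * t))


def _molecule_fragments(
    rng: np.random.Generator,
    chrom_len: int,
    cut_pos: np.ndarray,
    p: np.ndarray,
    shear_mean: float | None,
    shear_min: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment one genome copy: Bernoulli methylation, DpnI cuts, shearing.

    Shearing splits every piece larger than 1.5 * shear_mean at a point
    drawn near its middle, recursively, mimicking sonication toward a
    target size; split children are never below 0.3 * 1.5 * shear_mean.
    """
    meth = rng.random(cut_pos.size) < p
    cuts = cut_pos[meth]
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [chrom_len]))
    if shear_mean is not None:
        cutoff = 1.5 * shear_mean
        while True:
            length = ends - starts
            big = length > cutoff
            if not big.any():
                break
            frac = np.clip(rng.normal(0.5, 0.07, int(big.sum())), 0.3, 0.7)
            mid = starts[big] + np.rint(length[big] * frac).astype(np.int64)
            starts = np.concatenate((starts[~big], starts[big], mid))
            ends = np.concatenate((ends[~big], mid, ends[big]))
    keep = (ends - starts) >= shear_min
    return starts[keep], ends[keep]


def simulate_fragments(
    genome: GenomeSequence,
    catalog: SiteCatalog,
    classes: RegionClassMap,
    params: KineticsParams,
    config: SimConfig,
) -> tuple[dict[float, FragmentSet], pd.DataFrame]:
    """Simulate the digestion/sequencing readout of a methylation time course.

    Returns one sorted :class:`FragmentSet` per time point plus a ground
    truth table (chrom, cut_pos, class, k, A and the exact p(t) per time
    point for every catalog site).
    """
    if catalog.n_total == 0:
        logger.warning("empty site catalog: fragments arise from shearing only")
    rng = np.random.default_rng(config.seed)

    # per-chromosome site arrays and ground-truth probabilities
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    truth_rows = []
    for chrom in genome.chrom_names:
        sub = catalog.sites[catalog.sites["chrom"] == chrom]
        cut = sub["cut_pos"].to_numpy()
        labels = classes.classify(chrom, cut)
        k = np.array([params.for_class(c).k for c in labels])
        A = np.array([params.for_class(c).A for c in labels])
        per_chrom[chrom] = (cut, k, A)
        for i in range(len(cut)):
            row = {
                "chrom": chrom,
                "cut_pos": int(cut[i]),
                "class": labels[i],
                "k": k[i],
                "A": A[i],
            }
            for t in config.timepoints:
                row[f"p_{t:g}"] = A[i] * (1.0 - np.exp(-k[i] * t))
            truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    fragment_sets: dict[float, FragmentSet] = {}
    for t in config.timepoints:
        chroms_out, starts_out, ends_out = [], [], []
        for chrom in genome.chrom_names:
            cut, k, A = per_chrom[chrom]
            p = A * (1.0 - np.exp(-k * t))
            clen = genome.length(chrom)
            for _ in range(config.n_molecules):
                s, e = _molecule_fragments(
                    rng, clen, cut, p, config.shear_mean, config.shear_min
                )
                starts_out.append(s)
                ends_out.append(e)
                chroms_out.append(np.full(s.size, chrom, dtype=object))
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(chroms_out) if chroms_out else [],
                "start": np.concatenate(starts_out) if starts_out else [],
                "end": np.concatenate(ends_out) if ends_out else [],
            }
        )
        fragment_sets[t] = FragmentSet(df, sample_id=f"sim_t{t:g}", timepoint=t)
    return fragment_sets, truth


def simulate_phased_arrays(
    anchors: pd.DataFrame,
    genome: GenomeSequence,
    ndr_width: int = 140,
    nucleosome_len: int = NUCLEOSOME_LEN,
    linker_len: int = 53,
    n_nucleosomes: int = 10,
) -> RegionClassMap:
    """Lay positioned nucleosome arrays downstream of anchors.

    ``anchors`` needs columns chrom, pos, strand. Each anchor gets an NDR
    block of ``ndr_width`` bp at its position followed (strand-aware) by
    ``n_nucleosomes`` alternating nucleosome/linker blocks, giving a
    repeat length of ``nucleosome_len + linker_len``. Overlapping arrays:
    the later anchor wins (logged).
    """
    for col in ("chrom", "pos", "strand"):
        if col not in anchors.columns:
            raise ValueError(f"anchors missing column {col!r}")
    rows = []
    prev_end: dict[str, int] = {}
    for _, a in anchors.iterrows():
        chrom, pos, strand = a["chrom"], int(a["pos"]), a["strand"]
        if strand not in ("+", "-"):
            raise ValueError(f"invalid strand {strand!r}")
        clen = genome.length(chrom)
        if not 0 <= pos < clen:
            raise ValueError(f"anchor {chrom}:{pos} outside chromosome bounds")
        blocks = [("ndr", ndr_width)]
        for _ in range(n_nucleosomes):
            blocks.append(("nucleosome", nucleosome_len))
            blocks.append(("linker", linker_len))
        cursor = pos
        for label, width in blocks:
            if strand == "+":
                start, end = cursor, min(cursor + width, clen)
                cursor += width
            else:
                start, end = max(cursor - width, 0), cursor
                cursor -= width
            if start < end:
                rows.append((chrom, start, end, label))
        lo = min(pos, cursor)
        if chrom in prev_end and lo < prev_end[chrom]:
            logger.info("overlapping anchor arrays on %s; later anchor wins", chrom)
        prev_end[chrom] = max(pos, cursor)
    # later anchors win => list later intervals first (first match wins on lookup)
    rows.reverse()
    return RegionClassMap(
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    )


def simulate_dyad_fragments(
    classes: RegionClassMap,
    n_per_nucleosome: int = 40,
    jitter_sd: float = 25.0,
    length_range: tuple[int, int] = (130, 170),
    seed: int = 0,
) -> FragmentSet:
    """Synthetic MNase-protection readout of a positioned-array class map.

    For every nucleosome-labelled block, emit mononucleosome-sized
    fragments whose midpoints scatter around the block centre (Gaussian
    jitter), the way MNase-seq dyads scatter around the true dyad.
    """
    rng = np.random.default_rng(seed)
    nuc = classes.intervals[classes.intervals["label"] == "nucleosome"]
    chroms, starts, ends = [], [], []
    for _, iv in nuc.iterrows():
        center = (int(iv["start"]) + int(iv["end"])) // 2
        dyads = np.rint(center + rng.normal(0.0, jitter_sd, n_per_nucleosome)).astype(int)
        lengths = rng.integers(length_range[0], length_range[1] + 1, n_per_nucleosome)
        s = dyads - lengths // 2
        e = s + lengths
        ok = s >= 0
        chroms.append(np.full(ok.sum(), iv["chrom"], dtype=object))
        starts.append(s[ok])
        ends.append(e[ok])
    df = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms) if chroms else [],
            "start": np.concatenate(starts) if starts else [],
            "end": np.concatenate(ends) if ends else [],
        }
    )
    return FragmentSet(df, sample_id="sim_mnase")
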