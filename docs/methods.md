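# Methods

## The measurement model

The package quantifies chromatin accessibility from the kinetics of Dam
(E. coli DNA adenine methyltransferase) methylation at GATC sites.
Expressed in cells (or supplied to isolated nuclei), Dam methylates the
adenine of every GATC it can reach. Purified genomic DNA is digested with
DpnI, which cuts only fully methylated GATC between A and T (GA^TC,
blunt), then sheared and sequenced paired-end. For each GATC site, each
sequenced molecule testifies either that the site was methylated (the
molecule was cut there: two daughter fragments, one ending and one
starting at the cut coordinate) or that it was not (one fragment spanning
the intact motif).

### Site catalog

Every plus-strand occurrence of GATC is one site (the motif is its own
reverse complement). Coordinates are 0-based half-open; the cut
coordinate is `motif_start + 2`. Two filters mark sites unusable:

* **CpG overlap.** DpnI cannot cut GATC whose C carries 5mC, so a site
  whose C/G participates in a CpG dinucleotide cannot be scored. Since
  GATC contains no internal CpG, this is exactly the 5-mer context
  `GATCG` (plus strand) or its minus-strand mirror `CGATC`. Sites whose
  context is truncated by a sequence edge are left unflagged: no CpG is
  demonstrable. Literal sequence is used; ambiguity codes are not
  interpreted.
* **Half-site proximity.** Fragments shorter than ~150 bp are lost
  during purification, so when two adjacent cuts are closer than 150 bp
  the inter-cut fragment is systematically missing. The facing
  *half-sites* are marked unusable (the upstream site's downstream side
  and vice versa); a site leaves the usable set only when both half-sites
  are gone. The filter is idempotent and only ever clears flags.

### The fraction estimator

With L = fragments starting at the cut, R = fragments ending at the cut
and S = fragments strictly spanning the motif, the methylated fraction is

    f = (L + R) / (L + R + 2 S).

A cut molecule is observed twice (one L and one R), an uncut molecule
once (one S), so this is the exact fraction of cut molecules; on
per-molecule simulation without shearing it is unbiased at every p and
exact at p = 0 and p = 1. When a half-site was filtered, only the
surviving side's evidence enters: the downstream half-site is evidenced
by L and the upstream one by R, so a site with only its upstream
(left) half-site uses `R / (R + S)` and one with only its downstream
(right) half-site uses `L / (L + S)`. The filtered side's count is
exactly the evidence carried by the lost small fragments; scoring it
would re-import the loss as bias.

Sites whose informative denominator is below `min_informative`
(default 5) are reported missing, not zero — low-coverage zeros
destabilise rate fits. Shear breakpoints colliding with a cut coordinate
produce false end counts at ~1/shear_mean per site per molecule; this is
accepted as noise and not corrected.

## Kinetic models

Accessibility enters through first-order kinetics: a site accessible in
a fraction A of cells, methylated at rate k (per hour), has population
methylated fraction

    f(t) = A (1 - exp(-k t)).

* **Log-linear rate fit** (A = 1): ordinary least squares of
  `ln(1 - f)` on t; k = -slope, floored at 0. The intercept is free: a
  shared onset lag of enzyme expression shifts every subset's intercept
  identically, and the comparisons reported are *relative* rates, which
  are intercept-insensitive. Values >= 1 are clipped to `1 - 1e-6`
  before the log; a course saturated at 1 throughout is an error
  (use the saturating model). A constant course is a perfect fit of a
  constant and reports r² = 1 with k = 0. No weighting is applied.
* **Saturating fit**: bounded nonlinear least squares (trust-region)
  of A (1 - e^(-kt)) with A in [0, 1], k >= 0; initialisation
  A0 = min(1, 1.05 max f), k0 from the first two points' log-slope under
  A0; ftol 1e-8. A constant-zero course returns A = 0 with the rate
  flagged unidentifiable. On noiseless A = 1 data the fitted rate agrees
  with the log-linear rate to machine precision.
* **Relative rate**: a subset's k divided by the genome-wide reference
  k (error if the reference is 0). Scale-invariant by construction.

Summaries default to the **median** over sites per time point with a
5th–95th percentile band (linear interpolation between order statistics,
so bands are bit-for-bit reproducible); windowed analyses use the
**mean**, since 100-kb windows can hold few sites and the mean uses all
of them. Per-site rate fitting is available but noisy and not the
default; fits are subset-level.

## Aggregation conventions

Sites are assigned to features by the single cut coordinate with
half-open containment, so a motif straddling a boundary is never double
counted; a site may belong to several overlapping feature sets. Windows
are fixed, non-overlapping, anchored at 0, last partial window retained.
Per-chromosome rate distributions use fixed 0.05-wide bins anchored at
0; the modal relative rate is the centre of the most populated bin, ties
toward the lower bin. Gene activity is the mean of a signal track over
±1 kb of the TSS (uncovered bases count 0) against a threshold;
expression quintiles split active genes sorted ascending (ties broken by
gene id) into five contiguous groups as equal as possible, remainder to
the highest quintiles; inactive genes form the separate `NoTrans` group.

## Profiles

Methylation profiles average f over all (anchor, site) pairs per
strand-adjusted offset — sites are sparse, so per-anchor averaging first
would be dominated by empty anchors. Dyad profiles select
mononucleosome-sized fragments (120–180 bp inclusive), place one dyad at
`floor((start+end)/2)`, normalise each anchor's counts by that anchor's
region mean (anchors with empty regions are skipped), then average
across anchors; the asymmetry mirrors the two signals' sampling
structure. Both use a flank of 1005 bp (a 2010-bp region, offsets
−1005..+1004) and a 21-bp centred moving average that ignores missing
offsets — no zero fill, so offsets without a GATC site cannot create
artificial dips — truncated at the edges. The smoother is linear and the
identity on constants. Phasing is summarised by the Pearson correlation
of the two smoothed profiles over a chosen offset range (>= 10 paired
defined offsets required) and by the lag of the dyad profile's
autocorrelation maximum, which recovers the nucleosome repeat length.

## The simulator

The synthetic-data module generates the statistical structure the
analysis assumes, with exact ground truth:

* **Genome**: i.i.d. uniform A/C/G/T per chromosome (GATC every ~256 bp
  in expectation), region classes tiled in configurable blocks; minimum
  10 kb so kinetics are fittable. Deterministic given the seed; a single
  seeded RNG stream drives each simulation.
* **Methylation**: one Bernoulli per site per molecule with
  p(t) = A (1 - e^(-kt)) from the class at the cut position.
  Hemimethylation is not modelled — DpnI requires full methylation and
  the kinetics are phrased per site — and enzyme concentration is
  constant in time (the slowly rising expression of a transduced enzyme
  would make observed kinetics non-exponential; with the free-intercept
  fit and relative-rate reporting this simplification is immaterial to
  the quantities tested, but it is a documented divergence from live
  experiments).
* **Digestion and shearing**: cut at every methylated site, then shear
  each piece by recursive binary splitting: any piece longer than
  1.5 × shear_mean splits at a point drawn from a clipped normal around
  its middle. This mimics acoustic sonication, whose fragment lengths
  are unimodal around the target size (default 350 bp, a standard
  sonication target); split pieces never fall below 0.45 × shear_mean.
  A memoryless breakpoint process was rejected: its exponential length
  distribution puts heavy mass below the 150-bp survival limit and
  destroys fragment-end evidence adjacent to cuts ~2.5× more often than
  spanning evidence, biasing the estimator in a way real sonication
  profiles do not. Fragments below `shear_min` (default 150 bp) are then
  discarded — the loss that motivates the half-site filter, driven by
  close cut pairs rather than by shearing.
* **Nuclei regime**: linker DNA methylates fast and fully, nucleosomal
  DNA is inert. For unpositioned chromatin, cell-to-cell variation of
  nucleosome positions means a given site is in linker in a fraction of
  molecules equal to the linker fraction of the genome; this is encoded
  as A = linker fraction, so the population median plateaus there while
  a live-regime course keeps rising. For positioned arrays the
  linker/nucleosome geometry is explicit in the class map and A is 1
  (linker/NDR) or 0 (nucleosome).
* **Phased arrays**: an NDR block (default 140 bp) at each anchor,
  then alternating 147-bp nucleosome and configurable linker blocks
  (default 53 bp → 200-bp repeat), strand-aware; overlapping arrays
  resolve in favour of the later anchor.
* **Dyad readout**: mononucleosome-sized fragments centred on
  nucleosome-block midpoints with Gaussian jitter, sd 25 bp — nucleosome
  positioning variability (~15–20 bp) plus MNase digestion-edge
  variability of fragment midpoints. Much tighter jitter is unphysical:
  real dyad profiles around phased arrays are broad oscillations, not
  10-bp spikes.

### What the simulator does not emulate

Sequencing error, alignment ambiguity, PCR duplicates, GC bias,
copy-number variation, hemimethylation and time-varying enzyme
concentration are all absent. Passing recovery tests therefore shows the
*analysis* is correct under the stated generative model, not that real
libraries are free of these artefacts; on real data the upstream
alignment pipeline and replicate concordance carry that burden.

## Verification studies and problem sizes

The canonical studies in `damaccess.studies` (run by the test suite and
`scripts/acceptance.py`) use desk-scale problem sizes chosen so each
study's sampling error is well inside the tolerance it is checked
against:

* estimator calibration: 10-kb genome (~40 sites), 10 000 molecules per
  p ∈ {0, 0.25, 0.5, 0.75, 1}, no shearing — binomial SE ~0.005;
* rate recovery: 200-kb genome (80% euchromatin / 14% heterochromatin /
  6% centromere-like; class rates 1.0× / 0.8× / 0.4× of 0.03/h), four
  time points 12/24/48/72 h, 250 molecules per time point;
* nuclei plateau: 100-kb genome, linker fraction 0.35, fast rate 0.3/h,
  200 molecules;
* phased arrays: 99 anchors spaced 3 kb, six 200-bp repeats each,
  150 molecules, one 24-h time point.

## Known limitations

* Per-site rate fits at realistic coverage are noisy; rates are meant to
  be read at the subset/window level.
* The relative-rate normalisation assumes the genome-wide median course
  is dominated by a majority class; in a genome with no majority class
  the reference is a mixture rate and configured multipliers are no
  longer exactly the ground-truth relative rates.
* The CpG filter interprets sequence literally; variant-induced CpG
  contexts are invisible.
* bedGraph is the canonical track output; binary formats are out of
  scope.
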