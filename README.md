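# damaccess

Chromatin accessibility from Dam methylation kinetics at GATC sites.

**Who it is for.** Labs measuring in-vivo genome accessibility by
expressing E. coli Dam methyltransferase and reading out methylation
with DpnI digestion and paired-end sequencing. The open question this
readout addresses: is condensed chromatin (heterochromatin, centromeres)
actually closed to proteins in living cells, or only in the static
chromatin of isolated nuclei? Answering it requires quantitative,
per-site methylation *kinetics*, not just end-point signal.

**What it computes.** For every GATC site (DpnI cuts GA^TC only when
fully methylated), fragments from a sequenced time course testify
whether each molecule was cut (methylated) or intact. With L fragment
starts at the cut, R fragment ends at the cut and S fragments spanning
the motif, the methylated fraction is

    f = (L + R) / (L + R + 2S),

the exact fraction of cut molecules (one-sided forms are used where the
150-bp small-fragment loss filter removed a half-site). Site-subset time
courses are fitted with first-order kinetics

    f(t) = A · (1 − e^(−kt)),

via `ln(1 − f)` regression for the rate k (per hour) when A = 1, or
bounded nonlinear least squares when methylation saturates below 1 (A is
the accessible fraction — the fraction of cells in which the site is
ever reachable). Rates are reported relative to the genome-wide rate.
On top of this sit feature aggregation, 100-kb window rate maps,
per-chromosome rate distributions, expression quintiles, and
anchor-aligned methylation/nucleosome-dyad profiles with phasing
statistics. A fully seeded simulator (Dam methylation, DpnI digestion,
sonication, size selection, nuclei and phased-nucleosome regimes)
provides ground truth for every stage.

## Worked example

Simulate a four-time-point course over a genome that is 80% euchromatin,
14% heterochromatin and 6% centromere-like chromatin (class rates
1.0× / 0.8× / 0.4× of 0.03/h), quantify it, and recover the relative
rates:

```python
from damaccess import studies

result = studies.rate_recovery_study(seed=1)
print(f"genome-wide rate: {result.reference_k:.4f} /h")
for cls, (rel, n) in result.fitted.items():
    print(f"{cls:16s} relative rate {rel:.3f} (truth {result.truth[cls]:.1f}, {n} sites)")
```

prints

```
genome-wide rate: 0.0294 /h
euchromatin      relative rate 1.014 (truth 1.0, 310 sites)
heterochromatin  relative rate 0.828 (truth 0.8, 49 sites)
centromere_like  relative rate 0.400 (truth 0.4, 18 sites)
```

The fitted genome-wide rate matches the configured base rate (0.03/h,
i.e. the median site ~88% methylated at 72 h and still rising), and the
class relative rates recover the configured ordering: centromere-like
chromatin methylates ~2.5× slower than the genomic reference while
heterochromatin lags euchromatin only modestly — the kinetic signature
that distinguishes truly restricted chromatin from merely condensed
chromatin.

The same pipeline is scriptable from the shell:

```
damaccess simulate --out sim --seed 5
damaccess quantify --genome sim/genome.fa \
    --fragments 12:sim/fragments_t12.bed --fragments 24:sim/fragments_t24.bed \
    --fragments 48:sim/fragments_t48.bed --fragments 72:sim/fragments_t72.bed \
    --out quant
damaccess kinetics --track quant/track.tsv --out fits
damaccess windows  --track quant/track.tsv --out windows
```

Each stage writes plain-text artifacts (BED/bedGraph/TSV/JSON) plus a
JSON run manifest with config and input checksums.

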