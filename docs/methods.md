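# Methods

## Scope and model

`pahrisk` implements a dietary risk assessment for the 16 priority PAHs in
fish. The chain is:

1. **Descriptive statistics** — per group (species × cooking method) and
   per analyte: mean, median, min, max, sample SD (n−1 denominator), n;
   per-sample ΣPAH (sum of the 16 analytes) and PAH4
   (BaA + Chr + BbF + BaP) as additional rows. PAH4 membership follows the
   EU marker convention. Group differences use the two-sided Mann-Whitney
   U test (concentration data are typically non-normal): exact enumeration
   of the rank-assignment distribution when the combined sample size is
   ≤ 12 and the pooled data are tie-free, otherwise the normal
   approximation with tie-corrected variance and continuity correction.
   Per-analyte p-values are reported uncorrected, matching surveillance
   practice; a Holm adjustment is available but off by default.
2. **TEF collapse** — BEC = Σ C_i·TEF_i. Two schemes ship, differing only
   in dibenz[a,h]anthracene (DahA = 1 vs 5). The default keeps DahA = 1:
   applied to the pooled median profile of the calibration survey it
   reproduces the survey's reported BEC (2.6569 ≈ 2.65 µg/kg), which the
   DahA = 5 scheme does not. The collapse defaults to median
   concentrations for the same reason; means are a flag away (giving
   2.84 µg/kg).
3. **Intake** — EDI = C_mg · IR · (EF·ED) / (BW·AT) in mg/kg bw/day, with
   concentrations converted µg→mg internally so EDI·SF is dimensionless.
   ED is in years and EF in days/year, so EF·ED is the exposed days and
   EDI is the exposure-day fraction times C·IR/BW.
4. **Risk** — ILCR = EDI · SF. A second published form writes the risk
   directly from the BEC without an intake rate; read literally it is
   dimensionally inconsistent with the first, so this package defines the
   BEC route as the EDI route applied to the BaP-equivalent concentration.
   The two routes are then identical on every draw, and tests assert this
   exactly. Bands: < 10⁻⁶ negligible, 10⁻⁶–10⁻⁴ acceptable, > 10⁻⁴
   serious, configurable.

## Exposure parameter defaults

The calibration survey printed units for its exposure parameters but not
values (only BW = 70 kg and SF = 7.3 (mg/(kg·day))⁻¹), so its percentile
tables are not exactly reproducible; the defaults below are this package's
own choices, all overridable in config.

| parameter | adults | children | unit | rationale |
|---|---|---|---|---|
| IR | 0.02 | 0.0197 | kg/day | ≈ 7.3 kg/year per-capita fish intake; children's IR set so (IR/BW)_c/(IR/BW)_a ≈ 4.6, the near-constant children/adult dose ratio the survey's percentile table implies |
| EF | 365 | 365 | days/year | daily consumer, conservative |
| ED | 70 | 70 | years | lifetime exposure |
| BW | 70 | 15 | kg | standard adult / young-child reference weights |
| AT | 25,550 | 25,550 | days | 70 y × 365; lifetime averaging for carcinogens, so EF·ED/AT = 1 |
| SF | 7.3 | 7.3 | (mg/(kg·day))⁻¹ | oral slope factor for BaP |

In the default Monte Carlo configuration IR and BW are stochastic
(truncated normals: adults IR 0.02 ± 0.005 on [0.005, 0.05] kg/day,
BW 70 ± 10 on [45, 100] kg; children IR 0.0197 ± 0.005 on [0.004, 0.05],
BW 15 ± 3 on [8, 25]); EF, ED, AT and SF are fixed. Concentrations are
always stochastic, drawn per analyte from distributions moment-matched to
the pooled summary rows. Each stochastic input draws from its own RNG
substream derived from the master seed by stable (BLAKE2) hashing of its
label, so toggling one input's stochasticity, or adding a generator cell,
never perturbs any other stream.

## Synthetic-data generator

Each summary row (mean m, SD s, min, max) is fitted by method of moments.
The default family is a normal truncated to [min, max]: summary rows show
mean ≈ median (little skew) and hard ranges, and truncation guarantees
non-negative concentrations. Because truncation biases plug-in moments,
the underlying (µ, σ) are adjusted numerically (bounded least squares on
the truncated mean and SD, ≤ 100 evaluations at 10⁻⁶ relative tolerance,
then a 1-D root refinement of µ with geometrically expanded brackets) so
the truncated mean matches m to ~10⁻⁹. A zero SD degenerates to a point
mass; lognormal (log-moment transform, then truncated), uniform
([min, max]) and triangular (mode = 3m − min − max, clipped) are also
available.

**SD feasibility.** A truncated normal on [a, b] is log-concave, so its SD
cannot exceed roughly the uniform bound (b−a)/√12. Several *pooled*
summary rows print an SD above that bound (e.g. naphthalene 2.11 vs a
1.89 ceiling) because they are mixtures over species × cooking groups.
For such rows the fit saturates σ near the flat limit: the mean is still
matched exactly, the SD is the closest the family allows. Per-group rows
are generally feasible. This is the main respect in which the generator
under-disperses relative to the real pooled data.

**What the generator does not emulate.** Cells are sampled independently:
the true between-analyte covariance within a fish (strong, since cooking
raises many analytes together) is unknowable from the published summaries
and is not imputed. Passing tests therefore validate the computational
chain and the marginal calibration, not joint-distribution behaviour of
real samples. Analytical error (recovery, LOD censoring) is likewise not
modelled; published minima are taken at face value.

## Fixtures and known source inconsistencies

The packaged fixtures transcribe the published tables verbatim, including
their internal rounding slack: the pooled PAH4 mean prints 4.85 while its
four component means sum to 4.84, and the cooking-group ΣPAH rows are off
by ≤ 0.01 from the sum of their analyte means. Consistency checks
therefore use a ±0.02 absolute band (2-decimal rounding). Two narrative
figures in the source disagree with its own tables (a species total quoted
as 13.24 ± 1.84 where the table says 28.34, and a "highest/lowest" PAH4
sentence with the groups swapped); the fixtures follow the tables and the
discrepancy is recorded here rather than silently fixed. Per-cell sample
counts were never printed (sampling was described as triplicate), so
fixture `n` is left unset.

## Numerical choices

- Quantiles: linear interpolation of order statistics (`numpy.percentile`
  default) — stated so percentile tables are reproducible bit for bit.
- Rank-test exact/asymptotic switchover at combined n = 12; below it
  enumeration over C(n, nA) rank assignments is cheap and unambiguous.
  Contribution-ranking ties break by canonical analyte order.
- Truncated draws use inverse-CDF transforms of a `numpy` Generator's
  uniforms, so a seed fully determines every table and percentile.
- All-zero concentration profiles have an undefined contribution
  breakdown (flagged, not NaN-propagated); ranking such a profile raises.
- The WHO BaP screen (10 ng/kg bw/day) uses a strict inequality: a dose
  exactly at the guidance value fails.

## Problem sizes

The test suite runs the Monte Carlo engine at 10,000 iterations (the
stability point used for the headline percentile results) and the
generator recovery checks at 100,000 draws; both complete in seconds.

## Limitations

- The exposure defaults are package choices, not survey values; absolute
  EDI/ILCR percentiles depend on them linearly, and the survey's own
  printed ILCR figures (~10⁻⁸–10⁻⁹) cannot be reconstructed from any
  printed parameter set under any unit convention. The robust, and
  tested, conclusion is classification: 95th-percentile ILCR well below
  the 10⁻⁴ concern threshold under the defaults.
- Independent-cell sampling (above) understates tail risk if analytes
  co-vary positively within samples.
- No non-carcinogenic hazard quotient and no variance-based sensitivity
  analysis are implemented.
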