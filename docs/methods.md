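# Methods

## Scope and data model

The package analyses *integrated* GC-FID peak tables (retention time,
area) from high-temperature TG chromatography; peak detection and
integration from raw detector traces are upstream of it. Its in-memory
objects are: `FattyAcid` (acyl code, chain carbons, double bonds),
`Triacylglycerol` (three acyls in written order with derived CN/DB/ECN),
`PeakTable` (peaks plus the solvent-front and internal-standard retention
times), `RetentionModel` (the identification chart), and `OilProfile`
(TG name → mg per g oil, with a distinct Nd state for below-detection
entries).

Six acyls ship in the default registry — P 16:0, S 18:0, O 18:1, L 18:2,
Ln 18:3 and N 19:0 (the internal-standard acyl). The registry is
extensible from a delimited file so acyls found in other oils (gadoleic
20:1, erucic 22:1) can be registered; the defaults stay minimal because
the packaged reference tables use only these six. TG names are tokenized
greedy-longest-match ("OOLn" is O + O + Ln, never L + n). Equality for
co-elution purposes is by acyl *multiset*: the column cannot separate
sn-positional isomers (OOP vs OPO elute together), so they are one
analyte everywhere downstream.

## Retention model

Relative retention time `rrt = (rt − rt_solvent)/(rt_IS − rt_solvent)` is
affine-invariant in the clock, which the property suite asserts. The
identification chart lives in (DB, log₁₀ rrt) space:

- each monoacid standard anchors the point (3·db_acyl, log rrt);
- a TG of acyls A and B (counts n_A + n_B = 3) has DB = n_A·db_A + n_B·db_B,
  which places it on the A–B segment at parameter t = n_B/3. Interpolating
  the segment at the TG's DB is therefore *identical* to mole-fraction
  weighting of the two anchor log-rrts; the implementation uses the weighted
  form because it extends to the degenerate segment between two saturated
  anchors (PPP–SSS has no DB extent, yet PPS is still predicted, at 0.764 vs
  0.77 measured);
- a TG with three distinct acyls is predicted as the arithmetic mean of the
  pairwise-line values at the TG's DB, skipping degenerate (equal-DB) pairs;
  if every pair is degenerate the mole-fraction mean is used. These
  predictions are intrinsically less constrained ("between the lines"), so
  their matching tolerance is widened ×1.5.

Linolenoyl has no monoacid standard. The fit therefore back-infers a
*virtual* Ln anchor by solving the O–Ln line equation through the mixed
standard OOLn: log rrt(LnLnLn) = log rrt(OOO) + 3·(log rrt(OOLn) −
log rrt(OOO)), giving rrt 1.023 at DB 9. Virtual anchors are flagged as
such on the model and in its dump file. Without this inference the
Ln-containing oil TGs (OOLn, POLn) would be unpredictable and the
profile-based simulation impossible; with it, every profile TG is covered.

Prediction quality against the measured standards: all 12 mixed-acid
standards are predicted within 0.02 rrt (worst 0.014, OPO); the
acceptance-grade trio OOL/LLO/OOS is within 0.007.

### Matching and the printed-grid problem

The default matching half-width is 0.01 rrt — the rounding grid of the
reference table, which prints rrt to two decimals. Matching is gated on
linear rrt distance and ranked by |Δ log rrt|; ties in the ranked list are
broken alphabetically, and ambiguous peaks always carry their full ranked
candidate set (a peak at 0.85 is reported as {OOP, PSO}, never silently
resolved). rrt is not strictly monotone in DB at fixed CN (SSO and SSS
both print 0.91); matching is tolerance-based, not order-based, precisely
so such ties are representable.

Printing to two decimals creates *false* exact collisions: OOP and PSO
both read 0.85 yet the instrument quantified them as separate peaks. When
measured reference positions are used for matching
(`resolve_reference_rrts`), TGs of different multisets sharing a printed
value are spread ±0.001 around it, ordered by the chart prediction —
below the grid, so each value still rounds back to its printed figure.
Positional isomers keep one common position. The generator and the
identifier consult the same resolved table, which is what makes the
zero-noise round trip exact in both oils.

## Quantitation

`RRF = (area_std/conc_std)/(area_IS/conc_IS)`, so a compound responding
more strongly than NNN per unit mass has RRF > 1 and its raw area is
divided by RRF. The orientation is fixed by the round-trip property
(generate → quantify is the identity at zero noise). Contents follow
`area/(RRF·area_IS) · m_IS/m_sample · 1000` with the default preparation
of 30 mg oil + 3 mg NNN in 10 mL solvent (so 1 mg/g ↔ 3 µg/mL in the
vial). Peaks whose implied vial concentration is under the TG's LOD are
reported Nd; Nd propagates as 0 in sums but is preserved in all outputs
and files (token `Nd`).

Composition percentages divide by the summed *quantified* TG mass, not by
1000 mg/g of oil — the blend-percentage arithmetic of the reference data
is only consistent with that denominator (82.4/Σcolumn = 9.24%). Rounding
is half-up at the printed precision (integers for oil-level claims, two
decimals for blend indicators). Calibration linearity is ordinary least
squares (scipy) with a configurable r² floor of 0.99, the lowest
coefficient considered acceptable for the method.

TGs quantified in the oils but lacking a pure standard (PPO, POL, POLn)
receive RRF 1.0 (the unity-response convention) and the median reference
LOD/LOQ. Generator and quantifier share these defaults, so simulation
round trips are unaffected by the convention chosen.

## Validation metrics

Recovery = 100·detected/spiked, flagged outside 70–130% as a report-level
warning (FID response to polyunsaturated TGs is genuinely poor; observed
recoveries span 21–148%). RSD uses the sample (n−1) standard deviation —
replicate counts are 3–6. Intraday precision is the mean of within-day
RSDs; interday precision is the RSD of day means. LOD follows the
blank-ratio rule lod = low_conc · blank/signal, with LOQ = 3·LOD by
definition; the blank-ratio rule is unusual and loosely specified in the
source methods, and is implemented literally as the ratio. Reference
LOD/LOQ pairs respect the triple rule within 2% rounding. Recovery and
RSD are scale-invariant, asserted by property tests.

## Adulteration detection and blend estimation

Mixing is mass-linear in mg/g (`f·a + (1−f)·b` over the union namespace,
Nd as 0, Nd only when Nd in both parents); density differences between
the oils are ignored because blends are prepared by mass. Indicator
floors default to each TG's LOQ converted through the preparation
dilution (LOQ µg/mL · 10 mL / 30 mg). A direction is flagged when any of
its indicators reaches floor. At a 1% admixture the indicators sit at
0.2–1.2 mg/g — above floor in both directions.

The admixed fraction is estimated two ways: per indicator as
query/pure-content, and jointly by least squares over all TGs, weighted
1/RSD² using the reference RSDs where reported (median-imputed
otherwise), closed-form and clipped to [0, 1]. Replicate preparations are
averaged (`mean_profile`) before the joint fit — the usual
replicate-injection practice; a single 5%-noise injection carries an f̂
standard deviation near 0.03, while the 200-replicate pooled estimate
recovers f ∈ {1, 2.5, 5, 10}% within 0.004 in both directions at the
default seed.

On the *measured* blend profiles the joint estimate overshoots the
declared fractions substantially. That is a property of the data, not the
estimator: several measured blend columns deviate strongly from linear
mixing of the measured pures (OOP rises from 47.4 to 71.5 mg/g at a
declared 1%; POLn deviates up to 180% relative), and some columns are
non-monotone in f (PSO 4.1 at 5% vs 3.9 at 10%). The per-indicator ratio
is robust to this (OOLn gives 0.104 for the declared 10% blend) and is
what `theoretical_vs_experimental` quantifies per TG.

## Synthetic data

The generator emulates the study conditions: pure-oil profiles from the
packaged reference table, blend fractions 1/2.5/5/10% in both directions,
triplicate preparation, 30 mg oil + 3 mg NNN in 10 mL, and reference rrt
and RRF tables. Its noise model is multiplicative lognormal on areas
(median-unbiased, keeps areas positive; default σ = 5%, the observed
intraday area-precision bound) and truncated-Gaussian relative jitter on
retention times (default 0 — retention stability in the emulated system
is below 0.5% RSD and jitter is exercised separately in the precision
tests). The absolute time axis (solvent 2.0 min, IS 27.0 min) is a free
constant; only rrt is physically meaningful. Below-LOD TGs are omitted
from the table and surface as Nd downstream; co-eluting positional
isomers within one rrt rounding unit merge into a single peak. All
randomness flows through one seeded `numpy` generator; the full blend
series is a pure function of the config.

What passing synthetic tests do **not** show about real data: the
generator draws independent per-peak noise (no drift, no correlated
response changes, no baseline or integration errors), places peaks
exactly at reference rrts (no matrix-dependent shifts), and contains no
TGs outside the reference namespace. The measured blends' deviations from
linear mixing (above) are exactly the kind of structure it does not
emulate — which is why estimator accuracy is validated on synthetic
blends and detector behaviour on the measured tables separately.

## Problem sizes and numerical choices

The validation experiments use 200 replicate injections per blend
condition (2 directions × 4 fractions), chosen so the pooled estimator's
Monte-Carlo error is well below the 0.01 acceptance band; the full suite
runs in a few seconds. Degenerate inputs raise typed errors
(`DegenerateReferenceError` when IS and solvent coincide,
`ModelUnderdeterminedError` below two usable distinct-DB anchors,
`UnpredictableTGError` for acyls without anchors, parse errors naming the
offending residue); unknown peaks are data, not errors, and are returned
labelled unknown.

## Known limitations

- No stereospecific (sn-position) resolution — a column property the
  package mirrors by multiset identity, not a solvable limitation.
- Retention prediction requires every acyl to be anchored (directly or
  virtually); acyls absent from the standards are out of reach.
- The measured validation figures (recoveries, LODs, precisions) are
  instrument-dependent and are covered by formula-level properties, not
  reproduced numerically.
- Discriminating adulterants other than the two profiled oils, and
  chemometric classifiers over oil databases, are out of scope.
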