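# Methods

## Scope and data model

The package analyses regional hospital capacity at the NUTS-2 level from
three inputs in the Eurostat bulk-download TSV dialect — bed stocks,
in-patient discharges by ICD-10 chapter, and in-patient average length of
stay (AvLOS) by chapter — plus a (geo, year, population) table. Records
are assembled per region-year; regions missing beds, populations or the
all-diagnoses totals are skipped and reported, never imputed. Chapter
entries are attached only where both the discharge count and the AvLOS are
present; the covered share of total discharges is carried as a coverage
fraction. Region inclusion rules (countries kept, codes or prefixes
excluded, e.g. the autonomous cities and overseas regions) are
configuration, not code, because NUTS revisions renumber regions; the
default filter targets the DE/ES/FR/IT four-country setting under
NUTS-2016 codes.

## Bed-management indicators

With B beds, D discharges, O occupied bed-days and period T (days):
BOR = O/(B·T), AvLOS = O/D, TOI = (B·T − O)/D, BTO = D/B. Two exact
identities follow: AvLOS + TOI = T/BTO and BOR = AvLOS·BTO/T; they are
enforced by property tests at 1e-9 relative tolerance and are the geometry
behind the Barber-Johnson diagram (constant-BOR rays through the origin
with slope BOR/(1−BOR); constant-BTO lines AvLOS + TOI = T/BTO).

Choices:

* **Occupied bed-days are derived**, not read: the regional tables publish
  discharges and AvLOS, not in-patient days, so O = Σⱼ dⱼ·AvLOSⱼ when a
  chapter breakdown fully covers the totals (the two modes agree exactly
  when the total AvLOS is the discharge-weighted chapter mean), otherwise
  O = D·AvLOS_total. The pipeline's `occupied_mode` makes this explicit
  (`auto` default, `specialties`/`totals` to force a mode).
* **T = 365 days** always; leap years are ignored (the period is "a
  year"; one day in 366 is far below every band width involved).
* **BOR is a fraction internally** and a percentage only in reports and
  the distance metric, avoiding unit mistakes.
* The algebraic inverse (AvLOS = TOI·BOR/(1−BOR), D = B·T·(1−BOR)/TOI) is
  exposed for the generator; the degenerate fully-occupied point
  (BOR = 1, TOI = 0) has infinitely many preimages and is resolved by the
  convention D = B, AvLOS = T.

## Barber-Johnson classification

Efficiency bands: 1 < TOI < 3 days and 0.75 < BOR < 0.85, with centroid
(TOI = 2, BOR = 0.80). Membership is strict: a value exactly on a band
edge counts as outside, so ties never occur in zone assignment. Green =
both inside, yellow = exactly one, red = neither; the three zones tile the
plane.

Centroid distance is Euclidean over (TOI in days, BOR in percentage
points) by default — the literal reading of the published colouring — with
a band-normalised mode (each deviation divided by its half-band width,
1 day and 5 points) offered because the axes carry different units and no
scaling is stated in the source material for this kind of analysis.

## Case-mix and performance indices

Against a benchmark pooled over all included regions (reference chapter
discharges are sums; reference chapter AvLOS are discharge-weighted
means):

    CMI = Σⱼ AvLOSⱼᴿᴱᶠ·(dⱼˢᵀᴿ/d_ALLˢᵀᴿ) / AvLOS_ALLᴿᴱᶠ
    PI  = Σⱼ AvLOSⱼˢᵀᴿ·(dⱼᴿᴱᶠ/d_ALLᴿᴱᶠ) / AvLOS_ALLᴿᴱᶠ

* **AvLOS_ALLᴿᴱᶠ is defined as the discharge-weighted mean of the chapter
  reference AvLOS.** This is the choice that makes neutrality exact: a
  structure whose mix equals the benchmark mix has CMI = 1, and one whose
  chapter AvLOS equal the benchmark's has PI = 1, both to float precision.
* **Missing chapters**: both indices are computed over the specialties
  present in structure and benchmark, with the respective share vectors
  renormalised on that shared set, and the coverage fraction reported.
  Treating absent chapters as zero-length stays would bias both indices
  downward silently.
* **Quadrants are strict** (CMI > 1 counts as high complexity, PI < 1 as
  on-target), so CMI = 1 or PI = 1 classifies as outside target: green
  (CMI > 1, PI < 1), yellow (CMI ≤ 1, PI < 1), orange (CMI > 1, PI ≥ 1),
  red (CMI ≤ 1, PI ≥ 1). PI/CMI is exposed as the map-colouring scale.

PI is linear in the structure AvLOS vector (scaling all stays by k scales
PI by k and leaves CMI unchanged), and CMI is strictly increasing under
share shifts toward longer-stay chapters; both facts are property-tested
and exploited by the generator.

## Combined clustering and summaries

The 3×4 cross of zone and quadrant gives 12 cells, exposed in full with
generated labels; any coarser grouping is a configuration-supplied mapping
from cell id to group label, since no canonical merge exists. Per-country
distributions report integer percentages rounded half away from zero (the
convention behind printed figures such as "76%, 16 out of 21"); counts
always partition each country's region total.

Dispersion operations work on per-100k rates computed *before* the
statistic: percent change 100·(new − old)/old with the same rounding rule
for reporting; coefficient of variation as sample (n−1) standard deviation
over mean — the estimator is unstated in comparable published tables, so
it is switchable to the population form (`ddof=0`); country spans with
lexicographic tie-breaks; and strict counting of regions whose per-capita
bed stock increased between the two years.

## Synthetic-data generator

The generator emulates the three extracts plus populations for several
countries and two reference years, with every region's zone and quadrant
known exactly. Defaults mirror the four-country study setting: region
counts 16/19/22/21 (DE/ES/FR/IT), zone mix (0.45, 0.25, 0.30) and
quadrant mix (0.33, 0.45, 0.08, 0.14) close to the observed
cross-country distribution, bed densities uniform over the reported
219–1285 per-100k span, populations uniform over 0.3–12 million, ten
specialty chapters, and no noise. The design benchmark spreads chapter
AvLOS linearly over 4–13 days with geometrically decaying discharge
shares (common conditions dominate admissions).

Construction, per region-year:

1. **Stratified labels.** Zone and quadrant counts follow their mixes by
   largest-remainder apportionment; quadrant budgets are spread over zone
   groups by controlled rounding so both marginals are exact, and the
   (zone, quadrant) pairs are then shuffled onto synthetic NUTS-like codes
   (country prefix + two digits).
2. **Profile.** The quadrant fixes the sides of the CMI/PI targets; the
   magnitudes are drawn uniformly in 1 ± [0.07, 0.15]. The profile hits
   PI exactly by uniform AvLOS scaling and CMI to 1e-6 by bisection on the
   exponential tilt wⱼ(θ) ∝ shareⱼ·exp(θ·AvLOSⱼᴿᴱᶠ) (CMI(θ) is continuous
   and strictly increasing; exponents are centred for conditioning;
   convergence within 60 steps).
3. **Placement.** The profile pins the region's total AvLOS
   a = CMI·PI·AvLOS_ALL of the design benchmark, and the identities tie
   TOI to BOR via TOI = a·(1−BOR)/BOR. Each zone therefore becomes a
   union of feasible BOR intervals; one is sampled length-weighted, with
   margins (0.003 in BOR, 0.02 days in TOI) keeping placements off the
   strict-inequality boundaries, plus realism caps (TOI ≤ 30 days,
   BOR ≤ 0.98). Discharges follow from the exact inverse given the
   sampled bed stock.
4. **Self-consistent ground truth.** The pipeline pools its benchmark
   from the panel itself, which rescales every region's achieved PI by a
   common factor and perturbs achieved CMI (a pooled reference forces the
   discharge-weighted mean of both indices to 1). Ground-truth CMI/PI are
   therefore the *achieved* values against the pooled benchmark; a
   deterministic repair loop regenerates any region whose achieved
   quadrant crossed a boundary with targets pushed further from 1 (factor
   1.5, capped at 0.28 and at the attainable CMI range), iterating until
   intended and achieved labels agree (at most 30 rounds; in practice 0–2).
   A corollary: a quadrant mix putting every region on one side of PI = 1
   or CMI = 1 is infeasible against a pooled benchmark and is rejected
   with an explanatory error.
5. **Noise (optional).** Multiplicative lognormal noise (σ = `noise_sd`)
   on chapter discharges and AvLOS, applied after labelling with labels
   re-derived; totals are recomputed as exact aggregates and stays are
   scaled back if perturbed occupancy would exceed 98% of capacity.
   Recovery of the *intended* labels degrades monotonically with noise;
   recovery of the re-derived labels stays exact.

Exported fixtures use round-trip-exact float formatting (shortest-repr),
and CSV readers parse with round-trip precision, so re-ingestion
reproduces the panel bit for bit and noise-free label recovery through the
full pipeline is exactly 100%, not approximately.

What the generator does **not** emulate: real covariance between bed
stocks, admission rates and case mix beyond the accounting identities;
secular trends between the two years (years are generated independently);
regional spatial correlation; and reporting artefacts other than
missing-cell injection. Passing recovery tests therefore demonstrates
correctness of the algebra and plumbing, not robustness to the
idiosyncrasies of real extracts.

## Problem sizes and tolerances

Identity and inverse suites run 1,000 random draws each at 1e-9 relative
tolerance; the index-oracle suite 500 random instances of up to six
specialties; profile targeting 200 random targets at 1e-6 (CMI) and float
precision (PI); the recovery check uses 100 noise-free regions stratified
uniformly over all 12 grid cells, exported and re-ingested. These sizes
make the whole verification run in seconds while exercising every branch;
all random suites are seeded.

## Known limitations

* The case-mix index is AvLOS-based by construction; it proxies complexity
  through stay lengths, not through DRG cost weights.
* Occupied bed-days derived from discharges × AvLOS inherit any rounding
  in published AvLOS values.
* The external four-country reproduction depends on the Eurostat extract
  vintage; revised 2012/2017 values shift counts, which is why comparisons
  against reference classifications are reported per region
  (`match_report`) rather than asserted.
* No ICU-specific bed accounting and no live download client; inputs are
  files supplied by the user or the generator.
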