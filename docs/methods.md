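# Methods

## Setting

Spontaneous-report pharmacovigilance databases (FAERS being the largest)
hold voluntary case reports: one patient, one or more drug exposures with
role codes (PS primary suspect, SS secondary suspect, C concomitant, I
interacting), one or more adverse-event preferred terms (PTs), optional
demographics, and outcome codes (HO hospitalization, DE death, LT
life-threatening, DS disability, OT other). There is no treated-population
denominator, so incidence cannot be estimated; instead, *disproportionality
analysis* asks whether a drug–event pair is reported out of proportion to
the database background. This package implements that workflow for the
infection profile of the CDK4/6 inhibitors, with a synthetic report
generator standing in for a live database download.

## The reporting odds ratio

For drug D and preferred term P over a deduplicated report universe, the
2×2 table counts a (D and P), b (D, other PTs), c (P, other drugs), d
(neither). The reporting odds ratio and its Woolf (log-normal) interval
are

    ROR = (a/c)/(b/d) = ad/bc
    95% CI = exp( ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96

A pair is a *signal* when a ≥ 3 and the CI lower bound is strictly
greater than 1. Both thresholds are configurable (`min_a`, `ci_floor`);
the strict inequality at the floor is deliberate — a lower bound of
exactly 1.0 does not signal. `z` defaults to the conventional display
value 1.96 rather than Φ⁻¹(0.975) ≈ 1.95996; tests that cross-check
against statsmodels pass the exact quantile through.

**Zero cells.** Any zero cell leaves the CI (and for b=0 or c=0 the ROR
itself) undefined. No Haldane–Anscombe 0.5 correction is applied: the
result is flagged `ci_defined=False` and never signals. The a ≥ 3 gate
already removes the sparse tables a correction would mostly affect.

**Counting conventions.** What the universe a+b+c+d is made of is not
standardized across tools, so both conventions are implemented:

- `report_pt_pairs` (default): the universe is the set of distinct
  (report, PT) incidence pairs; a report with k distinct PTs contributes
  k rows, and a+b is the drug's total adverse-event count, as
  OpenVigil-style extracts print it.
- `reports`: the universe is the set of distinct reports.

Under either convention a report contributes at most 1 to a: PT
multiplicity within a report is collapsed. RORs differ slightly between
conventions (pair counting inflates b and c for polypharmacy/multi-event
reports); the default is pair counting, and the choice is a config field.

## The five-step pipeline

Per target drug, over a receipt-quarter window (default 2015Q1–2022Q3):
(1) extract every PT reported with the drug; (2) map PTs to system organ
classes; (3) keep PTs in the infection-related SOCs — by default
"infections and infestations" and "respiratory, thoracic and mediastinal
disorders" — and ROR-screen them; (4) enrol the PTs that signal; (5)
retrieve the cases listing an enrolled PT and keep those where the drug
is primary suspect. Two decisions deserve emphasis:

- **Screening uses all role codes; the PS restriction applies only to
  case retrieval.** This ordering makes "all infection AEs" and
  "infection AEs as PS" genuinely different stage counts, and the stage
  counts nest: |PS cases| ≤ |infection cases| ≤ |total AEs|.
- **Case-level counting for enrolled cases.** A case listing several
  enrolled PTs counts once; descriptive tables are per case, not per PT.

The SOC filter cannot encode the clinical judgment of which respiratory
terms are infection-related (e.g. keeping "pneumonitis" while dropping
"cough" would require a per-term decision), so the config exposes a PT
allow/deny list applied on top of the SOC selection rather than a
hard-coded rule.

Quarter filtering uses the report's receipt quarter (the `YYYYQn` prefix
of the version key, derived from `fda_dt` in the FAERS dialect).

## Deduplication and parsing

FAERS publishes follow-up versions of a case; all counting here is
defined on one record per case identifier — the one with the greatest
version key (receipt quarter + version sequence, compared numerically),
ties broken by keeping the record appearing last in input order. The
operation is idempotent and parse results are order-invariant: reports
are canonically sorted, and drugs/reactions/outcomes are stored sorted
and de-duplicated within a report, so shuffled input rows produce an
equal `ReportSet`.

Drug matching is exact normalized-name equality (whitespace-collapsed,
case-folded) against a configurable synonym list (generic + brand names).
Substring matching is deliberately rejected — "palbociclib tablet" does
not match "palbociclib" — because free-text matching belongs in a curation
step, not in the counting engine. Ages in the FAERS dialect are converted
to years (DY/365.25, MON/12, DEC×10); missing sex/age/country are kept as
explicit unknown categories.

## Severity and descriptive analyses

A case is *serious* if it carries any of HO/DE/LT/DS, *non-serious* if
its outcomes are non-empty but only OT, *unknown* if it has no outcome
code; the three labels partition every case set. The outcome table
assigns each case to exactly one category by precedence
DE > LT > DS > HO > OT (configurable), so outcome columns sum to case
totals and the serious aggregate equals the union of the four serious
categories. Age bands are <40, 40–64 (inclusive), ≥65, with median, IQR
and min–max range reported separately over non-missing ages.

Severity comparisons use the classic Pearson chi-square (Σ(O−E)²/E, no
continuity correction, df = (r−1)(c−1)), computed via
`scipy.stats.chi2_contingency(correction=False)`, with the unknown
category dropped from both the sex and age tables before testing; a zero
expected cell raises a degenerate-table error rather than returning a
meaningless statistic. The yearly trend reports, per receipt year, the
enrolled infection-case count as a proportion (4 decimals) of all
primary-suspect reports for the target drugs, with a missing (not zero)
proportion for a year with no reports.

Reference marginal counts for the three drugs' primary-suspect infection
cases (totals 892/337/52) ship in `faers_signal.reference`; the per-case
records rebuilt from them are synthetic reconstructions — marginals
exact, joint structure arbitrary — used only to verify count/percentage
arithmetic. One caveat those counts carry: the ribociclib serious
proportion printed in some summaries (66.77%, 225/337) is inconsistent
with the outcome table it accompanies, whose serious rows sum to 228
(67.66%); this package reports the value derived from the outcome table.

## The synthetic generator

`faers_signal.simulate` draws, per report: a drug subset (independent
Bernoulli per drug on its marginal probability, rejection-sampled until
non-empty), a role code per drug, then each PT as an independent
Bernoulli on its background probability multiplied by the largest
relative reporting rate among matching planted enrichments (capped at 1),
rejection-sampled until at least one PT is present. Sex, age band (age
uniform integer within band), country, receipt year/quarter and a single
outcome code are drawn independently. A configurable fraction of cases
(default 5%) emits a follow-up version one quarter later (sequence 2),
exercising deduplication; a Q4 original rolls into Q1 of the next year,
and the ground truth records the surviving version's year.

The stock universe (`default_config`) has the three CDK4/6 inhibitors at
marginal reporting probabilities 0.05/0.02/0.01 among five comparator
drugs, twenty PTs spanning the two infection SOCs plus common
non-infectious events (background probabilities 0.001–0.10), and five
planted enrichments of relative rate 4–12 — chosen so the planted pairs
have analytic expected case counts of roughly 11–74 per 5,000 reports,
i.e. signals a screening method *should* find alongside pairs near the
detection floor. Identical (config, seed) reproduces identical bytes.

`expected_cell_probabilities` provides the analytic oracle: exact
enumeration over drug subsets with the rejection steps conditioned in
(`P(PT_j | accepted, S) = q_j / (1 − Π(1−q_k))`), giving report-level
cell probabilities against which empirical RORs are checked within
Monte-Carlo error.

What the generator deliberately does not emulate: PT–PT correlation
(real reports cluster related terms), drug-name free text and
misspellings, country-specific reporting cultures, secular trends in
reporting volume, and duplicate reports that *differ* between versions.
Passing tests therefore demonstrate correctness of counting, screening
and summarization under a clean reporting model — not robustness to real
FAERS data-quality problems.

## Evaluation and problem sizes

`faers_signal.evaluation.screening_operating_characteristics` replicates
generate → deduplicate → screen and tallies planted-pair recovery and the
unplanted flag rate. The shipped evaluation uses 100 replicates of 5,000
reports (≈ 20 s): large enough that every planted pair with expected
a ≥ 10 is recovered in ≥ 95% of replicates while unplanted pairs are
flagged at ≈ 1% (the nominal one-sided 2.5% further reduced by the a ≥ 3
gate); small enough to rerun routinely. Statistical tests fix their seeds;
property-based tests run derandomized.

## Known limitations

- The ROR is a screening statistic: it flags reporting disproportion, not
  causation, and no multiplicity adjustment is applied across PTs (none
  is standard in this screening setting).
- Exact-name drug matching will under-count if synonym lists are
  incomplete; synonym curation is the user's responsibility.
- The PT→SOC map is user-supplied (MedDRA is licensed); a PT missing from
  the map is excluded from candidacy with a warning rather than guessed.
- Report-level age/sex/outcome fields are taken at face value; no
  cross-field plausibility checks beyond basic validation are applied.
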