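# Methods

## Pair-level classification

The evaluation table is stored as a literal 5×5 grid (`kanokit.core`),
rows indexed by the functional answer and columns by the dysfunctional
answer, both coded 1 = like … 5 = dislike.  The category multiset over
the 25 cells is {Q:2, A:3, O:1, R:7, I:9, M:3}.  The coding direction is
fixed; files coded the other way must be remapped in the codebook, the
core never guesses.  `classify_pair` and `evaluation_table` share the
grid constant, so the lookup has a single source of truth and the tests
enumerate all 25 cells.

## Modal attribute and ties

An item's attribute is the most frequent category among its respondents.
Reverse and questionable answers stay in the frequency row (rows still
sum to the number of valid respondents); they are dropped only from the
coefficient denominator.  Ties are broken by the fixed precedence
M > O > A > I > R > Q — the conservative convention that the category
with the larger dissatisfaction impact dominates — and the result
carries `is_tie` plus the tied set so a near-tie is never silent.  The
bundled example has clear modes on all 26 items, so the tie rule does
not affect its results.

## Coefficients, origin, quadrants

SI = (A+O)/(A+O+M+I) and DSI = −(O+M)/(A+O+M+I) are computed at full
precision.  Display rounding is half-away-from-zero at 2 decimals,
matching how such tables are conventionally printed (banker's rounding
would print 0.615 as 0.62 either way here, but the convention is made
explicit in `round_display`).

The matrix places each item at (|DSI|, SI).  The origin is the per-axis
mean over items, computed from full-precision values by default;
`compute_origin(..., from_rounded=True)` instead averages the 2-dp
display values for replicating published tables.  On the bundled survey
both paths give identical memberships.  Quadrant assignment uses ≥ on
both axes, so boundary items go to the higher-importance /
higher-satisfaction side; on the bundled survey two items sit essentially
on the published boundary and this convention places both as published.

Known quirk of the bundled survey's source report: it prints the two
origin means with their labels swapped (mean SI as 0.43 and mean |DSI|
as 0.49, where recomputation from its own table gives mean SI ≈ 0.489
and mean |DSI| ≈ 0.429).  Only the recomputed assignment reproduces the
published quadrant memberships, so this package reports the recomputed
values and does not silently relabel anything.

## Screening and planning

Screening removes logic-flagged questionnaires first, then applies the
minimum-completion-time filter (default 180 s, configurable) to the
remainder, so the two exclusion tallies are disjoint and
kept + excluded = received always holds.  What constitutes a "logical
error" is survey-specific; the caller supplies the boolean flag or their
own detector.  A second quirk of the bundled survey's source report: its
printed tallies (1,723 received, 68 + 83 excluded, 1,571 valid, 91.18%)
are off by one questionnaire — 1723 − 68 − 83 = 1572, while 91.18%
corresponds to 1571/1723.  The conservation invariant is kept; feeding
the printed tallies therefore yields 1,572 valid, and the discrepancy is
surfaced rather than absorbed.

Sample-size planning follows the Kendall rule: n between 5k and 10k for
k variables, multiplied by a non-response inflation factor (default 1.2,
i.e. 20% anticipated non-response) and ceiled to whole respondents.

## Reliability

Cronbach's α uses the closed form k/(k−1)·(1 − Σ item variances /
variance of row totals) with sample variances (n−1), on complete-case
matrices only.  Cohen's κ is unweighted, with chance agreement from the
product of the coders' marginals; κ ≥ 0.80 is flagged as substantial
agreement.  Both are validated in the tests against independent
implementations (pingouin, scikit-learn) and against hand-computed
fixtures.  α is computed on raw codes as given — no reverse-coding is
applied, since scale direction is a property of the instrument, not of
the statistic.

## Synthetic respondents

The generator draws each respondent's answer pair for each item i.i.d.
from that item's distribution over the 25 cells, so the expected
frequency row, modal category, SI and DSI are known exactly.  Two
shorthands: a target category with purity p (mass p uniform over the
category's cells, 1−p uniform elsewhere — the maximum-entropy default),
and `profile_from_frequencies`, which turns an observed frequency row
into the profile matching its category shares.  Completion times are
lognormal with default median 420 s and log-sd 0.5 (≈4–5% of
respondents under the 180 s threshold, comparable to real screening
rates); logic errors are Bernoulli with default rate 0.04, matching the
bundled survey's ≈4% flag rate.  Everything is reproducible from the
spec's seed via one `numpy` Generator.

What the generator does **not** emulate: within-respondent correlation
across items (no latent trait), demographic covariates, straight-lining
or other response styles, and item-order effects.  Tests passing on this
generator therefore demonstrate correctness of the counting and index
arithmetic under independence, not robustness to real response
behaviour.

## Problem sizes in the tests

Convergence checks use n = 50,000–100,000 respondents (sampling error
< 0.01–0.02 at 99% confidence for cell proportions), the
classification-recovery check 500 replicate surveys of n = 200 at
purity 0.6, and the α-on-noise check a 10,000 × 3 matrix.  These sizes
make the stochastic assertions comfortably stable under their fixed
seeds while the whole suite runs in well under a minute.

## Limitations

Only the standard 5-level evaluation-table dialect is implemented (no
3-level or continuous "analytical Kano" variants); category assignment
carries no significance test (e.g. Fong's test); reliability stops at α
and unweighted κ (no ω, ICC or factor analysis).  Pre-aggregated input
necessarily skips screening and reliability, which need respondent-level
data.
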