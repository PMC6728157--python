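# Methods

## Protocol semantics

A beacon serves one or more *dataset indexes*, each an exact-match map from a
canonical allele key to an observation record. Canonicalization is a
reference-free trim: shared trailing bases are removed first, then shared
leading bases (advancing the start coordinate), always leaving at least one
base on each side; base strings are uppercased and must match `[ACGT]+`.
Symbolic alleles (`<DEL>`, breakends, `N`) are rejected at query time and
skipped with a warning at ingest — structural-variant discovery is out of
scope. Left-alignment against a FASTA reference is deliberately not attempted:
the protocol promises exact-match semantics on the coordinates the producer
wrote, and a reference dependency would buy little for SNVs and small indels
while complicating deployment. Public coordinates are 0-based; the single
1-based→0-based conversion happens at VCF ingest and at query normalization.
Contig names are stored without a leading `chr` so GRCh-style and UCSC-style
VCFs interoperate.

Counts come from INFO `AC`/`AN` when the producer asserted them, otherwise
from GT columns (`.` treated as missing, phased and unphased separators
equivalent); carrier counts (`sample_count`) are only derivable from
genotypes and are taken from them whenever sample columns exist. Duplicate
normalized keys within one VCF are merged by summing counts, which preserves
total allele count and keeps frequencies well-defined under the "independent
observation batches" reading of a duplicated line.

The beacon-level answer is the OR over the datasets that passed both gates
(below). A dataset refused by a gate is reported as *denied* with no
existence bit at all — reporting a false "no" would corrupt any downstream
aggregation — and a query refused outright (exhausted budget, unknown token)
carries a typed error instead of an answer.

## Access tiers, consent, budgets

Tiers are totally ordered OPEN < REGISTERED < CONTROLLED. The disclosure map
is a policy default, configurable per beacon: OPEN sees only the existence
bit; REGISTERED additionally allele counts and frequencies; CONTROLLED
additionally carrier counts and the flat INFO metadata. The only structural
requirement is monotonicity (each tier's field set contains the lower tier's),
which the test suite asserts over randomized responses. Tokens are an
intentionally simple registry of opaque strings to tiers — institutional
OAuth2/OpenID-Connect flows are replaced by this stub, and a credential's own
tier claim caps what the registry can grant, so resolution never escalates.

Consent gating evaluates a total decision table: NRES and GRU allow every
research purpose; HMB allows health/medical/biomedical and disease-specific
research; DS(term) allows only disease-specific research with an exact string
match on the term (no ontology expansion — an extension point, not a
dependency this package should carry); POA allows only population-origins
research. Secondary consent modifiers are carried and displayed but not
enforced, since their semantics require policy context outside any software
artifact.

Information budgeting prices each *answered* query in bits of surprisal:
`-log2(max(f, floor))` for a "yes" at frequency `f`, with `floor = 1e-4`
(≈13.3 bits) so no single answer is priced as unbounded; a flat
`no_response_cost = 0.05` bits for a "no", because repeated "no"s also inform
a frequency-agnostic attacker (settable to 0); the floor price when a "yes"
has no frequency attached. Surprisal is the simplest monotone implementation
of the principle that rare alleles are more revealing than common ones.
Accounting is charge-then-lock: the query that crosses the threshold is still
answered, every later one is refused before any lookup — this avoids building
a "would this query be free?" oracle that would itself leak. The default
threshold is 30 bits, roughly the information needed to single out one person
among ~10^9. Budgets are keyed per credential; anonymous callers share one
OPEN pool key, since they cannot be told apart. Per-data-subject (rather than
per-caller) accounting and formal differential-privacy composition are out of
scope.

## Federation

A network registry fans each query out concurrently with a per-beacon timeout
(default 5 s); a timeout or transport failure is recorded as a failure marker
for that beacon only, never conflated with "no" — federation must distinguish
absence from unavailability. The caller's credential is forwarded unchanged
and every beacon applies its own policy locally. Aggregate beacons forward
live queries to their members and answer the OR; they keep no merged index
(member autonomy), expose no dataset detail, and short-circuit on the first
"yes" so not even the number of confirming members leaks.

## The attack simulator

The generator draws per-site alt-allele frequencies from Beta(a, b) restricted
to [f_min, 0.5] by inverse-CDF truncation (defaults a = b = 0.5,
f_min = 1e-3), then dosages as Binomial(2, f) per individual — independent
sites, no linkage disequilibrium, matching the independence assumptions of
both attack statistics. A beacon oracle over a member subset answers "yes"
wherever any member retains at least one alt copy after per-copy dropout δ
(default 1e-6), which models mismatch between the attacker's copy of the
target genome and the beacon's.

Each replicate draws a fresh membership, one member target and one non-member
target, and queries each target's alt-carried positions — rarest-first for the
frequency-aware likelihood-ratio attack (the attacker is assumed to know
population frequencies), uniformly shuffled for the frequency-agnostic
yes-count attack. Thresholds are empirical (1−α) quantiles of the non-member
statistics (`numpy` quantile, `method="higher"`), so the achieved
false-positive rate is ≤ α by construction even at small replicate counts
where asymptotic calibration would be unreliable; power counts member trials
*strictly* above the threshold, so heavy ties (e.g. both distributions sitting
at yes-fraction 1.0) read as zero power rather than spurious detection. The
likelihood computation runs in log space throughout; `(1−f)^{2N}` underflow
is benign by construction, and δ = 0 is rejected whenever a "no" response is
present because the membership likelihood of a "no" would be zero. Query-count
sweeps reuse one set of replicate draws: each target's full ordered response
sequence is computed once and the statistic at any count is read off its
prefix, making the doubling-then-bisection search for "smallest n reaching a
power goal" nearly free. Counts beyond a target's carried positions are
truncated with a warning, so every power curve plateaus at the target's
feasible cap.

Defense evaluation is paired: both arms share every random draw, the defended
arm prices each query from the beacon's own member-based allele frequency and
terminates the attacker's session at lockout, and the defended statistic uses
only the answered prefix (refusals contribute no evidence). An infinite
threshold reproduces the undefended arm bit-for-bit, which the tests assert.

## What the generator does and does not emulate

It reproduces the qualitative structure that matters for protocol-level
reasoning: membership evidence accumulates over queries, rarer alleles carry
more of it, and larger beacons dilute it. The suite demonstrates all three at
resolvable scales — power 1.0 at 10- and 100-member beacons collapsing to 0.0
at 1,000 members (5,000 yes-count queries, 100 replicates); rare-allele query
sets (f < 0.01) at power 1.0 against common-allele sets (f > 0.1) at 0.0; a
30-bit budget cutting a power-1.0 attack to ≤ 22 answered queries and power
0.0.

It does **not** emulate a realistic human site-frequency spectrum. The
truncated Beta(0.5, 0.5) spectrum with f_min = 1e-3 is far more
common-allele-heavy than resequencing data, where a large fraction of sites
are very rare: here even the rarest possible allele (f = 0.001) is present in
a 1,000-member beacon with probability 1 − 0.999^2000 ≈ 0.87, and a
non-member target sees a discriminating "no" only about once per 10^5
yes-count queries while carrying only ~16,000 queryable positions in total.
Against this spectrum the yes-count attack on a 1,000-member beacon therefore
never reaches high power at any feasible query count (the acceptance report
carries the feasible cap and the power there), whereas against a realistic
rare-variant-dominated spectrum the same attack succeeds within thousands of
queries at this beacon size. Passing the scaling tests says the machinery and
its monotonicities are right; absolute query budgets for real deployments must
be computed against real frequency spectra. Linkage disequilibrium, kinship
attacks, and genotype imputation are likewise out of scope, and all of them
make real attackers *stronger* — the simulator's absolute numbers are
optimistic for the defender.

## Problem sizes and reproducibility

Every stochastic experiment is driven by `numpy.random.SeedSequence` spawning
one child generator per replicate, so results are exactly reproducible from a
single integer seed and independent of replicate ordering. The suite runs its
Monte-Carlo checks at 100–200 replicates on populations of 500–5,000
individuals and 2,000–50,000 sites — sizes chosen so that the asserted
effects are resolvable several Monte-Carlo standard errors clear of their
thresholds; the headline sweep in `scripts/acceptance.py` uses the full
5,000 × 50,000 population with 200 replicates and completes in about a
minute. The null-calibration check compares attack power against its
false-positive target using the exact null standard error of the estimator —
the exceedance count over an empirically estimated order-statistic threshold
is beta-binomial, not binomial, which roughly one-and-a-half-folds the naive
standard error at 200 replicates.
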