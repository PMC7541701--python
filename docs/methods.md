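# Methods

## The measurement problem

A Morra player's sequence of shown hand-numbers is a random-generation
task executed under concurrent load (simultaneously calling sums, tracking
the opponent, keeping score, at roughly one response per second). The
package quantifies deviation from randomness in such sequences with five
indices, compares them across a 2 (expertise: expert/beginner, between
participants) × 2 (task: in-game Morra vs isolated RNGT, within
participants) design, and scores declarative memory of one's own response
frequencies with a rank distance. Because the recorded study data are not
publicly deposited, a synthetic-agent module generates sequences with the
statistical structure the analysis assumes; it is first-class, tested code.

## Randomness indices

All logarithms are base 2. For a sequence of length $n$ over an alphabet
of size $a$ (default $\{1..5\}$), with singlet counts $n_i$ and adjacent
ordered digram counts $n_{ij}$ (terms with count ≤ 1 contribute zero to
the $x\log_2 x$ sums):

- **Redundancy** $R = 100(1 - H/H_{\max})$,
  $H = \log_2 n - \frac1n\sum_i n_i \log_2 n_i$, $H_{\max} = \log_2 a$.
  $R$ depends on the log base only through $H_{\max}$; with base 2 and
  $a=5$, $H_{\max} = \log_2 5$. Values are clamped to $[0, 100]$ to absorb
  float dust at the exact bounds.
- **FPR** $= \sum_{ij} n_{ij}\log_2 n_{ij} / \sum_i n_i \log_2 n_i$
  (base-invariant). Undefined when no response repeats (zero denominator).
- **NSQ** $= 100 \cdot \mathrm{NS} / (a^2 - 1)$ where NS is the number of
  the $a^2$ possible digrams absent from the sequence. The denominator is
  $a^2-1$, the largest NS actually attainable (by a constant sequence,
  which realises exactly one digram); normalising by $a^2$ would make
  100% unattainable.
- **Coupon score**: the sequence is scanned left to right in
  non-overlapping segments; a segment ends exactly when all $a$
  alternatives have appeared since the segment start, and the scan
  restarts fresh. The score is the mean completed-segment length; an
  incomplete trailing segment is discarded. The hard restart is what makes
  the perfect-cycling sequence score exactly $a$.
- **Repetition-gap mean**: every occurrence of a value that has occurred
  before contributes the positional distance to its immediately previous
  occurrence (adjacent repeat = 1); the index averages over *all*
  recurrences, not only first repeats.

Indices whose preconditions fail raise `UndefinedIndexError`;
`randomness_profile` converts these to NaN plus an explicit flag, never a
silent 0 or bound value. All five indices are invariant under relabeling
of the alphabet (a property test checks this).

A note on the repetition gap: individual gaps can exceed $a$ (a gap of 9
is constructible over five symbols); $a$ is the ceiling attained by
perfect cycling and the value of the uncensored mean under uniform
responding, not a bound on single gaps. The package does not enforce any
per-gap cap.

## Game engine

A play (hand $h \in \{1..5\}$, call $c \in \{2..10\}$) is valid iff
$1 \le c - h \le 5$; the three beginner errors ($c-h>5$, $c=h$, $c<h$) get
distinct reason codes. A round is won by the side that alone called the
sum of hands; if both or neither called it, no one scores and play simply
continues (the traditional rules state no replay; "no score, continue" is
this package's choice, logged as a tie round). Matches run to a target
score (16 team, 10 singles). In team mode the scorer stays on and the
losing side substitutes its active player; a benched player re-enters with
agent state (the previous hand) intact. Agents that emit invalid plays are
by default rejected and resampled with a counter in the match record, so
a beginner-like agent cannot corrupt adjudication; `on_invalid="abort"`
raises instead. The 25×25 payoff matrix is generated by exhaustive
adjudication and is checked in tests against an independently transcribed
copy of the printed winning-combinations table.

## Standardization

Recorded sequences vary in length, so all sequences are standardized
before index computation: those with at least `standard_length` (default
57) responses are truncated to their first 57, shorter ones are excluded
with reason "below minimum length". The filter is applied per extracted
player sequence (that is what the index computation requires). Exclusions
are part of the output, and `|retained| + |excluded| = |input|` always
holds. Positions are 1-based in files; the length knob is configurable so
the length/sample-size tradeoff can be re-explored. At $n = 57$ and
$a = 5$ the pigeonhole principle guarantees the redundancy, FPR, NSQ and
repetition-gap indices are always defined; the coupon score can in
principle still be undefined if some alternative never appears.

## Rank distance

The declarative-memory score is the Spearman footrule between the
subjective ranking (believed most → least shown) and the actual frequency
ranking: for each response, the absolute difference between its positions
in the two rankings, summed. The per-rank vector lists displacements in
subjective-rank order. The maximum for five items is 12 (brute-forced for
small alphabets, $\lfloor a^2/2 \rfloor$ beyond); the total is always
even. Percent-of-maximum rounds half-up to an integer. Ties in observed
frequencies break by ascending face value and are flagged so tied cases
can be excluded downstream; ties cannot occur in printed integer rankings
but easily can in 57-response sequences.

## Synthetic agents

The generator is a first-order Markov chain over the alphabet. Response
probabilities are proportional to $w_j^{1+\lambda^*}$, where
$\lambda^* = \lambda_{\text{load}}$ under game load and 0 otherwise; for
every response after the first, the weight of the previous symbol is
additionally multiplied by $\mu^{1+\lambda^*}$. Load therefore enters as
one exponent sharpening both the favorite-number bias and the
perseveration. With uniform $w$, $\mu = 1$, $\lambda = 0$ the generator is
i.i.d. uniform — that configuration is checked against the
coupon-collector expectation $5 H_5 = 11.41\overline{6}$, the
geometric-recurrence gap law, and a chi-square uniformity test.

Default populations (calibration constants, not fitted values; whether
real beginners perseverate or avoid repetition cannot be identified from
cell means alone, and the defaults encode perseveration as the assumption):

| group    | w                         | mu  | lambda_load |
|----------|---------------------------|-----|-------------|
| expert   | (1, 1, 1, 1, 1)           | 0.9 | 0.1         |
| beginner | (1.5, 1.2, 1.0, 0.9, 0.7) | 1.8 | 1.0         |

The default study design is 9 participants per group, each contributing
one Morra sequence (under load, length 57) and one RNGT sequence (no
load, length 100, then standardized to its first 57 by the same
preprocessing step used for recorded data). Per-participant child seeds
are spawned deterministically from the master seed.

What the generator emulates: favorite-number bias, perseveration/
avoidance, load-dependent degradation, and the resulting ordering of cell
means (beginners worst under load on all five indices; near-coincident
groups in the isolated task). What it does not emulate: within-participant
learning or fatigue, opponent-dependent strategy, call/hand dependence,
higher-order sequential structure, or the heavy-tailed index distributions
of small real samples. Passing pattern-recovery tests therefore shows the
pipeline recovers the qualitative 2×2 signature from data with the assumed
structure — not that the assumed structure is the true generative process
of recorded games.

## Comparison report

Cell summaries are means and sample SDs (ddof = 1) per index. Effect
sizes use the overlap index OV: both samples get a Gaussian-kernel density
estimate with the classic Silverman bandwidth
$0.9\,\min(\mathrm{sd}, \mathrm{IQR}/1.34)\,m^{-1/5}$, evaluated on a
common 512-point grid spanning the pooled range ± 3 bandwidths; OV is the
trapezoidal integral of the pointwise minimum (clipped at 1). The kernel
and bandwidth rule are fixed conventions of this package. Zero-variance
samples fall back to discrete probability-mass overlap and are flagged.
Contrasts are two-sided permutation tests on the mean difference with
$p = (1 + \#\{|\Delta^*| \ge |\Delta|\})/(B+1)$ — valid and slightly
conservative under exchangeability. The four contrasts mirror the design:
between groups within each task, between tasks within each group. The
inferential layer of the original analysis (multivariate Bayesian
LMM/GLMM, WAIC weights, evidence ratios) is deliberately replaced by
these descriptive summaries, OV and permutation contrasts: the former is
an off-the-shelf-sampler exercise, while OV and the permutation machinery
are directly implementable and testable here. Published OV values were
computed on model-estimated distributions, so raw-value OVs are compared
only qualitatively. Correlations among indices are product-moment by
default (rank-based optional); constant columns yield flagged NaNs.

## Numerical choices and problem sizes

- Base-2 logarithms throughout; $x \log_2 x$ terms with $x \le 1$
  contribute zero.
- Redundancy clamped to $[0, 100]$; OV clipped at 1; permutation
  comparison uses a $10^{-12}$ slack on $|\Delta|$ to absorb float noise.
- Percent-of-maximum rank distance rounds half-up.
- Ranking ties break by ascending face value, flagged.
- Test and calibration sizes: oracle equivalence uses 1,000 random
  length-20 sequences; Monte-Carlo calibration uses 3,000 i.i.d.-uniform
  length-57 sequences, a 60,000-response sequence for the uncensored gap
  limit, and 1,000 null pairs for permutation uniformity; pattern recovery
  pools 200 replicate synthetic studies. These sizes put Monte-Carlo error
  well below the effects being checked while keeping the default suite
  fast.

## Known limitations

- **Window censoring of the repetition gap.** Under i.i.d. uniform
  responding, recurrence distances are geometric with mean $a = 5$, but in
  a finite window a gap can only be recorded if the previous occurrence
  lies inside the elapsed sequence. At $n = 57$ the exact expected
  recorded mean is 4.615 (closed form in the test suite), not 5.0; the
  recorded mean approaches 5.0 only as the window grows. Calibration
  tests therefore check the exact censored expectation at $n = 57$ and the
  5.0 limit at large $n$. The same caveat applies when comparing observed
  repetition-gap means against the "ideal" value 5.
- The coupon score discards the incomplete trailing segment, so very
  short or very repetitive sequences may have no defined value.
- OV on nine values per cell is a noisy effect size; the KDE conventions
  (kernel, bandwidth, grid) materially affect the third decimal.
- The synthetic-agent defaults are assumptions sufficient to produce the
  qualitative 2×2 signature, not estimates of human parameters.
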