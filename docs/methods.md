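# Methods

`invroute` reconstructs invasion pathways of a globally expanding insect
from a single maternally inherited barcode locus (the ~685 bp CO1
fragment). It implements the three analysis layers such a study needs:
descriptive haplotype accounting, a statistical-parsimony haplotype
network, and Approximate Bayesian Computation (ABC) scenario choice over
explicit coalescent models of introduction histories. This note documents
the models, the defaults, and the design decisions; nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Haplotype accounting

Sequences collapse to haplotypes by exact character identity after
uppercasing. `N` and `-` are never wildcard-matched: two sequences
differing only by an ambiguity code are distinct haplotypes. This is the
conservative convention of barcode-haplotype practice and keeps collapsing
deterministic. Labels are assigned `H1, H2, ...` in order of first
appearance; a user label map can pin sequences to an external numbering
(survey numberings are historical accidents — the packaged count table's
labels jump and back-fill — so the map, not the order, carries meaning).

The packaged global-survey count table stores specimen counts per locality
and haplotype. Published count tables of this kind are typeset in two
columns and commonly carry small internal inconsistencies; the packaged
counts were reconciled so that locality, country, and global totals agree
(916 specimens, 214 of them from the native range). Its haplotype
sequences are synthetic placeholders (pairwise distinct, fixed length);
only the counts are data.

## Statistical-parsimony (TCS) network

Pairwise mutational steps are Hamming distances with pairwise deletion of
ambiguous sites. The 95% connection limit is the largest step count `j`
whose probability of a homoplasy-free origin is at least 0.95. We compute
that probability from an explicit model: each site carries a Poisson number
of substitutions with Jukes–Cantor jumps, with the per-site mean `lambda`
calibrated so the expected number of differing sites over `m` equals `j`;
parsimony holds when no site took more than one substitution, giving

    P(parsimony | j, m) = [lambda e^-lambda / p_diff]^j
                          x [e^-lambda / (1 - p_diff)]^(m-j),
    p_diff = (3/4)(1 - e^(-4 lambda / 3)).

The limit is found by stepping `j` upward; a high-precision independent
evaluation (sympy arbitrary precision) serves as the test oracle. At 685 bp
the 95% limit is 8 steps, consistent with the ~9–13 commonly reported for
barcode-length fragments by TCS-style software.

Network assembly is the minimum-spanning-network rule: pairs are processed
in increasing step order up to the limit; within one step class every pair
whose endpoints were in different components *before* the class is
connected, so alternative equal-step connections are all retained and
reticulations survive rather than being broken by a frequency criterion
(the published TCS heuristic's loop resolution is ambiguous; this variant
is deterministic and equals the union of all minimum spanning trees, which
is what the exhaustive test oracle checks). A d-step connection inserts
d−1 zero-frequency intermediate nodes. Node attributes carry per-population
counts so a geographic pie-chart rendering can be layered on downstream.

## Scenario model

A scenario is a rooted backward-time demographic program: populations with
haploid effective sizes (numbers of transmitting females — the locus is
maternal), `merge` events (the child population's lineages move to a
parent: forward in time, a founding), and `admixture` events (each lineage
independently moves to parent A with probability r, else parent B). mtDNA
does not recombine, so migration is represented only by these discrete
events, matching how invasion hypotheses are posed (founding, bridgehead,
admixture), and there is no continuous gene flow.

Priors (defaults, all configurable per experiment):

| parameter | prior | units |
|---|---|---|
| effective sizes N | Uniform[10, 10000], integer | haploid individuals |
| event times t | Uniform[10, 10000] | generations |
| admixture rate r | Uniform[0.001, 0.999] | — |
| mean mutation rate | Uniform[1e-7, 1e-5] | per site per generation |
| locus mutation rate | Gamma(shape 2, mean = drawn mean) | same |
| mean kappa (C/T coefficient) | Uniform[1.5, 20] | — |
| locus kappa | Gamma(shape 2, mean = drawn mean) | — |

The size and time defaults are the standard defaults of the ABC software
family this pipeline mirrors; the admixture-rate prior is the package's own
choice (no established convention). The per-locus Gamma draws are
untruncated around the drawn mean — with a single locus the hierarchy is
near-cosmetic, and untruncated draws keep `E[locus rate] = E[mean rate]`
exactly, which the Monte-Carlo tests exploit. Introduced-population size
conditions (e.g. `N4 < min(N1, N2, N3)`) are enforced by rejection
sampling, as is strict ordering of event times in the listed (backward-
time) order; configs should list events oldest-last. Event-time constraints
from known detection years are *not* imposed — detection lags introduction
by an unknown amount, so the uniform time priors stand.

The shipped experiment library (`invroute/data/experiments/*.yaml`)
encodes the full set of published-style experiments: native-source
determination for the eastern US, Canada, the northwestern US, Europe
(minus Greece), and Greece; admixture variants for Canada and the
northwestern US; the seven California hypotheses plus the second-round
re-run after excluding scenarios below 0.10 posterior probability; the
Europe and Emilia-Romagna bridgehead tests; and the Greece/Hungary
introduction history. Rebuilding the published probabilities additionally
requires the underlying GenBank sequences, which users supply as
FASTA + population map; each experiment is then one CLI command.

## Coalescent and mutation engine

Genealogies follow the standard backward-time structured coalescent:
within a population of haploid size N, k lineages coalesce at rate
k(k−1)/(2N) (so E[T2] = N generations); at events, lineages move as
described above; simulation ends at the single root lineage. Times are in
generations; no calendar mapping is attempted.

Mutations are HKY with unequal base frequencies and transition coefficient
kappa, plus 10% invariant sites and continuous per-site Gamma(shape 2,
mean 1) rates on the variable sites (continuous rather than 4-category
discretization: simpler and exact for simulation). The generator is
normalized to one expected substitution per site per unit mutation
distance at stationarity. Substitutions are placed by uniformization:
candidate events form a Poisson process along each branch at the site's
rate times the generator's maximum exit rate, and each candidate jumps
according to its rate-matrix row or self-loops. This is an exact
continuous-time simulation — multiple hits arise naturally, the stationary
composition is exactly the configured frequencies, and the expected
substitution count per branch is rate x site-rate x branch length, which
is what the closed-form test oracles assert. The ancestral sequence is
drawn from the stationary frequencies; simulated data therefore start at
equilibrium composition. Base frequencies default to the empirical
composition of the observed alignment (floored at 1e-3 and renormalized so
a base missing from a small sample cannot zero the model), the common ABC
practice when the source publication is silent.

## Summary statistics

The rejection space uses the classic single-locus DNA panel: per
population — number of haplotypes, segregating sites, mean and variance of
pairwise differences, private segregating sites (polymorphic in the
population, monomorphic in the pooled remainder); per population pair —
mean between-population pairwise differences, pooled haplotype count, and
Hudson's FST (1 − mean-within / mean-between, within averaged over the two
populations). The exact panel used by the original analyses is not
recoverable, so the set is configurable with this default. Undefined
values (FST at zero between-population diversity, pairwise moments at
n = 1) are NaN and are imputed with the reference-table column mean before
standardization, keeping Euclidean distances well-defined. Note Hudson's
estimator is biased by −1/(n−1) on literally identical samples; the tests
account for that.

## ABC engine

The reference table simulates scenario -> parameters -> genealogy ->
alignment -> statistics per row, with scenarios drawn with equal weight;
the full-scale default is 10^6 rows (tests and the acceptance script scale
down to 10^3–5x10^4 rows, chosen so the whole suite re-runs comfortably on
one CPU). Statistics are standardized by reference-table mean/SD
(zero-variance columns are dropped with a warning); rejection keeps the
closest ceil(tolerance x n) rows (default tolerance 1%, the package's
choice — unstated in the analysis family's descriptions), ties broken by
row index.

Posteriors come either from retained-set proportions with binomial
normal-approximation CIs (direct) or from an unpenalized multinomial
logistic regression of scenario identity on (standardized statistics −
observed), evaluated at the observed point (logistic, the default). 95%
CIs use the delta method on the inverse observed information in the
reference-class parameterization; a bootstrap is deliberately not the
default (cost). If the unpenalized fit fails to converge (separation), a
ridge-penalized fit (C = 1) is used and flagged in the diagnostics.
Scenarios absent from the retained set get probability 0.

The prior/scenario pre-evaluation projects the observed vector into the
PCA space of the standardized reference table (inside-the-cloud check
against the empirical [0.5%, 99.5%] box per component) and reports
per-statistic tail probabilities with two-sided star flags at 5% / 1% /
0.1%.

Confidence in scenario choice is the posterior-based reclassification
rate: datasets re-simulated from the chosen scenario, with parameters
resampled from its retained (posterior) rows, are pushed through the same
rejection + regression classification, and confidence is the fraction
assigned back to the chosen scenario (default 500 datasets). Whether such
a "confidence" should instead be a prior-predictive error rate is a
genuine design fork; the reclassification definition is implemented
because it conditions on the data actually observed, and the simulation
count is configurable.

Every stochastic stage derives per-row streams by counter-based seed
splitting (`SeedSequence(seed, spawn_key=(row,))`), so reference tables
are bit-identical across reruns and worker counts, and a saved seed
regenerates any synthetic study byte-for-byte.

## Synthetic data

The synthetic-study generator emulates the study's shape: by default three
native and two introduced populations at 685 bp, introduced populations
founded from a native source through a strong bottleneck (introduced-size
priors bounded well below native sizes), occasionally by admixture. It
reproduces the qualitative signatures the real survey shows — one dominant
haplotype per introduced population, long rare-haplotype tails in natives,
reduced introduced diversity — and the count-table emulator reproduces the
same structure without sequences. What it does not emulate: real
geographic sampling heterogeneity, sequencing error and ambiguity codes,
within-population substructure, or selection; green tests on synthetic
data therefore validate the machinery and its statistics, not any claim
about the real organism's history.

## Numerical choices and degenerate inputs

- Distances and statistics use pairwise deletion of `N`/`-`; a pair with
  no shared unambiguous site contributes 0 differences.
- The parsimony-probability solver brackets `lambda` by doubling and uses
  Brent's method at 1e-14 tolerance; `j >= 0.75 m` (beyond saturation) has
  probability 0.
- Network tie-breaks are lexicographic on labels; intermediate nodes are
  named `A~B.k` after their endpoint pair.
- Rejection with a tolerance of 1 retains the whole table; a zero-variance
  statistic is excluded from the distance rather than producing NaN.
- A single retained scenario short-circuits the regression (probability 1
  with a note in diagnostics).
- Logistic CIs use a pseudo-inverse, so collinear retained statistics
  degrade gracefully.

## Known limitations

- Single-locus inference: posterior probabilities can be confident about
  wrong scenarios when the locus carries little variation; the PCA/tail
  pre-evaluation and the confidence measure are the guardrails, not cures.
- The TCS limit derivation is a principled reconstruction of the classic
  statistical-parsimony criterion, not a line-by-line transcription of any
  particular program's code; limits may differ by a step or two from other
  implementations.
- No ABC parameter estimation (posterior distributions of sizes/times) —
  scenario choice only.
- The engine is event-based and haploid; it is not a general demographic
  simulator (no continuous migration, growth curves, or recombination).
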