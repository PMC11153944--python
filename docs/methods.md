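# Methods

## Model

A segment's amplification history is modelled as a sequence of events over
{G, W}: G duplicates one fixed chromosome copy of the amplified lineage
("the same chromosome copy is gained sequentially"), W duplicates every copy
simultaneously and occurs at most once.  Mutations arise at a constant rate
*m* per chromosome copy per unit mutational time on [0, 1] (0 = tumour
initiation, 1 = sampling); each genomic site mutates at most once; each copy
is equally mutable; losses are not modelled.

A mutation that lands on a copy at time *t* is inherited by every copy
descended from that (copy, time) point, so its multiplicity at sampling
equals the number of surviving descendants of that lineage point.  For an
order with events at times t₁ < … < t_K the expected count in multiplicity
class *k* is a linear expression m·(c₀ + Σᵢ cᵢ tᵢ).

### Duration ledgers by forward simulation

Rather than transcribing per-state equations, the ledger for each
(order, minor) combination is generated: the copy forest is simulated
forward through the event sequence, and every copy-lineage interval between
consecutive events contributes its duration to the class equal to the number
of final copies descended from that lineage at that time.  This reproduces
the classical single-gain identities (n₁ = m(3 − 2t₁), n₂ = mt₁) and the
W-only closed form t₁ = 2n₂/(n₁ + 2n₂) exactly, and yields a square
(K+1)×(K+1) system — one class per unknown (m, t₁…t_K) — for every supported
state, verified exhaustively for majors 2–10.

The minor allele is handled outside the forest:

- minor = 2 (requires WGD): its pre-WGD copy contributes the interval up to
  the WGD at class 2, both copies contribute at class 1 afterwards.
- minor = 1 in a WGD sample: one surviving copy contributes duration 1 at
  class 1.  The implied loss is assumed to have removed the WGD duplicate's
  mutations symmetrically; this is the minimal assumption consistent with
  not modelling losses, and is the package's choice where the convention is
  genuinely open.
- minor = 0 contributes nothing.

A minor copy number of 2 without WGD leaves the allelic origin of mutations
ambiguous (no unique solution) and is rejected as untimeable, as are
histories that gain *different* chromosome copies — which is why candidate
orders are exactly G^a W G^b with 2(1+a)+b = major (WGD samples) or
G^(major−1) (non-WGD).

### Order inference and timing solve

Candidate orders are enumerated fewest-events-first.  An order is consistent
with an observed spectrum when every multiplicity class with a nonzero count
is among the classes the order predicts; the first consistent candidate (the
most parsimonious) is selected.  If none is consistent, the best-overlap
candidate is used and the result is flagged `INCONSISTENT_SPECTRUM`.

The timing system is linearised with uᵢ = m·tᵢ and solved exactly with one
dense linear solve; tᵢ = uᵢ/m.  Observed classes missing from the spectrum
enter as zero counts (keeping the system square); estimates are **not**
clamped to [0, 1] and events are not reordered — a time above 1 indicates an
event late in the tumour's history with few or no multiplicity-1 mutations,
and is surfaced via `TIME_EXCEEDS_ONE` rather than hidden.  A solved rate
m̂ ≤ 0 (possible only for degenerate spectra with no mass on the ledger's
classes) is an error, not a silent fix.

### Two-stage clock-like mode

Restricting timing to clock-like mutations (signature labels SBS1/SBS5, or
C>T at CpG dinucleotides; strand-symmetric, so G>A with a 5′ C counts) would
discard order information carried by non-clock-like mutations, so the
pipeline always infers the order from *all* mutations in the segment and
then times using only the filtered subset.  CpG detection uses the annotated
3-mer context or an indexed reference FASTA.

### Multiplicity assignment

Multiplicity is assigned per mutation by binomial maximum likelihood over
candidates k = 1…major, with expected VAF k·ρ/(ρ·C + 2(1−ρ)) at purity ρ and
tumour total copy number C (normal cells diploid; sex chromosomes are not
special-cased).  When the top copy number state is subclonal, candidates
become fraction-weighted expectations Σ_s f_s·min(k, major_s) — generally
non-integer — and the winning candidate is rounded up (ceiling), so the
final, partially clonal gain remains timeable.  Precomputed multiplicities
in the input override internal assignment.  Duplicate records at one
position are rejected (each site mutates once).

### Bootstrap confidence intervals

B = 500 resamples (default) of the n timed mutations with replacement;
the order is fixed, only times are re-solved; per-event mean and 2.5/97.5
percentiles are reported.  Resampling multiplicities with replacement is
exactly a multinomial draw over the observed spectrum, which is how it is
implemented (one batched solve for all resamples).  The upper bound is not
truncated at 1, so times above 1 stay inside their intervals.  Read-depth
uncertainty in the multiplicity estimates is not propagated.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `mutation_mode` | `all` | timing subset: `all`, `sbs` (SBS1/SBS5), `ct_cpg` |
| `bootstraps` | 500 | bootstrap resamples per segment |
| `few_mutations_threshold` | 10 | below this many timed mutations, flag `FEW_MUTATIONS` |
| minimum mutations | 3 | below this, the segment is refused outright |
| supported majors | 2–10 | longest history: 9 events |

## Simulation framework

The simulator is the package's validation engine.  A scenario fixes an
order, minor copy number, strictly increasing true times, a mutation count
and a clock-like fraction.  Clock-like mutations are distributed over
multiplicity classes in proportion to the duration-ledger expressions at the
true times; non-clock-like mutations are placed uniformly at random over the
expected classes and therefore carry order information but no timing
information.  Records are labelled with signatures (SBS5 / SBS3) and CpG /
non-CpG contexts so both clock-like filters act on simulated data exactly as
on annotated real data; optionally alt/depth read counts are drawn
binomially at the expected VAF.

Two allocation modes exist for the clock-like counts:

- `multinomial` (default): each mutation falls in a class independently —
  realistic sampling noise.  Used for the error-rate grids (how error falls
  with mutation number and rises with non-clock-like fraction) and for
  bootstrap-coverage checks, which need genuine sampling variability.
- `expected`: largest-remainder rounding of the expected counts — removes
  sampling noise.  Used by the mismatched-equation study, which asks a
  *systematic* question: how much does applying another candidate order's
  equations distort the times?  With sampling noise included, the rank
  correlations of late time points reflect noise rather than equation
  structure.

Time points are drawn i.i.d. uniform on (0, 1) and sorted (the draw
distribution is the package's choice).  The error metric is the mean
absolute deviation on the mutational-time scale, ×100 (a percentage of the
full timescale).

### What the simulations do and do not show

Simulated spectra satisfy the model exactly: constant rate, correct
multiplicities, no losses, no subclonal structure beyond the labelled
states.  Passing the recovery and coverage suites therefore demonstrates
internal consistency of the ledger/solver/bootstrap chain, not robustness to
multiplicity mis-assignment, rate variation over time, or unmodelled losses
— all of which affect real data and are discussed only qualitatively (the
flags exist to surface their footprints).  Read-count simulation exercises
the binomial assignment path but assumes the same binomial model used for
inference.

## Numerical and scale choices

- Linear systems are solved with LAPACK via `numpy.linalg.solve`; the
  ledgers are small integer matrices and exactly reproduce hand-derived
  closed forms to 1e−12 in tests.
- The recovery suite uses 1e5 mutations per order as one seeded pass over
  the canonical state series (major+1 without WGD, major+2 with WGD): at
  this size, per-event sampling error of 8–9-event orders is ~0.005–0.02,
  so the 0.02 check is run as a fixed-seed suite rather than a worst case
  over repetitions.
- Error-trend grids use 100 replicates per cell at n ∈ {10, 100, 1000} and
  clock fractions {1, 0.5, 0}; the mismatched-equation study uses 100
  mutations × 100 replicates over majors 4–7 (states with several candidate
  orders), where matched per-time-point rank correlation stays ≥ 0.9.  For
  8–10-copy states the *last* time points lose rank fidelity at this
  mutation count — the expected behaviour for late events separated by
  small duration classes.
- Bootstrap coverage of the single-gain 95% interval, measured over 200
  replicate experiments of 1000 mutations, sits in the nominal 0.90–0.99
  band.

## Known limitations

- Losses, more than one WGD, and histories gaining different copies are out
  of scope (untimeable or unmodelled); CN-LOH segments are timed but the
  loss itself is not placed in time.
- The flag vocabulary and the Battenberg-style column mapping are
  reconstructions of common practice; upstream tools with other conventions
  need renaming.
- Confidence intervals reflect resampling of multiplicities only; they are
  anti-conservative when multiplicity assignment is itself uncertain (low
  depth, low purity).
- Adjacent segments are timed independently even when they plausibly share
  history; pooling evidence across segments (including genome-wide WGD
  timing) is deliberately left to the user.
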