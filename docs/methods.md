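# Methods

This note documents the models, conventions and numerical choices behind the
package; it is the reference for anything a default value or a tie-break
leaves implicit.

## Signal model

The single-molecule substrate is the *bitvector*: one 0/1 vector per
sequencing read over a 1-based reference interval, a 1 marking a
misincorporation.  Misincorporations report chemical modification of the
underlying RNA: N1-A and N3-C methylation on the Watson-Crick face, and --
after borohydride reduction and depurination -- N7-G methylation read out
through abasic-site-induced misincorporation.  Deletions are not represented:
within a run of identical bases a deletion cannot be assigned to a position.

Per-position misincorporation rates are `r_i = hits_i / coverage_i`
(positions under `min_cov` reads, default 100, are flagged and excluded).
Reactivities rescale rates within a nucleotide class: box-plot outliers
(above Q3 + 1.5 IQR) are removed, the normalization factor is the mean of the
top 10% of the remaining rates, and `R_i = r_i / factor`.  Both constants are
exposed as parameters.  Per-base normalization is the default because A, C, G
and U differ in baseline reactivity; pooled normalization is available.  The
transform is scale-invariant and idempotent up to the factor re-estimating to
1 on an already-normalized profile.

## Read-level separation filter

Abasic sites and Watson-Crick methylations can smear misincorporation into
the next one or two nucleotides during reverse transcription.  Following the
separation analysis convention for this chemistry, events closer than
`min_sep = 2` positions within one read are collapsed to a single event; the
package keeps the 5'-most one (which of the smeared calls survives is
arbitrary; 5'-most makes the operation deterministic and idempotent).  The
collapse is applied by the simulator too, so synthetic reads carry the same
short-range anti-correlation artifact as parsed real reads — which is also
why the pair-level statistics use a separate, wider exclusion window.

## Co-occurring misincorporations (G-test)

For positions i, j the reads covering both are tallied into a 2x2 table and
tested with the likelihood-ratio statistic `G = 2 * sum O ln(O/E)`; cells
with `O = 0` contribute nothing, and a zero margin makes the pair undefined
(flagged, excluded).  The association sign is positive when `n11 * N >
row1 * col1`; negative associations are discarded downstream because the
structural mechanism of interest (transient breathing of a hydrogen-bonded
group, or a conformer mixture) produces *co*-modification.  Under
independence G is asymptotically chi-squared with 1 df, which the test suite
checks by simulation (KS test plus the 99th-percentile exceedance rate).

Pairs closer than `min_sep = 6` are excluded from the pair matrix.  This is
deliberately wider than the read-level collapse distance of 2: the collapse
deterministically suppresses nearby co-occurrences and would otherwise
manufacture negative short-range structure.  The window is a knob; 6 keeps a
comfortable margin over the collapse footprint at the cost of in-tract
pairs, which for G-quadruplex tracts are recoverable from cross-tract pairs.

G values are compared through Z-scores over a pair population — by default
the positive G-G pairs, since the question posed of the matrix is which G's
are structurally linked; `subset="all"` switches to all positive pairs.  The
G-G network links G positions whose pair has Z >= 2.0, and its connected
components expose clusters of structurally linked G's.

## Mutate-and-map matrices

Row m of the M2 matrix is the rate profile of reads carrying a mutation at
m (reads with several mutations enter several rows — the subsetting is by
bit, not by read identity).  The diagonal is undefined, rows with fewer than
`min_reads = 50` supporting reads are dropped (rates from fewer reads are
too noisy to Z-score against), and each column is Z-scored over its defined
rows, clipping negatives, so that a cell asks "did mutating m increase
reactivity at j relative to other mutants?".  The installed position's
neighbours are not excluded from the row profile.

## G-quadruplex enumeration

Conformers are all placements of four all-G tracts of length `tetrad`
(default 3) drawn from runs of at least `min_run` G's, ordered and
non-overlapping, loops within `[loop_min, loop_max]` (defaults 0-36) with at
most one zero-length loop (the QGRS convention), and span at most `max_span`
(default 45).  Overlapping placements within long runs are all counted.
Ranking conformers by the mean misincorporation rate of their G's puts the
most protected — most plausibly folded — conformer first; ties break by 5'
start, then span, a repository convention.

Register combinatorics for a (UG)_n tract are exact set operations: a tract
of n repeats supports `n - s + 1` placements of an s-repeat quadruplex; each
register excludes `n - s` repeat G's, and `s - (number of registers - 1)`
G's are engaged in every register.

## Bernoulli-mixture deconvolution

Reads are modelled as draws from a K-component product-Bernoulli mixture and
fit by EM.  Initialization draws per-read responsibilities from a flat
Dirichlet (10 restarts by default; the best final log-likelihood wins), mu is
clipped to `[1e-6, 1 - 1e-6]`, and convergence is a log-likelihood
improvement below `tol = 1e-4`.  The log-likelihood is nondecreasing across
iterations (asserted in tests).  K = 1 is the closed form (column means).
Model order can be compared by BIC with `(K - 1) + K L` parameters.  A fit
on identical reads with K >= 2 is flagged non-identifiable; a fit with fewer
than 10 positions differing by more than 0.01 between states is flagged
few-informative-positions (a warning, not a failure — deconvolution with
fewer differential positions is unreliable).  State profiles are normalized
separately per state (whether joint normalization is preferable is an open
modelling question; separate is the default here), and the state-1 minus
state-2 reactivity difference localizes the conformational change.

## Tertiary constraints and per-read folding

A G is annotated as tertiary when its rate is in the bottom quartile of G
rates (linear-interpolation percentile, ties included) *and* it has a
positive co-occurrence (Z >= 2.0, G-G population) with another
bottom-quartile G.  Protection alone is not enough — base-paired G's are
also protected; the correlation requirement selects G's whose protection is
coupled, the signature of a hydrogen-bonded group.

Bitvector editing then encodes the constraint logic per molecule: a read
with no misincorporation at any tertiary G is presumed to hold the tertiary
fold, so its tertiary G's are set to 1 (forced single-stranded in folding);
a read modified at a tertiary G is presumed to come from an alternative
conformation, so its tertiary G's are cleared (freed for pairing).  All
other G bits are cleared in both cases, because N7G misincorporation status
does not report Watson-Crick pairing and would wrongly force base-paired
G's open.  Note the two branches necessarily map to opposite tertiary-bit
patterns, so the edit is a one-shot transformation of raw reads, not an
idempotent projection.

Each edited read is folded with its 1-bits as forced-unpaired constraints.
The built-in engine maximizes canonical pairs (AU, GC, GU) with a minimum
hairpin of 3 unpaired nucleotides by Nussinov dynamic programming; the
O(L^3) fill is JIT-compiled with numba when available (pure-Python
fallback).  The traceback is deterministic: scanning an interval's 3' end,
it pairs that end with its 5'-most optimal partner before considering
leaving it unpaired.  Maximum pairing is a deliberately simple,
parameter-free engine — it is not a thermodynamic or statistically trained
model, and its structures are meaningful relative to each other (same
engine, different constraints), which is all the downstream clustering
uses.  A trained or thermodynamic engine can be substituted through the
external-backend hook (two lines on stdin — sequence and constraint string —
dot-bracket on stdout); constraint violations in external output are hard
errors.

Structures are encoded per position into six element classes (stem 1,
interior/bulge 2, multiloop 3, hairpin 4, 5' tail 5, 3' tail 6).  Unpaired
stretches of the exterior loop between helices are classed multiloop;
an entirely unpaired structure is all class 5.  Raw class integers feed a
2-component PCA (deterministic sign: each component's largest-magnitude
loading is made positive) and k-means (k-means++ with fixed seed);
one-hot encoding is available behind a flag.  Each cluster reports the
member read nearest its centroid in PCA space as representative, plus a
per-position majority-class consensus.  Folding the "10,000 most modified
reads" convention is implemented as ranking by 1-bit count after collapse
but before editing, ties in input order.

## Synthetic data

The generator draws each read from a mixture of conformers.  Accessibility
per position derives from the conformer's structure: unpaired 0.30, paired
0.03, quartet G 0.005, helix-terminal G 0.25 (the literature supports this
ordering, not absolute values; these are calibration constants, all
overridable).  A read in state k modifies position i with probability
`dose * a_i + background`, observes each adduct with probability
`detection`, and finally passes through the separation collapse.  Defaults:
dose 0.8, detection 0.95, background 0.002, breathing 0.02, min_sep 2 —
chosen so that fully accessible positions show rates in the tens of
percent, paired positions a few percent, and protected quadruplex G's a few
per mille, the qualitative pattern of N7G probing data.

Two mechanisms couple positions within a molecule: *breathing* opens an
entire quartet group all-or-none with a small per-molecule probability (the
minimal mechanism producing correlated G-G misincorporations), and mixture
membership itself.  Mutate-and-map pools install one uniform point mutation
per read (forced to bit 1 after the collapse — it is a real sequence change,
not a chemical event); a mutation inside a quartet group unfolds the whole
group for that molecule, and a mutation at a paired position exposes its
partner at single-strand accessibility.

What the generator does *not* emulate: sequence-dependent modification and
detection biases, reverse-transcription drop-off, mutagenic-PCR bias,
alignment artifacts, partial-length reads (it emits full-length reads), and
correlated detection noise.  Passing tests on this generator therefore
demonstrate the correctness and statistical calibration of the algorithms
under their stated model, not robustness to every artifact of real
libraries.

## Benchmark scenarios

`bashmap.scenarios` freezes the planted study conditions:

* **quad-switch** (`two_conformer_quadruplex`): L = 85 over {A, C, G}; a
  12-G three-tier quadruplex (major state, 80%) versus an open-core state
  (20%) in which the C block pairs 3' filler G's.  36 accessible filler G's
  anchor the upper quartiles of the G-rate distribution so the bottom
  quartile isolates the quartet.  Scenario dose is 0.5, breathing 0.01,
  background 0.001: at that dose a minor-state molecule reveals itself by at
  least one hit in its open quadruplex with probability ~0.84 while a
  closed-core molecule false-positives at ~0.05, so the per-read
  constraint-routing errors roughly cancel in the cluster proportions.  All
  pair-capable bases sit inside positions 5-81; the poly-A exterior can
  never pair, so folds are constant outside the variable block by
  construction.
* **m2-quartet**: a single tetrad of four mutually non-adjacent G's
  (separation filter cannot mask their co-detection), 200 reads per mutant
  row.
* **m2-hairpin**: a 10-bp G-C stem with a 12-nt loop, 200 reads per row,
  for partner recovery.
* **two-state Bernoulli**: 60 positions, complementary accessibility
  between states, no collapse (min_sep 0) — exact product-Bernoulli draws,
  the mixture model's own assumptions.
* **independent null**: 101 positions at rate 0.1, 2000 reads, no collapse —
  5050 exactly independent pairs for G-test calibration.

Problem sizes (10,000 reads for the end-to-end scenario, 12,000 / 6,400 for
the M2 scenarios, 20,000 for deconvolution) are the package's benchmark
conventions: large enough that binomial noise is far from the decision
margins, small enough to run comfortably on one CPU.

## Degenerate inputs and numerical guards

Zero-coverage or sub-`min_cov` positions are NaN-flagged, never silently 0.
An all-zero normalization class is left unnormalized and flagged.  A
zero-spread Z-score population (relative sd below 1e-12) maps to all-zero Z
rather than dividing by noise.  Constant M2 columns Z-score to 0.  Empty
pair tables and zero margins raise.  Proportions must sum to 1 within 1e-9.
PCA on identical vectors yields all-zero coordinates.

## Known limitations

* The built-in folding engine ignores thermodynamics and pseudoknots; the
  quadruplex itself is represented only through constraints, never as a
  folded element.
* The pair statistics implement the plain G-test with a sign filter; no
  read-quality weighting and no multiple-testing correction across pairs
  (the Z threshold is the documented procedure).
* Bottom-quartile tertiary-G selection presumes the quadruplex comprises at
  most ~25% of the reference's G's; references dominated by quadruplex G's
  need an explicit tertiary list (the CLI accepts one).
* The EM deconvolution fits product-Bernoulli states; the read-level
  collapse violates independence slightly, biasing mu downward near other
  modified positions at high rates.
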