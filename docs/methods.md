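# Methods

## Model and assumptions

A cell's karyotype is the vector of copy numbers of its 23 chromosome
types. During each division, every chromosome copy missegregates
independently with rate *p* (both copies to one daughter), so a random
daughter of a cell with *i* copies receives *i−1*, *i* or *i+1* copies;
events with two or more simultaneous missegregations of the same chromosome
carry O(p²) probability and are dropped (the *linearized* division rule).
Copy numbers outside [1, N] are lethal. Following a single random daughter
per division turns the population process into a Markov chain per
chromosome: the conditional-on-viable law of the lineage equals the
population fraction law because the two daughters are exchangeable. Because
chromosomes missegregate independently, the 23-chromosome chain is the
product of the per-chromosome chains and every population quantity
factorizes over chromosomes; the N^23 joint space is never enumerated.

Assumptions this inherits: discrete synchronous generations, no
cell-cycle-time variation, independence of chromosomes (violated only by
whole-genome duplication, which the duplication extension models per
chromosome — correct marginally, silent about cross-chromosome
correlation), and a hard viability cap N rather than a graded penalty.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| N | tolerated copy-number cap | 8 | copies |
| p | missegregation rate | — | per copy per division |
| s_k | chromosome score (oncogenic > 0) | packaged table | dimensionless |
| c, d | survival constants in Q_surv = e^{c+dS} | −0.036132164, 0.00039047 | dimensionless |
| μ | e^{d·s_k}, per-copy survival multiplier | 1 | dimensionless |
| C | e^{c_k}, per-chromosome constant | e^{c/23} | dimensionless |
| p_gd | whole-genome duplication rate | 0 | per division |
| m_r | gene-X inactivating mutation rate | 0 | per copy per generation |

The cap N = 8 and the (c, d) values are the calibration used throughout the
reference tables; c is chosen so Q_surv ≤ 1 for every valid karyotype. The
split of c into per-chromosome constants c_k is arbitrary (any split summing
to c yields identical product-chain behavior); the even split is the
default. With the even split, q_k(i) = C·μ^i can exceed 1 for strongly
oncogenic chromosomes — harmless for all matrix computations (a warning is
emitted), but the per-chromosome lineage simulator requires q ≤ 1 and
rejects such splits; the CLI rescales C automatically.

## Spectral computations

The quasi-stationary distribution is the left Perron eigenvector of the
sub-stochastic block, normalized to sum 1. All blocks are tridiagonal with
positive off-diagonals, hence similar to symmetric tridiagonal matrices:
the spectrum is real and simple.

- **Characteristic polynomials** are generated by the three-term
  determinant recurrence — exact `fractions.Fraction` arithmetic for the
  drift matrix J (the recurrence is integer-friendly), floats (or Fractions
  on request) for the scored matrix. The recurrence subtracts the
  `n(n−1)/4` term; the subtraction form is forced by the tridiagonal
  determinant expansion and is pinned by a unit test against the known
  degree-8 polynomial (constant term 2835/2).
- **Perron roots** come from Newton iteration started above the spectrum
  (Gershgorin bound: 0 for J, max_i μ^i for the scored matrix). For a
  polynomial with all real roots, Newton from above the largest root
  converges monotonically, so no bracketing is needed. Evaluation uses
  scaled recurrences (P_n/n! for J; P_n/(n!(p/2)^n μ^{n(n+1)/2}) for the
  scored family) so intermediates stay O(1) out to N in the hundreds.
- **Eigenvectors** use the closed form v_i ∝ P_{i−1}(α)/Π a_{j,j−1}. The
  one-directional recurrence loses the eigenvector to rounding wherever its
  entries decay steeply (it is the minimal solution there — pronounced for
  small p with μ < 1), so the scored eigenvector is computed by forward and
  backward sweeps spliced at the entry where both are reliable, the
  standard treatment for tridiagonal eigenvectors given an approximate
  eigenvalue.
- A dense left eigendecomposition (`quasi_stationary_numeric`) is kept as
  an independent route for every chain kind and is the only route for the
  duplication and gene-inactivation chains; closed form and eigensolver are
  cross-checked to 1e−9 in the tests. The second eigenvalue (for the
  mixing estimate 1/(1 − ρ̃/ρ)) comes from the symmetric-tridiagonal
  eigenvalue solver.
- For the gene-inactivation chain with m_r > 0 the σ/τ states are
  transient, the block is reducible, and the Perron vector carries no mass
  there; results are flagged `reducible` rather than treated as errors. As
  printed, that chain has no transition for missegregation of the
  *inactive* copy out of τ (toward a one-active-one-inactive 3-copy state);
  the matrix is implemented verbatim. The constant split for q_k(2) in the
  σ/τ rows reuses the same C as elsewhere.

## Dynamics

Propagation renormalizes the state vector every generation and accumulates
per-step log survival, so trajectories remain accurate where the raw
surviving fraction underflows (needed for diversity surfaces spanning
10 ≤ g ≤ 10⁶). Single-time queries beyond g = 10⁴ use repeated squaring
with per-step max rescaling. The two routes agree to 1e−10 where raw
propagation is representable. "Time to inactivation" is read on the
conditional-on-viable distribution by default (consistent with the
conditional convention used everywhere else); an unconditional flag exposes
the raw-mass reading. Mode ties break toward the smaller copy number.

## Diversity and optimal missegregation rates

The karyotype diversity index K sums per-chromosome Shannon entropies of
copy-number fractions among viable cells (0·ln 0 := 0; 0 ≤ K ≤ 23 ln N).
Surfaces over (g, p) grids advance each chromosome's matrix power
incrementally along the sorted g grid (O(log Δg) matrix products per grid
point). Optimal-p searches maximize log-scale objectives (log survival,
log K, or their sum — a monotone transform of survival × K that survives
underflow) on a log-spaced grid, refined by golden-section between the
argmax's neighbors; ties break toward smaller p. Founder cells default to
4 copies per chromosome for survival/diversity scans; a 2-copy founder
reproduces the diploid-start variants.

## The lineage simulator

`simulate_lineages` vectorizes lineages as integer state arrays and follows
the model directly: optional spontaneous death with probability 1 − q(i),
optional genome duplication (half the event mass doubles the count, half is
the never-created daughter), then division under either the linearized rule
(matching the matrices) or the full binomial rule in which every copy
missegregates independently — the latter quantifies the size of the dropped
O(p²) terms. The gene-inactivation variant applies the printed single-draw
thresholds, including the (1−p)^46 whole-genome no-missegregation factor.
Randomness comes from `numpy.random.default_rng(seed)` (PCG64); a fixed
seed reproduces samples bit for bit. The simulator is the oracle in the
test suite: one-generation lineage frequencies are compared against every
row of every built matrix (n = 10⁵, Bonferroni-corrected z-tests at family
level 1e−4), and multi-generation laws by chi-square with low-expectation
bins pooled.

## Test data and what passing shows

No external data exist; the packaged chromosome-score table is the model's
input, and all other fixtures are generated in-test from the model itself.
The simulator emulates exactly the process the matrices describe, so
agreement demonstrates internal consistency of the two routes (and the
smallness of the linearization error via the binomial rule), not fidelity
of the biological assumptions: constant missegregation rates, synchronous
divisions, chromosome independence and the exponential-score survival law
are modelling choices that real single-cell data can and do violate.

## Numerical tolerances and reference-value policy

Closed-form vs dense-eigensolver agreement is asserted at 1e−9; row
conservation at 1e−14; factorization identities at 1e−12 relative.
Published reference values are asserted at one unit in their last printed
decimal place. Several printed table entries (small tail components and
mean columns of the limiting-distribution tables, and the three
across-chromosome average means) disagree with both of this package's
independent routes — which agree with each other to 1e−12 and with a
40-digit exact-arithmetic recomputation — by a few units in the last
printed digit; those reference comparisons are left failing rather than
loosened, and the discrepancy is documented where it occurs.

## Known limitations

- Per-state p_gd vectors model copy-number-dependent duplication for one
  chromosome at a time; joint distributions across chromosomes are then
  unavailable (the product factorization breaks).
- The closed-form limiting distributions assume p > 0 (scored case); at
  p = 0 the chain is reducible and the conditional limit depends on the
  founder.
- No continuous-time variant, no variable generation times, no spatial
  structure or resource constraints.
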