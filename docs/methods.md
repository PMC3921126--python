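# Methods

## Model class and scope

The objects analyzed are one-dimensional series–parallel networks whose
leaves are ideal linear springs (σ = E ε, E > 0, stress/strain units) and
dashpots (σ = η ε̇, η > 0, stress·time/strain units).  Series joins share
stress and add strains; parallel joins share strain and add stresses.
Bridge (non-series-parallel) topologies, inertial elements, nonlinear
elements, and continuum (2D/3D) mechanics are out of scope, as is practical
identifiability from noisy data: the analysis is purely structural, assuming
perfect knowledge of the stress–strain relation at the bounding nodes.

Networks are stored canonically: nested joins of the same mode are flattened
(associativity), children are sorted by a deterministic key (leaves before
composites, then by serialized form), and every leaf carries a unique
parameter symbol.  All reported results refer to this canonical form;
derived equations are invariant to it (tested by permutation/flattening
property tests).

## Constitutive derivation and reduction

Each subtree carries a pair of differential operators (P, Q) with
P(D) σ = Q(D) ε, combined by

* series:   P = P₁Q₂ + P₂Q₁,  Q = Q₁Q₂,
* parallel: P = P₁P₂,         Q = Q₁P₂ + Q₂P₁.

Coefficients are exact multivariate polynomials over the rationals (sympy);
no floating point enters the symbolic path.  When both summed operators lack
low-order terms the composed pair acquires a common factor D^m,
m = min of the two low orders; it is divided out *at every join*, not once
at the end, so intermediate shapes match the per-join analysis.  For
spring–dashpot operators a power of D is the only generic common factor;
this structural gcd is certified at each join by checking that the resultant
of the residual pair is nonzero at random rational parameter points (see the
genericity protocol below).  Reduced equations always satisfy: the stress
operator has a constant term (P.lo = 0), the strain operator's low order is
0 or 1, and Q.hi − P.hi ∈ {0, 1}; these are asserted, not assumed.

### Normalization convention

The equation is made monic by dividing both operators by one designated
leading coefficient.  Since Q.hi ≥ P.hi in reduced form, the strain-side
leading coefficient is always used (this realizes the "higher-order
operator, strain side on ties" rule without case splits).  The non-monic
coefficients, ordered stress side ascending then strain side ascending,
form the coefficient map c(θ).  Identifiability verdicts depend only on the
fibers of c, and the non-monic coefficient *count* — the quantity the local
criterion uses — is invariant to which leading coefficient is designated.

## Type calculus

With n = P.hi, the four reduced shape patterns are

| type | Q.hi  | Q.lo | minimal representative |
|------|-------|------|------------------------|
| A    | n     | 0    | spring                 |
| B    | n + 1 | 1    | dashpot                |
| C    | n + 1 | 0    | Voigt element          |
| D    | n     | 1    | Maxwell element        |

The two join tables (rows/columns A, B, C, D, u) give the type of a
series/parallel join of two locally identifiable typed systems, with the
absorbing marker `u` for an unidentifiable result:

```
parallel         series
   A B C D u        A B C D u
A  u C u A u     A  u D A u u
B  C u u B u     B  D u B u u
C  u u u C u     C  A B C D u
D  A B C D u     D  u u D u u
u  u u u u u     u  u u u u u
```

The parallel table is anchored by parallel(A, B) = C (the Voigt element) and
the series table by series(A, B) = D (the Maxwell element); the suite
re-derives all 20 distinct pairings from scratch (constitutive equation →
shape classification → coefficient count) and checks every cell against
them.  The typing function τ maps springs to A, dashpots to B, and folds
n-ary joins pairwise left-to-right over the canonically sorted children.
Fold-order independence is asserted by property test, not assumed.  The
trace records the label of every node and the first join that produced `u`,
which is reported as the localized cause of unidentifiability.

## Identifiability decisions

**Local.**  A network is locally identifiable iff its non-monic coefficient
count equals its element count.  The count never exceeds the element count
(asserted on every enumerated network), so a deficit always means
unidentifiable.

**Global.**  A locally identifiable network is globally identifiable iff it
can be constructed by attaching one spring or dashpot at a time at the
bounding nodes.  On the canonical flattened tree this is implemented as the
caterpillar/spine condition: every internal node has at most one internal
child, recursively.  Wrapping a network with single elements (in either
mode) generates exactly such trees under associativity, and attaching a
Maxwell element in series (or a Voigt element in parallel) is reducible to
two single-element steps, so the spine condition captures the
one-element-at-a-time constructions; it is additionally cross-validated
against the preimage oracle on every locally identifiable enumerated network
with up to five elements — any disagreement fails the build.  When the
condition holds an explicit build order is emitted (innermost spine node
outward, leaf siblings in canonical order).

## Shape factorization and the Sylvester certificate

A join of two locally identifiable systems poses a factorization problem:
recover (U₁, K₁, U₂, K₂) from f = U₁K₂ + U₂K₁ and g = K₁K₂, where for a
series join the unknown operators U are the stress sides and the known monic
pair K the strain sides (roles swapped for parallel).  After dividing the
common D^m out of the known pair, the linear part of the problem is the
block matrix [M₁ | M₂] whose columns are the D-shifts of the reduced known
operators, rows aligned by monomial degree.  The join is identifiability-
preserving iff this matrix is square, and square shape matrices are
generically invertible: a column permutation exposes a block-triangular form
whose middle block is the Sylvester matrix of the reduced known operators,
so the determinant is a product of nonzero triangular diagonals and a
generically nonzero resultant.  `is_good_quadruple` certifies both facts at
random rational operator coefficients — exact determinant ≠ 0 in every draw,
and an explicit column permutation found by exhaustive search (the matrices
arising from the type pairings have at most a handful of columns; the search
is skipped above eight columns).  Rows are tried in both degree
orientations, since the case analysis behind the block structure swaps the
two systems without loss of generality.

## Genericity protocol

A claim that holds "generically" (gcd degree, matrix rank, nonzero
determinant or resultant) is accepted only when it holds at several
independent random rational parameter points: each parameter is drawn
uniformly from the integers 2..1000 (as exact rationals), three draws by
default.  Exact arithmetic avoids float tolerances entirely; a draw
disagreeing with the others signals a non-generic sample and is surfaced as
an error or warning rather than silently ignored.  Parameters are sampled
positive because spring moduli and viscosities are physical positive
quantities; the genericity statements themselves do not depend on this
restriction.

## Numerical oracles

**Jacobian rank.**  The coefficient map is finite-to-one iff its Jacobian
has full column rank at a generic point.  Each coefficient is cᵢ = pᵢ/L
with pᵢ and the designated leading coefficient L integer-coefficient
polynomials, so by the quotient rule the Jacobian at any point with L ≠ 0
has the same rank as the polynomial matrix [L ∂pᵢ/∂θⱼ − pᵢ ∂L/∂θⱼ].  That
matrix is evaluated with exact big-integer arithmetic at integer points from
the genericity protocol and its rank computed over the rationals — the
oracle is float-free and shares no code path with the counting criterion.

**Preimage count.**  For a locally identifiable network (at most 8
parameters), a random integer point θ₀ (components 2..1000) fixes a target
c₀ = c(θ₀); the equation c(θ) = c₀ is solved by damped least squares
(Levenberg–Marquardt) in log-parameter space — enforcing positivity — from
multistart points drawn log-uniformly from [10⁻², 10²] per coordinate, plus
one start at θ₀ itself so the trivial preimage is always represented.
Solutions with maximum relative residual below 10⁻⁹ are clustered at
relative tolerance 10⁻⁴; the number of distinct clusters is returned, and
finding no solution at all raises rather than returning zero.  Default
n_starts is 200 for single-model queries; the enumerated sweep over ≤5-element
networks uses 24 starts per network, enough to expose the arm-permutation
preimages of the locally-only models at that size while keeping the sweep
fast.  A globally identifiable model yields 1; a chain of k Voigt arms
behind a series spring yields k! (arm permutations), e.g. 6 for the
three-arm generalized Kelvin–Voigt chain.

Both oracles are validations of the symbolic machinery, not part of it: the
verdicts come from exact counting and the spine condition.

## Enumeration and problem sizes

`enumerate_networks(n)` generates every canonical series–parallel network
with n leaves, leaf kinds enumerated as unordered multisets within the
canonical form (2, 6, 20, 80, 340, 1570 networks for n = 1..6).
`random_network` samples a uniform binary split recursively (mode and split
point uniform, leaf kind fair-coin) and canonicalizes.  The exhaustive
cross-validation sweeps run the Jacobian oracle on all 2018 networks with up
to six elements and the preimage oracle on the 36 locally identifiable
networks with up to five elements; these sizes keep a full verification run
within a few minutes on one CPU while covering every type combination that
can arise (the type calculus is closed over four labels, all reachable
within three elements).

## Known limitations

* The generic-gcd routine is specific to spring–dashpot composition, where
  the only generic common factor is a power of D; it is not a general
  multivariate polynomial gcd.
* The preimage oracle is stochastic: it can in principle miss a preimage
  basin (understating the count) and therefore validates rather than decides;
  all decisions rest on the exact symbolic criteria.
* The Sylvester-block certificate searches column permutations exhaustively
  and is restricted to matrices with at most eight columns; larger matrices
  are still certified by their exact determinant.
* Two built-in fixtures (`roscoe10_reconstruction`, and the generalized
  models' default arm counts) reconstruct classical literature models from
  textual descriptions; reports flag the reconstruction explicitly.
* Identifiability is *generic*: verdicts hold for almost every parameter
  value, not for special degenerate configurations (e.g. exactly equal
  moduli), and positivity of parameters is assumed throughout the oracles.
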