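# springdash

Structural identifiability analysis of viscoelastic spring–dashpot networks.

## The problem

Linear viscoelastic materials — arterial walls, soft tissues, polymers — are
routinely modeled by networks of ideal springs (Hooke's law, σ = E ε) and
dashpots (Newtonian damping, σ = η ε̇) joined in series and in parallel.
Any such series–parallel network obeys a single linear constitutive ODE
relating the total stress σ and total strain ε at its bounding nodes,

    σ + a₁ σ̇ + … + aₙ σ⁽ⁿ⁾ = b₀ ε + b₁ ε̇ + … + b_{n+1} ε⁽ⁿ⁺¹⁾,

whose coefficients are nonlinear functions of the spring constants E and
viscosities η.  Whether those element parameters can be recovered from
observations of σ and ε alone is the question of *structural
identifiability*: the parameter-to-coefficient map c(θ) must be one-to-one
(global identifiability) or at least finite-to-one (local identifiability).
Fitting an unidentifiable network to data — a common hazard in, e.g.,
cardiovascular tissue modeling — produces parameter estimates with no
physical meaning.

`springdash` decides both questions symbolically, exactly, and explains a
negative verdict:

* **Constitutive derivation.** The reduced equation P(D) σ = Q(D) ε is built
  by exact operator algebra: series joins give P = P₁Q₂ + P₂Q₁, Q = Q₁Q₂;
  parallel joins give P = P₁P₂, Q = Q₁P₂ + Q₂P₁; common D-power factors are
  divided out at every step.
* **Local identifiability by counting.** A network is locally identifiable
  iff the number of non-monic coefficients of its normalized constitutive
  equation equals the number of elements.
* **Type calculus.** Every reduced equation has one of four shape types
  (A: spring-like, B: dashpot-like, C: Voigt-like, D: Maxwell-like).  Two
  5×5 *identifiability tables* give the type of any series or parallel join
  of typed subsystems — or the absorbing marker `u` — so identifiability of
  arbitrarily large networks is decided without deriving any equation, and
  the first `u`-producing join localizes the failure.
* **Global identifiability.** A locally identifiable network is globally
  identifiable iff it can be grown one element at a time at the bounding
  nodes — a caterpillar/spine condition on the canonical tree, for which the
  tool emits an explicit build order.
* **Independent oracles.** Every symbolic verdict can be cross-checked
  numerically: an exact (rational-arithmetic) Jacobian rank test of c(θ),
  and a multistart parameter-recovery search that counts distinct preimages
  of a generic coefficient vector.
* **Shape-factorization machinery.** The padded block matrix that maps
  unknown sub-operator coefficients to composed coefficients, with its
  embedded Sylvester block, certifies *why* the counting criterion works:
  square shape matrices are generically invertible.

## Worked example

Networks are written in a tiny DSL: `E…` tokens are springs, `n…` dashpots,
`-` joins in series, `|` in parallel.  The Burgers model (a Maxwell element
in series with a Voigt element):

```
$ springdash analyze "(E1 - n1) - (E2 | n2)"
network:    E1 - n1 - (E2 | n2)
equation:   [1/E1*D^2 + ((E1*n1 + E1*n2 + E2*n1)/(E1*n1*n2))*D + E2/(n1*n2)] sigma = [D^2 + E2/n2*D] eps
shapes:     P (2, 0)  Q (2, 1)
type:       D
local:      locally_identifiable (4 parameters, 4 non-monic coefficients)
global:     globally_identifiable
build:      E2, n2 (parallel), E1 (series), n1 (series)
```

The four non-monic coefficients match the four parameters, so the model is
locally identifiable (type D), and since it can be assembled one element at
a time (build order shown), it is globally identifiable: E1, n1, E2, n2 are
uniquely recoverable from stress–strain data.

A three-arm generalized Kelvin–Voigt chain is locally but *not* globally
identifiable — permuting its Voigt arms leaves the equation unchanged:

```
$ springdash analyze --model generalized_kelvin_voigt
network:    E0 - (E1 | n1) - (E2 | n2) - (E3 | n3)
...
type:       A
local:      locally_identifiable (7 parameters, 7 non-monic coefficients)
global:     locally_only
```

And a ten-element reconstruction of a classical generalized-Maxwell-type
model is unidentifiable, with the fatal join pinpointed:

```
$ springdash analyze --model roscoe10_reconstruction
...
type:       u
local:      unidentifiable (10 parameters, 8 non-monic coefficients)
failure:    series join of [E0 - n0] (type D) with
            [(E1 - n1) | (E2 - n2) | (E3 - n3) | (E4 - n4)] (type D) -> u
```

Other subcommands: `springdash tables` prints both identifiability tables,
`springdash enumerate 4 --global-only` catalogs all canonical networks of up
to four elements that are globally identifiable, and `springdash oracle
"E1 - n1" --seed 1` runs the numerical cross-checks.  The same functionality
is available as a library (`springdash.derive_constitutive`,
`springdash.tau`, `springdash.global_identifiability`, …).

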