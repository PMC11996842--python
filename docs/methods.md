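# Methods

## Model overview

`qcogsim` treats a decision maker's belief state as a unit vector in a
small complex Hilbert space and a judgment as a projective measurement.
Three layers sit on top of that core:

1. a **closed-form angle model** of the conjunction fallacy,
2. an **observer layer** that perturbs the model's parameters and scales
   probabilities multiplicatively, and
3. a **collapse layer** that makes the selection of a definite judgment
   dynamical and irreversible through non-Hermitian evolution.

All Hilbert-space objects carry string basis labels, and compatibility is
checked by label equality rather than dimension alone; this is the main
guard against silently tensoring or projecting across the system/observer
boundary.

### Conjunction model

The belief state |ψ⟩ = cosθ|B⟩ + sinθ|F⟩ and conjunction direction
|B_F⟩ = cosφ|B⟩ + sinφ|F⟩ give P(T) = cos²θ and P(T∧F) = cos²(θ−φ). The
closed forms are implemented directly but are required (and tested) to
agree with the generic Born-rule evaluation through the Hilbert layer to
1e−12 — a structural consistency constraint, not a numerical convenience.
Angles are radians internally; the degree-based constructors exist only at
the API boundary because the linear correction term sin(2Δ)(δθ−δφ) is
dimensionally meaningful only in radians.

The familiar empirical judgment rates for the Linda task (≈0.15 for the
single event, ≈0.85 for the conjunction) are shipped as reference
constants for calibration demos. They are cited values from the
behavioural literature, not model outputs, and no fitting procedure is
provided: the package deliberately exposes (θ, φ) as free parameters.

### Observer layer

The conscious-influence factor g = 1 + η·|⟨ψ_focus|ψ_init⟩|² multiplies a
standard probability. Two conventions are possible once several outcomes
are in play, and both are exposed:

- **raw**: pᵢ·gᵢ, un-renormalized — this matches the closed-form worked
  numbers and is the default single-outcome report (clipped at 1 with a
  warning if the product overflows);
- **renormalized**: pᵢgᵢ/Σⱼpⱼgⱼ for a complete outcome set, which is what
  a coherent probability model requires.

Similarly the combined perturbed-and-influenced conjunction probability is
available both as the product form [cos²Δ − sin(2Δ)(δθ−δφ)]·g and as the
first-order expansion that drops the O(η·δ) cross terms; the two differ by
less than ηδ on the canonical parameter ranges.

First-order time-dependent perturbation theory for the interaction
Ĥ_int = λ(Â_sys ⊗ Â_intO) assumes a static observer state (Ĥ_intO = 0),
under which the observer degrees of freedom enter only through the scalar
overlap ⟨ψ_focus|ψ_init⟩. The correction amplitude

    A⁽¹⁾ = −iλ⟨ψ_focus|ψ_init⟩ ∫₀ᵗ ⟨a|Â_sys(t′)|ψ₀⟩ dt′

is evaluated by adaptive quadrature (absolute tolerance 1e−10) on the
interaction-picture matrix element, computed in the eigenbasis of the
(Hermitian) system Hamiltonian. Non-Hermitian system generators are
rejected here by contract: decaying dynamics belong to the collapse layer.

### Collapse layer

The total generator is Ĥ_total = (Ĥ_sys − iΓ̂)⊗Î + Î⊗Ĥ_intO + Ĥ_int with
Γ̂ Hermitian PSD, so the anti-Hermitian part is exactly −i(Γ̂⊗Î) and the
norm is non-increasing. The decision scenarios use the diagonal special
case aᵢ(t) = aᵢ(0)e^{(−iλᵢ−γᵢ)t} (ħ = 1; λ, γ in inverse-time units), with
conjunction amplitude a₂ = (a₁+a₃)/√2.

Two probability conventions coexist by design:

- **raw** probabilities follow the model algebra literally, including the
  subtraction P(Y) = |a₃|² − P(X∧Y) ("the conjunction absorbs part of
  Y"), which can be negative, and are not renormalized after non-unitary
  decay — the ranking logic of the scenarios compares unnormalized moduli;
- **reported** probabilities clamp negatives to zero and renormalize to a
  proper distribution at each time point (a fully decayed row falls back
  to the uniform distribution rather than 0/0).

General evolution computes `expm(−iHt)` per time point; with dimensions
≤ 12 this is cheaper and simpler than any propagator caching or splitting
scheme, and it is the oracle against which the closed form is tested to
1e−10.

The quantum-Zeno suppression ratio takes the state with the minimal decay
rate as the collapse target and reports the non-target reported
probability mass at time t relative to t = 0: 1 when nothing decays,
strictly decreasing in the decay rates, → 0 as γt → ∞.

### Contextual updating

Contexts are CPTP channels (validated Kraus completeness within 1e−8);
the contextual Born rule applies the channel and then Tr(ρ′Πᵢ) over a
validated complete orthogonal projector set. With the identity channel the
code path is arithmetically identical to the standard Born rule, and the
test suite asserts bit-identity, not approximate equality.

The decay dynamics can be absorbed into a measurement instrument with
operators Mᵢ = e^{−Γ̂t}Πᵢ. Note the convention: the collapse engine's Γ̂
acts on *amplitudes* (aᵢ decays as e^{−γᵢt}, probability as e^{−2γᵢt}), so
in the more common probability-rate convention Γ̃ = 2Γ̂ these operators are
the familiar half-rate form e^{−Γ̃t/2}Πᵢ. The equivalence
Tr(ρ₀Mᵢ†Mᵢ) = |aᵢ(t)|² on shared fixtures is part of the acceptance
suite and pins the convention down. For t > 0 the instrument is
subnormalized, mirroring the norm loss of the non-unitary evolution.

The dimension-weighted belief update q(j) = ((d+1)/d)Σᵢp(i)r(j|i) is
implemented literally alongside a normalized variant; the literal form
sums to (d+1)/d by construction and tends to the classical mixture as
d → ∞. No "corrected" form is guessed.

## Scenario defaults

The collapse scenarios require only *orderings* of their parameters, not
magnitudes: salience λ₁ > λ₂ > λ₃ (the congruent state is most strongly
reinforced by observer intent) and decay γ increasing from the most to
the least congruent state (high-free-energy states are pruned fastest).
The shipped defaults

    lam   = (1.2, 0.7, 0.2)
    gamma = (0.1, 0.3, 0.6)
    a0    = (1/√2, 0, 1/√2)

are this package's choice of a representative point satisfying those
constraints, with initial weight split evenly between the two component
states and none pre-assigned to the conjunction (it is generated by
interference). Violating the orderings raises a config error unless
`strict_ordering: false` is set, which exists precisely so that
counterfactual runs (e.g. inverting the decay ordering inverts the
ranking) remain expressible.

The evaluation time defaults to the grid time maximizing the gap between
the top two reported outcomes ("after sufficient time" made operational
and deterministic); a fixed `t_eval` can be supplied instead. Ranking
ties within `tie_tol` (default 1e−9) are broken lexicographically by
label and reported explicitly.

For the prisoner's dilemma the three branches are:

- *unknown*: P = |a₁(t)|² + |a₂(t)|², the interference-boosted
  cooperation probability;
- *cooperate known*: the state collapses to the bare cooperation branch,
  P = |a₁(t)|² with the slow cooperation decay rate and no interference;
- *defect known*: collapse favors defection, modelled by re-assigning the
  fast defection-branch decay rate to the cooperation amplitude,
  P = |a₁(0)|²e^{−2γ_B t}.

The cooperate/defect branch assignments are a modelling choice (the
qualitative description constrains only their ordering); with any
γ_A < γ_B and nonzero interference the sure-thing-principle violation
P(unknown) > max(others) follows structurally.

## The two-path shift simulator

`two_path_shift` emulates focused-intent experiments on two-outcome
quantum random processes: a baseline Bernoulli probability (default 0.5)
shifted multiplicatively to p′ = p(1 + η·overlap²), sessions of n
i.i.d. trials (default 10⁶, one session) drawn from a seeded generator,
and the observed frequency reported with its z-score against the
*baseline*. What it emulates: the statistical footprint of a small,
stable multiplicative probability shift. What it does not emulate: human
participants, session-to-session drift, selection effects, or any
physical mechanism — so passing tests show that the *model's* shift is
recoverable at realistic sample sizes, not that such shifts occur
empirically. Empirical effect sizes reported in that literature come from
meta-analyses over many participants and are not reproducible at desk
scale; the simulator's acceptance check is therefore property-based
(observed frequency within the binomial 3σ band of the analytic shifted
probability at fixed seed).

## Numerical choices

- Tolerances: 1e−10 structural (hermiticity, idempotency, normalization),
  1e−8 probabilistic (completeness, trace preservation); every predicate
  takes an explicit `tol`.
- Degenerate inputs: zero states raise a dedicated error rather than
  normalizing to NaN; zero-probability measurement outcomes raise an
  explicit error; a fully decayed distribution reports uniform.
- The first-order angle formula's truncation error is Θ(cos(2Δ)·δ²), so
  the δ-halving error-ratio check (expected factor ≈ 4) uses a Δ grid
  excluding the neighbourhood of Δ = 45°, where the quadratic coefficient
  vanishes and the error becomes third order (halving ratio → 8).
- The worked combined probability is quoted two ways because the printed
  chain rounds its intermediate: the unrounded pipeline gives
  0.9494 × 1.005 = 0.9541, while rounding the perturbed probability to
  0.949 first gives 0.9537 ≈ 0.953(7). Tests pin both.
- Fixture generators derive everything from `numpy.random.default_rng(seed)`
  and fix the QR phase convention, so fixtures are byte-identical per
  seed.

## Known limitations

- No parameter fitting to human data; (θ, φ, η, λᵢ, γᵢ) are inputs.
- Disjunction-fallacy and order-effect tasks are out of scope (no
  quantitative model to implement).
- The collapse dynamics are pure-state and non-Hermitian; Lindblad
  master-equation decoherence and an explicit environment space are not
  modelled.
- Second-order perturbation theory and time-dependent influence strengths
  are not implemented.
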