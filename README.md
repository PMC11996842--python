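# qcogsim

A quantum-cognition simulator for decision scientists and computational
modellers: Hilbert-space models of decision-making "fallacies", an
observer-coupled perturbation layer, a non-Hermitian collapse engine,
contextual (QBist-style) probability updating, and a handful of
observer-thermodynamics closed forms.

## The scientific problem

People systematically violate classical probability when judging events.
In the Linda task they rank "bank teller **and** feminist" (T∧F) above
"bank teller" (T), even though classically P(T∧F) ≤ P(T) always; in
prisoner's-dilemma experiments players cooperate more when the opponent's
move is *unknown* than when it is known either way, violating the
sure-thing principle. Quantum probability theory models these patterns by
representing the belief state as a vector in a complex Hilbert space and
judgments as projective measurements, so *interference* between belief
components can produce classically impossible orderings.

`qcogsim` implements this model family plus an explicit observer layer:

- **Conjunction model** — |ψ⟩ = cosθ|B⟩ + sinθ|F⟩ with conjunction
  direction |B_F⟩ = cosφ|B⟩ + sinφ|F⟩, giving P(T) = cos²θ and
  P(T∧F) = cos²(θ−φ); the fallacy occurs iff |θ−φ| < θ.
- **Observer perturbation** — contextual angle shifts (δθ, δφ) handled
  exactly and to first order, and a multiplicative conscious-influence
  factor g = 1 + η·|⟨ψ_focus|ψ_init⟩|² scaling outcome probabilities;
  first-order time-dependent perturbation theory for a weak coupling
  Ĥ_int = λ(Â_sys ⊗ Â_intO).
- **Non-Hermitian collapse** — a PSD decay operator Γ̂ enters the
  generator as −iΓ̂, damping incongruent states
  (aᵢ(t) = aᵢ(0)e^{(−iλᵢ−γᵢ)t}) and freezing the system into preferred
  "eigenform" states, quantum-Zeno style. Conjunction states
  (|x⟩+|y⟩)/√2 carry interference cross terms.
- **Contextual updating** — CPTP context channels, a contextual Born rule
  that reduces bit-for-bit to Tr(ρΠᵢ) under the identity context, and
  Kraus-instrument updates ρ → MᵢρMᵢ†/Tr(ρMᵢ†Mᵢ).
- **Observer thermodynamics** — Landauer bound ln(2)k_BT, one-bit
  question energy βk_BT, Schwarzschild/Bekenstein–Hawking quantities, and
  the fitness-beats-truth probability (|X|−3)/(|X|−1).

## Worked example

```bash
qcog worked-examples
```

prints the closed-form conjunction pipeline at θ = 60°, φ = 50° with
contextual shifts δθ = 5°, δφ = 2° and observer influence η = 0.01 at
squared overlap 0.5:

```
theta = 60 deg, phi = 50 deg
P(T)              = 0.2500
P(T∧F)            = 0.9698
fallacy (P(T∧F) > P(T)): True
P(T) perturbed    = 0.1786
P(T∧F)' exact     = 0.9494
P(T∧F)' 1st order = 0.9519
g                 = 1.0050
P_combined        = 0.9541
```

Reading: the conjunction is judged far more probable than the single
event (0.9698 vs 0.25 — the fallacy). The contextual shift moves the
effective angle difference from 10° to 13°, lowering P(T∧F) slightly
(0.9494) but lowering P(T) much more (0.1786), so the fallacy
*strengthens*; the observer's influence factor g = 1.005 then nudges the
combined probability up to 0.9541.

The same API drives the collapse scenarios:

```python
from qcogsim import ScenarioConfig, run_linda_collapse, run_prisoner_dilemma

ranking, table = run_linda_collapse(ScenarioConfig("linda_collapse"))
print(ranking.labels)        # ('F', 'F∧BT', 'BT')

probs, rank, violated = run_prisoner_dilemma(ScenarioConfig("prisoner_dilemma"))
print(rank.labels, violated) # ('A_unknown', 'A_cooperate', 'A_defect') True
```

and YAML scenario files run from the shell:

```bash
qcog run scenario.yaml --out results.csv
qcog sweep --param eta --range 0:0.05:0.005 --out sweep.csv
qcog thermo --landauer 300 --black-hole 1.989e30
```

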