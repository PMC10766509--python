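# tpslearn

Machine-guided transition path sampling: learn the committor of a rare
event while sampling its transition paths, validate the model on the fly,
and distill it into compact symbolic expressions — exercised end to end on
built-in toy stochastic dynamics with known committors.

## The problem

Rare transitions between metastable states A and B (assembly, folding,
nucleation) are governed by the **committor** p_B(x): the probability that a
trajectory launched from configuration x with thermal velocities reaches B
before A. It is the ideal reaction coordinate, but it is expensive to
estimate and hard to interpret. For Markovian time-reversible dynamics, the
probability that a two-way shot from x yields a transition path (TP) is

    P(TP | x) = 2 p_B(x) (1 − p_B(x)),

so knowing the committor also tells you where to shoot from: sampling and
learning are the same problem.

## The method

`tpslearn` implements the closed loop:

1. **Two-way shooting TPS** — select a frame of the current TP from the
   Lorentzian distribution p_sel(x) ∝ 1/(q(x)² + γ²) centred on the learned
   transition-state ensemble q = 0, redraw Maxwell–Boltzmann velocities,
   propagate forward and backward until commitment, and Metropolis-accept
   with p_acc = min(1, p_sel(X_SP|χ′)/p_sel(X_SP|χ)).
2. **Maximum-likelihood committor** — every committed trial is a Bernoulli
   datum (x_i, s_i) with s_i = +1 (entered A first) or −1 (entered B).
   A pyramidal network log-predictor q(x|w), with p_B = 1/(1+e^−q),
   minimizes l(w|θ) = Σ_i log(1 + e^{s_i q(x_i|w)}).
3. **Live validation** — the expected TP count over the last k shots,
   n_exp = Σ 2 p_B(1−p_B), is compared with the generated count; the
   efficiency factor α_eff = min(1, (1 − n_gen/n_exp)²) scales the learning
   rate and gates retraining, preventing overfitting a model that already
   predicts well.
4. **Distillation** — permutation importance Δl_i selects the few relevant
   inputs; a (N+1) evolution strategy over expression trees minimizes
   −log L + λC (C = number of mathematical operations), and a Pareto front
   over (loss, C) ranks the candidate formulas.
5. **Mechanism analysis** — projected TPs are compared by dynamic time
   warping, clustered hierarchically into competing channels, and rendered
   as per-path density maps.

The simulation engine is a black box: the package ships overdamped
(Euler–Maruyama) and underdamped (velocity Verlet with velocity
randomization) Langevin integrators for analytic toy potentials — a 1D
quartic double well with an exact quadrature committor, and a 2D double
well with two competing transition channels — plus Behler-style G²/G⁵
symmetry functions with isotropic normalization for featurizing 3D point
environments.

## Worked example

```python
import numpy as np, tpslearn as t

potential = t.QuarticDoubleWell()                       # U = 4 (1 - x^2)^2
states = [t.half_line_state("A", -0.8, "le"), t.half_line_state("B", 0.8, "ge")]
engine = t.EngineParams(timestep=0.005, kT=1.0, max_steps=200_000)

model = t.NeuralCommittor(1, t.build_pyramid(12, 2, 6, 0.0), seed=0)
run = t.run_guided_sampling(potential, engine, states, lambda P: P, model,
                            n_steps=2000, seed=0,
                            saddle_guesses=[np.array([0.0])],
                            epochs_per_update=30)
```

Running `python examples/02_guided_sampling.py` (which is exactly this)
prints:

```
MC steps: 2000, acceptance 24.3%, 4000 shooting records
generated TPs: 637, expected from the model: 689.1
final |generated - expected| = 52.1 (plateaus once the committor is learned)
committor MAE vs quadrature oracle on 9 grid points: 0.030
```

Each two-way shot contributed two Bernoulli records; after 2000 moves the
generated TP count tracks the model's own expectation within a few percent,
and the learned committor deviates from the exact quadrature solution by a
mean absolute error of 0.03. The other scripts in `examples/` demonstrate
the shooting oracle, symbolic distillation, pathway clustering and the
symmetry functions, one capability each.

A thin CLI mirrors the library for shell-launched runs:
`tpslearn sample|train|validate|attribute|distill|cluster|fixtures --help`.

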