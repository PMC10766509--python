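"""Distill a committor into a compact formula: attribution picks the
relevant inputs, symbolic regression searches expression space.

Shooting records are planted from p_B = sigmoid(2 x1 - 1) with a decoy
noise input x2.  Permutation importance ranks x1 first; a (N+1) evolution
strategy over {+, -, *} trees with fitted constants then recovers a linear
log-predictor whose likelihood matches the planted model.
"""

import numpy as np

import tpslearn as t
from tpslearn.datasets import logistic_records

X1, s, _ = logistic_records(1200, np.array([2.0]), -1.0, rng=7)
rng = np.random.default_rng(0)
X = np.column_stack([X1[:, 0], rng.normal(size=len(s))])  # add decoy input

net = t.NeuralCommittor(2, t.build_pyramid(8, 2, 4, 0.0), seed=0)
net.fit(X, s, epochs=200, learning_rate=3e-3, seed=0)
imp = t.permutation_importance(net, X, s, n_perms=50, rng=1, names=("x1", "x2"))
for i in imp.ranking:
    print(f"input {imp.names[i]}: delta_l = {imp.delta_l[i]:8.2f} "
          f"(+- {imp.stderr[i]:.2f})")

cfg = t.SymRegConfig(lam=1e-4, n_offspring=4, generations=120, seed=3,
                     binary_ops=("+", "-", "*"), unary_ops=("neg",))
res = t.evolve(X[:, :1], s, ("x1",), cfg)
planted_nll = t.shooting_nll(2.0 * X[:, 0] - 1.0, s)
print(f"\nbest expression: {res.best.expression}")
print(f"complexity C = {res.best.complexity}, "
      f"NLL = {res.best.train_loss:.2f} (planted model: {planted_nll:.2f})")

losses = np.array([m.train_loss for m in res.evaluated])
C = np.array([m.complexity for m in res.evaluated], float)
front, knee = t.pareto_front(losses, C)
print(f"Pareto front: {front.size} of {len(res.evaluated)} candidates; "
      f"knee at C = {C[front][knee]:.0f}")
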