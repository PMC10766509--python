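"""Distilling a learned committor into compact analytic expressions.

A (N+1) evolution strategy searches expression trees over a small set of
relevant inputs z: each generation creates N offspring by random structural
changes to the fittest expression, fits every offspring's numeric constants
by gradient-based optimization, and keeps the fittest of parent and
offspring.  Fitness is the shooting negative log-likelihood of the
expression-as-log-predictor plus a complexity penalty,

    l_sr(w_sr | theta) = -log L[p_B(z)] + lambda * C,

where C counts the mathematical operations in the tree.  Scanning lambda and
input subsets produces a candidate pool ranked on a Pareto front of
(validation loss, complexity); the knee of the front balances accuracy
against simplicity.

Operators are protected so evaluation is total: log of a non-positive
argument, division by (near-)zero and overflow flag the affected rows as
invalid, and invalid rows contribute a fixed finite penalty
(``SENTINEL_PENALTY`` per record) to the loss instead of crashing the
search.  Complexity counts every operator node, including unary negation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .committor import _softplus

__all__ = [
    "BinaryOp",
    "Constant",
    "Expression",
    "ExpressionModel",
    "SymRegConfig",
    "UnaryOp",
    "Variable",
    "evolve",
    "mga2_contact_expression",
    "optimize_constants",
    "pareto_front",
    "polymer_folding_expression",
    "random_expression",
    "regularized_loss",
    "CLATHRATE_CONSTANTS",
    "SENTINEL_PENALTY",
]

SENTINEL_PENALTY = 1e3  # loss contribution per invalid (sentinel) record
_DIV_GUARD = 1e-12

# Reference constants of a gas-hydrate nucleation committor model (metadata
# only: the corresponding functional form is not recorded here, so no
# evaluation is built from these values).
CLATHRATE_CONSTANTS = {
    "alpha": 0.0502, "beta": 3.17, "gamma_per_K": 0.109, "delta": 0.0149,
    "n_w0": 2.0, "T0_K": 270.0,
}


# ---------------------------------------------------------------- tree nodes

class Node:
    arity = 0

    def children(self):
        return ()

    def copy(self):
        raise NotImplementedError


@dataclass
class Constant(Node):
    value: float

    def copy(self):
        return Constant(self.value)

    def __str__(self):
        return f"{self.value:.6g}"


@dataclass
class Variable(Node):
    index: int
    name: str = ""

    def copy(self):
        return Variable(self.index, self.name)

    def __str__(self):
        return self.name or f"z{self.index}"


_UNARY = {"neg", "exp", "log"}
_BINARY = {"+", "-", "*", "/", "pow"}


@dataclass
class UnaryOp(Node):
    op: str
    child: Node
    arity = 1

    def children(self):
        return (self.child,)

    def copy(self):
        return UnaryOp(self.op, self.child.copy())

    def __str__(self):
        return f"-({self.child})" if self.op == "neg" else f"{self.op}({self.child})"


@dataclass
class BinaryOp(Node):
    op: str
    left: Node
    right: Node
    arity = 2

    def children(self):
        return (self.left, self.right)

    def copy(self):
        return BinaryOp(self.op, self.left.copy(), self.right.copy())

    def __str__(self):
        if self.op == "pow":
            return f"({self.left})**({self.right})"
        return f"({self.left} {self.op} {self.right})"


def _eval_node(node: Node, X: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    if isinstance(node, Constant):
        return np.full(X.shape[0], node.value)
    if isinstance(node, Variable):
        return X[:, node.index].astype(float)
    with np.errstate(all="ignore"):
        if isinstance(node, UnaryOp):
            v = _eval_node(node.child, X, invalid)
            if node.op == "neg":
                out = -v
            elif node.op == "exp":
                out = np.exp(np.minimum(v, 700.0))
            elif node.op == "log":
                bad = ~(v > 0)
                invalid |= bad
                out = np.log(np.where(bad, 1.0, v))
            else:
                raise ValueError(f"unknown unary op {node.op!r}")
        elif isinstance(node, BinaryOp):
            a = _eval_node(node.left, X, invalid)
            b = _eval_node(node.right, X, invalid)
            if node.op == "+":
                out = a + b
            elif node.op == "-":
                out = a - b
            elif node.op == "*":
                out = a * b
            elif node.op == "/":
                bad = np.abs(b) <= _DIV_GUARD
                invalid |= bad
                out = a / np.where(bad, 1.0, b)
            elif node.op == "pow":
                out = np.power(np.abs(a) + 1e-30, b)
            else:
                raise ValueError(f"unknown binary op {node.op!r}")
        else:
            raise ValueError("malformed expression tree")
    bad = ~np.isfinite(out)
    if bad.any():
        invalid |= bad
        out = np.where(bad, 0.0, out)
    return out


class Expression:
    """A log-predictor expression tree q_sr(z | w_sr) over named inputs."""

    def __init__(self, root: Node, var_names: tuple[str, ...]):
        self.root = root
        self.var_names = tuple(var_names)

    def copy(self) -> "Expression":
        return Expression(self.root.copy(), self.var_names)

    def evaluate(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (q, valid) — invalid rows carry the sentinel value 0."""
        X = np.atleast_2d(np.asarray(X, float))
        invalid = np.zeros(X.shape[0], bool)
        q = _eval_node(self.root, X, invalid)
        return q, ~invalid

    def q(self, X: np.ndarray) -> np.ndarray:
        return self.evaluate(X)[0]

    @property
    def complexity(self) -> int:
        """Number of mathematical operations: every operator node counts."""
        def count(n: Node) -> int:
            return (1 if n.arity else 0) + sum(count(c) for c in n.children())
        return count(self.root)

    def constants(self) -> list[Constant]:
        out = []

        def walk(n: Node):
            if isinstance(n, Constant):
                out.append(n)
            for c in n.children():
                walk(c)
        walk(self.root)
        return out

    def get_constant_values(self) -> np.ndarray:
        return np.array([c.value for c in self.constants()])

    def set_constant_values(self, values: np.ndarray) -> None:
        consts = self.constants()
        if len(values) != len(consts):
            raise ValueError("constant vector length mismatch")
        for c, v in zip(consts, values):
            c.value = float(v)

    def nodes(self) -> list[Node]:
        out = []

        def walk(n: Node):
            out.append(n)
            for c in n.children():
                walk(c)
        walk(self.root)
        return out

    def to_prefix(self) -> str:
        def walk(n: Node) -> str:
            if isinstance(n, Constant):
                return f"c:{n.value!r}"
            if isinstance(n, Variable):
                return f"v:{n.index}"
            if isinstance(n, UnaryOp):
                return f"({n.op} {walk(n.child)})"
            return f"({n.op} {walk(n.left)} {walk(n.right)})"
        return walk(self.root)

    def __str__(self):
        return str(self.root)


def parse_prefix(text: str, var_names: tuple[str, ...]) -> Expression:
    """Inverse of ``Expression.to_prefix``."""
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse() -> Node:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            op = tokens[pos]
            pos += 1
            if op in _UNARY:
                node = UnaryOp(op, parse())
            else:
                node = BinaryOp(op, parse(), parse())
            assert tokens[pos] == ")"
            pos += 1
            return node
        if tok.startswith("c:"):
            return Constant(float(tok[2:]))
        if tok.startswith("v:"):
            i = int(tok[2:])
            return Variable(i, var_names[i] if i < len(var_names) else "")
        raise ValueError(f"bad token {tok!r}")

    return Expression(parse(), var_names)


@dataclass
class ExpressionModel:
    """An expression with its fitted loss bookkeeping."""

    expression: Expression
    fitness: float = np.inf
    train_loss: float = np.inf
    validation_loss: float | None = None

    @property
    def complexity(self) -> int:
        return self.expression.complexity


# ---------------------------------------------------------------- loss / fit

def _raw_nll(expr: Expression, X: np.ndarray, s: np.ndarray) -> float:
    q, valid = expr.evaluate(X)
    s = np.asarray(s, float)
    nll = float(np.sum(_softplus(s[valid] * q[valid])))
    return nll + SENTINEL_PENALTY * float(np.sum(~valid))


def regularized_loss(expr: Expression, X: np.ndarray, s: np.ndarray,
                     lam: float) -> float:
    """-log L + lambda * C with the sentinel penalty for invalid rows."""
    if np.asarray(X).size == 0:
        raise ValueError("empty training data")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return _raw_nll(expr, X, s) + lam * expr.complexity


def optimize_constants(expr: Expression, X: np.ndarray, s: np.ndarray,
                       rng: np.random.Generator | int = 0,
                       maxiter: int = 200, n_restarts: int = 3) -> Expression:
    """Fit the expression's constants by quasi-Newton minimization of the NLL.

    Returns a copy with fitted constants; the loss never exceeds the loss at
    the incoming constants.  Non-finite starts fall back to seeded random
    restarts (bounded).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    expr = expr.copy()
    consts = expr.constants()
    if not consts:
        return expr
    X = np.atleast_2d(np.asarray(X, float))
    s = np.asarray(s, float)

    def objective(vec):
        expr.set_constant_values(vec)
        return _raw_nll(expr, X, s)

    x0 = expr.get_constant_values()
    best_val, best_vec = objective(x0), x0.copy()
    starts = [x0] + [rng.normal(scale=1.0, size=x0.shape) for _ in range(n_restarts)]
    for k, start in enumerate(starts):
        if not np.isfinite(objective(start)):
            continue
        res = minimize(objective, start, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_vec = res.fun, res.x.copy()
        if k == 0 and best_val < objective(x0) * 0.999 + 1e-12:
            break  # the warm start already converged well; skip restarts
    expr.set_constant_values(best_vec)
    return expr


# ---------------------------------------------------------------- evolution

@dataclass(frozen=True)
class SymRegConfig:
    lam: float = 1e-4
    n_offspring: int = 4
    generations: int = 200
    unary_ops: tuple[str, ...] = ("neg", "exp", "log")
    binary_ops: tuple[str, ...] = ("+", "-", "*", "/")
    max_depth: int = 4
    max_nodes: int = 24  # offspring larger than this are discarded
    const_scale: float = 1.0
    optimizer_maxiter: int = 100
    optimizer_restarts: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.n_offspring < 1 or self.generations < 1:
            raise ValueError("n_offspring and generations must be >= 1")


def random_expression(var_names: tuple[str, ...], config: SymRegConfig,
                      rng: np.random.Generator, depth: int | None = None) -> Expression:
    depth = config.max_depth if depth is None else depth

    def grow(d: int) -> Node:
        if d <= 0 or rng.random() < 0.3:
            if rng.random() < 0.5 and var_names:
                return Variable(int(rng.integers(len(var_names))),
                                var_names[int(rng.integers(len(var_names)))])
            return Constant(float(rng.normal(scale=config.const_scale)))
        if config.unary_ops and rng.random() < 0.25:
            return UnaryOp(str(rng.choice(config.unary_ops)), grow(d - 1))
        op = str(rng.choice(config.binary_ops))
        return BinaryOp(op, grow(d - 1), grow(d - 1))

    # leaves drawn independently above can desync index/name; fix up
    root = grow(depth)
    expr = Expression(root, var_names)
    for n in expr.nodes():
        if isinstance(n, Variable):
            n.name = var_names[n.index]
    return expr


def _mutate(expr: Expression, config: SymRegConfig,
            rng: np.random.Generator) -> Expression:
    """One random structural change: operator swap, subtree replacement or
    constant injection."""
    out = expr.copy()
    nodes = out.nodes()
    kind = rng.random()
    if kind < 0.4:  # operator swap (same arity)
        ops = [n for n in nodes if n.arity]
        if ops:
            n = ops[int(rng.integers(len(ops)))]
            if isinstance(n, UnaryOp):
                n.op = str(rng.choice(config.unary_ops))
            else:
                n.op = str(rng.choice(config.binary_ops))
            return out
    if kind < 0.75:  # replace a random subtree with a fresh shallow one
        target = nodes[int(rng.integers(len(nodes)))]
        repl = random_expression(out.var_names, config, rng, depth=2).root
        if target is out.root:
            out.root = repl
        else:
            for n in out.nodes():
                if isinstance(n, UnaryOp) and n.child is target:
                    n.child = repl
                    break
                if isinstance(n, BinaryOp):
                    if n.left is target:
                        n.left = repl
                        break
                    if n.right is target:
                        n.right = repl
                        break
        return out
    # constant injection: wrap a random node additively or multiplicatively
    target = nodes[int(rng.integers(len(nodes)))]
    op = "+" if rng.random() < 0.5 else "*"
    wrapped = BinaryOp(op, target.copy(), Constant(float(rng.normal(scale=config.const_scale))))
    if target is out.root:
        out.root = wrapped
    else:
        for n in out.nodes():
            if isinstance(n, UnaryOp) and n.child is target:
                n.child = wrapped
                break
            if isinstance(n, BinaryOp):
                if n.left is target:
                    n.left = wrapped
                    break
                if n.right is target:
                    n.right = wrapped
                    break
    return out


def _fit_constant_model(X: np.ndarray, s: np.ndarray,
                        var_names: tuple[str, ...]) -> Expression:
    """Closed-form best constant log-predictor (the guard candidate)."""
    s = np.asarray(s, float)
    p_B = np.clip(np.mean(s == -1), 1e-9, 1 - 1e-9)
    return Expression(Constant(float(np.log(p_B / (1 - p_B)))), var_names)


@dataclass
class EvolveResult:
    best: ExpressionModel
    history: np.ndarray  # best fitness per generation (monotone nonincreasing)
    evaluated: list[ExpressionModel]
    stagnant_generations: int = 0


def evolve(X: np.ndarray, s: np.ndarray, var_names: tuple[str, ...],
           config: SymRegConfig = SymRegConfig(),
           initial: Expression | None = None) -> EvolveResult:
    """(N+1) evolution strategy over expression trees, fully seeded.

    The fitted best-constant model is always part of the comparison, so the
    returned expression is never worse (in regularized loss) than predicting
    a single number.
    """
    rng = np.random.default_rng(config.seed)
    X = np.atleast_2d(np.asarray(X, float))
    s = np.asarray(s, float)

    def model_of(expr: Expression) -> ExpressionModel:
        fitted = optimize_constants(expr, X, s, rng=rng,
                                    maxiter=config.optimizer_maxiter,
                                    n_restarts=config.optimizer_restarts)
        train = _raw_nll(fitted, X, s)
        return ExpressionModel(fitted, fitness=train + config.lam * fitted.complexity,
                               train_loss=train)

    guard = model_of(_fit_constant_model(X, s, var_names))
    parent = model_of(initial) if initial is not None else \
        model_of(random_expression(var_names, config, rng))
    if guard.fitness < parent.fitness:
        parent = guard
    evaluated = [guard, parent]
    history = np.empty(config.generations)
    stagnant = 0
    for g in range(config.generations):
        offspring = []
        for _ in range(config.n_offspring):
            try:
                mutant = _mutate(parent.expression, config, rng)
                if len(mutant.nodes()) > config.max_nodes:
                    continue  # size cap keeps the search in compact forms
                child = model_of(mutant)
            except (ValueError, FloatingPointError):
                continue
            offspring.append(child)
        if not offspring:
            stagnant += 1
        evaluated.extend(offspring)
        for child in offspring:
            if child.fitness < parent.fitness:
                parent = child
        history[g] = parent.fitness
    if guard.fitness < parent.fitness:
        parent = guard
    return EvolveResult(parent, history, evaluated, stagnant)


# ---------------------------------------------------------------- pareto

def pareto_front(losses: np.ndarray, complexities: np.ndarray) -> tuple[np.ndarray, int]:
    """Non-dominated candidates under (loss down, complexity down).

    Returns (front indices sorted by complexity, knee position within the
    front).  The knee is the front point of maximal perpendicular distance
    to the chord through the front's endpoints in normalized (C, loss)
    coordinates — a suggestion; the whole front is returned.
    """
    losses = np.asarray(losses, float)
    C = np.asarray(complexities, float)
    if losses.size == 0:
        raise ValueError("no candidates")
    n = losses.size
    dominated = np.zeros(n, bool)
    for i in range(n):
        dominated[i] = np.any((losses <= losses[i]) & (C <= C[i])
                              & ((losses < losses[i]) | (C < C[i])))
    front = np.flatnonzero(~dominated)
    front = front[np.argsort(C[front], kind="stable")]
    if front.size <= 2:
        return front, int(front.size - 1)
    cx, cy = C[front], losses[front]
    sx = (cx - cx[0]) / max(cx[-1] - cx[0], 1e-300)
    sy = (cy - cy[0]) / max(abs(cy[-1] - cy[0]), 1e-300)
    # chord from first (simplest) to last (most accurate) front point
    d = np.abs(sy - sy[-1] * sx) / np.sqrt(1.0 + sy[-1] ** 2)
    return front, int(np.argmax(d))


# ---------------------------------------------------------------- worked forms

def polymer_folding_expression() -> Expression:
    """Distilled committor of homopolymer coil-to-crystal folding:

        q_B(U, Q6) = alpha (U - U0) + beta log(Q6 - Q6,0) + gamma

    with alpha = -7.144, beta = 3.269, gamma = 11.942, U0 = -2.351 and
    Q6,0 = 0.035 (U: polymer potential energy, Q6: global crystallinity).
    Complexity 7 under the operator-counting convention used here.
    """
    U, Q6 = Variable(0, "U"), Variable(1, "Q6")
    root = BinaryOp(
        "+",
        BinaryOp(
            "+",
            BinaryOp("*", Constant(-7.144), BinaryOp("-", U, Constant(-2.351))),
            BinaryOp("*", Constant(3.269),
                     UnaryOp("log", BinaryOp("-", Q6, Constant(0.035)))),
        ),
        Constant(11.942),
    )
    return Expression(root, ("U", "Q6"))


def mga2_contact_expression() -> Expression:
    """Distilled committor of transmembrane-dimer assembly in terms of two
    switched interhelical contacts:

        q_B(x9, x22) = -exp(x9^2) * log(x9 - x9 / log(x22)).
    """
    x9, x22 = Variable(0, "x9"), Variable(1, "x22")
    root = UnaryOp(
        "neg",
        BinaryOp(
            "*",
            UnaryOp("exp", BinaryOp("*", x9.copy(), x9.copy())),
            UnaryOp("log", BinaryOp("-", x9.copy(),
                                    BinaryOp("/", x9.copy(), UnaryOp("log", x22)))),
        ),
    )
    return Expression(root, ("x9", "x22"))
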