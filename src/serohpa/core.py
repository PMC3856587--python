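"""Generic synchronous Boolean network (SBN) engine.

A Boolean network is a set of N named nodes, each holding a binary value
(1 = active, 0 = inactive).  Every node has an ordered list of input nodes
(in-degree ``k``, at least 1) and a truth table of length ``2**k`` giving its
next value for each combination of current input values.  All nodes are
updated simultaneously at each discrete time step (synchronous update).
Because the state space is finite and the update deterministic, every
trajectory eventually enters a cycle (the *attractor*; period 1 is a fixed
point).

Conventions
-----------
* A *state* is a 1-D ``numpy`` array of 0/1 values, position ``i`` holding
  node ``i``'s value.  A *trajectory* is a 2-D array of shape ``(T+1, N)``
  whose row ``t`` is the state at time ``t``.
* Truth tables are indexed little-endian in the listed input order: for a
  node with inputs ``(j0, j1, ..., j_{k-1})`` and current state ``s``, the
  next value is ``table[s[j0]*1 + s[j1]*2 + ... + s[j_{k-1}]*2**(k-1)]``.
* *Clamped* nodes (environmental inputs, and in-silico knockouts) copy their
  value from the current state instead of consulting a rule; they stay at
  whatever value the initial state gives them.

The module also provides a line-oriented text format for networks (one
Boolean expression per node, BoolNet-flavored), a JSON dialect, and the
normalized Hamming distance used as the divergence statistic between paired
trajectories.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidRuleError",
    "NetworkFormatError",
    "BooleanNetwork",
    "AttractorResult",
    "evaluate_node",
    "step",
    "step_batch",
    "simulate",
    "simulate_batch",
    "find_attractor",
    "normalized_hamming",
    "parse_bnet",
    "read_bnet",
    "write_bnet",
    "network_to_json",
    "network_from_json",
    "trajectory_frame",
]


class InvalidRuleError(ValueError):
    """A truth table is inconsistent with its node's in-degree."""


class NetworkFormatError(ValueError):
    """A network definition (text or JSON) could not be parsed."""


# ---------------------------------------------------------------------------
# Network representation
# ---------------------------------------------------------------------------


def _as_state(x: Sequence[int] | np.ndarray, n: int | None = None) -> np.ndarray:
    s = np.asarray(x, dtype=np.uint8)
    if s.ndim != 1:
        raise ValueError(f"state must be 1-D, got shape {s.shape}")
    if n is not None and s.shape[0] != n:
        raise ValueError(f"state length {s.shape[0]} != network size {n}")
    if s.size and s.max() > 1:
        raise ValueError("state entries must be 0 or 1")
    return s


@dataclass(eq=False)
class BooleanNetwork:
    """A synchronous Boolean network.

    Parameters
    ----------
    nodes
        Ordered node identifiers (length N).
    inputs
        Per-node ordered input indices; ``inputs[i]`` has length ``k_i >= 1``.
    truth_tables
        Per-node bit sequence of length ``2**k_i`` (little-endian indexing in
        the listed input order).
    clamped
        Indices of nodes whose value is held fixed at its current value;
        their truth tables are never consulted.
    """

    nodes: list[str]
    inputs: list[np.ndarray]
    truth_tables: list[np.ndarray]
    clamped: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise NetworkFormatError("duplicate node names")
        if len(self.inputs) != n or len(self.truth_tables) != n:
            raise NetworkFormatError("inputs/truth_tables length != node count")
        self.inputs = [np.asarray(ix, dtype=np.intp) for ix in self.inputs]
        self.truth_tables = [
            np.asarray(tt, dtype=np.uint8) for tt in self.truth_tables
        ]
        for i, (ix, tt) in enumerate(zip(self.inputs, self.truth_tables)):
            if ix.ndim != 1 or ix.size < 1:
                raise NetworkFormatError(f"node {self.nodes[i]}: needs >= 1 input")
            if ix.min() < 0 or ix.max() >= n:
                raise NetworkFormatError(f"node {self.nodes[i]}: input out of range")
            if tt.shape[0] != 1 << ix.size:
                raise InvalidRuleError(
                    f"node {self.nodes[i]}: table length {tt.shape[0]} != 2^{ix.size}"
                )
            if tt.size and tt.max() > 1:
                raise InvalidRuleError(f"node {self.nodes[i]}: table entries not 0/1")
        self.clamped = frozenset(int(c) for c in self.clamped)
        if self.clamped and (min(self.clamped) < 0 or max(self.clamped) >= n):
            raise NetworkFormatError("clamped index out of range")
        self._index = {name: i for i, name in enumerate(self.nodes)}
        # column sum of the wiring-count matrix must equal each node's k
        cm = self.connection_matrix()
        if not np.array_equal(cm.sum(axis=0), self.in_degrees()):
            raise NetworkFormatError("connection-matrix column sums != k")
        self._free = np.array(
            [i for i in range(n) if i not in self.clamped], dtype=np.intp
        )
        self._weights = [
            (np.uint64(1) << np.arange(ix.size, dtype=np.uint64)).astype(np.int64)
            for ix in self.inputs
        ]

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def in_degrees(self) -> np.ndarray:
        return np.array([ix.size for ix in self.inputs], dtype=np.intp)

    @property
    def k_max(self) -> int:
        return int(self.in_degrees().max())

    def connection_matrix(self) -> np.ndarray:
        """N x N wiring-count matrix: entry (i, j) = number of connections
        from node i into node j.  Column sums equal each node's in-degree."""
        n = len(self.nodes)
        cm = np.zeros((n, n), dtype=np.intp)
        for j, ix in enumerate(self.inputs):
            for i in ix:
                cm[i, j] += 1
        return cm

    def padded_rules_matrix(self, k_max: int | None = None) -> np.ndarray:
        """Export the per-node truth tables as a single ``2**k_max x N``
        rules matrix.

        Columns for nodes with fewer than ``k_max`` inputs are padded by
        replicating the table over the ignored high-order input slots, so
        row ``r`` of column ``i`` holds ``truth_tables[i][r % 2**k_i]``.
        """
        k = self.k_max if k_max is None else int(k_max)
        if k < self.k_max:
            raise ValueError(f"k_max {k} < maximum in-degree {self.k_max}")
        return np.column_stack(
            [np.tile(tt, 1 << (k - ix.size)) for ix, tt in zip(self.inputs, self.truth_tables)]
        )

    # -- derived networks ---------------------------------------------------

    def with_clamped(self, names: Iterable[str]) -> "BooleanNetwork":
        """A copy of the network with the given nodes additionally clamped."""
        extra = {self.index(n) for n in names}
        return BooleanNetwork(
            nodes=list(self.nodes),
            inputs=[ix.copy() for ix in self.inputs],
            truth_tables=[tt.copy() for tt in self.truth_tables],
            clamped=self.clamped | extra,
        )


# ---------------------------------------------------------------------------
# Update semantics
# ---------------------------------------------------------------------------


def evaluate_node(
    truth_table: Sequence[int] | np.ndarray, input_bits: Sequence[int] | np.ndarray
) -> int:
    """Next value of a single node given its current input bits.

    The table index is the little-endian binary encoding of ``input_bits``
    (the first listed input is the least-significant bit).
    """
    tt = np.asarray(truth_table, dtype=np.uint8)
    bits = _as_state(input_bits)
    if tt.shape[0] != 1 << bits.shape[0]:
        raise InvalidRuleError(
            f"table length {tt.shape[0]} != 2^{bits.shape[0]} for {bits.shape[0]} inputs"
        )
    idx = int(bits.astype(np.int64) @ (1 << np.arange(bits.shape[0], dtype=np.int64)))
    return int(tt[idx])


def step(net: BooleanNetwork, s: Sequence[int] | np.ndarray) -> np.ndarray:
    """One synchronous update: every non-clamped node reads *all* its inputs
    from ``s`` and takes its truth-table value; clamped nodes copy ``s``."""
    s = _as_state(s, net.n_nodes)
    out = s.copy()
    for i in net._free:
        idx = s[net.inputs[i]].astype(np.int64) @ net._weights[i]
        out[i] = net.truth_tables[i][idx]
    return out


def step_batch(net: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Synchronous update applied row-wise to an ``(m, N)`` array of states."""
    states = np.asarray(states, dtype=np.uint8)
    if states.ndim != 2 or states.shape[1] != net.n_nodes:
        raise ValueError(f"expected (m, {net.n_nodes}) array, got {states.shape}")
    out = states.copy()
    for i in net._free:
        idx = states[:, net.inputs[i]].astype(np.int64) @ net._weights[i]
        out[:, i] = net.truth_tables[i][idx]
    return out


def simulate(
    net: BooleanNetwork, s0: Sequence[int] | np.ndarray, T: int
) -> np.ndarray:
    """Trajectory of ``T + 1`` states (rows), ``states[0]`` being ``s0``."""
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    s = _as_state(s0, net.n_nodes)
    traj = np.empty((T + 1, net.n_nodes), dtype=np.uint8)
    traj[0] = s
    for t in range(T):
        s = step(net, s)
        traj[t + 1] = s
    return traj


def simulate_batch(net: BooleanNetwork, states0: np.ndarray, T: int) -> np.ndarray:
    """Batched trajectories: ``(T + 1, m, N)`` from ``m`` initial states."""
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    states0 = np.asarray(states0, dtype=np.uint8)
    traj = np.empty((T + 1,) + states0.shape, dtype=np.uint8)
    traj[0] = states0
    for t in range(T):
        traj[t + 1] = step_batch(net, traj[t])
    return traj


@dataclass
class AttractorResult:
    """Transient length plus the repeating cycle of states.

    ``transient_length`` is the first time index at which the cycle is
    entered; ``cycle`` is a ``(period, N)`` array of the distinct states of
    the cycle in visit order.
    """

    transient_length: int
    cycle: np.ndarray

    @property
    def period(self) -> int:
        return int(self.cycle.shape[0])

    @property
    def recurrence_time(self) -> int:
        """First time step at which a previously visited state recurs
        (= transient length + period): the span of the run that shows the
        full cyclic pattern once."""
        return self.transient_length + self.period


def find_attractor(
    net: BooleanNetwork,
    s0: Sequence[int] | np.ndarray,
    max_steps: int = 10_000,
) -> AttractorResult | None:
    """Simulate until a previously visited state recurs.

    Bookkeeping is a hash map from state to first-seen time, so transient
    and period are exact.  Returns ``None`` (an explicit not-found outcome,
    not an error) if no recurrence happens within ``max_steps`` updates.
    """
    if max_steps < 1:
        raise ValueError(f"max_steps must be >= 1, got {max_steps}")
    s = _as_state(s0, net.n_nodes)
    seen: dict[bytes, int] = {}
    visited: list[np.ndarray] = []
    for t in range(max_steps + 1):
        key = s.tobytes()
        if key in seen:
            t0 = seen[key]
            return AttractorResult(
                transient_length=t0, cycle=np.array(visited[t0:], dtype=np.uint8)
            )
        seen[key] = t
        visited.append(s)
        if t == max_steps:
            break
        s = step(net, s)
    return None


# ---------------------------------------------------------------------------
# Divergence statistic
# ---------------------------------------------------------------------------


def normalized_hamming(
    a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray
) -> float:
    """Fraction of positions at which two equal-length bit vectors differ."""
    a = _as_state(a)
    b = _as_state(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return float(np.mean(a != b))


# ---------------------------------------------------------------------------
# Text format (BoolNet-flavored)
# ---------------------------------------------------------------------------
#
#   # comment
#   targets, factors
#   NODE, <expression over node names using & | ! and parentheses>
#
# A node whose expression is exactly its own name is an environmental input
# and is clamped.  Expressions may otherwise reference any node, including
# the target itself (e.g. persistence terms).

_TOKEN_RE = re.compile(r"\s*(?:([A-Za-z_][A-Za-z0-9_]*)|([()&|!]))")
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _tokenize(expr: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            raise NetworkFormatError(f"bad token at {expr[pos:]!r} in {expr!r}")
        tokens.append(m.group(1) or m.group(2))
        pos = m.end()
    return tokens


def _parse_expr(tokens: list[str], expr: str):
    """Recursive-descent parse to a nested-tuple AST:
    ('var', name) | ('not', x) | ('and', x, y) | ('or', x, y)."""
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(expected=None):
        nonlocal pos
        tok = peek()
        if tok is None or (expected is not None and tok != expected):
            raise NetworkFormatError(f"unexpected end/token near {tok!r} in {expr!r}")
        pos += 1
        return tok

    def factor():
        tok = peek()
        if tok == "!":
            take()
            return ("not", factor())
        if tok == "(":
            take()
            node = disjunction()
            take(")")
            return node
        if tok is None or tok in "&|)":
            raise NetworkFormatError(f"expected operand in {expr!r}")
        return ("var", take())

    def conjunction():
        node = factor()
        while peek() == "&":
            take()
            node = ("and", node, factor())
        return node

    def disjunction():
        node = conjunction()
        while peek() == "|":
            take()
            node = ("or", node, conjunction())
        return node

    ast = disjunction()
    if peek() is not None:
        raise NetworkFormatError(f"trailing tokens in {expr!r}")
    return ast


def _ast_vars(ast, out: list[str]) -> None:
    if ast[0] == "var":
        if ast[1] not in out:
            out.append(ast[1])
    elif ast[0] == "not":
        _ast_vars(ast[1], out)
    else:
        _ast_vars(ast[1], out)
        _ast_vars(ast[2], out)


def _ast_eval(ast, env: dict[str, int]) -> int:
    op = ast[0]
    if op == "var":
        return env[ast[1]]
    if op == "not":
        return 1 - _ast_eval(ast[1], env)
    if op == "and":
        return _ast_eval(ast[1], env) & _ast_eval(ast[2], env)
    return _ast_eval(ast[1], env) | _ast_eval(ast[2], env)


def compile_expression(expr: str) -> tuple[list[str], np.ndarray]:
    """Compile a Boolean expression to ``(input_names, truth_table)``.

    Input order is the order of first appearance in the expression; the
    truth table is indexed little-endian in that order.
    """
    ast = _parse_expr(_tokenize(expr), expr)
    names: list[str] = []
    _ast_vars(ast, names)
    k = len(names)
    table = np.empty(1 << k, dtype=np.uint8)
    for m in range(1 << k):
        env = {name: (m >> j) & 1 for j, name in enumerate(names)}
        table[m] = _ast_eval(ast, env)
    return names, table


def parse_bnet(text: str) -> BooleanNetwork:
    """Parse the line-oriented network format (see module docstring)."""
    rules: list[tuple[str, str]] = []
    saw_header = False
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not saw_header:
            head = [p.strip().lower() for p in line.split(",")]
            if head != ["targets", "factors"]:
                raise NetworkFormatError("first line must be 'targets, factors'")
            saw_header = True
            continue
        target, _, expr = line.partition(",")
        target, expr = target.strip(), expr.strip()
        if not _NAME_RE.match(target) or not expr:
            raise NetworkFormatError(f"bad rule line {raw!r}")
        rules.append((target, expr))
    if not saw_header:
        raise NetworkFormatError("missing 'targets, factors' header")
    if not rules:
        raise NetworkFormatError("no rules")
    names = [t for t, _ in rules]
    order = {name: i for i, name in enumerate(names)}
    if len(order) != len(names):
        raise NetworkFormatError("duplicate target")
    inputs, tables, clamped = [], [], set()
    for i, (target, expr) in enumerate(rules):
        in_names, table = compile_expression(expr)
        unknown = [n for n in in_names if n not in order]
        if unknown:
            raise NetworkFormatError(f"rule for {target} uses unknown node {unknown[0]!r}")
        if expr == target:
            clamped.add(i)  # environmental input: NODE, NODE
        inputs.append(np.array([order[n] for n in in_names], dtype=np.intp))
        tables.append(table)
    return BooleanNetwork(names, inputs, tables, frozenset(clamped))


def read_bnet(path) -> BooleanNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_bnet(fh.read())


def _table_to_expression(node: str, in_names: list[str], table: np.ndarray) -> str:
    k = len(in_names)
    if table.min() == table.max():
        # constant rule: keep every input in the expression so wiring survives
        lead = in_names[0]
        tail = "".join(f" & {n}" for n in in_names[1:])
        if table[0] == 0:
            return f"{lead} & !{lead}{tail}"
        tail_or = "".join(f" | !{n}" for n in in_names[1:])
        return f"({lead} | !{lead}){tail}{tail_or}" if k > 1 else f"{lead} | !{lead}"
    minterms = []
    for m in range(1 << k):
        if table[m]:
            lits = [
                n if (m >> j) & 1 else f"!{n}" for j, n in enumerate(in_names)
            ]
            minterms.append("(" + " & ".join(lits) + ")" if k > 1 else lits[0])
    return " | ".join(minterms)


def write_bnet(net: BooleanNetwork) -> str:
    """Serialize a network to the text format.

    Clamped nodes are written as ``NODE, NODE``; other rules are written in
    disjunctive normal form over the node's inputs (first minterm lists the
    inputs in their stored order, so a round-trip preserves wiring, tables
    and the clamped set).
    """
    lines = ["targets, factors"]
    for i, name in enumerate(net.nodes):
        if i in net.clamped:
            lines.append(f"{name}, {name}")
            continue
        in_names = [net.nodes[j] for j in net.inputs[i]]
        lines.append(f"{name}, {_table_to_expression(name, in_names, net.truth_tables[i])}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON dialect and trajectory export
# ---------------------------------------------------------------------------


def network_to_json(net: BooleanNetwork) -> str:
    obj = {
        "nodes": list(net.nodes),
        "inputs": [ix.tolist() for ix in net.inputs],
        "truth_tables": [tt.tolist() for tt in net.truth_tables],
        "clamped": sorted(net.nodes[i] for i in net.clamped),
    }
    return json.dumps(obj, indent=1)


def network_from_json(text: str) -> BooleanNetwork:
    try:
        obj = json.loads(text)
        return BooleanNetwork(
            nodes=obj["nodes"],
            inputs=[np.asarray(ix, dtype=np.intp) for ix in obj["inputs"]],
            truth_tables=[np.asarray(tt, dtype=np.uint8) for tt in obj["truth_tables"]],
            clamped=frozenset(obj["nodes"].index(n) for n in obj.get("clamped", [])),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise NetworkFormatError(f"bad JSON network: {exc}") from exc


def trajectory_frame(net: BooleanNetwork, trajectory: np.ndarray) -> pd.DataFrame:
    """Trajectory as a DataFrame with one row per node and columns t0..tT."""
    traj = np.asarray(trajectory, dtype=np.uint8)
    return pd.DataFrame(
        traj.T, index=net.nodes, columns=[f"t{t}" for t in range(traj.shape[0])]
    )
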