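"""Unit and property tests for the synchronous Boolean network engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from serohpa.core import (
    BooleanNetwork,
    InvalidRuleError,
    NetworkFormatError,
    compile_expression,
    evaluate_node,
    find_attractor,
    network_from_json,
    network_to_json,
    normalized_hamming,
    parse_bnet,
    simulate,
    step,
    step_batch,
    trajectory_frame,
    write_bnet,
)
from serohpa.fixtures import RandomNetSpec, random_network

from oracles import exhaustive_attractor, full_transition_table, naive_hamming


# ---------------------------------------------------------------------------
# evaluate_node
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "table, bits, expected",
    [
        ((0, 0, 0, 0), (1, 0), 0),          # constant-zero rule
        ((0, 1, 1, 1), (0, 0), 0),          # OR rule
        ((0, 1, 1, 1), (1, 0), 1),
        # AND rule enumerated over all four input pairs
        ((0, 0, 0, 1), (0, 0), 0),
        ((0, 0, 0, 1), (1, 0), 0),
        ((0, 0, 0, 1), (0, 1), 0),
        ((0, 0, 0, 1), (1, 1), 1),
    ],
)
def test_evaluate_node_tables(table, bits, expected):
    assert evaluate_node(table, bits) == expected


def test_evaluate_node_little_endian():
    # table index = b0*1 + b1*2: table (0,1,0,0) fires only for b0=1, b1=0
    assert evaluate_node((0, 1, 0, 0), (1, 0)) == 1
    assert evaluate_node((0, 1, 0, 0), (0, 1)) == 0


def test_evaluate_node_length_mismatch():
    with pytest.raises(InvalidRuleError):
        evaluate_node((0, 1, 0), (1, 0))


# ---------------------------------------------------------------------------
# step / simulate
# ---------------------------------------------------------------------------


def test_step_synchronous_hand_example(not_copy_net):
    # A <- NOT B, B <- A from (1,1): both rules read the *old* state
    assert step(not_copy_net, [1, 1]).tolist() == [0, 1]


def test_step_identity_fixed_point(identity_net):
    for s in ([0, 0, 0], [1, 0, 1], [1, 1, 1]):
        assert step(identity_net, s).tolist() == list(s)


def test_step_clamped_node_holds_value():
    net = parse_bnet("targets, factors\nX, X\nY, X | Y\n")
    succ = step(net, [0, 1])
    assert succ[0] == 0  # clamped X copies its value
    succ = step(net, [1, 0])
    assert succ[0] == 1


def test_step_batch_matches_scalar(not_copy_net):
    states = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
    batch = step_batch(not_copy_net, states)
    for row_in, row_out in zip(states, batch):
        assert step(not_copy_net, row_in).tolist() == row_out.tolist()


def test_simulate_hand_trajectory(not_copy_net):
    traj = simulate(not_copy_net, [1, 1], 4)
    assert traj.tolist() == [[1, 1], [0, 1], [0, 0], [1, 0], [1, 1]]


def test_simulate_length_and_errors(identity_net):
    traj = simulate(identity_net, [1, 0, 1], 5)
    assert traj.shape == (6, 3)
    assert (traj == traj[0]).all()
    with pytest.raises(ValueError):
        simulate(identity_net, [1, 0, 1], -1)


def test_step_is_pure(not_copy_net):
    s = np.array([1, 0], dtype=np.uint8)
    a = step(not_copy_net, s)
    b = step(not_copy_net, s)
    assert a.tolist() == b.tolist()
    assert s.tolist() == [1, 0]  # input untouched


# ---------------------------------------------------------------------------
# find_attractor
# ---------------------------------------------------------------------------


def test_attractor_identity_fixed_point(identity_net):
    res = find_attractor(identity_net, [1, 0, 1])
    assert res.transient_length == 0
    assert res.period == 1


def test_attractor_period_four(not_copy_net):
    res = find_attractor(not_copy_net, [1, 1])
    assert res.transient_length == 0
    assert res.period == 4
    # applying the update to the last cycle state yields the first
    assert step(not_copy_net, res.cycle[-1]).tolist() == res.cycle[0].tolist()


def test_attractor_not_found_is_value(not_copy_net):
    assert find_attractor(not_copy_net, [1, 1], max_steps=2) is None
    with pytest.raises(ValueError):
        find_attractor(not_copy_net, [1, 1], max_steps=0)


@pytest.mark.parametrize("seed", range(8))
def test_attractor_matches_exhaustive_oracle_3_nodes(seed):
    net = random_network(RandomNetSpec(N=3, K=2, bias=0.5, seed=seed))
    table = full_transition_table(net)
    for code in range(8):
        s0 = np.array([(code >> i) & 1 for i in range(3)], dtype=np.uint8)
        want_t, want_cycle = exhaustive_attractor(net, s0, table)
        got = find_attractor(net, s0)
        assert got.transient_length == want_t
        assert got.cycle.tolist() == want_cycle.tolist()


# ---------------------------------------------------------------------------
# normalized Hamming distance
# ---------------------------------------------------------------------------


def test_hamming_basics():
    a = np.zeros(41, dtype=np.uint8)
    b = a.copy()
    assert normalized_hamming(a, b) == 0.0
    b[7] = 1
    assert normalized_hamming(a, b) == pytest.approx(1 / 41)
    assert normalized_hamming(1 - a, a) == 1.0
    with pytest.raises(ValueError):
        normalized_hamming([0, 1], [0, 1, 1])


@given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
def test_hamming_matches_naive_loop(x, y):
    a = np.array([(x >> i) & 1 for i in range(12)], dtype=np.uint8)
    b = np.array([(y >> i) & 1 for i in range(12)], dtype=np.uint8)
    assert normalized_hamming(a, b) == pytest.approx(naive_hamming(a, b))


@given(
    st.integers(0, 2**10 - 1), st.integers(0, 2**10 - 1), st.integers(0, 2**10 - 1)
)
def test_hamming_is_a_metric(x, y, z):
    bits = lambda v: np.array([(v >> i) & 1 for i in range(10)], dtype=np.uint8)
    a, b, c = bits(x), bits(y), bits(z)
    dab = normalized_hamming(a, b)
    assert dab >= 0.0
    assert (dab == 0.0) == (x == y)
    assert dab == normalized_hamming(b, a)
    assert normalized_hamming(a, c) <= dab + normalized_hamming(b, c)


# ---------------------------------------------------------------------------
# construction invariants, padded export
# ---------------------------------------------------------------------------


def test_invalid_table_length_rejected():
    with pytest.raises(InvalidRuleError):
        BooleanNetwork(["A", "B"], [[1], [0, 1]], [[0, 1], [0, 1]])


def test_connection_matrix_column_sums():
    net = random_network(RandomNetSpec(N=7, K=3, seed=1))
    cm = net.connection_matrix()
    assert (cm.sum(axis=0) == net.in_degrees()).all()


def test_padded_rules_matrix_semantics():
    net = parse_bnet("targets, factors\nA, A & B\nB, !A\n")
    padded = net.padded_rules_matrix(k_max=4)
    assert padded.shape == (16, 2)
    # padding replicates each table over the ignored high-order slots
    for r in range(16):
        assert padded[r, 0] == net.truth_tables[0][r % 4]
        assert padded[r, 1] == net.truth_tables[1][r % 2]
    with pytest.raises(ValueError):
        net.padded_rules_matrix(k_max=1)


# ---------------------------------------------------------------------------
# text and JSON formats
# ---------------------------------------------------------------------------


def test_compile_expression_input_order():
    names, table = compile_expression("B & !A")
    assert names == ["B", "A"]  # order of first appearance
    # index = B*1 + A*2: true only for B=1, A=0 -> index 1
    assert table.tolist() == [0, 1, 0, 0]


@pytest.mark.parametrize(
    "expr, truth",
    [
        ("A & B", [0, 0, 0, 1]),
        ("A | B", [0, 1, 1, 1]),
        ("!A", [1, 0]),
        ("A & !B | C & A", None),  # precedence: ! over & over |
        ("(A | B) & !(A & B)", None),  # xor via parentheses
    ],
)
def test_compile_expression_tables(expr, truth):
    names, table = compile_expression(expr)
    if truth is not None:
        assert table.tolist() == truth
    # cross-check against python eval on every assignment
    for m in range(1 << len(names)):
        env = {n: (m >> j) & 1 for j, n in enumerate(names)}
        py = expr.replace("!", " not ").replace("&", " and ").replace("|", " or ")
        assert table[m] == int(bool(eval(py, {}, env)))


@pytest.mark.parametrize("bad", ["A &", "A ) B", "A @ B", "", "A & (B"])
def test_malformed_expressions_rejected(bad):
    with pytest.raises(NetworkFormatError):
        compile_expression(bad)


def test_parse_bnet_errors():
    with pytest.raises(NetworkFormatError):
        parse_bnet("A, B\n")  # missing header
    with pytest.raises(NetworkFormatError):
        parse_bnet("targets, factors\nA, B\n")  # unknown node B
    with pytest.raises(NetworkFormatError):
        parse_bnet("targets, factors\nA, !A\nA, A\n")  # duplicate target


@pytest.mark.parametrize("seed", range(5))
def test_bnet_round_trip_random_networks(seed):
    net = random_network(RandomNetSpec(N=6, K=2, bias=0.4, seed=seed))
    back = parse_bnet(write_bnet(net))
    assert back.nodes == net.nodes
    assert back.clamped == net.clamped
    for ix_a, ix_b, tt_a, tt_b in zip(
        net.inputs, back.inputs, net.truth_tables, back.truth_tables
    ):
        assert sorted(ix_a.tolist()) == sorted(ix_b.tolist())
        # semantics must agree on every input assignment of the round-trip
    for code in range(1 << 6):
        s = np.array([(code >> i) & 1 for i in range(6)], dtype=np.uint8)
        assert step(net, s).tolist() == step(back, s).tolist()


def test_bnet_round_trip_preserves_clamping(catalog):
    back = parse_bnet(write_bnet(catalog.network))
    assert back.clamped == catalog.network.clamped
    s = np.ones(41, dtype=np.uint8)
    assert step(back, s).tolist() == step(catalog.network, s).tolist()


def test_json_round_trip(catalog):
    back = network_from_json(network_to_json(catalog.network))
    assert back.nodes == catalog.network.nodes
    assert back.clamped == catalog.network.clamped
    for a, b in zip(back.truth_tables, catalog.network.truth_tables):
        assert a.tolist() == b.tolist()


def test_trajectory_frame_layout(not_copy_net):
    traj = simulate(not_copy_net, [1, 1], 3)
    frame = trajectory_frame(not_copy_net, traj)
    assert list(frame.index) == ["A", "B"]
    assert list(frame.columns) == ["t0", "t1", "t2", "t3"]
    assert frame.loc["A"].tolist() == [1, 0, 0, 1]
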