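"""Independent brute-force oracles used to cross-check the engine.

The attractor oracle tabulates the *entire* 2^N transition graph and finds
transient and period by walking with visit times — no hashing shortcuts —
so it is an independent check of ``find_attractor``'s bookkeeping.
"""

import numpy as np

from serohpa.core import BooleanNetwork, step


def encode(state: np.ndarray) -> int:
    return int(sum(int(b) << i for i, b in enumerate(state)))


def decode(code: int, n: int) -> np.ndarray:
    return np.array([(code >> i) & 1 for i in range(n)], dtype=np.uint8)


def full_transition_table(net: BooleanNetwork) -> list[int]:
    """Successor of every one of the 2^N states."""
    n = net.n_nodes
    return [encode(step(net, decode(code, n))) for code in range(1 << n)]


def exhaustive_attractor(net: BooleanNetwork, s0: np.ndarray, table=None):
    """(transient_length, cycle_states) from the full transition graph."""
    if table is None:
        table = full_transition_table(net)
    code = encode(np.asarray(s0, dtype=np.uint8))
    seen: dict[int, int] = {}
    path: list[int] = []
    while code not in seen:
        seen[code] = len(path)
        path.append(code)
        code = table[code]
    t0 = seen[code]
    cycle = [decode(c, net.n_nodes) for c in path[t0:]]
    return t0, np.array(cycle, dtype=np.uint8)


def naive_hamming(a, b) -> float:
    """Positionwise-loop normalized Hamming distance."""
    assert len(a) == len(b)
    diff = 0
    for x, y in zip(a, b):
        if int(x) != int(y):
            diff += 1
    return diff / len(a)
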