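"""Synthetic Boolean networks for testing the engine independently of the
biological model.

:func:`random_network` builds classic N-K random Boolean networks (every
node gets K distinct inputs chosen uniformly — self-inputs allowed — and an
i.i.d. Bernoulli truth table), which exercise the simulator and the
stability machinery on networks with known construction invariants.
:func:`toy_paper_motif` is a 6-node abridgment of the depression model
(stress → CRH → ACTH → cortisol ⊣ TPH2 → 5-HT ⊣ TPH2) small enough to
verify by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BooleanNetwork, parse_bnet

__all__ = ["RandomNetSpec", "random_network", "toy_paper_motif"]


@dataclass(frozen=True)
class RandomNetSpec:
    """Parameters of a random N-K Boolean network.

    ``bias`` is the probability that a truth-table entry is 1.
    """

    N: int
    K: int
    bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.K <= self.N:
            raise ValueError(f"need 1 <= K <= N, got K={self.K}, N={self.N}")
        if self.K > 4:
            raise ValueError(f"K must be <= 4, got {self.K}")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError(f"bias must be in [0, 1], got {self.bias}")


def random_network(spec: RandomNetSpec) -> BooleanNetwork:
    """Seeded random N-K network satisfying the engine's construction
    invariants (exact table lengths, connection-matrix column sums = K)."""
    rng = np.random.default_rng(spec.seed)
    inputs = [
        np.sort(rng.choice(spec.N, size=spec.K, replace=False)) for _ in range(spec.N)
    ]
    tables = [
        (rng.random(1 << spec.K) < spec.bias).astype(np.uint8) for _ in range(spec.N)
    ]
    nodes = [f"n{i}" for i in range(spec.N)]
    return BooleanNetwork(nodes=nodes, inputs=inputs, truth_tables=tables)


_TOY = """\
targets, factors
stress, stress
CRH, stress
ACTH, CRH
CORT, ACTH
TPH2, !CORT & !HT5
HT5, TPH2
"""


def toy_paper_motif() -> BooleanNetwork:
    """6-node abridgment of the depression model.

    Under sustained stress the cortisol arm pins TPH2 (and hence 5-HT) off:
    from the all-on state the trajectory reaches the fixed point
    ``stress=CRH=ACTH=CORT=1, TPH2=HT5=0`` in two steps.  Without stress
    the TPH2 ⇄ 5-HT negative loop free-runs: from ``(0,1,1,1,1,1)`` the
    trajectory enters a period-4 cycle after a 3-step transient.
    """
    return parse_bnet(_TOY)
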