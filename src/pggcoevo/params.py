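"""Model parameters and mechanism variants.

All constants of the co-evolution model live in :class:`GameParams`:
the public-goods gain factor ``r``, the Fermi noise ``k_noise``, the
Poisson mean ``lam`` and weight ceiling ``m_max`` of the edge-breaking
rule, the isolated-node reconnection probability ``p_isolated``, and
the global edge cap (defaulting to the initial edge count N*k0/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum


class Variant(str, Enum):
    """Which edge-rule stages run in a Monte Carlo step.

    BASELINE        no edge dynamics (pure strategy evolution)
    BREAK_ONLY      edge breaking only (stage A)
    BREAK_ISOLATED  edge breaking + isolated-node reconnection (A + C)
    FULL            breaking + isolated + dominant-node reconnection
    """

    BASELINE = "BASELINE"
    BREAK_ONLY = "BREAK_ONLY"
    BREAK_ISOLATED = "BREAK_ISOLATED"
    FULL = "FULL"


#: stages ("A" break, "B" dominant reconnection, "C" isolated rejoin)
#: enabled by each variant
STAGES_BY_VARIANT: dict[Variant, frozenset[str]] = {
    Variant.BASELINE: frozenset(),
    Variant.BREAK_ONLY: frozenset("A"),
    Variant.BREAK_ISOLATED: frozenset("AC"),
    Variant.FULL: frozenset("ABC"),
}

_VALUE_MODES = ("edge_attributed", "node_total")
_ENTROPY_MODES = ("weight", "binned")
_ISOLATED_MODES = ("resample", "hold")
_UPDATE_MODES = ("sync", "async")


@dataclass(frozen=True)
class GameParams:
    """Full configuration of one simulation.

    Parameters
    ----------
    N : population size (nodes keep ids 0..N-1 for the whole run).
    k0 : initial regular degree; must be even and smaller than N.
    r : public-goods gain factor, > 1. The contribution cost is fixed
        at 1, so payoffs are in units of the cost.
    k_noise : Fermi imitation noise; 0 means fully rational updating.
    lam : mean of the Poisson CDF that maps breaking weight to a
        removal probability.
    m_max : ceiling of the integer breaking weight (floor is 0).
    p_isolated : probability that an isolated cooperator reconnects to
        the largest component in a given step.
    edge_cap : hard upper bound on the edge count; ``None`` means the
        initial edge count N*k0/2.
    variant : which edge-rule stages run (see :class:`Variant`).
    value_mode : how an edge's breaking value is computed.
        ``edge_attributed`` (default) sums the per-edge payoff
        attribution of both endpoints over both centered games;
        ``node_total`` sums the endpoints' full round payoffs.
    entropy_mode : ``binned`` (default; Shannon entropy of the
        histogram of rounded excess average degrees — starts at 0 on a
        regular graph and rises with heterogeneity, which is what makes
        it a usable onset indicator) or ``weight`` (per-node normalized
        rounded excess degrees; equals ln N on any regular graph).
    init_coop_fraction : probability that a node starts as cooperator.
    isolated_strategy : ``resample`` lets degree-0 nodes redraw C/D
        uniformly each step (so they can "choose to cooperate");
        ``hold`` freezes them.
    zero_value_satisfies : tie handling of the weight update. The
        default ``False`` counts a breaking value of exactly 0 — an
        edge that earns its endpoints nothing, the universal state of
        defector-only regions — as unsatisfying (+3), which lets dead
        regions keep fragmenting and cooperation re-emerge. ``True``
        counts 0 as satisfying (-1), under which full defection is an
        absorbing frozen state.
    isolated_target : whom a rejoining isolated cooperator attaches
        to inside the largest component: ``cooperator`` (default)
        picks a uniform cooperative member when one exists (falling
        back to any member), ``any`` picks a uniform member.
    update_mode : ``sync`` applies all Fermi adoptions simultaneously
        from the pre-update snapshot; ``async`` applies them in seeded
        node order (sensitivity checks only).
    stage_order : order in which active stages run inside a step.
    """

    N: int = 1000
    k0: int = 4
    r: float = 2.0
    k_noise: float = 0.1
    lam: float = 6.0
    m_max: int = 10
    p_isolated: float = 0.5
    edge_cap: int | None = None
    variant: Variant = Variant.FULL
    value_mode: str = "edge_attributed"
    entropy_mode: str = "binned"
    init_coop_fraction: float = 0.5
    isolated_strategy: str = "resample"
    zero_value_satisfies: bool = False
    isolated_target: str = "cooperator"
    update_mode: str = "sync"
    stage_order: tuple[str, ...] = ("A", "C", "B")

    def __post_init__(self) -> None:
        if self.k0 % 2 != 0:
            raise ValueError(f"k0 must be even, got {self.k0}")
        if not 0 < self.k0 < self.N:
            raise ValueError(f"need 0 < k0 < N, got k0={self.k0}, N={self.N}")
        if self.r <= 1:
            raise ValueError(f"gain factor r must exceed 1, got {self.r}")
        if self.k_noise < 0:
            raise ValueError("k_noise must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.m_max < 0:
            raise ValueError("m_max must be >= 0")
        if not 0 <= self.p_isolated <= 1:
            raise ValueError("p_isolated must lie in [0, 1]")
        if not 0 <= self.init_coop_fraction <= 1:
            raise ValueError("init_coop_fraction must lie in [0, 1]")
        if self.value_mode not in _VALUE_MODES:
            raise ValueError(f"value_mode must be one of {_VALUE_MODES}")
        if self.entropy_mode not in _ENTROPY_MODES:
            raise ValueError(f"entropy_mode must be one of {_ENTROPY_MODES}")
        if self.isolated_strategy not in _ISOLATED_MODES:
            raise ValueError(f"isolated_strategy must be one of {_ISOLATED_MODES}")
        if self.isolated_target not in ("cooperator", "any"):
            raise ValueError("isolated_target must be 'cooperator' or 'any'")
        if self.update_mode not in _UPDATE_MODES:
            raise ValueError(f"update_mode must be one of {_UPDATE_MODES}")
        if sorted(self.stage_order) != ["A", "B", "C"]:
            raise ValueError("stage_order must be a permutation of ('A','B','C')")
        object.__setattr__(self, "variant", Variant(self.variant))
        if self.edge_cap is None:
            object.__setattr__(self, "edge_cap", self.N * self.k0 // 2)
        elif self.edge_cap < 0:
            raise ValueError("edge_cap must be >= 0")

    @property
    def active_stages(self) -> frozenset[str]:
        return STAGES_BY_VARIANT[self.variant]

    def with_(self, **changes) -> "GameParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)
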