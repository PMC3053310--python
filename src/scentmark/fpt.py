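"""First-passage theory of the 1D two-animal system.

The boundary return time ``T_R`` — the mean time for a resident to
visit its territory boundary and come back — controls how often scent
marks are refreshed, and hence whether territories persist.  Two
analytically tractable limits bracket it:

* **Vanishing active scent time.**  With no lasting scent the two
  animals interact only on meeting, so the relevant variable is their
  *relative* separation.  Both walkers move at every time-step, so the
  separation changes by two lattice units with probability 1/4 each way
  and is unchanged with probability 1/2; on the periodic ring this
  two-unit walk relabels to a unit-step *lazy* walk on an ``M``-node
  cycle, ``M = L/2``.  On meeting the walkers reflect off each other,
  which requires remembering which way walker 1 moved into the meeting;
  the meeting node is therefore split into an entry ("walker 1 just
  moved left", reflecting) and an exit ("walker 1 just moved right",
  absorbing) copy.  ``T_R`` is twice the mean first-passage time from
  the entry to the exit copy, and ``T_R / (L/2)^2 -> 4`` as ``L``
  grows (exactly ``4 (1 - 1/L)`` at finite ``L``; the normalization is
  the squared per-animal span ``L/N``).

* **Permanent scent.**  Territories freeze where the two scent profiles
  first meet; each resident then bounces inside a fixed segment.  For a
  random walk on a segment of ``s`` sites the mean first-passage time
  from the reflecting to the absorbing edge is ``s**2``, so a full
  boundary round trip takes ``2 s**2`` and ``T_R`` is obtained by
  averaging ``(2 s1^2 + 2 s2^2) / 2`` over the stochastic distribution
  of frozen territory sizes ``(s1, s2)``.  Size fluctuations around the
  even split ``L/2`` push the coefficient slightly above 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SimConfig

__all__ = [
    "TransitionModel",
    "ReturnTimeEstimate",
    "build_relative_master_equation",
    "mean_first_passage",
    "evolve_distribution",
    "segment_traverse_mfpt",
    "segment_traverse_mfpt_exact",
    "boundary_return_time",
    "boundary_return_time_limit",
    "extrapolate_coefficient",
]


@dataclass
class TransitionModel:
    """Finite Markov chain with one absorbing target state."""

    L: int
    P: np.ndarray  # (n, n) row-stochastic
    start: int
    target: int
    labels: list[str]

    @property
    def n_states(self) -> int:
        return self.P.shape[0]


@dataclass
class ReturnTimeEstimate:
    """Boundary return time and its coefficient of proportionality.

    ``coefficient`` is ``T_R`` divided by the squared per-animal span
    ``(L / N)**2`` (two animals here); ``uncertainty`` is the standard
    error (0 for the exact master-equation regime).
    """

    L: int
    regime: str  # "small_tas" | "large_tas"
    T_R: float
    coefficient: float
    uncertainty: float
    n_replicates: int = 0


def build_relative_master_equation(L: int) -> TransitionModel:
    """Master equation for the separation of two mutually reflecting walkers.

    States: ``met+`` (just met, walker 1 moved left — the chain's start,
    from which the pair separates deterministically), the ``M - 1``
    strictly separated configurations (``M = L/2``), and the absorbing
    ``met-`` (just met, walker 1 moved right).  Rows sum to one; the
    target row is an identity row.

    ``L`` must be even and at least 4: on an odd ring the two-unit
    relative steps alias the whole lattice (a parity artefact with a
    four-fold different limit), and below 4 sites the start and target
    meeting states are not distinct.
    """
    if L < 4:
        raise ValueError("need L >= 4 for distinct start/target meeting states")
    if L % 2:
        raise ValueError(
            "L must be even: on an odd ring the relative walk aliases the "
            "full lattice and the return-time scaling changes"
        )
    M = L // 2
    n = M + 1  # met+ = 0, separations 1..M-1, met- = M
    P = np.zeros((n, n))
    P[0, 1] = 1.0  # forced separation after meeting
    for j in range(1, M):
        P[j, j] = 0.5
        P[j, j - 1] = 0.25  # j=1 -> met+ (reflecting entry)
        P[j, j + 1] = 0.25  # j=M-1 -> met- (absorbing exit)
    P[M, M] = 1.0
    labels = ["met+"] + [f"sep{2*j}" for j in range(1, M)] + ["met-"]
    return TransitionModel(L=L, P=P, start=0, target=M, labels=labels)


def mean_first_passage(model: TransitionModel, start: int | None = None) -> float:
    """Exact MFPT to the target via the linear system ``(I - Q) tau = 1``."""
    start = model.start if start is None else start
    n = model.n_states
    keep = np.arange(n) != model.target
    Q = model.P[np.ix_(keep, keep)]
    try:
        tau = np.linalg.solve(np.eye(Q.shape[0]) - Q, np.ones(Q.shape[0]))
    except np.linalg.LinAlgError as e:
        raise ValueError("target unreachable from some transient state") from e
    idx = np.flatnonzero(keep)
    return float(tau[np.searchsorted(idx, start)])


def evolve_distribution(model: TransitionModel, k: int, p0: np.ndarray | None = None) -> np.ndarray:
    """State distribution after ``k`` steps (default: started at ``start``)."""
    p = np.zeros(model.n_states) if p0 is None else np.asarray(p0, dtype=float).copy()
    if p0 is None:
        p[model.start] = 1.0
    for _ in range(k):
        p = p @ model.P
    return p


def segment_traverse_mfpt(length: int) -> float:
    """Mean first-passage time across a segment: reflecting -> absorbing edge.

    Closed form ``length**2`` for a nearest-neighbour walk.
    """
    if length < 1:
        raise ValueError("segment length must be >= 1")
    return float(length) ** 2


def segment_traverse_mfpt_exact(length: int) -> float:
    """Same quantity from an explicit master-equation solve (validation)."""
    n = length  # transient sites 0..length-1, absorb at `length`
    P = np.zeros((n + 1, n + 1))
    P[0, min(1, n)] = 1.0  # reflecting edge
    for j in range(1, n):
        P[j, j - 1] = 0.5
        P[j, j + 1] = 0.5
    P[n, n] = 1.0
    model = TransitionModel(L=length, P=P, start=0, target=n, labels=[])
    return mean_first_passage(model)


def boundary_return_time(L: int) -> float:
    """Exact small-``tas`` boundary return time, ``2 x`` the meeting MFPT.

    Equals ``L**2 - L`` (the closed form of the master-equation solve).
    """
    return 2.0 * mean_first_passage(build_relative_master_equation(L))


def boundary_return_time_limit(
    L: int,
    regime: str,
    replicates: int = 1000,
    seed: int = 0,
    max_steps: int | None = None,
) -> ReturnTimeEstimate:
    """Boundary return time in one of the two analytic limits.

    ``small_tas``: exact, from the relative-separation master equation.
    ``large_tas``: never-expiring scent is simulated from uniformly
    random initial positions until the territories freeze; the frozen
    sizes feed the segment first-passage law and ``T_R`` is averaged
    over replicates.
    """
    half = L / 2.0
    if regime == "small_tas":
        tr = boundary_return_time(L)
        return ReturnTimeEstimate(L, regime, tr, tr / half**2, 0.0)
    if regime != "large_tas":
        raise ValueError("regime must be 'small_tas' or 'large_tas'")
    sizes = frozen_territory_sizes(L, replicates, seed, max_steps)
    tr_each = sizes[:, 0] ** 2 + sizes[:, 1] ** 2  # mean of 2*s^2 over animals
    tr = float(np.mean(tr_each))
    err = float(np.std(tr_each, ddof=1) / math.sqrt(len(tr_each)))
    return ReturnTimeEstimate(
        L, regime, tr, tr / half**2, err / half**2, n_replicates=replicates
    )


def frozen_territory_sizes(
    L: int, replicates: int, seed: int = 0, max_steps: int | None = None
) -> np.ndarray:
    """Frozen (s1, s2) for two animals with permanent scent, (R, 2).

    Each replicate starts from two uniformly random distinct sites and
    runs until every site carries scent, after which the interface
    midpoints no longer move; the overlap interval is split at its
    midpoint between the two residents.
    """
    from ._kernels import step_chunk
    from .observables import pair_boundaries_1d
    from .sim import init_state

    if max_steps is None:
        max_steps = 200 * L * L
    out = np.empty((replicates, 2))
    empty_i = np.empty(0, dtype=np.int64)
    empty_p = np.zeros((1, 2, 2), dtype=np.int64)
    empty_s = np.zeros((0, 2, L), dtype=np.float64)

    def _advance(state, nsteps):
        R = state.rng.random((nsteps, 3, 2))
        step_chunk(
            state.pos, state.upos, state.heading, state.nsince,
            state.last_visit, np.int64(state.time), np.int64(nsteps),
            np.int64(L), np.int64(1), np.float64(np.inf), False, 0.5, 2.0,
            R, np.int64(0), empty_p, empty_p, empty_i, empty_s, np.int64(0),
        )
        state.time += nsteps

    for r in range(replicates):
        cfg = SimConfig(
            dims=1, L=L, N=2, tas=math.inf, T_max=max_steps,
            seed=seed + r, placement="random",
        )
        state = init_state(cfg)
        check = max(4 * L, 64)
        frozen = False
        while state.time < max_steps:
            _advance(state, check)
            if np.isfinite(state.last_visit).any(axis=0).all():
                frozen = True
                break
        if not frozen:
            raise RuntimeError(
                f"territories failed to freeze within {max_steps} steps (L={L})"
            )
        # a few extra steps let a zero-width abutment settle into overlap
        _advance(state, 2 * L)
        bl, br = pair_boundaries_1d(state.last_visit, state.time, cfg)
        if math.isnan(bl):
            raise RuntimeError("degenerate frozen interface")
        s0 = (br - bl) % L
        out[r] = (s0, L - s0)
    return out


def extrapolate_coefficient(Ls: np.ndarray, coeffs: np.ndarray) -> float:
    """Large-``L`` limit of a coefficient ladder by a fit linear in 1/L."""
    Ls = np.asarray(Ls, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    if Ls.size < 2:
        return float(coeffs[-1])
    A = np.vstack([np.ones_like(Ls), 1.0 / Ls]).T
    sol, *_ = np.linalg.lstsq(A, coeffs, rcond=None)
    return float(sol[0])
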