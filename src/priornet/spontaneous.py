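"""Spontaneous stage: synchronous recurrent dynamics under internal
currents only, fixed-point search, and classification of stable states
as retrieved patterns.

With the external current off, activity evolves as
x' = sign(J x / 2N) synchronously.  For symmetric J this parallel
dynamics terminates in a fixed point or a 2-cycle; only fixed points
count as attractors.  A stable state "conforms" when it equals the
pattern a stimulus nu would evoke — for sigmoidal tuning a step
pattern sign(nu − mu_i) over the sorted offsets, for periodic tuning a
contiguous half-ring sign(sin(2π(nu − mu_i))).  At finite N the
internal current of neurons near the step boundary is close to zero,
so stable states generically carry a small number of boundary defects
relative to the ideal conforming form (the defect fraction shrinks as
the network grows; conformity becomes exact only in the large-N,
large-tau limit).  Every recorded stable state is therefore labelled
with the nu of its nearest (minimum-Hamming) conforming pattern, and
the ``conforming`` flag records whether the match is exact.  The
scalar nu labels the attractor (the "retrieved pattern"); pattern
identity, not nu, is what distinguishes attractors.

Probing never mutates J or mu: plasticity and adaptation are off during
the spontaneous stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import PERIODIC, SIGMOIDAL, TuningConfig, sign_pm1

FIXED_POINT = "fixed_point"
CYCLE2 = "cycle2"
NO_CONVERGENCE = "no_convergence"

#: Default cap on synchronous updates; symmetric parallel dynamics is
#: observed to settle (fixed point or 2-cycle) well within 4N steps.
DEFAULT_MAX_STEPS_FACTOR = 4


@dataclass
class FixedPointResult:
    """Outcome of iterating the spontaneous dynamics from one start.

    ``steps`` counts synchronous updates applied when stability (or a
    2-cycle) was detected; an initial state that is already fixed
    reports steps = 1, because one update is needed to confirm it.
    """

    outcome: str
    pattern: np.ndarray | None
    steps: int


@dataclass(eq=False)
class AttractorRecord:
    """One stable state of the spontaneous dynamics.

    ``nu`` is the midpoint of the interval of stimulus values whose
    evoked pattern is nearest to ``pattern`` in Hamming distance;
    ``conforming`` is True iff the match is exact (the state equals the
    evoked pattern of some stimulus), in which case ``defects`` is 0.
    ``session`` is filled in by the experiment driver.
    """

    pattern: np.ndarray
    conforming: bool
    nu: float | None
    session: int | None = None
    steps: int | None = None
    defects: int | None = None


@dataclass
class AttractorCensus:
    """Stable states found by probing, with diagnostics kept separate.

    ``attractors`` holds every distinct stable fixed point reached from
    the conforming starts whose defect count does not exceed the census
    cap (states further from every retrieved pattern — most prominently
    the global sign-flip twins of step attractors, which are stable but
    not of the retrieved form — are counted in ``n_spurious`` instead).
    ``n_conforming`` counts census states matching a retrieved pattern
    exactly.  2-cycles and non-converged probes are never part of the
    census.
    """

    attractors: list[AttractorRecord]
    n_conforming: int
    n_spurious: int
    n_cycles: int
    n_no_convergence: int
    n_probes: int

    @property
    def nonconforming(self) -> list[np.ndarray]:
        """Patterns of census states that are not exactly conforming."""
        return [rec.pattern for rec in self.attractors if not rec.conforming]


def default_defect_cap(N: int) -> int:
    """Census cap on boundary defects, 2 * ceil(sqrt(N)).

    Near the step boundary the mean internal current vanishes linearly
    in the rank distance (slope ~ 1/N) while its finite-size noise is
    ~ 1/sqrt(N), so stable states carry O(sqrt(N)) defect neurons
    around the boundary.  Sign-flip twins and other non-retrieved
    stable states sit O(N) away from every retrieved pattern, far
    above the cap.
    """
    return 2 * int(np.ceil(np.sqrt(N)))


def internal_current(J: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Recurrent input (1/2N) J x; each component is bounded by (N−1)/2N."""
    J = np.asarray(J)
    x = np.asarray(x)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"J must be square, got shape {J.shape}")
    if x.shape[0] != J.shape[1]:
        raise ValueError(f"dimension mismatch: J is {J.shape}, x has length {x.shape[0]}")
    N = J.shape[0]
    return (J.astype(np.float64) @ x.astype(np.float64)) / (2.0 * N)


def step_spontaneous(J: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One synchronous update: all neurons read the same time slice."""
    return sign_pm1(internal_current(J, x))


def find_fixed_point(J: np.ndarray, x0: np.ndarray, max_steps: int | None = None) -> FixedPointResult:
    """Iterate the synchronous dynamics until a fixed point or 2-cycle."""
    N = np.asarray(x0).shape[0]
    if max_steps is None:
        max_steps = DEFAULT_MAX_STEPS_FACTOR * N
    if max_steps < 1:
        raise ValueError(f"max_steps must be >= 1, got {max_steps}")
    cur = np.asarray(x0, dtype=np.int8).copy()
    prev: np.ndarray | None = None
    for s in range(1, max_steps + 1):
        nxt = step_spontaneous(J, cur)
        if np.array_equal(nxt, cur):
            return FixedPointResult(FIXED_POINT, cur, s)
        if prev is not None and np.array_equal(nxt, prev):
            return FixedPointResult(CYCLE2, None, s)
        prev, cur = cur, nxt
    return FixedPointResult(NO_CONVERGENCE, None, max_steps)


def step_pattern(nu: float, mu: np.ndarray, tuning: TuningConfig) -> np.ndarray:
    """Pattern evoked by stimulus value ``nu``: the conforming form of stable states.

    Sigmoidal tuning gives sign(nu − mu_i) (a +1 prefix over sorted
    offsets); periodic tuning gives sign(sin(2π(nu − mu_i))) (a
    contiguous half-ring of +1 on the circle).
    """
    mu = np.asarray(mu, dtype=float)
    if tuning.kind == SIGMOIDAL:
        return sign_pm1(nu - mu)
    return sign_pm1(np.sin(2.0 * np.pi * (nu - mu)))


def periodic_candidate_nus(mu: np.ndarray) -> np.ndarray:
    """Midpoints of the circular intervals where the periodic pattern is constant.

    The pattern sign(sin(2π(nu − mu_i))) changes only when nu crosses an
    offset or an offset's antipode, so the breakpoints are
    {mu_i} ∪ {mu_i + 1/2 mod 1}; one representative nu per interval
    enumerates every realisable half-ring pattern.
    """
    mu = np.asarray(mu, dtype=float)
    b = np.sort(np.concatenate([np.mod(mu, 1.0), np.mod(mu + 0.5, 1.0)]))
    mids = 0.5 * (b[:-1] + b[1:])
    wrap = np.mod(0.5 * (b[-1] + b[0] + 1.0), 1.0)
    return np.concatenate([mids, [wrap]])


def _sigmoidal_nu(k: int, mu: np.ndarray) -> float:
    """Midpoint of the nu interval evoking the prefix-k step pattern.

    Interior intervals are (mu_k, mu_{k+1}); the boundary intervals are
    (0, mu_1) and (mu_N, 1).
    """
    N = mu.size
    lo = mu[k - 1] if k > 0 else 0.0
    hi = mu[k] if k < N else 1.0
    return 0.5 * (lo + hi)


def classify_attractor(
    x: np.ndarray,
    mu: np.ndarray,
    tuning: TuningConfig,
    session: int | None = None,
    steps: int | None = None,
) -> AttractorRecord:
    """Label a stable state with its nearest retrieved pattern.

    Sigmoidal: the nearest evoked pattern is the +1-prefix (over sorted
    offsets) minimising the Hamming distance; nu is the midpoint of its
    admissible interval (mu_k, mu_{k+1}), with boundary intervals
    (0, mu_1) and (mu_N, 1).  Periodic: nearest half-ring pattern, nu
    the midpoint of its admissible arc.  ``conforming`` is True iff the
    state equals the evoked pattern exactly (zero defects); ties in the
    nearest-pattern search break toward the smallest candidate index.
    """
    x = np.asarray(x, dtype=np.int8)
    mu = np.asarray(mu, dtype=float)
    N = mu.size
    if tuning.kind == SIGMOIDAL:
        # Hamming distance to the prefix-k pattern, for all k at once:
        # d(k) = #(minus entries before k) + #(plus entries from k on).
        is_plus = (x == 1).astype(np.int64)
        plus_before = np.concatenate([[0], np.cumsum(is_plus)])
        minus_before = np.arange(N + 1) - plus_before
        d = minus_before + (plus_before[-1] - plus_before)
        k = int(np.argmin(d))
        defects = int(d[k])
        return AttractorRecord(x, defects == 0, _sigmoidal_nu(k, mu),
                               session, steps, defects)
    cands = periodic_candidate_nus(mu)
    patterns = np.stack([step_pattern(nu, mu, tuning) for nu in cands], axis=1)
    d = (N - x.astype(np.int64) @ patterns.astype(np.int64)) // 2
    j = int(np.argmin(d))
    defects = int(d[j])
    return AttractorRecord(x, defects == 0, float(cands[j]), session, steps, defects)


def probe_patterns(mu: np.ndarray, tuning: TuningConfig) -> np.ndarray:
    """All distinct conforming patterns, as columns of an (N, P) int8 array.

    Sigmoidal tuning admits exactly N+1 step patterns (one per
    inter-offset interval of nu, plus the two boundary intervals);
    periodic tuning admits the half-ring rotations, enumerated from one
    nu per constant-pattern arc and de-duplicated.  Starting the
    spontaneous dynamics from every conforming pattern guarantees that
    every conforming attractor is found, since each is its own start.
    """
    mu = np.asarray(mu, dtype=float)
    N = mu.size
    if tuning.kind == SIGMOIDAL:
        rows = np.arange(N)[:, None]
        cols = np.arange(N + 1)[None, :]
        return np.where(rows < cols, 1, -1).astype(np.int8)
    cands = periodic_candidate_nus(mu)
    X = np.stack([step_pattern(nu, mu, tuning) for nu in cands], axis=1)
    _, first = np.unique(X, axis=1, return_index=True)
    return X[:, np.sort(first)]


def _iterate_batch(J: np.ndarray, X0: np.ndarray, max_steps: int):
    """Run the synchronous dynamics on many starts at once.

    Returns per-column outcome codes (1 fixed, 2 cycle, 0 none), step
    counts, and the fixed-point patterns.  J entries are small integers,
    exactly representable in float32, so the BLAS path is exact.
    """
    N, P = X0.shape
    Jf = np.ascontiguousarray(J, dtype=np.float32)
    cur = X0.astype(np.float32)
    prev = np.zeros_like(cur)  # 0 never equals ±1: no spurious cycle at step 1
    outcome = np.zeros(P, dtype=np.int8)
    steps = np.zeros(P, dtype=np.int64)
    finals = np.zeros((N, P), dtype=np.int8)
    active = np.arange(P)
    one = np.float32(1.0)
    for s in range(1, max_steps + 1):
        z = Jf @ cur
        nxt = np.where(z >= 0, one, -one)
        fixed = (nxt == cur).all(axis=0)
        cyc = (~fixed) & (nxt == prev).all(axis=0)
        done = fixed | cyc
        if done.any():
            outcome[active[fixed]] = 1
            outcome[active[cyc]] = 2
            steps[active[done]] = s
            finals[:, active[fixed]] = cur[:, fixed].astype(np.int8)
            keep = ~done
            prev, cur, active = cur[:, keep], nxt[:, keep], active[keep]
            if active.size == 0:
                break
        else:
            prev, cur = cur, nxt
    steps[outcome == 0] = max_steps
    return outcome, steps, finals


def enumerate_attractors(
    J: np.ndarray,
    mu: np.ndarray,
    tuning: TuningConfig,
    max_steps: int | None = None,
    max_defects: int | None = None,
) -> AttractorCensus:
    """Probe the spontaneous dynamics from every conforming pattern.

    Each distinct stable fixed point reached is recorded once (by exact
    binary pattern) and labelled with the nu of its nearest retrieved
    pattern; nu is a derived label, not the identity.  States with more
    than ``max_defects`` defect neurons (default ``default_defect_cap``)
    are not retrieved patterns — e.g. global sign-flip twins — and are
    tallied as spurious.  2-cycles of the synchronous dynamics are
    excluded from the census but counted, as are probes that fail to
    settle within ``max_steps``.  Probing is pure: J and mu are not
    modified.
    """
    mu = np.asarray(mu, dtype=float)
    N = mu.size
    if max_steps is None:
        max_steps = DEFAULT_MAX_STEPS_FACTOR * N
    if max_defects is None:
        max_defects = default_defect_cap(N)
    X0 = probe_patterns(mu, tuning)
    outcome, steps, finals = _iterate_batch(np.asarray(J), X0, max_steps)
    attractors: list[AttractorRecord] = []
    n_spurious = 0
    seen: set[bytes] = set()
    for col in np.nonzero(outcome == 1)[0]:
        pat = finals[:, col]
        key = pat.tobytes()
        if key in seen:
            continue
        seen.add(key)
        rec = classify_attractor(pat, mu, tuning, steps=int(steps[col]))
        if rec.defects <= max_defects:
            attractors.append(rec)
        else:
            n_spurious += 1
    return AttractorCensus(
        attractors=attractors,
        n_conforming=sum(rec.conforming for rec in attractors),
        n_spurious=n_spurious,
        n_cycles=int(np.sum(outcome == 2)),
        n_no_convergence=int(np.sum(outcome == 0)),
        n_probes=X0.shape[1],
    )
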