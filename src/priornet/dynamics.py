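"""Stimulus-driven stage: network state, stochastic binary Hebbian
plasticity, and adaptation of tuning offsets toward presented stimuli.

Synapses are symmetric with values J_ij = ±1 (J_ii = 0).  On each trial
a misaligned synapse (J_ij != x_i x_j) flips toward the Hebbian product
with probability 1/tau; aligned synapses never change.  Tuning offsets
drift toward the presented stimulus with the same timescale tau and are
kept sorted ascending after every trial (only the offsets are permuted,
no other per-neuron parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import TuningConfig, stimulus_pattern


@dataclass
class NetworkState:
    """Full mutable state of one simulated network.

    Attributes
    ----------
    x : (N,) int8 array of ±1 activities.
    J : (N, N) int8 symmetric synaptic matrix, zero diagonal, ±1 elsewhere.
    mu : (N,) float array of current tuning offsets, sorted ascending.
    mu0 : (N,) float array of fixed initial offsets, (i - 1/2)/N.
    t : trial counter.
    """

    x: np.ndarray
    J: np.ndarray
    mu: np.ndarray
    mu0: np.ndarray
    t: int = 0

    @property
    def N(self) -> int:
        return int(self.mu.size)

    def copy(self) -> "NetworkState":
        return NetworkState(
            x=self.x.copy(), J=self.J.copy(), mu=self.mu.copy(),
            mu0=self.mu0.copy(), t=self.t,
        )


def init_network(N: int, seed=None) -> NetworkState:
    """Fresh network: random symmetric ±1 synapses, offsets at mu0.

    ``seed`` may be an integer seed or an existing Generator (in which
    case draws are consumed from it, keeping a single documented stream
    per simulation).
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    J = np.zeros((N, N), dtype=np.int8)
    iu, ju = np.triu_indices(N, k=1)
    vals = (rng.integers(0, 2, size=iu.size, dtype=np.int8) * 2 - 1).astype(np.int8)
    J[iu, ju] = vals
    J[ju, iu] = vals
    mu0 = (np.arange(1, N + 1) - 0.5) / N
    return NetworkState(x=np.ones(N, dtype=np.int8), J=J, mu=mu0.copy(), mu0=mu0, t=0)


def _random_distinct(rng: np.random.Generator, m: int, k: int) -> np.ndarray:
    """Uniform random k-subset of range(m); O(k) when k << m.

    Drawing uniform elements and inserting into a set until it reaches
    size k yields a uniformly distributed k-subset (every subset equally
    likely by exchangeability).  For dense draws fall back to a partial
    permutation.
    """
    if k >= m:
        return np.arange(m)
    if k > m // 8:
        return rng.permutation(m)[:k]
    have = np.unique(rng.integers(0, m, size=k))
    while have.size < k:
        extra = rng.integers(0, m, size=k - have.size)
        have = np.union1d(have, extra)
    return have


def hebbian_update(
    J: np.ndarray,
    x: np.ndarray,
    tau: float,
    rng: np.random.Generator,
    *,
    inplace: bool = False,
    pair_indices: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """One trial of stochastic Hebbian plasticity on the upper triangle.

    Potentiation (−1 → +1) occurs with probability (1 + x_i x_j)/(2 tau)
    and depression (+1 → −1) with probability (1 − x_i x_j)/(2 tau).
    Equivalently — since one of the two is always zero — each unordered
    pair flips toward x_i x_j with probability 1/tau when misaligned and
    never changes when aligned.  The implementation draws
    K ~ Binomial(M, 1/tau) pairs uniformly at random and assigns
    J_ij := x_i x_j there; the assignment is idempotent on aligned
    pairs, so the transition law is exactly the one above.  Symmetry is
    enforced by mirroring the assignment (half the synapses are updated
    and J_ji is set equal to J_ij); the diagonal is untouched.
    """
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    N = J.shape[0]
    if pair_indices is None:
        pair_indices = np.triu_indices(N, k=1)
    iu, ju = pair_indices
    out = J if inplace else J.copy()
    m = iu.size
    n_updates = int(rng.binomial(m, 1.0 / tau))
    if n_updates:
        sel = _random_distinct(rng, m, n_updates)
        i, j = iu[sel], ju[sel]
        target = (x[i] * x[j]).astype(np.int8)
        out[i, j] = target
        out[j, i] = target
    return out


def adapt_offsets(mu: np.ndarray, mu0: np.ndarray, alpha: float, tau: float) -> np.ndarray:
    """One trial of adaptation to the mean, then re-sort ascending.

    Each offset moves by (mu0_i − Θ(mu_i − alpha))/tau with Θ the unit
    step (Θ(z) = 1 for z >= 0; the value at zero is a convention).
    Offsets below the stimulus move up by mu0_i/tau, offsets at or above
    it move down by (1 − mu0_i)/tau, so every offset is attracted by the
    stimulus.  The full ascending sort is the closure of pairwise
    reordering; mu0 is never modified.
    """
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    mu = np.asarray(mu, dtype=float)
    theta = (mu >= alpha).astype(float)
    return np.sort(mu + (mu0 - theta) / tau)


def stimulus_trial(
    state: NetworkState,
    alpha: float,
    tuning: TuningConfig,
    tau: float,
    rng: np.random.Generator,
    *,
    inplace: bool = False,
    pair_indices: tuple[np.ndarray, np.ndarray] | None = None,
) -> NetworkState:
    """One stimulus-driven trial: activity, plasticity, adaptation.

    Order within the trial: (1) the activity is instantaneously enforced
    by the stimulus, (2) synapses update from that activity, (3) offsets
    adapt and are re-sorted.  The trial counter is incremented.
    """
    st = state if inplace else state.copy()
    st.x = stimulus_pattern(tuning, st.mu, alpha)
    hebbian_update(st.J, st.x, tau, rng, inplace=True, pair_indices=pair_indices)
    st.mu = adapt_offsets(st.mu, st.mu0, alpha, tau)
    st.t += 1
    return st


def save_checkpoint(state: NetworkState, path) -> None:
    """Write a NetworkState to an .npz container (J as int8, offsets as float)."""
    np.savez_compressed(path, x=state.x, J=state.J, mu=state.mu, mu0=state.mu0,
                        t=np.asarray(state.t))


def load_checkpoint(path) -> NetworkState:
    with np.load(path) as data:
        return NetworkState(
            x=data["x"].astype(np.int8), J=data["J"].astype(np.int8),
            mu=data["mu"], mu0=data["mu0"], t=int(data["t"]),
        )
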