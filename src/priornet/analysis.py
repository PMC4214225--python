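"""Summary statistics over simulation results: attractor histograms
against the stimulus density, attractor counts per session/tau/N, the
power-law scaling fit, and distribution-matching statistics.

The Kolmogorov–Smirnov distance is used wherever an empirical set of
values on (0, 1) — retrieved patterns or tuning offsets — is compared
with a stimulus distribution: matching is exact only in the large-N,
large-tau limit, so finite-size tolerances are calibrated by pilot
simulation rather than theory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_1samp, linregress

from .experiment import ExperimentResult
from .spontaneous import default_defect_cap
from .stimulus import StimulusDistribution


@dataclass
class ScalingFit:
    """Least-squares power law count ~ N**exponent on log10–log10 axes."""

    exponent: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]


def pooled_nus(
    results: Iterable[ExperimentResult],
    sessions: Sequence[int] | None = None,
) -> np.ndarray:
    """Retrieved-pattern values pooled across runs (1-based session filter)."""
    chunks = [res.nus(sessions) for res in results]
    if not chunks:
        return np.zeros(0)
    return np.concatenate(chunks)


def attractor_histogram(
    results: Iterable[ExperimentResult],
    bins: int = 50,
    sessions: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled nu values binned on (0, 1), normalised to a density.

    Returns (density, edges); bin mass density * bin width sums to 1.
    Raises ValueError when no attractors were recorded at all.
    """
    nus = pooled_nus(list(results), sessions)
    if nus.size == 0:
        raise ValueError("no attractors to histogram")
    density, edges = np.histogram(nus, bins=bins, range=(0.0, 1.0), density=True)
    return density, edges


def distribution_match(values, dist: StimulusDistribution) -> float:
    """Two-sided KS distance between the empirical CDF of ``values`` and ``dist``."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError(f"need at least 10 values, got {values.size}")
    return float(ks_1samp(values, dist.cdf_at).statistic)


def count_attractors(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Distinct stable states (attractors) per session per run.

    Columns: session, tau, N, replicate, count.  The replicate label is
    taken from the sweep tag when present, else the position in the list.
    """
    rows = []
    for ri, res in enumerate(results):
        replicate = res.tag["replicate"] if res.tag and "replicate" in res.tag else ri
        for s, count in zip(range(1, len(res.sessions) + 1), res.counts()):
            rows.append({
                "session": s,
                "tau": res.config.tau,
                "N": res.config.N,
                "replicate": replicate,
                "count": count,
            })
    return pd.DataFrame(rows, columns=["session", "tau", "N", "replicate", "count"])


def mean_count(results: Sequence[ExperimentResult], sessions: Sequence[int]) -> float:
    """Mean attractor count over the given sessions (1-based), across runs."""
    keep = set(sessions)
    vals = [c for res in results
            for s, c in zip(range(1, len(res.sessions) + 1), res.counts()) if s in keep]
    return float(np.mean(vals))


def n_locations(records, radius: int | None = None) -> int:
    """Number of distinct attractor locations in one session.

    Stable states that are finite-size defect variants of the same
    retrieved pattern sit within O(sqrt(N)) Hamming distance of each
    other, while distinct early-session attractor locations (separate
    stimulus modes) are O(N) apart.  Single-linkage clustering at
    ``radius`` (default ``default_defect_cap(N)``) counts the
    locations.  Useful early in learning, when attractors are sparse
    and well separated; at stationarity neighbouring attractors are no
    longer separated from defect variants and the raw state count is
    the meaningful quantity.
    """
    records = list(records)
    if not records:
        return 0
    pats = np.stack([np.asarray(r.pattern, dtype=np.int8) for r in records]).astype(np.int16)
    N = pats.shape[1]
    if radius is None:
        radius = default_defect_cap(N)
    ham = (N - pats @ pats.T) // 2
    adj = ham <= radius
    # union-find over the handful of session states
    parent = list(range(len(records)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(len(records))})


def scaling_fit(points: Sequence[tuple[float, float]]) -> ScalingFit:
    """Fit log10(count) = exponent * log10(N) + intercept by least squares."""
    pts = [(float(n), float(c)) for n, c in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points, got {len(pts)}")
    if any(c <= 0 for _, c in pts):
        raise ValueError("counts must be positive for a log-log fit")
    logn = np.log10([n for n, _ in pts])
    logc = np.log10([c for _, c in pts])
    fit = linregress(logn, logc)
    return ScalingFit(
        exponent=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=pts,
    )


# -- plotting ----------------------------------------------------------------


def plot_attractor_map(result: ExperimentResult, ax=None):
    """Stimulus density with one row of attractor markers per session."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    dist = result.distribution
    dmax = float(dist.density.max())
    ax.plot(dist.grid, dist.density, "k-", lw=1.5, label="p(alpha)")
    n_sess = len(result.sessions)
    for s, sess in enumerate(result.sessions, start=1):
        y = -dmax * s / n_sess
        nus = [rec.nu for rec in sess if rec.nu is not None]
        ax.plot(nus, [y] * len(nus), "b*", ms=6)
    ax.axhline(0.0, color="0.7", lw=0.5)
    ax.set_xlabel("stimulus alpha / retrieved pattern nu")
    ax.set_yticks([])
    ax.set_xlim(0, 1)
    return ax


def plot_session_counts(table: pd.DataFrame, ax=None):
    """Mean attractor count per session, one line per tau."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for tau, sub in table.groupby("tau"):
        means = sub.groupby("session")["count"].mean()
        ax.plot(means.index, means.values, "o-", label=f"tau={tau:g}")
    ax.set_xlabel("session")
    ax.set_ylabel("number of attractors")
    ax.legend()
    return ax


def plot_scaling(fit: ScalingFit, ax=None):
    """Log-log attractor count vs N with the fitted power law."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    n = np.array([p for p, _ in fit.points])
    c = np.array([q for _, q in fit.points])
    ax.loglog(n, c, "ko")
    grid = np.linspace(n.min(), n.max(), 50)
    ax.loglog(grid, 10**fit.intercept * grid**fit.exponent, "b-",
              label=f"~N^{fit.exponent:.2f}")
    ax.set_xlabel("number of neurons N")
    ax.set_ylabel("number of attractors")
    ax.legend()
    return ax
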