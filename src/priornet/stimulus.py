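"""Stimulus ensembles and tuning curves.

Stimuli are scalars ``alpha`` in (0, 1) drawn i.i.d. from a probability
density built as the normalised square of a truncated cosine series with
random Gaussian coefficients.  Squaring guarantees non-negativity; the
cosine basis keeps the density smooth and non-periodic on the unit
interval.  Each model neuron responds to a stimulus through a tuning
curve — monotonic (``tanh``) or periodic (``sin``) — shifted by a
per-neuron tuning offset ``mu_i``; the binary evoked pattern is the sign
of the tuning-curve output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

SIGMOIDAL = "sigmoidal"
PERIODIC = "periodic"
_KINDS = (SIGMOIDAL, PERIODIC)

DEFAULT_N_TERMS = 5
DEFAULT_GRID_SIZE = 10_000


def sign_pm1(values) -> np.ndarray:
    """Elementwise sign mapped to {-1, +1}, with sign(0) = +1.

    The network activation is the sign of a current that can be exactly
    zero, so a fixed tie-break convention is required; +1 is used
    everywhere in the package.
    """
    v = np.asarray(values)
    return np.where(v >= 0, 1, -1).astype(np.int8)


@dataclass(frozen=True)
class TuningConfig:
    """Tuning-curve family shared by all neurons.

    Parameters
    ----------
    kind : {"sigmoidal", "periodic"}
        ``sigmoidal`` uses ``tanh(beta * (alpha - mu))``, ``periodic``
        uses ``sin(2 * pi * (alpha - mu))``.
    beta : float
        Gain of the sigmoidal curve; must be positive.  Only the sign of
        the current matters for binary activity, so the specific value
        is irrelevant and defaults to 1.
    """

    kind: str = SIGMOIDAL
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")


@dataclass(frozen=True, eq=False)
class StimulusDistribution:
    """A stimulus density p(alpha) on (0, 1) with its CDF on a grid.

    Built as ``p(alpha) ∝ (sum_k c_k cos(k * pi * alpha))**2`` and
    normalised by trapezoidal quadrature.  Sampling uses inverse-CDF
    interpolation on the grid, which is cheap and deterministic given
    the random stream.
    """

    coefficients: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    cdf: np.ndarray
    seed: int | None = None

    # -- construction ---------------------------------------------------

    @classmethod
    def from_coefficients(
        cls,
        coefficients: Sequence[float],
        grid_size: int = DEFAULT_GRID_SIZE,
        seed: int | None = None,
    ) -> "StimulusDistribution":
        coeffs = np.asarray(coefficients, dtype=float)
        if coeffs.ndim != 1 or coeffs.size < 1:
            raise ValueError("coefficients must be a non-empty 1-d sequence")
        if grid_size < 100:
            raise ValueError(f"grid_size must be >= 100, got {grid_size}")
        grid = np.linspace(0.0, 1.0, int(grid_size))
        k = np.arange(coeffs.size)
        series = np.cos(np.pi * np.outer(grid, k)) @ coeffs
        f = series**2
        norm = np.trapezoid(f, grid)
        if norm <= 0:
            raise ValueError("degenerate coefficients: density is identically zero")
        density = f / norm
        cdf = cumulative_trapezoid(density, grid, initial=0.0)
        cdf = cdf / cdf[-1]
        return cls(coefficients=coeffs, grid=grid, density=density, cdf=cdf, seed=seed)

    @classmethod
    def from_seed(
        cls,
        seed: int,
        n_terms: int = DEFAULT_N_TERMS,
        grid_size: int = DEFAULT_GRID_SIZE,
    ) -> "StimulusDistribution":
        """Draw the ``n_terms`` Fourier coefficients i.i.d. standard normal."""
        if n_terms < 1:
            raise ValueError(f"n_terms must be >= 1, got {n_terms}")
        if grid_size < 100:
            raise ValueError(f"grid_size must be >= 100, got {grid_size}")
        rng = np.random.default_rng(seed)
        coeffs = rng.standard_normal(int(n_terms))
        return cls.from_coefficients(coeffs, grid_size=grid_size, seed=int(seed))

    # -- queries ---------------------------------------------------------

    @property
    def grid_size(self) -> int:
        return int(self.grid.size)

    def sample(self, rng: np.random.Generator, size=None):
        """Inverse-CDF sample(s); a scalar when ``size`` is None."""
        u = rng.random(size)
        return np.interp(u, self.cdf, self.grid)

    def cdf_at(self, values):
        return np.interp(values, self.grid, self.cdf)

    def density_at(self, values):
        return np.interp(values, self.grid, self.density)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "coefficients": [float(c) for c in self.coefficients],
            "grid_size": self.grid_size,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "StimulusDistribution":
        return cls.from_coefficients(
            data["coefficients"],
            grid_size=data.get("grid_size", DEFAULT_GRID_SIZE),
            seed=data.get("seed"),
        )

    @classmethod
    def from_json(cls, path) -> "StimulusDistribution":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def external_current(tuning: TuningConfig, mu, alpha: float) -> np.ndarray:
    """Tuning-curve response of neurons with offsets ``mu`` to stimulus ``alpha``."""
    mu = np.asarray(mu, dtype=float)
    if tuning.kind == SIGMOIDAL:
        return np.tanh(tuning.beta * (alpha - mu))
    return np.sin(2.0 * np.pi * (alpha - mu))


def stimulus_pattern(tuning: TuningConfig, mu, alpha: float) -> np.ndarray:
    """Binary activity pattern evoked by ``alpha``: sign of the external current.

    During stimulus presentation the internal current is zero, so the
    activity is enforced entirely by the tuning curves.
    """
    return sign_pm1(external_current(tuning, mu, alpha))
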