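"""Full simulations: alternating stimulus-driven blocks and spontaneous
probing sessions under a declarative configuration.

One simulation presents T random stimuli in total, pausing after every
T/n_sessions trials to enumerate the attractors of the spontaneous
dynamics (10 sessions by default).  Probing is side-effect free, so the
network state entering the next stimulus block is exactly the state
that exited the previous one.  A run is fully determined by
(density_seed, sim_seed): the density seed draws the Fourier
coefficients of the stimulus density, and the simulation seed drives a
single random stream from which, per trial, one uniform is consumed for
the stimulus and then the synaptic transition draws.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import NetworkState, init_network, stimulus_trial
from .spontaneous import AttractorRecord, enumerate_attractors
from .stimulus import DEFAULT_GRID_SIZE, StimulusDistribution, TuningConfig


@dataclass
class ExperimentConfig:
    """Declarative description of one simulation.

    The model has three parameters — the network size N, the total
    number of trials T, and the shared plasticity/adaptation timescale
    tau (in trials).  The remaining fields fix the tuning-curve family,
    the random density, and the session protocol.
    """

    N: int
    T: int
    tau: float
    tuning: TuningConfig = field(default_factory=TuningConfig)
    density_seed: int = 0
    sim_seed: int = 0
    n_sessions: int = 10
    grid_size: int = DEFAULT_GRID_SIZE

    def __post_init__(self) -> None:
        if isinstance(self.tuning, Mapping):
            self.tuning = TuningConfig(**self.tuning)
        elif isinstance(self.tuning, str):
            self.tuning = TuningConfig(kind=self.tuning)
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.n_sessions < 1:
            raise ValueError(f"n_sessions must be >= 1, got {self.n_sessions}")
        if self.T < self.n_sessions:
            raise ValueError(f"T must be >= n_sessions, got T={self.T} < {self.n_sessions}")
        if self.T % self.n_sessions != 0:
            raise ValueError(
                f"T must be divisible by n_sessions, got T={self.T}, n_sessions={self.n_sessions}"
            )
        if self.grid_size < 100:
            raise ValueError(f"grid_size must be >= 100, got {self.grid_size}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tuning"] = {"kind": self.tuning.kind, "beta": self.tuning.beta}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)


@dataclass
class ExperimentResult:
    """Everything one simulation produced, plus its provenance.

    ``sessions[k]`` holds the stable states recorded in session k+1,
    each labelled with its retrieved-pattern value nu; ``diagnostics[k]``
    the counts of exactly-conforming states, 2-cycles and non-converged
    probes of that session; ``offsets[k]`` a snapshot of the sorted
    tuning offsets at probing time.
    """

    config: ExperimentConfig
    distribution: StimulusDistribution
    sessions: list[list[AttractorRecord]]
    diagnostics: list[dict]
    offsets: list[np.ndarray]
    final_state: NetworkState
    tag: dict | None = None

    def counts(self) -> list[int]:
        """Distinct stable states (attractors) per session."""
        return [len({rec.pattern.tobytes() for rec in sess}) for sess in self.sessions]

    def nus(self, sessions: Sequence[int] | None = None) -> np.ndarray:
        """Pooled retrieved-pattern values, optionally restricted to sessions (1-based)."""
        keep = None if sessions is None else set(sessions)
        vals = [
            rec.nu
            for sess in self.sessions
            for rec in sess
            if rec.nu is not None and (keep is None or rec.session in keep)
        ]
        return np.asarray(vals, dtype=float)

    def save(self, outdir) -> Path:
        """Write config.json, density.json, attractors.csv, offsets.csv."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)
        self.distribution.to_json(out / "density.json")
        attractors_frame(self).to_csv(out / "attractors.csv", index=False)
        off = pd.DataFrame(
            np.asarray(self.offsets),
            index=pd.Index(range(1, len(self.offsets) + 1), name="session"),
        )
        off.to_csv(out / "offsets.csv")
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(self.diagnostics, fh, indent=2)
        return out


def rle_encode(pattern: np.ndarray) -> str:
    """Run-length encode a ±1 pattern, e.g. (+1,+1,−1) -> '+2-1'."""
    pattern = np.asarray(pattern)
    out = []
    start = 0
    for end in range(1, pattern.size + 1):
        if end == pattern.size or pattern[end] != pattern[start]:
            out.append(("+" if pattern[start] > 0 else "-") + str(end - start))
            start = end
    return "".join(out)


def rle_decode(text: str) -> np.ndarray:
    runs = re.findall(r"([+-])(\d+)", text)
    if "".join(s + n for s, n in runs) != text:
        raise ValueError(f"not a run-length encoded pattern: {text!r}")
    parts = [np.full(int(n), 1 if s == "+" else -1, dtype=np.int8) for s, n in runs]
    return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int8)


def attractors_frame(result: ExperimentResult) -> pd.DataFrame:
    """Attractor table: session, nu, conforming, pattern RLE, steps."""
    rows = [
        {
            "session": rec.session,
            "nu": rec.nu,
            "conforming": rec.conforming,
            "pattern_rle": rle_encode(rec.pattern),
            "steps": rec.steps,
            "defects": rec.defects,
        }
        for sess in result.sessions
        for rec in sess
    ]
    return pd.DataFrame(
        rows, columns=["session", "nu", "conforming", "pattern_rle", "steps", "defects"]
    )


def run_experiment(
    config: ExperimentConfig,
    log: Callable[[str], None] | None = None,
) -> ExperimentResult:
    """Run T stimulus trials with a probing session every T/n_sessions trials."""
    dist = StimulusDistribution.from_seed(config.density_seed, grid_size=config.grid_size)
    rng = np.random.default_rng(config.sim_seed)
    state = init_network(config.N, rng)
    pairs = np.triu_indices(config.N, k=1)
    block = config.T // config.n_sessions
    sessions: list[list[AttractorRecord]] = []
    diagnostics: list[dict] = []
    offsets: list[np.ndarray] = []
    for s in range(1, config.n_sessions + 1):
        for _ in range(block):
            alpha = float(dist.sample(rng))
            stimulus_trial(state, alpha, config.tuning, config.tau, rng,
                           inplace=True, pair_indices=pairs)
        census = enumerate_attractors(state.J, state.mu, config.tuning)
        for rec in census.attractors:
            rec.session = s
        sessions.append(census.attractors)
        diagnostics.append({
            "session": s,
            "trial": state.t,
            "n_attractors": len(census.attractors),
            "n_conforming": census.n_conforming,
            "n_spurious": census.n_spurious,
            "n_cycles": census.n_cycles,
            "n_no_convergence": census.n_no_convergence,
        })
        offsets.append(state.mu.copy())
        if log is not None:
            log(f"session {s:2d} trial {state.t:7d} attractors {len(census.attractors):4d} "
                f"cycles {census.n_cycles:3d} nonconforming {len(census.nonconforming):3d}")
    return ExperimentResult(
        config=config, distribution=dist, sessions=sessions,
        diagnostics=diagnostics, offsets=offsets, final_state=state,
    )


def derive_seeds(master_seed: int, cell_index: int, replicate: int) -> tuple[int, int]:
    """Counter-based (density_seed, sim_seed) pair for one sweep cell/replicate."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(cell_index), int(replicate)))
    dseed, sseed = (int(v) for v in ss.generate_state(2) % (2**31))
    return dseed, sseed


def run_sweep(
    base: ExperimentConfig,
    over: Mapping[str, Sequence],
    replicates: int = 1,
    master_seed: int = 0,
    *,
    vary_density: bool = True,
    log: Callable[[str], None] | None = None,
) -> list[ExperimentResult]:
    """Grid of independent runs with reproducible per-cell seeds.

    ``over`` maps config field names to value lists; the cross product
    is run ``replicates`` times each.  Seeds are derived from
    ``master_seed`` by a counter-based scheme, so re-running the sweep
    assigns identical seeds.  With ``vary_density=False`` every run
    keeps the base density seed (one shared stimulus distribution)
    while simulation seeds still differ.
    """
    if not over or any(len(v) == 0 for v in over.values()):
        raise ValueError("parameter grid must be non-empty")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    unknown = [k for k in over if not hasattr(base, k)]
    if unknown:
        raise ValueError(f"unknown config fields in grid: {unknown}")
    names = list(over)
    results: list[ExperimentResult] = []
    for ci, cell in enumerate(itertools.product(*(over[n] for n in names))):
        for r in range(replicates):
            dseed, sseed = derive_seeds(master_seed, ci, r)
            if not vary_density:
                dseed = base.density_seed
            cfg = dataclasses.replace(
                base, **dict(zip(names, cell)), density_seed=dseed, sim_seed=sseed
            )
            if log is not None:
                log(f"cell {dict(zip(names, cell))} replicate {r}")
            res = run_experiment(cfg)
            res.tag = {"cell": dict(zip(names, cell)), "replicate": r}
            results.append(res)
    return results
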