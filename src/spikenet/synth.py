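"""Synthetic multi-area spike-train sessions with planted signed couplings.

The generator emulates the statistical structure that short-latency
functional-connectivity analysis operates on, with a known ground truth:

* Poisson-like baseline firing, realized as Bernoulli-per-bin thinning at
  1 ms bins (at <= 100 spikes/s the per-bin probability stays <= 0.1, so the
  binary-train approximation of a Poisson process is accurate);
* planted positive couplings: each source spike triggers, with a stated
  transmission probability, one extra target spike at a lag drawn uniformly
  from the coupling's [lag, lag+duration-1] window (mono- and polysynaptic
  "sharp interval" signatures);
* planted negative couplings: probabilistic deletion of target spikes inside
  the same lag window (a co-silencing signature);
* a shared slow sinusoidal rate modulation (default 200 ms period, relative
  amplitude 0.5) multiplying every unit's rate, the confound that jitter
  correction must remove;
* multiple trials per stimulus type and multi-area unit labels with 3-D
  positions.

Sessions carry their ground truth so downstream detection can be scored for
sensitivity, precision, sign accuracy and lag error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data import SpikeTrainSet

__all__ = [
    "PopulationConfig",
    "CouplingConfig",
    "ModulationConfig",
    "GroundTruthCouplings",
    "make_ground_truth",
    "draw_couplings",
    "simulate_session",
    "RecoveryReport",
    "evaluate_recovery",
]

TAU_MAX = 12  # bins; couplings must act within the detector's lag range


@dataclass(frozen=True)
class PopulationConfig:
    """Unit population: per-area counts, baseline rates, spatial layout."""

    areas: dict = field(default_factory=lambda: {"V1": 20, "LM": 20, "AM": 20})
    rate_hz: tuple | float = (5.0, 15.0)  # scalar or uniform (low, high)
    area_spacing_um: float = 400.0
    position_jitter_um: float = 100.0

    @property
    def n_units(self) -> int:
        return int(sum(self.areas.values()))


@dataclass(frozen=True)
class CouplingConfig:
    """Planted-coupling settings.

    ``n_couplings`` pairwise couplings are drawn on random distinct ordered
    pairs; ``n_pffl_triangles`` additionally plants all-positive transitive
    triangles (a->b, b->c, a->c) on disjoint unit triples, giving the motif
    stage a known ground-truth feedforward-loop structure to recover.
    """

    n_couplings: int = 10
    frac_positive: float = 0.8
    lag_range: tuple = (1, 12)        # bins, inclusive
    duration_range: tuple = (1, 4)    # bins, inclusive
    transmission: tuple | float = 0.5  # scalar or uniform (low, high)
    n_pffl_triangles: int = 0


@dataclass(frozen=True)
class ModulationConfig:
    """Shared slow rate envelope multiplying every unit's rate.

    ``kind="sinusoid"`` gives a periodic envelope (period ``period_ms``,
    random phase per trial). ``kind="filtered_noise"`` gives an aperiodic
    Gaussian-process envelope with correlation time ``correlation_ms`` —
    the shape of cortical state fluctuations, and the confound whose
    decaying lagged correlation jitter correction is meant to remove (a
    strictly periodic envelope spreads its correlogram structure over every
    lag and is largely invisible to sharp-interval detection).
    ``amplitude`` is the envelope's relative SD / half-range; the noise
    envelope is clipped to [0, 1 + 3*amplitude].
    """

    period_ms: float = 200.0
    amplitude: float = 0.5
    kind: str = "sinusoid"
    correlation_ms: float = 100.0

    def __post_init__(self):
        if self.kind not in ("sinusoid", "filtered_noise"):
            raise ValueError(f"unknown modulation kind {self.kind!r}")

    @property
    def peak_factor(self) -> float:
        return (
            1.0 + self.amplitude
            if self.kind == "sinusoid"
            else 1.0 + 3.0 * self.amplitude
        )


@dataclass
class GroundTruthCouplings:
    """Planted couplings plus the population and confound they live in."""

    couplings: pd.DataFrame  # source, target, sign, lag, duration, transmission
    units: pd.DataFrame      # area, rate_hz, x, y, z per unit id
    modulation: ModulationConfig | None = None

    def __post_init__(self):
        c = self.couplings
        if len(c):
            if (c["source"] == c["target"]).any():
                raise ValueError("self-couplings are not allowed")
            if ((c["lag"] < 1) | (c["lag"] > TAU_MAX)).any():
                raise ValueError(f"lags must lie in [1, {TAU_MAX}] bins")
            if ((c["transmission"] <= 0) | (c["transmission"] > 1)).any():
                raise ValueError("transmission probabilities must be in (0, 1]")
        if (self.units["rate_hz"] <= 0).any():
            raise ValueError("baseline rates must be positive")


def make_ground_truth(
    population: PopulationConfig = PopulationConfig(),
    coupling: CouplingConfig = CouplingConfig(),
    modulation: ModulationConfig | None = None,
    seed: int = 0,
) -> GroundTruthCouplings:
    """Draw a population and a set of planted couplings (seed-deterministic).

    Couplings occupy distinct ordered unit pairs, never self-pairs. Unit
    positions cluster by area (areas spaced ``area_spacing_um`` apart along
    x, 3-D Gaussian scatter within an area).
    """
    if population.n_units < 1:
        raise ValueError("population must contain at least one unit")
    lo, hi = coupling.lag_range
    if lo < 1 or hi > TAU_MAX or lo > hi:
        raise ValueError(f"coupling lags must lie within [1, {TAU_MAX}]")
    n_pairs = population.n_units * (population.n_units - 1)
    if coupling.n_couplings > n_pairs:
        raise ValueError("requested more couplings than ordered pairs")

    rng = np.random.default_rng(seed)
    areas = [a for a, k in population.areas.items() for _ in range(int(k))]
    n = len(areas)
    if np.isscalar(population.rate_hz):
        rates = np.full(n, float(population.rate_hz))
    else:
        rates = rng.uniform(*population.rate_hz, size=n)
    if np.any(rates <= 0):
        raise ValueError("baseline rates must be positive")
    centers = {
        a: i * population.area_spacing_um for i, a in enumerate(population.areas)
    }
    pos = rng.normal(0.0, population.position_jitter_um, size=(n, 3))
    pos[:, 0] += np.array([centers[a] for a in areas])
    units = pd.DataFrame(
        {
            "area": areas,
            "rate_hz": rates,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
        },
        index=pd.Index(range(n), name="unit"),
    )

    couplings = draw_couplings(units, coupling, rng)
    return GroundTruthCouplings(
        couplings=couplings, units=units, modulation=modulation
    )


def draw_couplings(
    units: pd.DataFrame, coupling: CouplingConfig, seed_or_rng
) -> pd.DataFrame:
    """Draw a coupling table over an existing unit population.

    Used to plant distinct coupling sets (one per stimulus type) on one
    shared population. Couplings occupy distinct ordered pairs of the units'
    positional indices.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n = len(units)
    n_pairs = n * (n - 1)
    k = coupling.n_couplings
    n_tri = coupling.n_pffl_triangles
    if k + 3 * n_tri > n_pairs or 3 * n_tri > n:
        raise ValueError("requested more couplings than ordered pairs")
    lo, hi = coupling.lag_range
    if lo < 1 or hi > TAU_MAX or lo > hi:
        raise ValueError(f"coupling lags must lie within [1, {TAU_MAX}]")
    ids = units.index.to_numpy()
    dlo, dhi = coupling.duration_range

    def draw_attrs(m, signs):
        return pd.DataFrame(
            {
                "sign": signs,
                "lag": rng.integers(lo, hi + 1, size=m),
                "duration": rng.integers(dlo, dhi + 1, size=m),
                "transmission": (
                    np.full(m, float(coupling.transmission))
                    if np.isscalar(coupling.transmission)
                    else rng.uniform(*coupling.transmission, size=m)
                ),
            }
        )

    frames = []
    used_pairs: set = set()
    if n_tri:
        triple_units = rng.choice(n, size=3 * n_tri, replace=False)
        edges = []
        for t in range(n_tri):
            a, b, c = triple_units[3 * t : 3 * t + 3]
            edges += [(a, b), (b, c), (a, c)]
        used_pairs.update(edges)
        tri = draw_attrs(3 * n_tri, np.ones(3 * n_tri, dtype=int))
        tri.insert(0, "target", ids[[e[1] for e in edges]])
        tri.insert(0, "source", ids[[e[0] for e in edges]])
        frames.append(tri)
    if k:
        free = [
            p for p in range(n_pairs)
            if (p // (n - 1), _tgt(p, n)) not in used_pairs
        ]
        pair_idx = rng.choice(len(free), size=k, replace=False)
        src = np.array([free[i] // (n - 1) for i in pair_idx])
        tgt = np.array([_tgt(free[i], n) for i in pair_idx])
        pairwise = draw_attrs(
            k, np.where(rng.random(k) < coupling.frac_positive, 1, -1)
        )
        pairwise.insert(0, "target", ids[tgt])
        pairwise.insert(0, "source", ids[src])
        frames.append(pairwise)
    if not frames:
        return pd.DataFrame(
            columns=["source", "target", "sign", "lag", "duration", "transmission"]
        )
    return pd.concat(frames, ignore_index=True)


def _tgt(pair_index: int, n: int) -> int:
    s, t = divmod(pair_index, n - 1)
    return t + 1 if t >= s else t


def simulate_session(
    truth: GroundTruthCouplings,
    n_trials: int = 100,
    n_bins: int = 2000,
    seed: int = 0,
    bin_ms: float = 1.0,
    stimulus: str = "stim",
) -> SpikeTrainSet:
    """Simulate one session of binned binary spike trains.

    Baseline trains are Bernoulli-per-bin with the unit's rate times the
    shared modulation envelope (random phase per trial). Couplings then act
    on the baseline source spikes: positive couplings add target spikes at
    lags uniform in the coupling window with the stated transmission
    probability, negative couplings delete target spikes in the window.
    """
    c = truth.couplings
    max_reach = int((c["lag"] + c["duration"]).max()) if len(c) else 0
    if n_bins <= max_reach:
        raise ValueError("trials must be longer than the maximum coupling reach")
    rng = np.random.default_rng(seed)
    rates = truth.units["rate_hz"].to_numpy()
    p_bin = rates * bin_ms / 1000.0
    mod = truth.modulation
    peak = mod.peak_factor if mod else 1.0
    if np.any(p_bin * peak > 1.0):
        raise ValueError("per-bin spike probability exceeds 1; lower the rate")

    if mod is None:
        env = np.ones((n_trials, n_bins))
    elif mod.kind == "sinusoid":
        period = mod.period_ms / bin_ms
        phases = rng.uniform(0, 2 * np.pi, size=n_trials)
        t = np.arange(n_bins)
        env = 1.0 + mod.amplitude * np.sin(
            2 * np.pi * t[None, :] / period + phases[:, None]
        )  # (M, N)
    else:  # aperiodic Gaussian-process envelope, shared across units
        width = max(mod.correlation_ms / bin_ms / 2.0, 1.0)
        kernel_t = np.arange(-int(4 * width), int(4 * width) + 1)
        kernel = np.exp(-0.5 * (kernel_t / width) ** 2)
        noise = rng.standard_normal((n_trials, n_bins + len(kernel) - 1))
        sm = np.stack(
            [np.convolve(row, kernel, mode="valid") for row in noise]
        )
        sm /= np.sqrt(np.sum(kernel**2))  # unit marginal SD
        env = np.clip(1.0 + mod.amplitude * sm, 0.0, 1.0 + 3.0 * mod.amplitude)

    prob = env[:, :, None] * p_bin[None, None, :]
    base = (rng.random((n_trials, n_bins, len(rates))) < prob).astype(np.uint8)
    out = base.copy()

    for row in c.sort_values(["source", "target"]).itertuples():
        s_pos = truth.units.index.get_loc(row.source)
        t_pos = truth.units.index.get_loc(row.target)
        trials, times = np.nonzero(base[:, :, s_pos])
        fired = rng.random(len(times)) < row.transmission
        if row.sign > 0:
            offs = rng.integers(row.lag, row.lag + row.duration, size=len(times))
            tt = times + offs
            ok = fired & (tt < n_bins)
            out[trials[ok], tt[ok], t_pos] = 1
        else:
            for m, t0 in zip(trials[fired], times[fired]):
                out[m, t0 + row.lag : t0 + row.lag + row.duration, t_pos] = 0

    units = truth.units.drop(columns=["rate_hz"])
    return SpikeTrainSet(
        spikes=out,
        trial_stimulus=np.array([stimulus] * n_trials),
        units=units,
        bin_ms=bin_ms,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """How well a detected network recovers the planted couplings."""

    n_planted: int
    n_detected: int
    n_true: int
    sensitivity: float
    precision: float | None
    sign_accuracy: float | None
    lag_errors: tuple

    def as_dict(self) -> dict:
        return {
            "n_planted": self.n_planted,
            "n_detected": self.n_detected,
            "n_true": self.n_true,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "sign_accuracy": self.sign_accuracy,
        }


def evaluate_recovery(
    truth: GroundTruthCouplings, detected: nx.DiGraph
) -> RecoveryReport:
    """Score a detected functional network against the planted couplings.

    A detection matches a planted coupling when source, target and sign
    agree and the detected lag falls within +/- 1 bin of the planted lag
    window. Precision and sign accuracy are reported as None (absent) when
    undefined (no detections / no pair-matched detections).
    """
    unknown = set(detected.nodes) - set(truth.units.index)
    if unknown:
        raise ValueError(f"detected nodes outside the truth id space: {unknown}")
    planted = {
        (row.source, row.target): row
        for row in truth.couplings.itertuples()
    }
    n_detected = detected.number_of_edges()
    n_true = 0
    n_pair_matched = 0
    n_sign_ok = 0
    lag_errors = []
    for u, v, d in detected.edges(data=True):
        row = planted.get((u, v))
        if row is None:
            continue
        lag_ok = (row.lag - 1) <= d["lag"] <= (row.lag + row.duration)
        if not lag_ok:
            continue
        n_pair_matched += 1
        if int(d["sign"]) == int(row.sign):
            n_sign_ok += 1
            n_true += 1
            lag_errors.append(int(d["lag"]) - int(row.lag))
    n_planted = len(planted)
    return RecoveryReport(
        n_planted=n_planted,
        n_detected=n_detected,
        n_true=n_true,
        sensitivity=(n_true / n_planted) if n_planted else 0.0,
        precision=(n_true / n_detected) if n_detected else None,
        sign_accuracy=(n_sign_ok / n_pair_matched) if n_pair_matched else None,
        lag_errors=tuple(lag_errors),
    )
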