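"""Jitter-corrected cross-correlograms and functional-connection detection.

The raw CCG between source A and target B at non-negative lag tau is the
trial-averaged count of lagged coincidences, corrected for window overlap by
the triangle factor theta(tau) = N - tau and normalized by the geometric mean
of the two units' mean spike counts per bin:

    CCG_AB(tau) = (1/M) sum_i sum_t x_A^i(t) x_B^i(t+tau)
                  / (theta(tau) sqrt(lambda_A lambda_B))

Slow shared rate fluctuations are removed by interval jittering: the
expected CCG under uniform redistribution of spikes within fixed 25 ms
windows is subtracted (CCG_jc = CCG - CCG_jittered). The jitter expectation
is computed analytically by replacing each spike of both trains with a
uniform mass over its jitter window; a seeded Monte-Carlo resampling mode is
available as a cross-check.

A signed directed connection is a "sharp peak" (duration D = 1) or "sharp
interval" (D > 1): a window of the corrected CCG starting at lag
t0 <= tau_max whose mean exceeds mu +/- n*sigma of the set of ALL same-length
moving-average windows along the lag axis. Among qualifying durations the
smallest is reported. Mutually zero-lag detections are resolved by keeping
the direction with the higher significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import SpikeTrainSet

__all__ = [
    "DetectionParams",
    "CCGCurve",
    "Detection",
    "filter_units_by_rate",
    "compute_ccg",
    "ccg_matrix",
    "detect_connection",
    "resolve_zero_lag",
    "normalized_entropy",
    "build_network",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection constants (defaults follow the study's settings)."""

    tau_max: int = 12          # max connection lag, bins
    n_sigma: float = 4.0       # significance multiplier on sigma_C(D)
    jitter_window: int = 25    # jitter window, bins
    entropy_threshold: float = 0.9
    min_rate_hz: float = 2.0
    n_lags: int = 100          # lag-axis length L for forming C(D)

    def __post_init__(self):
        if self.tau_max < 1 or self.n_sigma <= 0 or self.jitter_window < 2:
            raise ValueError("invalid detection parameters")
        if self.n_lags < self.tau_max + 1:
            raise ValueError("lag axis must cover tau_max")


@dataclass
class CCGCurve:
    """Raw, jitter-expected and corrected correlogram over lags 0..L."""

    raw: np.ndarray
    jitter_expectation: np.ndarray
    lags: np.ndarray

    @property
    def corrected(self) -> np.ndarray:
        return self.raw - self.jitter_expectation


@dataclass(frozen=True)
class Detection:
    """One detected sharp peak/interval."""

    t0: int
    duration: int
    sign: int
    zscore: float
    weight: float


def filter_units_by_rate(
    data: SpikeTrainSet, min_rate_hz: float = 2.0
) -> SpikeTrainSet:
    """Keep only units firing at >= ``min_rate_hz`` under EVERY stimulus type.

    The survivor set is identical across stimulus types, so downstream
    networks share one node set.
    """
    rate_table = np.stack(
        [data.rates_hz(s).to_numpy() for s in data.stimulus_types]
    )
    keep = (rate_table >= min_rate_hz).all(axis=0)
    if not keep.any():
        raise ValueError("no units survive the firing-rate filter")
    return data.select_units(data.unit_ids[keep])


def _jitter_smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Replace each spike with a uniform mass over its jitter window.

    Operates along axis 1 of an (M, N, ...) array; a trailing partial window
    is averaged over its own length.
    """
    n = x.shape[1]
    starts = np.arange(0, n, window)
    sums = np.add.reduceat(x.astype(np.float64), starts, axis=1)
    sizes = np.diff(np.append(starts, n)).astype(float)
    shape = [1] * x.ndim
    shape[1] = len(starts)
    means = sums / sizes.reshape(shape)
    return np.repeat(means, np.diff(np.append(starts, n)), axis=1)


def _pad_flatten(x: np.ndarray, pad: int) -> np.ndarray:
    """(M, N, U) -> (M*(N+pad), U) with zero guard bins between trials."""
    m, n, u = x.shape
    out = np.zeros((m, n + pad, u), dtype=np.float32)
    out[:, :n, :] = x
    return out.reshape(m * (n + pad), u)


def _coincidence_matrix(x: np.ndarray, y: np.ndarray, n_lags: int) -> np.ndarray:
    """sum_trials sum_t x(t) y(t+tau) for tau = 0..n_lags, all unit pairs.

    ``x``/``y`` are zero-padded flattened (T, U) arrays sharing a layout with
    at least ``n_lags`` guard bins per trial.
    """
    t, u = x.shape
    out = np.empty((n_lags + 1, u, u), dtype=np.float64)
    for tau in range(n_lags + 1):
        a = x[: t - tau] if tau else x
        b = y[tau:]
        out[tau] = a.T @ b
    return out


def ccg_matrix(
    data: SpikeTrainSet,
    params: DetectionParams,
    jitter_mode: str = "analytic",
    n_jitter: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and jitter-expected CCGs for every ordered unit pair.

    Returns two (U, U, L+1) arrays indexed [source, target, lag]. The jitter
    expectation is analytic by default; ``jitter_mode="mc"`` averages
    ``n_jitter`` seeded within-window spike redistributions instead.
    """
    if data.n_bins <= params.n_lags:
        raise ValueError("trials shorter than the lag axis")
    return _ccg_pairs(
        data, params.n_lags, params.jitter_window, jitter_mode, n_jitter, seed
    )


def _ccg_pairs(
    data: SpikeTrainSet,
    L: int,
    jitter_window: int,
    jitter_mode: str = "analytic",
    n_jitter: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    lam = data.mean_count_per_bin()
    if np.any(lam <= 0):
        raise ValueError("zero-rate unit: the CCG normalization vanishes")
    m, n = data.n_trials, data.n_bins
    x = data.spikes.astype(np.float32)

    flat = _pad_flatten(x, L)
    raw_counts = _coincidence_matrix(flat, flat, L)

    if jitter_mode == "analytic":
        sm = _pad_flatten(_jitter_smooth(x, jitter_window), L)
        jit_counts = _coincidence_matrix(sm, sm, L)
    elif jitter_mode == "mc":
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(raw_counts)
        for _ in range(n_jitter):
            xj = _jitter_resample(data.spikes, jitter_window, rng)
            fj = _pad_flatten(xj.astype(np.float32), L)
            acc += _coincidence_matrix(fj, fj, L)
        jit_counts = acc / n_jitter
    else:
        raise ValueError("jitter_mode must be 'analytic' or 'mc'")

    theta = (n - np.arange(L + 1)).astype(np.float64)
    norm = m * theta[:, None, None] * np.sqrt(lam[None, :, None] * lam[None, None, :])
    raw = np.transpose(raw_counts / norm, (1, 2, 0))
    jit = np.transpose(jit_counts / norm, (1, 2, 0))
    return raw, jit


def _jitter_resample(spikes: np.ndarray, window: int, rng) -> np.ndarray:
    """One within-window uniform redistribution of every unit's spikes."""
    m, n, u = spikes.shape
    out = np.zeros_like(spikes)
    starts = np.arange(0, n, window)
    for s in starts:
        e = min(s + window, n)
        block = spikes[:, s:e, :]
        counts = block.sum(axis=1)
        order = rng.permuted(
            np.broadcast_to(np.arange(e - s)[None, :, None], block.shape), axis=1
        )
        out[:, s:e, :] = order < counts[:, None, :]
    return out


def compute_ccg(
    train_a: np.ndarray,
    train_b: np.ndarray,
    params: DetectionParams,
    jitter_mode: str = "analytic",
    n_jitter: int = 50,
    seed: int = 0,
) -> CCGCurve:
    """CCG curve from source ``train_a`` to target ``train_b``.

    Trains are (M, N) binary arrays with equal trial counts and lengths.
    """
    a = np.atleast_2d(np.asarray(train_a))
    b = np.atleast_2d(np.asarray(train_b))
    if a.shape != b.shape:
        raise ValueError("trains must share trial count and length")
    x = np.stack([a, b], axis=2)
    L = min(params.n_lags, a.shape[1] - 1)
    data = SpikeTrainSet(
        spikes=x.astype(np.uint8),
        trial_stimulus=np.array(["_"] * a.shape[0]),
        units=_two_unit_table(),
    )
    raw, jit = _ccg_pairs(
        data, L, params.jitter_window, jitter_mode, n_jitter, seed
    )
    return CCGCurve(raw=raw[0, 1], jitter_expectation=jit[0, 1], lags=np.arange(L + 1))


def _two_unit_table() -> pd.DataFrame:
    return pd.DataFrame({"area": ["_", "_"]}, index=pd.Index([0, 1], name="unit"))


def normalized_entropy(raw: np.ndarray | CCGCurve) -> float:
    """Shannon entropy of the raw CCG's lag distribution over log(#lags).

    The raw (non-negative) curve is normalized to sum 1; an all-zero curve is
    maximally unreliable and scores 0.
    """
    if isinstance(raw, CCGCurve):
        raw = raw.raw
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need >= 2 lag bins")
    total = raw.sum()
    if total <= 0:
        return 0.0
    p = raw / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(raw.size))


def _moving_average(x: np.ndarray, d: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[d:] - c[:-d]) / d


def detect_connection(
    curve: CCGCurve | np.ndarray, params: DetectionParams, min_t0: int = 0
) -> Detection | None:
    """Best sharp peak/interval in a corrected CCG, or None.

    For each duration D in [1, tau_max+1] the moving-average set C(D) spans
    the whole lag axis; candidate onsets are t0 in [min_t0, tau_max-D+1]. The
    smallest qualifying D wins (it carries the highest significance); within
    it, the window with the largest |Z| is reported. A constant curve
    (sigma = 0) yields no detection for that duration.
    """
    cc = curve.corrected if isinstance(curve, CCGCurve) else np.asarray(curve, float)
    if not np.all(np.isfinite(cc)):
        raise ValueError("corrected CCG must be finite")
    for d in range(1, params.tau_max + 2):
        if d > cc.size:
            break
        ma = _moving_average(cc, d)
        mu, sigma = float(ma.mean()), float(ma.std())
        if sigma == 0.0:
            continue
        hi = params.tau_max - d + 1
        if hi < min_t0:
            continue
        cand = ma[min_t0 : hi + 1]
        z = (cand - mu) / sigma
        sig = np.abs(z) > params.n_sigma
        if not sig.any():
            continue
        k = int(np.flatnonzero(sig)[np.argmax(np.abs(z[sig]))])
        t0 = min_t0 + k
        sign = 1 if z[k] > 0 else -1
        window = cc[t0 : t0 + d]
        weight = float(window.max() if sign > 0 else window.min())
        return Detection(
            t0=t0, duration=d, sign=sign, zscore=float(z[k]), weight=weight
        )
    return None


def resolve_zero_lag(
    det_ab: Detection | None,
    det_ba: Detection | None,
    curve_ab: CCGCurve | np.ndarray | None,
    curve_ba: CCGCurve | np.ndarray | None,
    params: DetectionParams,
) -> tuple[Detection | None, Detection | None]:
    """Resolve mutually zero-lag detections between the two orderings.

    When both directions peak at t0 = 0, the direction with the higher
    significance is the primary one; the other survives only if it also has
    a significant window at t0 > 0, in which case it is re-reported at that
    window. An exact significance tie keeps the A->B ordering (callers pass
    pairs in lexicographic source/target order, making the tie-break
    deterministic and logged by convention).
    """
    if det_ab is None or det_ba is None:
        return det_ab, det_ba
    if det_ab.t0 != 0 or det_ba.t0 != 0:
        return det_ab, det_ba
    ab_wins = abs(det_ab.zscore) >= abs(det_ba.zscore)
    if ab_wins:
        loser = detect_connection(curve_ba, params, min_t0=1)
        return det_ab, loser
    winner = det_ba
    loser = detect_connection(curve_ab, params, min_t0=1)
    return loser, winner


def build_network(
    data: SpikeTrainSet,
    params: DetectionParams = DetectionParams(),
    stimulus=None,
    jitter: bool = True,
    jitter_mode: str = "analytic",
    seed: int = 0,
) -> nx.DiGraph:
    """Signed directed functional network of a (rate-filtered) session.

    Evaluates every ordered unit pair: pairs whose raw CCG fails the
    normalized-entropy reliability filter are excluded; surviving pairs are
    screened for sharp peaks/intervals on the jitter-corrected CCG
    (``jitter=False`` skips the correction, for comparison runs); mutually
    zero-lag detections are resolved to a primary direction. Edge weight is
    the signed corrected-CCG extremum within the winning window. Unit
    metadata (area, position, rate) is attached to the nodes and per-pair
    exclusion counts to ``graph.graph["exclusions"]``.
    """
    if stimulus is not None:
        data = data.select_trials(stimulus)
    raw, jit = ccg_matrix(data, params, jitter_mode=jitter_mode, seed=seed)
    corrected = raw - jit if jitter else raw

    ids = data.unit_ids
    u = len(ids)
    rates = data.rates_hz()
    excl = {"low_entropy": 0, "zero_lag_dropped": 0}

    detections: dict[tuple[int, int], Detection] = {}
    entropy_ok = np.zeros((u, u), dtype=bool)
    for i in range(u):
        for j in range(u):
            if i == j:
                continue
            if normalized_entropy(raw[i, j]) < params.entropy_threshold:
                excl["low_entropy"] += 1
                continue
            entropy_ok[i, j] = True
            det = detect_connection(corrected[i, j], params)
            if det is not None:
                detections[(i, j)] = det

    # zero-lag resolution per unordered pair, lexicographic order fixed
    for i in range(u):
        for j in range(i + 1, u):
            d_ab, d_ba = detections.get((i, j)), detections.get((j, i))
            if d_ab is None or d_ba is None:
                continue
            r_ab, r_ba = resolve_zero_lag(
                d_ab, d_ba, corrected[i, j], corrected[j, i], params
            )
            for key, old, new in (((i, j), d_ab, r_ab), ((j, i), d_ba, r_ba)):
                if new is None:
                    del detections[key]
                    excl["zero_lag_dropped"] += 1
                elif new is not old:
                    detections[key] = new

    g = nx.DiGraph()
    g.graph["params"] = params
    g.graph["exclusions"] = excl
    g.graph["jitter"] = jitter
    for k, uid in enumerate(ids):
        attrs = {"rate_hz": float(rates.loc[uid])}
        for col in ("area", "x", "y", "z"):
            if col in data.units.columns:
                attrs[col] = data.units.loc[uid, col]
        g.add_node(uid, **attrs)
    for (i, j), det in sorted(detections.items()):
        g.add_edge(
            ids[i],
            ids[j],
            sign=det.sign,
            weight=det.weight,
            lag=det.t0,
            duration=det.duration,
            significance=det.zscore,
        )
    return g
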