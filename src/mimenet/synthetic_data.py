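"""Generators of multichannel signals with known directed-coupling ground
truth.

Three families: linear autoregressive channels with planted lagged
couplings, coupled Hénon-type chaotic maps, and a band-limited-noise base
that mimics scalp-potential autocorrelation. Multi-subject builders stack
synchronized "brains" with unidirectional subject-to-subject coupling
(driver–responder pairs, star ensembles, alternating "ping-pong" pairs)
and two-condition variants that plant a contrast structure.

All generators are fully deterministic under their seed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .signal_io import MultichannelRecording, build_augmented

__all__ = [
    "CouplingSpec",
    "gen_coupled_linear",
    "gen_coupled_nonlinear",
    "gen_two_brain",
    "gen_ensemble",
    "gen_two_condition",
    "DEFAULT_LABELS",
]

log = logging.getLogger(__name__)

#: 10–20-system labels used for generated channels (first n_channels taken)
DEFAULT_LABELS = ["P4", "T8", "C4", "F4", "F3", "C3", "T7", "P3", "O1", "O2"]

BURN_IN = 1000


@dataclasses.dataclass
class CouplingSpec:
    """Ground-truth description of one generated subject.

    couplings: list of (source_channel, target_channel, lag, strength);
    base_process: "ar1", "bandlimited" (resonant AR(2)) or "henon";
    for "henon" the coupling strength is the map coupling c and noise_sd is
    observational noise added after iteration.
    """

    n_channels: int = 4
    couplings: list[tuple[int, int, int, float]] = dataclasses.field(
        default_factory=list)
    base_process: str = "ar1"
    ar_coeff: float = 0.5
    resonance_hz: float = 10.0
    pole_radius: float = 0.85
    noise_sd: float = 1.0
    fs: float = 100.0
    duration_s: float = 60.0
    seed: int = 0
    subject_id: str = "S1"

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        for s, d, lag, w in self.couplings:
            if not (0 <= s < self.n_channels and 0 <= d < self.n_channels):
                raise ValueError(f"coupling ({s},{d}) out of channel range")
            if lag < 1:
                raise ValueError("coupling lags must be >= 1")
            if w < 0:
                raise ValueError("coupling strengths must be >= 0")
        if self.base_process not in {"ar1", "bandlimited", "henon"}:
            raise ValueError(f"unknown base process {self.base_process!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def labels(self) -> list[str]:
        if self.n_channels <= len(DEFAULT_LABELS):
            return DEFAULT_LABELS[: self.n_channels]
        return [f"ch{i}" for i in range(self.n_channels)]

    def truth_edges(self) -> list[tuple[str, str]]:
        lab = self.labels()
        return [(lab[s], lab[d]) for s, d, _, w in self.couplings if w > 0]


def _base_coeffs(spec: CouplingSpec) -> list[float]:
    if spec.base_process == "ar1":
        return [spec.ar_coeff]
    r, w0 = spec.pole_radius, 2 * np.pi * spec.resonance_hz / spec.fs
    return [2 * r * np.cos(w0), -r * r]


def _check_stable(K: int, base: list[float],
                  couplings: list[tuple[int, int, int, float]]) -> None:
    """Spectral radius of the VAR companion matrix must stay below 1."""
    p = max([len(base)] + [lag for _, _, lag, _ in couplings] or [1])
    A = np.zeros((p, K, K))
    for i, a in enumerate(base):
        A[i] += a * np.eye(K)
    for s, d, lag, w in couplings:
        A[lag - 1][d, s] += w
    comp = np.zeros((K * p, K * p))
    comp[:K, :] = np.concatenate(A, axis=1)
    if p > 1:
        comp[K:, :-K] = np.eye(K * (p - 1))
    rho = float(np.max(np.abs(np.linalg.eigvals(comp))))
    if rho >= 1.0:
        raise ValueError(f"unstable coupling spec: spectral radius {rho:.3f}")


def _simulate_linear(K: int, n_samples: int, base: list[float],
                     couplings: list[tuple[int, int, int, float]],
                     noise_sd: float, rng: np.random.Generator,
                     modulation: dict[tuple[int, int], np.ndarray] | None = None,
                     ) -> np.ndarray:
    """Iterate the coupled AR system; returns (K, n_samples) after burn-in.

    ``modulation`` maps a (source, target) channel pair to a per-sample gain
    (length burn_in + n_samples) applied on top of the coupling strength.
    """
    if modulation:
        # time-varying gains: verify stability of every gain configuration
        # that actually occurs (alternating-direction pairs are stable even
        # though both directions together would not be)
        gates = np.vstack([
            modulation.get((s, d), np.ones(BURN_IN + n_samples))
            for s, d, _, _ in couplings
        ])
        configs = np.unique(gates, axis=1).T
        for cfg in configs[:16]:
            _check_stable(K, base, [
                (s, d, lag, w * g)
                for (s, d, lag, w), g in zip(couplings, cfg)
            ])
    else:
        _check_stable(K, base, couplings)
    total = BURN_IN + n_samples
    p = max([len(base)] + [lag for _, _, lag, _ in couplings] or [1])
    x = np.zeros((K, total))
    noise = rng.normal(0.0, noise_sd, size=(K, total))
    for t in range(p, total):
        v = noise[:, t].copy()
        for i, a in enumerate(base):
            v += a * x[:, t - 1 - i]
        for s, d, lag, w in couplings:
            g = 1.0
            if modulation and (s, d) in modulation:
                g = modulation[(s, d)][t]
            v[d] += w * g * x[s, t - lag]
        x[:, t] = v
    return x[:, BURN_IN:]


def gen_coupled_linear(spec: CouplingSpec
                       ) -> tuple[MultichannelRecording, list[tuple[str, str]]]:
    """Linear AR channels with planted lagged couplings.

    Returns the (unstandardized) recording and the ground-truth directed
    edge list in channel-label terms.
    """
    if spec.base_process == "henon":
        raise ValueError("use gen_coupled_nonlinear for the henon base")
    rng = np.random.default_rng(spec.seed)
    data = _simulate_linear(spec.n_channels, spec.n_samples,
                            _base_coeffs(spec), spec.couplings,
                            spec.noise_sd, rng)
    rec = MultichannelRecording(data, spec.fs, spec.labels(),
                                subject_id=spec.subject_id)
    return rec, spec.truth_edges()


class _Diverged(RuntimeError):
    pass


def _simulate_henon(K: int, n_samples: int,
                    couplings: list[tuple[int, int, int, float]],
                    rng: np.random.Generator) -> np.ndarray:
    total = BURN_IN + n_samples
    x = np.zeros((K, total))
    x[:, :2] = rng.uniform(0.0, 0.5, size=(K, 2))
    driven = {d: (s, c) for s, d, _, c in couplings if c > 0}
    for t in range(2, total):
        prev, prev2 = x[:, t - 1], x[:, t - 2]
        v = 1.4 - prev**2 + 0.3 * prev2
        for d, (s, c) in driven.items():
            v[d] = (1.4 - (c * prev[s] * prev[d] + (1 - c) * prev[d] ** 2)
                    + 0.3 * prev2[d])
        if np.any(np.abs(v) > 1e5):
            raise _Diverged
        x[:, t] = v
    return x[:, BURN_IN:]


def gen_coupled_nonlinear(spec: CouplingSpec, max_reseeds: int = 20
                          ) -> tuple[MultichannelRecording, list[tuple[str, str]]]:
    """Coupled Hénon-type chaotic maps with unidirectional coupling.

    Each coupling (s, d, lag, c) makes channel d's quadratic term a
    c-weighted mix of its own state and the source's (the standard coupled
    Hénon benchmark); at most one source per driven channel. Diverging
    orbits are rejected and re-seeded with a logged notice. noise_sd is
    observational noise added to the orbit.
    """
    for d in {c[1] for c in spec.couplings}:
        if sum(1 for c in spec.couplings if c[1] == d) > 1:
            raise ValueError(f"channel {d} has more than one henon source")
    for attempt in range(max_reseeds):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, attempt]))
        try:
            data = _simulate_henon(spec.n_channels, spec.n_samples,
                                   spec.couplings, rng)
            break
        except _Diverged:
            log.warning("henon orbit diverged (attempt %d), re-seeding",
                        attempt + 1)
            warnings.warn("henon orbit diverged; re-seeded", RuntimeWarning,
                          stacklevel=2)
    else:
        raise RuntimeError("all henon re-seeds diverged")
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    rec = MultichannelRecording(data, spec.fs, spec.labels(),
                                subject_id=spec.subject_id)
    return rec, spec.truth_edges()


def _offset(couplings, off_s, off_d):
    return [(s + off_s, d + off_d, lag, w) for s, d, lag, w in couplings]


def _split_combined(data: np.ndarray, specs: list[CouplingSpec]
                    ) -> list[MultichannelRecording]:
    recs, start = [], 0
    for sp in specs:
        recs.append(MultichannelRecording(
            data[start:start + sp.n_channels], sp.fs, sp.labels(),
            subject_id=sp.subject_id))
        start += sp.n_channels
    return recs


def gen_two_brain(reader_spec: CouplingSpec, listener_spec: CouplingSpec,
                  coupling: float, lag: int = 1,
                  driver_channels: list[int] | None = None,
                  driven_channels: list[int] | None = None,
                  ) -> tuple[MultichannelRecording, dict]:
    """Two synchronized subjects where a subset of the first subject's
    channels unidirectionally drives a subset of the second's.

    Swap the spec arguments to generate the role-swapped variant. Returns
    the augmented recording and a truth dict naming the driver subject and
    the coupled channel pairs.
    """
    if reader_spec.fs != listener_spec.fs:
        raise ValueError("subject sampling rates differ")
    if reader_spec.subject_id == listener_spec.subject_id:
        raise ValueError("subjects need distinct ids")
    nA, nB = reader_spec.n_channels, listener_spec.n_channels
    driver_channels = driver_channels or list(range(min(2, nA)))
    driven_channels = driven_channels or list(range(min(2, nB)))

    cross = []
    if coupling > 0:
        for s, d in zip(driver_channels, driven_channels):
            cross.append((s, nA + d, lag, coupling))
    combined = (_offset(reader_spec.couplings, 0, 0)
                + _offset(listener_spec.couplings, nA, nA) + cross)
    rng = np.random.default_rng(reader_spec.seed)
    n = min(reader_spec.n_samples, listener_spec.n_samples)
    data = _simulate_linear(nA + nB, n, _base_coeffs(reader_spec), combined,
                            reader_spec.noise_sd, rng)
    recA, recB = _split_combined(data, [reader_spec, listener_spec])
    truth = {
        "driver": reader_spec.subject_id if coupling > 0 else None,
        "responder": listener_spec.subject_id if coupling > 0 else None,
        "coupled_pairs": [(s, d) for s, d in
                          zip(driver_channels, driven_channels)]
        if coupling > 0 else [],
        "strength": coupling,
        "lag": lag,
    }
    return build_augmented(recA, recB), truth


def gen_ensemble(n_subjects: int,
                 coupling_graph: list[tuple[int, int]],
                 spec: CouplingSpec, *,
                 strength: float = 0.6, lag: int = 1,
                 pingpong_pairs: list[tuple[int, int]] | None = None,
                 window_samples: int = 1000, pingpong_block: int = 2,
                 n_cross: int = 2) -> dict:
    """Multi-subject ensemble with an asymmetric subject-level flow graph.

    ``coupling_graph`` lists directed subject-index edges (a, b): subject
    a's first ``n_cross`` channels drive subject b's first ``n_cross``
    channels. ``pingpong_pairs`` lists unordered pairs whose coupling
    direction alternates every ``pingpong_block`` windows of
    ``window_samples`` samples, so per-window dominance swaps while
    time-averaged weights stay comparable. The graph restricted to
    non-ping-pong edges must be acyclic.

    Returns {"subjects": [recordings], "augmented": {(a,b): recording for
    a<b}, "truth": {...}}.
    """
    pingpong_pairs = [tuple(sorted(p)) for p in (pingpong_pairs or [])]
    for a, b in coupling_graph:
        if not (0 <= a < n_subjects and 0 <= b < n_subjects) or a == b:
            raise ValueError(f"invalid graph edge ({a}, {b})")
    static = [e for e in coupling_graph
              if tuple(sorted(e)) not in pingpong_pairs]
    g = {i: set() for i in range(n_subjects)}
    for a, b in static:
        g[a].add(b)
    seen, done = set(), set()

    def _dfs(u):
        seen.add(u)
        for v in g[u]:
            if v in seen and v not in done:
                raise ValueError("static coupling graph has a cycle")
            if v not in seen:
                _dfs(v)
        done.add(u)

    for u in range(n_subjects):
        if u not in seen:
            _dfs(u)

    nch = spec.n_channels
    total = BURN_IN + spec.n_samples

    def cross_edges(a, b, channels):
        return [(a * nch + c, b * nch + c, lag, strength)
                for c in channels]

    # static edges drive the low channels, ping-pong pairs the high ones,
    # so no channel is driven by two subjects at once (which would dilute
    # per-window dominance of the planted direction)
    static_ch = list(range(min(n_cross, nch)))
    ping_ch = [nch - 1 - c for c in range(min(n_cross, nch))]

    couplings, modulation = [], {}
    for a, b in static:
        couplings.extend(cross_edges(a, b, static_ch))
    for a, b in pingpong_pairs:
        block = (np.arange(total) - BURN_IN) // window_samples // pingpong_block
        gate_ab = (block % 2 == 0).astype(float)
        for s, d, lg, w in cross_edges(a, b, ping_ch):
            couplings.append((s, d, lg, w))
            modulation[(s, d)] = gate_ab
        for s, d, lg, w in cross_edges(b, a, ping_ch):
            couplings.append((s, d, lg, w))
            modulation[(s, d)] = 1.0 - gate_ab
    for i in range(n_subjects):
        couplings.extend(_offset(spec.couplings, i * nch, i * nch))

    rng = np.random.default_rng(spec.seed)
    data = _simulate_linear(n_subjects * nch, spec.n_samples,
                            _base_coeffs(spec), couplings, spec.noise_sd,
                            rng, modulation=modulation)
    specs = [dataclasses.replace(spec, subject_id=f"S{i + 1}")
             for i in range(n_subjects)]
    recs = _split_combined(data, specs)
    augmented = {(a, b): build_augmented(recs[a], recs[b])
                 for a in range(n_subjects) for b in range(a + 1, n_subjects)}
    return {
        "subjects": recs,
        "augmented": augmented,
        "truth": {
            "links": sorted(static),
            "pingpong": pingpong_pairs,
            "strength": strength,
            "lag": lag,
            "window_samples": window_samples,
            "pingpong_block": pingpong_block,
        },
    }


def gen_two_condition(base_spec: CouplingSpec,
                      delta_edges: list[tuple[int, int, int, float]],
                      ) -> tuple[MultichannelRecording,
                                 MultichannelRecording, dict]:
    """Two recordings differing only in planted coupling strengths.

    Condition B equals condition A's generative model with the
    ``delta_edges`` strength increments added; the same seed drives the
    noise in both so the contrast isolates the planted difference.
    Returns (recA, recB, truth).
    """
    recA, _ = gen_coupled_linear(base_spec)
    merged = {(s, d, lag): w for s, d, lag, w in base_spec.couplings}
    for s, d, lag, dw in delta_edges:
        merged[(s, d, lag)] = merged.get((s, d, lag), 0.0) + dw
    specB = dataclasses.replace(
        base_spec,
        couplings=[(s, d, lag, w) for (s, d, lag), w in merged.items()])
    recB, _ = gen_coupled_linear(specB)
    lab = base_spec.labels()
    truth = {
        "stronger_in_B": [(lab[s], lab[d]) for s, d, _, dw in delta_edges
                          if dw > 0],
        "delta_edges": delta_edges,
    }
    return recA, recB, truth
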