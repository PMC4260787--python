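"""Directed causality between a pair of series via non-uniform mixed
embedding.

The measure asks how much of the information that the selected past carries
about the target's future is contributed by the driver's lagged values. An
embedding is grown greedily: each cycle adds the lagged candidate (from
either series) with the highest conditional mutual information with the
future vector given the components already chosen, and growth stops when
the best addition no longer raises the mutual information appreciably. The
causality index is then

    R(X -> Y) = I(future; B_x | B_y) / I(future; B)   in [0, 1],

where B is the selected embedding and B_x, B_y its driver- and
driven-sourced parts. R = 0 when no driver component is selected.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from ._neighbors import SortedCloud

from .cmi_estimation import estimate_cmi, estimate_mi, jitter
from .signal_io import MultichannelRecording, WindowSpec

__all__ = [
    "MimeParams",
    "Candidate",
    "CycleRecord",
    "MixedEmbedding",
    "CausalityMatrix",
    "build_candidates",
    "select_mixed_embedding",
    "mime_causality",
    "causality_matrix",
]

DRIVER = "driver"
DRIVEN = "driven"


@dataclasses.dataclass(frozen=True)
class MimeParams:
    """Parameters of the embedding search.

    T: prediction horizon (future vector length, samples)
    Lx, Ly: maximum lag counts for the driver and driven series
    A: stopping threshold in (0, 1); growth stops once the ratio
       I(future; B_old) / I(future; B_new) reaches A
    k: neighbour count of the CMI estimator
    max_cycles: cap on embedding size
    """

    T: int = 1
    Lx: int = 5
    Ly: int = 5
    A: float = 0.95
    k: int = 4
    max_cycles: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.A < 1:
            raise ValueError(f"A must be in (0,1), got {self.A}")
        if self.T < 1 or self.Lx < 1 or self.Ly < 1:
            raise ValueError("T, Lx, Ly must all be >= 1")
        if self.T > min(self.Lx, self.Ly):
            raise ValueError(
                f"T={self.T} must not exceed min(Lx, Ly)="
                f"{min(self.Lx, self.Ly)}"
            )
        if self.k < 1 or self.max_cycles < 1:
            raise ValueError("k and max_cycles must be >= 1")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class Candidate:
    """One lagged scalar candidate: ``values[t] = series[t - lag]`` over the
    shared valid time range."""

    source: str  # DRIVER or DRIVEN
    lag: int
    values: np.ndarray = dataclasses.field(repr=False, compare=False)


@dataclasses.dataclass(frozen=True)
class CycleRecord:
    cycle: int
    source: str
    lag: int
    criterion: float
    mi_before: float
    mi_after: float
    stop_ratio: float
    accepted: bool


@dataclasses.dataclass
class MixedEmbedding:
    components: list[tuple[str, int]]
    selection_trace: list[CycleRecord]

    def __post_init__(self) -> None:
        if len(set(self.components)) != len(self.components):
            raise ValueError("duplicate (source, lag) components")

    def __len__(self) -> int:
        return len(self.components)

    def lags(self, source: str) -> list[int]:
        return [lag for s, lag in self.components if s == source]


def _min_length(params: MimeParams) -> int:
    return max(params.Lx, params.Ly) + params.T + 100


def build_candidates(x: np.ndarray, y: np.ndarray, params: MimeParams,
                     ) -> tuple[np.ndarray, list[Candidate]]:
    """Build the future cloud of the driven series and the lagged candidate
    set from both series, aligned on a common valid time range.

    x is the driver, y the driven. Candidate lags run from 0 (current
    sample) back to L-1; the future vector is (y[t+1], ..., y[t+T]).
    Returns (future, candidates) with future of shape (n_valid, T).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("driver and driven series must have equal length")
    n = x.size
    if n < _min_length(params):
        raise ValueError(
            f"series of {n} samples too short; need >= {_min_length(params)} "
            f"for Lmax={max(params.Lx, params.Ly)}, T={params.T}"
        )
    lmax = max(params.Lx, params.Ly)
    t = np.arange(lmax - 1, n - params.T)  # valid current-sample indices

    future = np.column_stack([y[t + h] for h in range(1, params.T + 1)])
    candidates = [
        Candidate(DRIVER, j, x[t - j]) for j in range(params.Lx)
    ] + [
        Candidate(DRIVEN, j, y[t - j]) for j in range(params.Ly)
    ]
    return future, candidates


def select_mixed_embedding(future: np.ndarray, candidates: list[Candidate],
                           params: MimeParams) -> MixedEmbedding:
    """Greedy forward selection of the mixed embedding.

    Each cycle picks the candidate maximising I(future; candidate | B); the
    first cycle conditions on nothing (plain MI). Growth stops when the
    best criterion is non-positive, when I(future; B_old)/I(future; B_new)
    >= A (the addition contributed almost nothing — the grown embedding is
    discarded and B_old returned), or at max_cycles.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    future = np.atleast_2d(np.asarray(future, dtype=np.float64))
    remaining = list(range(len(candidates)))
    chosen: list[int] = []
    trace: list[CycleRecord] = []
    B: np.ndarray | None = None  # (n, j) selected columns
    mi_old = 0.0

    for cycle in range(1, params.max_cycles + 1):
        if not remaining:
            break
        # trees over the candidate-independent marginal spaces, shared
        # across this cycle's criterion evaluations
        if B is None:
            cloud_xz = SortedCloud(future)
            cloud_z = None
        else:
            cloud_xz = SortedCloud(np.hstack((future, B)))
            cloud_z = SortedCloud(B)
        scores = [
            estimate_cmi(future, candidates[i].values, B, params.k,
                         _cloud_xz=cloud_xz, _cloud_z=cloud_z)
            for i in remaining
        ]
        best_pos = int(np.argmax(scores))
        best_idx = remaining[best_pos]
        best = candidates[best_idx]
        criterion = scores[best_pos]

        if criterion <= 0.0:
            trace.append(CycleRecord(cycle, best.source, best.lag, criterion,
                                     mi_old, mi_old, np.inf, accepted=False))
            break

        B_new = (best.values[:, None] if B is None
                 else np.hstack((B, best.values[:, None])))
        mi_new = max(estimate_mi(future, B_new, params.k), 0.0)
        ratio = mi_old / mi_new if mi_new > 0 else np.inf
        accepted = ratio < params.A
        trace.append(CycleRecord(cycle, best.source, best.lag, criterion,
                                 mi_old, mi_new, ratio, accepted))
        if not accepted:
            break
        chosen.append(best_idx)
        remaining.remove(best_idx)
        B, mi_old = B_new, mi_new

    return MixedEmbedding(
        components=[(candidates[i].source, candidates[i].lag) for i in chosen],
        selection_trace=trace,
    )


def _pair_rng(x: np.ndarray, y: np.ndarray, seed: int) -> np.random.Generator:
    """Jitter stream keyed by the pair's data, so a pair's causality value
    does not depend on where its channels sit in a matrix."""
    hx = zlib.crc32(np.ascontiguousarray(x).tobytes())
    hy = zlib.crc32(np.ascontiguousarray(y).tobytes())
    return np.random.default_rng(np.random.SeedSequence([seed, hx, hy]))


def _standardize_series(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=np.float64).ravel()
    sd = s.std()
    if sd == 0:
        raise ValueError("constant series has no causality structure")
    return (s - s.mean()) / sd


def mime_causality(x: np.ndarray, y: np.ndarray,
                   params: MimeParams | None = None, *, seed: int = 0,
                   return_embedding: bool = False):
    """Causality index R(X -> Y) in [0, 1] for driver series x and driven
    series y.

    Series are z-scored, tie-breaking jitter is added (seeded from ``seed``
    and the data itself), the mixed embedding is selected, and the CMI
    ratio is evaluated with both terms clamped at 0. Conventions: no driver
    component selected => R = 0; non-positive denominator => R = 0.
    """
    params = params or MimeParams()
    xs = _standardize_series(x)
    ys = _standardize_series(y)
    rng = _pair_rng(xs, ys, seed)
    xs = jitter(xs, rng)
    ys = jitter(ys, rng)

    future, candidates = build_candidates(xs, ys, params)
    emb = select_mixed_embedding(future, candidates, params)

    by_key = {(c.source, c.lag): c.values for c in candidates}
    cols = {DRIVER: [], DRIVEN: []}
    for source, lag in emb.components:
        cols[source].append(by_key[(source, lag)])

    if not cols[DRIVER]:
        r = 0.0
    else:
        Bx = np.column_stack(cols[DRIVER])
        By = np.column_stack(cols[DRIVEN]) if cols[DRIVEN] else None
        B = np.column_stack(cols[DRIVER] + cols[DRIVEN])
        denom = estimate_mi(future, B, params.k, clamp=True)
        if denom <= 0.0:
            r = 0.0
        else:
            numer = estimate_cmi(future, Bx, By, params.k, clamp=True)
            r = float(np.clip(numer / denom, 0.0, 1.0))
    return (r, emb) if return_embedding else r


@dataclasses.dataclass
class CausalityMatrix:
    """K×K matrix of pairwise causality values: entry (i, j) is the flow
    from channel i (row, source) to channel j (column, target)."""

    values: np.ndarray
    channel_labels: list[str]
    window: WindowSpec | None = None
    block_boundaries: dict[str, tuple[int, int]] | None = None
    params: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        k = len(self.channel_labels)
        if self.values.shape != (k, k):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{k} labels"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("causality values must lie in [0, 1]")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly 0")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(self.n_channels, dtype=bool)
        return self.values[mask]

    def block(self, source_subject: str, target_subject: str) -> np.ndarray:
        if not self.block_boundaries:
            raise ValueError("matrix carries no block boundaries")
        r0, r1 = self.block_boundaries[source_subject]
        c0, c1 = self.block_boundaries[target_subject]
        return self.values[r0:r1, c0:c1]

    def save(self, path: str | Path) -> None:
        """Write the matrix as labelled CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame(self.values, index=self.channel_labels,
                     columns=self.channel_labels).to_csv(path)
        meta = {
            "window": self.window.as_dict() if self.window else None,
            "block_boundaries": self.block_boundaries,
            "params": self.params,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CausalityMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar = path.with_suffix(path.suffix + ".json")
        window = blocks = params = None
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if meta.get("window"):
                window = WindowSpec(**meta["window"])
            if meta.get("block_boundaries"):
                blocks = {k: tuple(v)
                          for k, v in meta["block_boundaries"].items()}
            params = meta.get("params")
        return cls(df.to_numpy(), [str(c) for c in df.columns],
                   window=window, block_boundaries=blocks, params=params)


def causality_matrix(window_data: MultichannelRecording,
                     params: MimeParams | None = None, *, seed: int = 0,
                     pairs: list[tuple[int, int]] | None = None,
                     ) -> CausalityMatrix:
    """Pairwise causality matrix of a standardized window.

    ``pairs`` restricts computation to selected (source, target) index
    pairs (e.g. only cross-subject blocks); unlisted entries stay 0.
    """
    if not window_data.standardized:
        raise ValueError("window must be standardized before analysis")
    params = params or MimeParams()
    k = window_data.n_channels
    if pairs is None:
        pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    values = np.zeros((k, k))
    for i, j in pairs:
        if i == j:
            continue
        values[i, j] = mime_causality(window_data.data[i],
                                      window_data.data[j],
                                      params, seed=seed)
    return CausalityMatrix(
        values=values,
        channel_labels=list(window_data.channel_labels),
        block_boundaries=window_data.block_boundaries,
        params=params.as_dict(),
    )
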