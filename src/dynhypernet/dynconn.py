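"""Sliding-window dynamic functional connectivity.

A subject's multivariate signal (T timepoints x N components) is sliced into
overlapping rectangular windows; within each window the Pearson correlation of
every unordered component pair is computed.  Linking the correlations of one
pair across windows yields that functional connection's *relevant time series*;
stacking all M = N(N-1)/2 of them column-wise gives the W x M relevant-series
matrix every later stage of the pipeline operates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubjectTimeSeries",
    "WindowSpec",
    "ConnectionIndex",
    "RelevantSeriesMatrix",
    "DegenerateWindowError",
    "InvalidWindowError",
    "count_windows",
    "windowed_correlations",
    "build_relevant_series",
]

GROUPS = ("positive", "negative")


class InvalidWindowError(ValueError):
    """Window specification incompatible with the series length."""


class DegenerateWindowError(ValueError):
    """A component has zero variance inside some window."""


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular sliding window: ``length`` timepoints, advanced by ``step``."""

    length: int
    step: int = 1

    def __post_init__(self) -> None:
        if self.length < 2:
            raise InvalidWindowError(f"window length must be >= 2, got {self.length}")
        if self.step < 1:
            raise InvalidWindowError(f"window step must be >= 1, got {self.step}")


@dataclass
class SubjectTimeSeries:
    """One subject's component signals with a binary group label.

    ``data`` is a real (T, N) matrix; every column must have nonzero variance
    over the full series and T >= 2, N >= 3.
    """

    subject_id: str
    group: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (T, N) matrix")
        T, N = self.data.shape
        if T < 2:
            raise ValueError(f"need at least 2 timepoints, got {T}")
        if N < 3:
            raise ValueError(f"need at least 3 components, got {N}")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in series")
        sd = self.data.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"subject {self.subject_id}: zero-variance component(s) {dead.tolist()}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


class ConnectionIndex:
    """Bijection between unordered component pairs (i, j), i < j, and flat ids.

    Pairs are ordered lexicographically (i ascending, then j), 0-based; the flat
    index is shared by every downstream stage, so hypernetwork node ``m`` always
    denotes the same component pair across subjects.
    """

    def __init__(self, n_components: int) -> None:
        if n_components < 2:
            raise ValueError("need at least 2 components")
        self.n_components = int(n_components)
        iu = np.triu_indices(self.n_components, k=1)
        self._pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
        self._flat = {p: m for m, p in enumerate(self._pairs)}

    @property
    def n_connections(self) -> int:
        """M = N(N-1)/2."""
        return len(self._pairs)

    def to_flat(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        return self._flat[(i, j)]

    def to_pair(self, m: int) -> tuple[int, int]:
        return self._pairs[m]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(self._pairs)

    def labels(self) -> list[str]:
        return [f"{i}-{j}" for i, j in self._pairs]


@dataclass
class RelevantSeriesMatrix:
    """W x M matrix of windowed correlations (one column per connection)."""

    values: np.ndarray
    window_spec: WindowSpec
    connection_index: ConnectionIndex

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_connections(self) -> int:
        return self.values.shape[1]


def count_windows(T: int, spec: WindowSpec) -> int:
    """Number of full windows, W = floor((T - l) / s) + 1.

    Trailing partial windows are discarded.  Raises :class:`InvalidWindowError`
    when the spec admits no window.
    """
    if spec.length > T:
        raise InvalidWindowError(
            f"window length {spec.length} exceeds series length {T}"
        )
    W = (T - spec.length) // spec.step + 1
    if W < 1:
        raise InvalidWindowError("window spec yields no windows")
    return W


def windowed_correlations(
    ts: SubjectTimeSeries, spec: WindowSpec, on_degenerate: str = "error"
) -> np.ndarray:
    """Per-window Pearson correlation matrices, shape (W, N, N).

    Window ``w`` covers rows [w*s, w*s + l).  A zero-variance component inside a
    window raises :class:`DegenerateWindowError` naming the window and component
    (``on_degenerate='error'``), or substitutes r = 0 for the affected pairs
    (``on_degenerate='zero'``).
    """
    if on_degenerate not in ("error", "zero"):
        raise ValueError("on_degenerate must be 'error' or 'zero'")
    T, N = ts.data.shape
    W = count_windows(T, spec)
    out = np.empty((W, N, N))
    for w in range(W):
        seg = ts.data[w * spec.step : w * spec.step + spec.length]
        sd = seg.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            if on_degenerate == "error":
                raise DegenerateWindowError(
                    f"subject {ts.subject_id}: component {dead[0]} has zero "
                    f"variance in window {w}"
                )
            keep = sd > 0
            r = np.zeros((N, N))
            if keep.sum() >= 2:
                r[np.ix_(keep, keep)] = np.corrcoef(seg[:, keep], rowvar=False)
            np.fill_diagonal(r, 1.0)
        else:
            r = np.corrcoef(seg, rowvar=False)
        out[w] = np.clip(r, -1.0, 1.0)
    return out


def build_relevant_series(
    ts: SubjectTimeSeries, spec: WindowSpec, on_degenerate: str = "error"
) -> RelevantSeriesMatrix:
    """Assemble the relevant-series matrix (windows x connections).

    Column ``m`` holds [r_{i,j}(1), ..., r_{i,j}(W)] for the pair mapped to
    ``m`` by :class:`ConnectionIndex`.  With a single full-length window
    (l = T) this degenerates to the static, full-series correlation profile.
    """
    corr = windowed_correlations(ts, spec, on_degenerate=on_degenerate)
    idx = ConnectionIndex(ts.n_components)
    iu = np.triu_indices(ts.n_components, k=1)
    values = corr[:, iu[0], iu[1]]
    return RelevantSeriesMatrix(values=values, window_spec=spec, connection_index=idx)
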