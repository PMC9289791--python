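"""Spatio-temporal warping (STW) feature extraction.

STW measures, for every unordered pair of recording channels, the
dynamic-time-warping (DTW) alignment cost between the two channels'
simultaneous observation windows — and repeats this on the first and
second difference streams of each window.  For ``NC`` channels this
yields ``NC·(NC−1)/2 · 3`` raw distances per window (360 for a
16-channel cuff).

On top of the raw distances the extractor keeps a long-short-term memory
in the style of an LSTM cell, but with no trained parameters:

* the log-scaled distances ``L = log(1 + raw)`` are accumulated into a
  running **cell state** (long-term memory, an "information highway");
* ``L`` is multiplied elementwise with the previous window's output
  (short-term **window fusion**; a pointwise switch passes ``L`` through
  unchanged on the first window of each stimulus);
* the cell state, weighted by a scalar ``β`` (0.75 ≤ β ≤ 1.25), is added
  back in, the sum is L2-normalised, and the normalised log of the cell
  state is added to form the output.

The state is reset at stimulus boundaries so no information leaks across
events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Literal

import numpy as np
from numba import njit

from .features_td import FeatureMatrix, l2_normalize
from .preprocess import WindowSet

__all__ = [
    "STWConfig",
    "STWState",
    "dtw_distance",
    "derivative_streams",
    "stw_feature_count",
    "stw_raw_vector",
    "stw_step",
    "run_stw_framework",
]


@dataclass(frozen=True)
class STWConfig:
    """STW extractor parameters.

    Parameters
    ----------
    beta : float
        Cell-state weight in the output mix; kept in the documented
        range [0.75, 1.25] (default 1.0).
    eps : float
        Positive guard added inside logarithms.
    dtw_cost : {"absolute", "squared"}
        Local cost of aligning two samples (default absolute
        difference).
    dtw_band : int | None
        Optional Sakoe–Chiba radius constraining the warping path;
        ``None`` (default) means unconstrained.
    prev_partner : {"output", "log"}
        Whether window fusion multiplies with the previous window's
        final output (default) or with its raw log-scaled distances.
    enforce_beta_range : bool
        Reject beta outside [0.75, 1.25] (default True).
    """

    beta: float = 1.0
    eps: float = 1e-8
    dtw_cost: Literal["absolute", "squared"] = "absolute"
    dtw_band: int | None = None
    prev_partner: Literal["output", "log"] = "output"
    enforce_beta_range: bool = True

    def __post_init__(self):
        if self.enforce_beta_range and not 0.75 <= self.beta <= 1.25:
            raise ValueError(f"beta={self.beta} outside the documented range [0.75, 1.25]")
        if not self.eps > 0:
            raise ValueError("eps must be > 0")
        if self.dtw_cost not in ("absolute", "squared"):
            raise ValueError(f"unknown dtw_cost {self.dtw_cost!r}")
        if self.dtw_band is not None and self.dtw_band < 0:
            raise ValueError("dtw_band must be >= 0")


@dataclass
class STWState:
    """Memory of the STW extractor between windows of one stimulus.

    ``cell`` is the accumulated long-term state (length F), ``prev_out``
    the previous window's output (absent iff ``t == 0``), ``t`` the
    iteration counter.
    """

    cell: np.ndarray
    prev_out: np.ndarray | None = None
    t: int = 0
    prev_log: np.ndarray | None = None  # kept only for prev_partner="log"

    @classmethod
    def initial(cls, n_features: int) -> "STWState":
        return cls(cell=np.zeros(n_features), prev_out=None, t=0)


@njit(cache=True, fastmath=True)
def _dtw_full(s, t, squared):  # pragma: no cover - exercised via dtw_distance
    n = s.shape[0]
    m = t.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    d = s[0] - t[0]
    prev[0] = d * d if squared else abs(d)
    for j in range(1, m):
        d = s[0] - t[j]
        prev[j] = prev[j - 1] + (d * d if squared else abs(d))
    for i in range(1, n):
        si = s[i]
        d = si - t[0]
        cur[0] = prev[0] + (d * d if squared else abs(d))
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            d = si - t[j]
            cur[j] = best + (d * d if squared else abs(d))
        tmp = prev
        prev = cur
        cur = tmp
    return prev[m - 1]


@njit(cache=True, fastmath=True)
def _dtw_band(s, t, squared, band):  # pragma: no cover
    n = s.shape[0]
    m = t.shape[0]
    inf = np.inf
    prev = np.full(m, inf)
    cur = np.full(m, inf)
    for i in range(n):
        # Sakoe-Chiba window around the (scaled) diagonal
        c = i * m // n
        lo = max(0, c - band)
        hi = min(m, c + band + 1)
        for j in range(m):
            cur[j] = inf
        for j in range(lo, hi):
            d = s[i] - t[j]
            cost = d * d if squared else abs(d)
            if i == 0 and j == 0:
                best = 0.0
            else:
                best = inf
                if j > 0 and cur[j - 1] < best:
                    best = cur[j - 1]
                if i > 0:
                    if prev[j] < best:
                        best = prev[j]
                    if j > 0 and prev[j - 1] < best:
                        best = prev[j - 1]
            cur[j] = cost + best
        tmp = prev
        prev = cur
        cur = tmp
    return prev[m - 1]


def dtw_distance(s: np.ndarray, t: np.ndarray, cfg: STWConfig | None = None) -> float:
    """Dynamic-time-warping alignment cost between two sequences.

    Classic dynamic programme over monotone warping paths with symmetric
    steps {(1,0), (0,1), (1,1)} and local cost ``|s_i − t_j|`` (or its
    square).  Symmetric in its arguments and zero iff the sequences can
    be aligned exactly.
    """
    cfg = cfg or STWConfig()
    s = np.ascontiguousarray(s, dtype=np.float64)
    t = np.ascontiguousarray(t, dtype=np.float64)
    if s.size == 0 or t.size == 0:
        raise ValueError("empty sequence")
    if cfg.dtw_band is None:
        return float(_dtw_full(s, t, cfg.dtw_cost == "squared"))
    return float(_dtw_band(s, t, cfg.dtw_cost == "squared", int(cfg.dtw_band)))


def derivative_streams(window: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The window plus its first and second difference streams.

    Returns ``(d0, d1, d2)`` with lengths ``N``, ``N−1`` and ``N−2``.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for second differences")
    return x, np.diff(x), np.diff(x, n=2)


def stw_feature_count(nc: int) -> int:
    """Output feature count: ``NC·(NC−1)/2`` channel pairs × 3 streams."""
    if nc < 2:
        raise ValueError("STW needs at least 2 channels")
    return nc * (nc - 1) // 2 * 3


def stw_feature_names(nc: int) -> list[str]:
    return [
        f"stw.ch{x:02d}-ch{y:02d}.d{k}"
        for x, y in combinations(range(nc), 2)
        for k in range(3)
    ]


def stw_raw_vector(block: np.ndarray, cfg: STWConfig | None = None) -> np.ndarray:
    """Raw DTW distance vector of one observation window.

    ``block`` is ``(NC, W)``.  For each unordered channel pair (x < y,
    lexicographic) and each derivative order k ∈ {0, 1, 2} the DTW
    distance between the two channels' k-th difference streams is
    computed; ordering is pairs-major, derivative-minor.
    """
    cfg = cfg or STWConfig()
    block = np.atleast_2d(np.asarray(block, dtype=float))
    nc, W = block.shape
    if W < 3:
        raise ValueError("window must have at least 3 samples")
    derivs = [derivative_streams(block[c]) for c in range(nc)]
    out = np.empty(stw_feature_count(nc))
    i = 0
    for x, y in combinations(range(nc), 2):
        for k in range(3):
            out[i] = dtw_distance(derivs[x][k], derivs[y][k], cfg)
            i += 1
    return out


def stw_step(raw: np.ndarray, state: STWState, cfg: STWConfig | None = None
             ) -> tuple[np.ndarray, STWState]:
    """One LSTM-style update of the STW extractor.

    With ``L = log(1 + raw + eps)`` (non-negative because raw DTW costs
    are non-negative)::

        cell'  = cell + L                       # long-term accumulation
        fused  = L ⊙ prev_out  (or L at t = 0)  # short-term fusion
        out    = normalize(fused + β·cell') + normalize(log(1 + |cell'|))

    ``normalize`` is L2 with an all-zero guard.  Returns the output and
    the advanced state ``(cell', prev_out = out, t + 1)``.
    """
    cfg = cfg or STWConfig()
    raw = np.asarray(raw, dtype=float)
    if raw.shape != state.cell.shape:
        raise ValueError("raw vector length does not match state")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite raw DTW vector")
    L = np.log1p(raw + cfg.eps)
    cell = state.cell + L
    if state.prev_out is None:
        fused = L
    else:
        partner = state.prev_out if cfg.prev_partner == "output" else state.prev_log
        fused = L * partner
    out = l2_normalize(fused + cfg.beta * cell) + l2_normalize(np.log1p(np.abs(cell)))
    return out, STWState(cell=cell, prev_out=out, t=state.t + 1, prev_log=L)


def run_stw_framework(ws: WindowSet, cfg: STWConfig | None = None) -> FeatureMatrix:
    """STW features for every window of a WindowSet.

    Windows are processed in time order within each stimulus; the memory
    state is reset at stimulus boundaries.  Deterministic for fixed
    config.  Columns: ``stw_feature_count(NC)`` (360 for NC = 16).
    """
    cfg = cfg or STWConfig()
    from .features_td import _iter_events

    nc = ws.n_channels
    F = stw_feature_count(nc)
    rows = np.empty((len(ws), F))
    for _ev, idxs in _iter_events(ws):
        state = STWState.initial(F)
        for i in idxs:
            out, state = stw_step(stw_raw_vector(ws.windows[i], cfg), state, cfg)
            rows[i] = out
    return FeatureMatrix(values=rows, labels=list(ws.labels),
                         names=stw_feature_names(nc))
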