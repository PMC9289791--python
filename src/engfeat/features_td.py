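"""Time-domain feature frameworks: MAV, MAV&WL, TDD and TSD.

All four frameworks share the window-fusion step: the feature vector of
each running observation window is multiplied elementwise with a partner
vector from an earlier window of the same stimulus and L2-normalised,
which injects temporal memory into the features before classification.

* **MAV** — per-channel mean absolute value (NC features).
* **MAV&WL** — MAV plus waveform length per channel (2·NC features).
* **TDD** — six descriptors (f1–f6) derived from root-squared power
  spectrum moments computed entirely in the time domain (Parseval's
  relation), extracted from each channel and from a log-scaled nonlinear
  version of it, the two combined with a cosine-like similarity; the
  similarity vector is fused with the one from the 3rd-previous window
  (6·NC features).
* **TSD** — TDD extended with the coefficient of variation and the
  Teager–Kaiser energy operator (f7–f8), computed on every channel *and*
  every between-channel difference stream Cx−Cy, with a normalised
  similarity and lag-1 fusion (8·(NC + NC·(NC−1)/2) features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .preprocess import WindowSet

__all__ = [
    "TDDConfig",
    "FeatureMatrix",
    "mav",
    "wavelength",
    "nonlinear_version",
    "tdd_descriptors",
    "tdd_similarity",
    "tsd_extra_descriptors",
    "tsd_similarity",
    "channel_difference_streams",
    "window_fusion",
    "run_mav_framework",
    "run_mav_wl_framework",
    "run_tdd_framework",
    "run_tsd_framework",
]

#: guard for logarithms of potentially non-positive arguments
DEFAULT_EPS = 1e-8


@dataclass(frozen=True)
class TDDConfig:
    """Knobs of the TDD/TSD descriptor family.

    Parameters
    ----------
    lambda_ : float
        Power-normalisation exponent applied to the root-squared moments,
        ``m = m̄**lambda_ / lambda_`` (default 0.1).
    fusion_lag : int
        How many windows back the TDD fusion partner sits (default 3).
    eps : float
        Positive guard for logarithms and divisions.
    """

    lambda_: float = 0.1
    fusion_lag: int = 3
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        if not 0 < self.lambda_ <= 1:
            raise ValueError("lambda_ must be in (0, 1]")
        if self.fusion_lag < 1:
            raise ValueError("fusion_lag must be >= 1")
        if not self.eps > 0:
            raise ValueError("eps must be > 0")


@dataclass
class FeatureMatrix:
    """Instances-by-features matrix with aligned labels and column names."""

    values: np.ndarray
    labels: list[object]
    names: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        if self.values.shape[1] != len(self.names):
            raise ValueError("one name per column required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        """Render as a pandas DataFrame with a trailing ``label`` column."""
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        labels = df["label"].tolist()
        df = df.drop(columns=["label"])
        return cls(values=df.to_numpy(), labels=labels, names=list(df.columns))


# ---------------------------------------------------------------------------
# scalar / vector primitives
# ---------------------------------------------------------------------------

def mav(window: np.ndarray) -> float:
    """Mean absolute value ``(1/N)·Σ|x_j|``."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def wavelength(window: np.ndarray) -> float:
    """Waveform length ``Σ|x_{j+1} − x_j|`` (cumulative path length)."""
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError("wavelength needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def nonlinear_version(window: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Logarithmically scaled nonlinear copy of the signal: ``log(x²+eps)²``."""
    x = np.asarray(window, dtype=float)
    return np.log(x * x + eps) ** 2


def _glog(a: np.ndarray | float, eps: float) -> np.ndarray | float:
    """log of |a| guarded away from zero."""
    return np.log(np.maximum(np.abs(a), eps))


def _tdd_matrix(X: np.ndarray, cfg: TDDConfig) -> np.ndarray:
    """f1..f6 for each row of ``X`` (streams x samples) -> (streams, 6)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, N = X.shape
    if N < 3:
        raise ValueError("TDD descriptors need at least 3 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    eps, lam = cfg.eps, cfg.lambda_
    d1 = np.diff(X, axis=1)
    d2 = np.diff(X, n=2, axis=1)

    m0b = np.sqrt(np.sum(X * X, axis=1))
    m2b = np.sqrt(np.sum(d1 * d1, axis=1) / N)
    m4b = np.sqrt(np.sum(d2 * d2, axis=1) / N)
    # power-normalised moments m = m̄**λ / λ
    m0 = m0b ** lam / lam
    m2 = m2b ** lam / lam
    m4 = m4b ** lam / lam

    f1 = _glog(m0, eps)
    f2 = _glog(m0 - m2, eps)
    f3 = _glog(m0 - m4, eps)
    sparseness = m0 / np.sqrt(
        np.maximum(np.abs(m0 - m2), eps) * np.maximum(np.abs(m0 - m4), eps)
    )
    f4 = _glog(sparseness, eps)
    irregularity = np.sqrt(
        (m2 * m2) / np.maximum(np.abs(m0 * m4), eps)
    )
    f5 = _glog(irregularity, eps)
    wlr = np.sum(np.abs(d1), axis=1) / np.maximum(np.sum(np.abs(d2), axis=1), eps)
    f6 = _glog(wlr, eps)
    return np.column_stack([f1, f2, f3, f4, f5, f6])


def tdd_descriptors(window: np.ndarray, cfg: TDDConfig | None = None) -> np.ndarray:
    """The six time-domain power-spectrum descriptors f1..f6 of one window.

    The root-squared moments are ``m̄0 = (Σx²)^½``,
    ``m̄2 = ((1/N)Σ(Δx)²)^½`` and ``m̄4 = ((1/N)Σ(Δ²x)²)^½`` (Δ = first
    difference); each is power-normalised to ``m = m̄**λ/λ``.  Then::

        f1 = log m0            f4 = log( m0 / √(m0−m2)·√(m0−m4) )
        f2 = log(m0 − m2)      f5 = log √(m2² / (m0·m4))
        f3 = log(m0 − m4)      f6 = log( Σ|Δx| / Σ|Δ²x| )

    All logarithms are taken of ``max(|·|, eps)``.
    """
    cfg = cfg or TDDConfig()
    return _tdd_matrix(np.asarray(window, dtype=float)[None, :], cfg)[0]


def _tsd_extra_matrix(X: np.ndarray, eps: float) -> np.ndarray:
    """f7 (COV) and f8 (TKEO) for each row of ``X`` -> (streams, 2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, N = X.shape
    if N < 3:
        raise ValueError("COV/TKEO need at least 3 samples")
    mean = np.mean(X, axis=1)
    sd = np.std(X, axis=1, ddof=1)
    cov = sd / np.maximum(np.abs(mean), eps)
    cov = np.where(sd == 0, 0.0, cov)  # constant window -> COV = 0
    f7 = np.log(np.abs(cov) + eps)
    tkeo = np.sum(X[:, 1:-1] ** 2 - X[:, :-2] * X[:, 2:], axis=1)
    f8 = np.log(np.abs(tkeo) + eps)
    return np.column_stack([f7, f8])


def tsd_extra_descriptors(window: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """f7 and f8: log coefficient of variation and log |Teager–Kaiser energy|.

    ``COV = std(x, ddof=1) / mean(x)`` (0 for a constant window, the mean
    guarded away from zero) and ``TKEO = Σ_{j=1}^{N−2} (x_j² −
    x_{j−1}·x_{j+1})``.
    """
    return _tsd_extra_matrix(np.asarray(window, dtype=float)[None, :], eps)[0]


def tdd_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise cosine-like similarity ``−2·a_i·b_i / (a_i² + b_i²)``.

    Bounded in [−1, 1]; defined as 0 where both entries are 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    denom = a * a + b * b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, -2.0 * a * b / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def tsd_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Norm-coupled similarity ``a_i·b_i / (Σa² + Σb²)``.

    Each element is bounded by ½ in magnitude; defined as the zero vector
    when both inputs have zero norm.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    denom = float(np.sum(a * a) + np.sum(b * b))
    if denom == 0:
        return np.zeros_like(a)
    return a * b / denom


def channel_difference_streams(block: np.ndarray) -> list[np.ndarray]:
    """Individual channels followed by all pairwise differences Cx − Cy.

    For ``NC`` channels this yields ``NC + NC·(NC−1)/2`` streams; the
    difference pairs are ordered lexicographically with x < y.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    nc = block.shape[0]
    streams = [block[i] for i in range(nc)]
    if nc < 2:
        warnings.warn("single channel: no between-channel difference streams")
        return streams
    for x, y in combinations(range(nc), 2):
        streams.append(block[x] - block[y])
    return streams


def _stream_matrix(block: np.ndarray) -> np.ndarray:
    """Stacked (streams x samples) matrix version of channel_difference_streams."""
    return np.vstack(channel_difference_streams(block))


def stream_names(channel_ids: list[str]) -> list[str]:
    names = list(channel_ids)
    names += [f"{x}-{y}" for x, y in combinations(channel_ids, 2)]
    return names


def l2_normalize(v: np.ndarray) -> np.ndarray:
    """L2 normalisation with an all-zero guard (zeros map to zeros)."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        return np.zeros_like(v)
    return v / n


def window_fusion(current: np.ndarray, previous: np.ndarray | None) -> np.ndarray:
    """Fuse a window's features with an earlier window's.

    Elementwise product followed by L2 normalisation; when no partner
    exists yet (first windows of a stimulus — the "pointwise switch")
    the current vector is simply L2-normalised.
    """
    current = np.asarray(current, dtype=float)
    if previous is None:
        return l2_normalize(current)
    previous = np.asarray(previous, dtype=float)
    if current.shape != previous.shape:
        raise ValueError("length mismatch between fusion partners")
    return l2_normalize(current * previous)


# ---------------------------------------------------------------------------
# framework runners
# ---------------------------------------------------------------------------

def _iter_events(ws: WindowSet):
    """Yield (event_index, [window indices]) groups in stream order."""
    if len(ws) == 0:
        raise ValueError("empty WindowSet")
    groups: dict[int, list[int]] = {}
    order: list[int] = []
    for i, (ev, _w) in enumerate(ws.source):
        if ev not in groups:
            groups[ev] = []
            order.append(ev)
        groups[ev].append(i)
    for ev in order:
        yield ev, groups[ev]


def _run_simple(ws: WindowSet, per_window, names: list[str]) -> FeatureMatrix:
    """Shared loop: raw features per window, lag-1 fusion with the previous
    *fused* output, reset at event boundaries."""
    rows = np.empty((len(ws), len(names)))
    for _ev, idxs in _iter_events(ws):
        prev_fused = None
        for i in idxs:
            fused = window_fusion(per_window(ws.windows[i]), prev_fused)
            prev_fused = fused
            rows[i] = fused
    return FeatureMatrix(values=rows, labels=list(ws.labels), names=names)


def run_mav_framework(ws: WindowSet) -> FeatureMatrix:
    """Per-channel MAV with recursive lag-1 window fusion (NC columns)."""
    nc = ws.n_channels
    names = [f"mav.ch{c:02d}" for c in range(nc)]
    return _run_simple(ws, lambda w: np.mean(np.abs(w), axis=1), names)


def run_mav_wl_framework(ws: WindowSet) -> FeatureMatrix:
    """Per-channel MAV and waveform length, fused (2·NC columns)."""
    nc = ws.n_channels

    def per_window(w):
        return np.concatenate([
            np.mean(np.abs(w), axis=1),
            np.sum(np.abs(np.diff(w, axis=1)), axis=1),
        ])

    names = [f"mav.ch{c:02d}" for c in range(nc)] + [f"wl.ch{c:02d}" for c in range(nc)]
    return _run_simple(ws, per_window, names)


def _tdd_similarity_block(block: np.ndarray, cfg: TDDConfig) -> np.ndarray:
    """(NC, 6) similarity vectors: descriptors of each channel vs its
    nonlinear version, combined with the cosine-like measure."""
    a = _tdd_matrix(block, cfg)
    b = _tdd_matrix(nonlinear_version(block, cfg.eps), cfg)
    return tdd_similarity(a, b)


def run_tdd_framework(ws: WindowSet, cfg: TDDConfig | None = None) -> FeatureMatrix:
    """TDD framework: 6 fused similarity descriptors per channel.

    Per channel, the f1–f6 descriptors of the window and of its nonlinear
    version are combined with :func:`tdd_similarity`; that 6-vector is
    fused with the same vector from the ``fusion_lag``-th previous window
    of the same stimulus (pointwise switch while no partner exists).
    Columns: 6·NC.
    """
    cfg = cfg or TDDConfig()
    nc = ws.n_channels
    names = [f"tdd.ch{c:02d}.f{j + 1}" for c in range(nc) for j in range(6)]
    rows = np.empty((len(ws), 6 * nc))
    for _ev, idxs in _iter_events(ws):
        history: list[np.ndarray] = []  # similarity blocks, one per window
        for i in idxs:
            s_cur = _tdd_similarity_block(ws.windows[i], cfg)  # (NC, 6)
            t = len(history)
            partner = history[t - cfg.fusion_lag] if t >= cfg.fusion_lag else None
            fused = np.vstack([
                window_fusion(s_cur[c], None if partner is None else partner[c])
                for c in range(nc)
            ])
            history.append(s_cur)
            rows[i] = fused.ravel()
    return FeatureMatrix(values=rows, labels=list(ws.labels), names=names)


def run_tsd_framework(ws: WindowSet, cfg: TDDConfig | None = None) -> FeatureMatrix:
    """TSD framework: 8 fused similarity descriptors per stream.

    Streams are every channel plus every between-channel difference
    Cx−Cy (NC + NC·(NC−1)/2 of them).  Per stream, the f1–f8 descriptors
    of the stream and of its nonlinear version are combined with
    :func:`tsd_similarity` (n = 8) and fused with the previous window's
    similarity vector (lag 1).  Columns: 8·(NC + NC·(NC−1)/2).
    """
    cfg = cfg or TDDConfig()
    nc = ws.n_channels
    if nc < 2:
        raise ValueError("TSD needs at least 2 channels")
    snames = stream_names([f"ch{c:02d}" for c in range(nc)])
    names = [f"tsd.{s}.f{j + 1}" for s in snames for j in range(8)]
    n_streams = len(snames)
    rows = np.empty((len(ws), 8 * n_streams))

    def sim_block(block: np.ndarray) -> np.ndarray:
        X = _stream_matrix(block)
        Xn = nonlinear_version(X, cfg.eps)
        a = np.hstack([_tdd_matrix(X, cfg), _tsd_extra_matrix(X, cfg.eps)])
        b = np.hstack([_tdd_matrix(Xn, cfg), _tsd_extra_matrix(Xn, cfg.eps)])
        return np.vstack([tsd_similarity(a[s], b[s]) for s in range(n_streams)])

    for _ev, idxs in _iter_events(ws):
        prev: np.ndarray | None = None
        for i in idxs:
            s_cur = sim_block(ws.windows[i])  # (n_streams, 8)
            fused = np.vstack([
                window_fusion(s_cur[s], None if prev is None else prev[s])
                for s in range(n_streams)
            ])
            prev = s_cur
            rows[i] = fused.ravel()
    return FeatureMatrix(values=rows, labels=list(ws.labels), names=names)
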