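"""Per-residue 27-dimensional probability features and their complex mapping.

A residue t is described by the probabilities of t and its four
sequence neighbours on each side adopting Helix, Sheet or Coil —
nine P(H) values, nine P(E), nine P(C), in that block order.  Real
features are scaled to [-1, 1] by a symmetric min-max map and then
placed on the unit circle by z = exp(i * alpha * x), the input layer
of the complex-valued classifier.

The probability matrices used to develop the original method are not
publicly available, so this module also provides a synthetic generator
that emulates their statistical structure: each residue receives a
Dirichlet-distributed probability triplet concentrated on its true
3-state label, with a single concentration parameter controlling
informativeness, and windows reuse neighbour triplets exactly as a
sliding-window encoder would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .chains import ChainSet, SS3_STATES

__all__ = [
    "FeatureSet",
    "normalize_features",
    "circular_transform",
    "generate_synthetic_features",
    "CircularFeatureMap",
    "minmax_scale_sym",
    "to_unit_circle",
    "write_feature_tsv",
    "read_feature_tsv",
]

N_FEATURES = 27
WINDOW = 9
HALF_WINDOW = WINDOW // 2

#: header of the tab-separated serialization, fixed
_TSV_COLUMNS = ["chain_id", "residue_index", "label"] + [
    f"p{s}_{j - HALF_WINDOW:+d}" for s in ("H", "E", "C") for j in range(WINDOW)
]


def minmax_scale_sym(
    x: np.ndarray,
    ref_min: np.ndarray | None = None,
    ref_max: np.ndarray | None = None,
    mode: str = "feature",
    clip: bool = True,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Scale values to [-1, 1] via 2*(x - min)/(max - min) - 1.

    ``mode='feature'`` uses per-column extrema over the whole batch
    (optionally the supplied reference extrema); ``mode='vector'`` uses
    each row's own min and max, which carries no reusable state.
    Values outside a supplied reference range are clipped to +-1.

    Returns ``(scaled, min_used, max_used)``; extrema are None in
    vector mode.
    """
    x = np.asarray(x, dtype=float)
    if mode == "vector":
        mn = x.min(axis=-1, keepdims=True)
        mx = x.max(axis=-1, keepdims=True)
        span = mx - mn
        bad = np.nonzero(span.ravel() == 0)[0]
        if bad.size:
            raise ValueError(
                f"degenerate scale (max == min) in vector(s) {bad.tolist()[:5]}"
            )
        return 2.0 * (x - mn) / span - 1.0, None, None
    if mode != "feature":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref_min is None or ref_max is None:
        ref_min = x.min(axis=0)
        ref_max = x.max(axis=0)
    ref_min = np.asarray(ref_min, dtype=float)
    ref_max = np.asarray(ref_max, dtype=float)
    span = ref_max - ref_min
    bad = np.nonzero(span == 0)[0]
    if bad.size:
        raise ValueError(
            f"degenerate scale (max == min) for feature index(es) {bad.tolist()}"
        )
    scaled = 2.0 * (x - ref_min) / span - 1.0
    if clip:
        scaled = np.clip(scaled, -1.0, 1.0)
    return scaled, ref_min, ref_max


def to_unit_circle(x_norm: np.ndarray, alpha: float = math.pi / 2) -> np.ndarray:
    """Map [-1, 1] reals onto the complex unit circle: z = exp(i*alpha*x).

    The map is injective on [-1, 1] for alpha < pi; larger alpha is
    rejected because +1 and -1 would collide (or wrap).
    """
    if not 0 < alpha < math.pi:
        raise ValueError(f"alpha must be in (0, pi) for injectivity, got {alpha}")
    return np.exp(1j * alpha * np.asarray(x_norm, dtype=float))


@dataclass
class FeatureSet:
    """A batch of per-residue feature vectors with labels and provenance.

    ``values`` holds raw probabilities in [0, 1] (n x 27); ``normalized``
    and ``complex_form`` are filled by :func:`normalize_features` and
    :func:`circular_transform`.  ``chain_ids`` / ``residue_indices``
    trace every row back to its residue.
    """

    values: np.ndarray
    labels: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray
    normalized: np.ndarray | None = None
    complex_form: np.ndarray | None = None
    norm_min: np.ndarray | None = None
    norm_max: np.ndarray | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U1")
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        n = len(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"values must be (n, {N_FEATURES}), got {self.values.shape}"
            )
        for arr, what in (
            (self.labels, "labels"),
            (self.chain_ids, "chain_ids"),
            (self.residue_indices, "residue_indices"),
        ):
            if len(arr) != n:
                raise ValueError(f"{what} length {len(arr)} != n vectors {n}")

    def __len__(self) -> int:
        return len(self.values)

    def select(self, mask: np.ndarray) -> "FeatureSet":
        """Row subset (boolean mask or index array); norm state is dropped."""
        return FeatureSet(
            self.values[mask],
            self.labels[mask],
            self.chain_ids[mask],
            self.residue_indices[mask],
        )

    def for_chains(self, ids: Sequence[str]) -> "FeatureSet":
        wanted = set(ids)
        mask = np.fromiter((c in wanted for c in self.chain_ids), bool, len(self))
        return self.select(mask)


def normalize_features(
    fs: FeatureSet,
    ref_extrema: tuple[np.ndarray, np.ndarray] | None = None,
    mode: str = "feature",
) -> FeatureSet:
    """Return a copy of ``fs`` with values scaled to [-1, 1].

    With ``ref_extrema`` (a (min, max) pair of 27-vectors, e.g. recorded
    from a development set) the reference range is used and out-of-range
    values clip to +-1 — the blind-test path, where new proteins are
    normalized with respect to the development set's extrema.  Without
    it, extrema of ``fs`` itself are used and recorded on the result.
    """
    if ref_extrema is not None:
        ref_min, ref_max = (np.asarray(a, float) for a in ref_extrema)
        if ref_min.shape != (N_FEATURES,) or ref_max.shape != (N_FEATURES,):
            raise ValueError(f"ref_extrema must be two {N_FEATURES}-vectors")
        scaled, mn, mx = minmax_scale_sym(fs.values, ref_min, ref_max, mode="feature")
    else:
        scaled, mn, mx = minmax_scale_sym(fs.values, mode=mode)
    out = FeatureSet(fs.values, fs.labels, fs.chain_ids, fs.residue_indices)
    out.normalized = scaled
    out.norm_min, out.norm_max = mn, mx
    return out


def circular_transform(fs: FeatureSet, alpha: float = math.pi / 2) -> FeatureSet:
    """Return a copy with the unit-circle complex form filled in."""
    if fs.normalized is None:
        raise ValueError("normalize_features must be applied first")
    out = FeatureSet(fs.values, fs.labels, fs.chain_ids, fs.residue_indices)
    out.normalized = fs.normalized
    out.norm_min, out.norm_max = fs.norm_min, fs.norm_max
    out.complex_form = to_unit_circle(fs.normalized, alpha)
    out.alpha = alpha
    return out


#: weight of the uniform component in the Dirichlet mean direction
_SMOOTH = 0.05


def generate_synthetic_features(
    chains: ChainSet,
    kappa: float,
    seed: int | np.random.Generator,
) -> FeatureSet:
    """Draw synthetic probability-triplet features for every interior residue.

    Each residue receives one triplet over (H, E, C) from
    Dirichlet(kappa * m + 1), where m puts weight 1 - 0.05 on the true
    state plus 0.05 spread uniformly.  kappa -> infinity concentrates
    the triplet on the true state (near-indicator); kappa -> 0 recovers
    the flat Dirichlet whose mean is (1/3, 1/3, 1/3).  The 27-vector of
    residue t concatenates the P(H), P(E), P(C) triplet components of
    positions t-4 .. t+4, so neighbouring windows share triplets; only
    residues with four neighbours on both sides are emitted (chain
    length minus 8 vectors per chain).

    Identical (chains, kappa, seed) reproduce identical output.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state_idx = {s: i for i, s in enumerate(SS3_STATES)}

    values, labels, cids, ridx = [], [], [], []
    for chain in chains:
        c = chain.with_ss3()
        L = len(c)
        if L < WINDOW:
            continue
        onehot = np.zeros((L, 3))
        onehot[np.arange(L), [state_idx[s] for s in c.ss3]] = 1.0
        mean_dir = (1.0 - _SMOOTH) * onehot + _SMOOTH / 3.0
        # Dirichlet with per-row concentration, via normalized Gamma draws
        conc = kappa * mean_dir + 1.0
        g = rng.gamma(shape=conc)
        triplets = g / g.sum(axis=1, keepdims=True)
        for t in range(HALF_WINDOW, L - HALF_WINDOW):
            win = triplets[t - HALF_WINDOW : t + HALF_WINDOW + 1]  # (9, 3)
            values.append(win.T.ravel())  # 9xP(H), 9xP(E), 9xP(C)
            labels.append(c.ss3[t])
            cids.append(c.chain_id)
            ridx.append(t)
    if not values:
        raise ValueError("no chain long enough to emit a full window")
    return FeatureSet(
        np.asarray(values), np.asarray(labels), np.asarray(cids, dtype=object),
        np.asarray(ridx),
    )


class CircularFeatureMap(TransformerMixin, BaseEstimator):
    """Scale real features to [-1, 1] and map them onto the unit circle.

    fit() records per-feature extrema (``mode='feature'``); transform()
    applies the symmetric min-max scaling — clipping values outside the
    fitted range — followed by z = exp(i*alpha*x).  ``mode='vector'``
    scales each sample by its own extrema and keeps no state.

    Attributes
    ----------
    data_min_, data_max_ : ndarray of shape (n_features,)
        Extrema recorded at fit time (feature mode).
    """

    def __init__(self, alpha: float = math.pi / 2, mode: str = "feature"):
        self.alpha = alpha
        self.mode = mode

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.mode == "feature":
            _, self.data_min_, self.data_max_ = minmax_scale_sym(X, mode="feature")
        else:
            minmax_scale_sym(X, mode=self.mode)  # validates mode & degeneracy
            self.data_min_ = self.data_max_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mode == "feature":
            if not hasattr(self, "data_min_"):
                raise ValueError("CircularFeatureMap is not fitted")
            xn, _, _ = minmax_scale_sym(
                X, self.data_min_, self.data_max_, mode="feature"
            )
        else:
            xn, _, _ = minmax_scale_sym(X, mode=self.mode)
        return to_unit_circle(xn, self.alpha)


def write_feature_tsv(fs: FeatureSet, path: str | Path) -> None:
    """Serialize raw features as tab-separated text with the fixed header."""
    df = pd.DataFrame(fs.values, columns=_TSV_COLUMNS[3:])
    df.insert(0, "chain_id", fs.chain_ids)
    df.insert(1, "residue_index", fs.residue_indices)
    df.insert(2, "label", fs.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_tsv(path: str | Path) -> FeatureSet:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _TSV_COLUMNS:
        raise ValueError(f"{path}: unexpected feature-file header")
    return FeatureSet(
        df[_TSV_COLUMNS[3:]].to_numpy(float),
        df["label"].to_numpy(),
        df["chain_id"].to_numpy(object),
        df["residue_index"].to_numpy(int),
    )
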