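"""Mixing-matrix estimation from single-stain controls and linear unmixing.

A multi-channel acquisition is modeled per pixel as ``observed = M @ a`` with
``M`` a channels x fluorophores response matrix (plus an optional
autofluorescence column). Unmixing solves a nonnegative least-squares
problem per pixel by default; a fast pseudoinverse-and-clip mode is
available for large stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "MixingMatrix",
    "CrosstalkReport",
    "CollinearFluorophoresError",
    "fit_mixing_matrix",
    "unmix",
    "crosstalk_metric",
]


class CollinearFluorophoresError(ValueError):
    """Raised when two fluorophore spectra are too similar to separate."""


@dataclass
class MixingMatrix:
    M: np.ndarray                      # (channels, fluors), columns max-1
    channels: list = None
    fluors: list = None
    autofluor_profile: np.ndarray | None = None

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        C, F = self.M.shape
        if self.channels is None:
            self.channels = [f"ch{c:02d}" for c in range(C)]
        if self.fluors is None:
            self.fluors = [f"fluor{f:02d}" for f in range(F)]
        if np.any(self.M < 0):
            raise ValueError("mixing matrix entries must be nonnegative")

    @property
    def home_channels(self) -> np.ndarray:
        return np.argmax(self.M, axis=0)

    def normalized(self) -> np.ndarray:
        """Columns scaled to unit maximum (the reporting convention)."""
        mx = self.M.max(axis=0, keepdims=True)
        return self.M / np.where(mx > 0, mx, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.normalized(), index=self.channels,
                            columns=self.fluors)


@dataclass
class CrosstalkReport:
    matrix: pd.DataFrame               # fluor x channel, home-normalized
    mean_adjacent_crosstalk: float     # percent
    per_pair: list = field(default_factory=list)


def _check_condition(M, cond_threshold, fluors):
    cond = np.linalg.cond(M)
    if cond > cond_threshold:
        # name the most collinear pair
        norm = M / np.linalg.norm(M, axis=0, keepdims=True)
        cos = norm.T @ norm
        np.fill_diagonal(cos, -np.inf)
        i, j = np.unravel_index(np.argmax(cos), cos.shape)
        raise CollinearFluorophoresError(
            f"mixing matrix is near-singular (condition number {cond:.3g}); "
            f"fluorophores {fluors[i]!r} and {fluors[j]!r} have "
            f"nearly identical spectra (cosine {cos[i, j]:.6f})"
        )


def fit_mixing_matrix(
    control_stacks,
    autofluor_stack: np.ndarray | None = None,
    top_quantile: float = 0.95,
    cond_threshold: float = 1e6,
    fluors=None,
    channels=None,
) -> MixingMatrix:
    """Estimate the mixing matrix from one single-stain control per fluorophore.

    For each control the per-channel response is the median over the
    brightest pixels (top ``1 - top_quantile`` fraction) of the control's
    home channel, after subtracting the per-channel autofluorescence
    profile. Columns are scaled to unit maximum.
    """
    stacks = list(control_stacks)
    if not stacks:
        raise ValueError("need at least one control stack")
    C = stacks[0].shape[0]
    for s in stacks:
        if s.ndim != 3 or s.shape[0] != C:
            raise ValueError("all control stacks must share channel ordering")

    if autofluor_stack is not None:
        af_profile = np.median(autofluor_stack.reshape(C, -1), axis=1)
    else:
        af_profile = np.zeros(C)

    cols = []
    for s in stacks:
        corrected = np.clip(s - af_profile[:, None, None], 0, None)
        mean_per_ch = corrected.reshape(C, -1).mean(axis=1)
        home = int(np.argmax(mean_per_ch))
        home_img = corrected[home].ravel()
        thr = np.quantile(home_img, top_quantile)
        bright = home_img >= thr
        if not np.any(bright) or home_img.max() <= 0:
            raise ValueError("control stack has no bright pixels in its home channel")
        col = np.median(corrected.reshape(C, -1)[:, bright], axis=1)
        mx = col.max()
        if mx <= 0:
            raise ValueError("control stack yields an all-zero response column")
        cols.append(col / mx)
    M = np.column_stack(cols)
    fluors = list(fluors) if fluors is not None else [
        f"fluor{f:02d}" for f in range(M.shape[1])
    ]
    _check_condition(M, cond_threshold, fluors)
    return MixingMatrix(M=M, channels=channels, fluors=fluors,
                        autofluor_profile=af_profile)


def unmix(stack: np.ndarray, mm: MixingMatrix, method: str = "nnls") -> np.ndarray:
    """Solve per-pixel fluorophore abundances from a multi-channel stack.

    The autofluorescence profile, when present, enters as an extra column
    and is dropped from the returned abundances. ``method`` is ``"nnls"``
    (default; abundances are nonnegative by construction) or ``"pinv"``
    (unconstrained least squares clipped at zero).
    """
    stack = np.asarray(stack, dtype=float)
    C, F = mm.M.shape
    if stack.ndim != 3 or stack.shape[0] != C:
        raise ValueError(
            f"stack has {stack.shape[0] if stack.ndim == 3 else '?'} channels, "
            f"mixing matrix expects {C}"
        )
    A = mm.M
    extra = 0
    if mm.autofluor_profile is not None and np.any(mm.autofluor_profile > 0):
        af = mm.autofluor_profile / max(mm.autofluor_profile.max(), 1e-12)
        A = np.column_stack([A, af])
        extra = 1
    H, W = stack.shape[1:]
    Y = stack.reshape(C, -1)
    if method == "pinv":
        X = np.clip(np.linalg.pinv(A) @ Y, 0, None)
    elif method == "nnls":
        X = np.empty((A.shape[1], Y.shape[1]))
        nonzero = Y.any(axis=0)
        X[:, ~nonzero] = 0.0
        for i in np.nonzero(nonzero)[0]:
            X[:, i], _ = nnls(A, Y[:, i])
    else:
        raise ValueError(f"unknown unmix method {method!r}")
    if extra:
        X = X[:-extra]
    return X.reshape(F, H, W)


def crosstalk_metric(
    stacks,
    home_channels=None,
    bright_quantile: float = 0.95,
    channel_names=None,
) -> CrosstalkReport:
    """Quantify bleed-through of single-fluorophore acquisitions.

    ``stacks`` holds one acquisition per fluorophore (raw, or the unmixed
    output restacked per fluorophore). For fluorophore ``f`` the report row
    is the mean per-channel intensity over pixels bright in ``f``'s home
    channel, normalized to the home-channel value. Mean adjacent crosstalk
    averages the entries at the channels spectrally adjacent to each home
    channel (channel order is assumed wavelength-sorted) and is reported in
    percent.
    """
    stacks = list(stacks)
    n_fluor = len(stacks)
    C = stacks[0].shape[0]
    if home_channels is None:
        home_channels = [
            int(np.argmax(s.reshape(C, -1).mean(axis=1))) for s in stacks
        ]
    home_channels = list(home_channels)
    rows = np.zeros((n_fluor, C))
    for f, s in enumerate(stacks):
        h = home_channels[f]
        flat = s.reshape(C, -1)
        home_img = flat[h]
        if home_img.max() <= 0:
            raise ValueError(
                f"fluorophore {f} has an empty bright-pixel set "
                f"(home channel {h} is all zero)"
            )
        thr = np.quantile(home_img, bright_quantile)
        bright = home_img >= thr
        if thr <= 0:
            bright = home_img > 0
        means = flat[:, bright].mean(axis=1)
        rows[f] = means / means[h]
    names = list(channel_names) if channel_names is not None else [
        f"ch{c:02d}" for c in range(C)
    ]
    matrix = pd.DataFrame(rows, columns=names,
                          index=[f"fluor{f:02d}" for f in range(n_fluor)])
    per_pair = []
    vals = []
    for f, h in enumerate(home_channels):
        for nb in (h - 1, h + 1):
            if 0 <= nb < C:
                pct = 100.0 * rows[f, nb]
                per_pair.append((h, nb, pct))
                vals.append(pct)
    mean_adj = float(np.mean(vals)) if vals else 0.0
    return CrosstalkReport(matrix=matrix, mean_adjacent_crosstalk=mean_adj,
                           per_pair=per_pair)
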