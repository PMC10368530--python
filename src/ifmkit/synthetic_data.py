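"""Synthetic spectral stacks and patient cohorts with known ground truth.

Every generator emits truth labels alongside its outputs so recovery tests
never need to peek at generator internals, and all randomness flows from a
single integer seed (same seed, same bytes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SpectralSimSpec",
    "CohortSimSpec",
    "MarkerMixture",
    "SpectralSim",
    "CohortSim",
    "adjacent_bleed_matrix",
    "simulate_spectral_stack",
    "simulate_cohort",
    "default_marker_params",
    "DEFAULT_PANEL",
]

# 13-marker immune-focused panel plus the epithelial markers used for the
# tumor mask and lineage calling.
IMMUNE_MARKERS = [
    "CD3", "CD8", "CD45", "CD45RO", "CD68", "CD163", "CD4",
    "CD20", "aSMA", "FOXP3", "PD1", "PDL1", "CD31",
]
DEFAULT_PANEL = ["panCK", "Ecad"] + IMMUNE_MARKERS


def adjacent_bleed_matrix(n_channels: int, n_fluors: int | None = None,
                          bleed: float = 0.35) -> np.ndarray:
    """Mixing matrix with a given bleed coefficient into adjacent channels.

    Column ``f`` has its home response in channel ``f`` and ``bleed`` times
    that response in the spectrally adjacent channels; columns are scaled to
    sum to 1.
    """
    if n_fluors is None:
        n_fluors = n_channels
    if n_channels < n_fluors:
        raise ValueError("need at least as many channels as fluorophores")
    M = np.zeros((n_channels, n_fluors))
    for f in range(n_fluors):
        M[f, f] = 1.0
        if f > 0:
            M[f - 1, f] = bleed
        if f + 1 < n_channels:
            M[f + 1, f] = bleed
    return M / M.sum(axis=0, keepdims=True)


@dataclass
class SpectralSimSpec:
    n_channels: int
    n_fluors: int
    mixing: np.ndarray
    autofluor_level: float = 0.0
    noise_sd: float = 0.0
    image_shape: tuple[int, int] = (64, 64)
    seed: int = 0
    abundance_scale: float = 100.0
    disjoint_supports: bool = False
    noise_mode: str = "relative"   # "relative": sd = noise_sd * clean signal
    #                                "additive": sd = noise_sd, flat

    def __post_init__(self):
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (self.n_channels, self.n_fluors):
            raise ValueError("mixing must be (n_channels, n_fluors)")
        if self.n_channels < self.n_fluors:
            raise ValueError("n_channels must be >= n_fluors")
        if np.any(self.mixing < 0):
            raise ValueError("mixing entries must be nonnegative")
        if np.any(self.mixing.sum(axis=0) == 0):
            raise ValueError("mixing has a zero column (invisible fluorophore)")
        homes = np.argmax(self.mixing, axis=0)
        if np.unique(homes).size != self.n_fluors:
            raise ValueError("each fluorophore needs a unique home channel")
        if self.autofluor_level < 0 or self.noise_sd < 0:
            raise ValueError("autofluor_level and noise_sd must be >= 0")
        if self.noise_mode not in ("relative", "additive"):
            raise ValueError("noise_mode must be 'relative' or 'additive'")

    @property
    def home_channels(self) -> np.ndarray:
        return np.argmax(self.mixing, axis=0)


@dataclass
class SpectralSim:
    spec: SpectralSimSpec
    stack: np.ndarray                 # (C, H, W) observed multiplex image
    abundances: np.ndarray            # (F, H, W) ground truth
    controls: list                    # per-fluor observed single-stain stacks
    control_abundances: list          # per-fluor truth abundance maps
    autofluor_stack: np.ndarray       # unstained acquisition (C, H, W)
    autofluor_map: np.ndarray         # (H, W) spatial autofluorescence truth

    def write(self, outdir: str | Path) -> None:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / "stack.tif", self.stack.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(outdir / "truth_abundances.tif",
                         self.abundances.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(outdir / "autofluor.tif",
                         self.autofluor_stack.astype(np.float32),
                         photometric="minisblack")
        for f, ctrl in enumerate(self.controls):
            tifffile.imwrite(outdir / f"control_{f:02d}.tif",
                             ctrl.astype(np.float32),
                             photometric="minisblack")
        truth = {
            "mixing": self.spec.mixing.tolist(),
            "home_channels": self.spec.home_channels.tolist(),
            "autofluor_level": self.spec.autofluor_level,
            "noise_sd": self.spec.noise_sd,
            "seed": self.spec.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def _blob_map(rng, shape, sigma, fill=0.3):
    noise = rng.standard_normal(shape)
    sm = gaussian_filter(noise, sigma)
    thr = np.quantile(sm, 1.0 - fill)
    mask = sm > thr
    mag = np.clip(sm - thr, 0, None)
    mx = mag.max()
    return mask * (0.5 + mag / mx if mx > 0 else 1.0)


def simulate_spectral_stack(spec: SpectralSimSpec) -> SpectralSim:
    """Generate observed stack = mixing @ abundances + autofluorescence + noise.

    Also emits one single-stain control acquisition per fluorophore (only
    that fluorophore's abundance nonzero, autofluorescence and noise still
    present) and an unstained autofluorescence-only acquisition.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    C, F = spec.n_channels, spec.n_fluors

    abundances = np.zeros((F, H, W))
    if spec.disjoint_supports:
        cols = np.array_split(np.arange(W), F)
        for f, cc in enumerate(cols):
            abundances[f][:, cc] = spec.abundance_scale * (
                0.5 + rng.random((H, len(cc)))
            )
    else:
        for f in range(F):
            abundances[f] = spec.abundance_scale * _blob_map(
                rng, (H, W), sigma=max(2.0, min(H, W) / 12.0)
            )

    af_map = spec.autofluor_level * gaussian_filter(
        rng.random((H, W)), sigma=max(2.0, min(H, W) / 8.0)
    )
    af_profile = np.ones(C)

    def observe(abund, rng_local):
        clean = np.einsum("cf,fhw->chw", spec.mixing, abund)
        clean = clean + af_profile[:, None, None] * af_map[None]
        if spec.noise_sd > 0:
            if spec.noise_mode == "relative":
                sd = spec.noise_sd * clean
            else:
                sd = spec.noise_sd
            clean = clean + sd * rng_local.standard_normal(clean.shape)
        return np.clip(clean, 0, None)

    stack = observe(abundances, rng)
    controls, control_truth = [], []
    for f in range(F):
        a = np.zeros_like(abundances)
        ctrl_map = spec.abundance_scale * _blob_map(
            rng, (H, W), sigma=max(2.0, min(H, W) / 12.0)
        )
        a[f] = ctrl_map
        controls.append(observe(a, rng))
        control_truth.append(ctrl_map)
    af_rng = rng
    autofluor_stack = observe(np.zeros_like(abundances), af_rng)
    return SpectralSim(
        spec=spec,
        stack=stack,
        abundances=abundances,
        controls=controls,
        control_abundances=control_truth,
        autofluor_stack=autofluor_stack,
        autofluor_map=af_map,
    )


@dataclass
class MarkerMixture:
    """Two-population log-normal intensity mixture for one marker."""

    neg_mu: float
    neg_sigma: float
    pos_mu: float
    pos_sigma: float
    pos_fraction: float

    def __post_init__(self):
        if not (0.0 < self.pos_fraction < 1.0):
            raise ValueError("positive fraction must lie in (0, 1)")
        if self.pos_mu <= self.neg_mu:
            raise ValueError("positive log-mean must exceed negative log-mean")


def default_marker_params(markers=None) -> dict:
    markers = list(markers) if markers is not None else list(DEFAULT_PANEL)
    return {
        m: MarkerMixture(neg_mu=3.0, neg_sigma=0.5, pos_mu=6.0,
                         pos_sigma=0.5, pos_fraction=0.2)
        for m in markers
    }


@dataclass
class CohortSimSpec:
    n_specimens: int = 40
    cells_per_specimen: int = 2000
    markers: list = field(default_factory=lambda: list(DEFAULT_PANEL))
    tumor_fraction: float = 0.4
    infiltration_effect: dict = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 365.0
    censoring_rate: float = 0.3
    intensity_params: dict | None = None
    seed: int = 0
    tissue_size_um: tuple[float, float] = (10_000.0, 10_000.0)
    geometry: str = "blob"            # "blob" or "disk"
    survival_dist: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    covariate_mode: str = "binary"    # "binary" or "fraction"
    infiltration_spread: float = 0.5
    tumor_panck_rate: float = 0.9
    stroma_panck_rate: float = 0.03

    def __post_init__(self):
        if self.cells_per_specimen < 100:
            raise ValueError(
                "cells_per_specimen must be >= 100 (medians unstable below)"
            )
        if not (0.0 < self.tumor_fraction < 1.0):
            raise ValueError("tumor_fraction must lie in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.geometry not in ("blob", "disk"):
            raise ValueError("geometry must be 'blob' or 'disk'")
        if self.intensity_params is None:
            self.intensity_params = default_marker_params(self.markers)
        for m in self.markers:
            if m not in self.intensity_params:
                raise ValueError(f"missing intensity params for marker {m!r}")
        unknown = set(self.infiltration_effect) - set(self.markers)
        if unknown:
            raise ValueError(f"infiltration_effect for unknown markers: {unknown}")


@dataclass
class CohortSim:
    spec: CohortSimSpec
    cells: list                      # one DataFrame per specimen
    clinical: pd.DataFrame           # specimen_id, pfs_days, event + truth_*

    @property
    def cells_combined(self) -> pd.DataFrame:
        return pd.concat(self.cells, ignore_index=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells_combined.to_csv(outdir / "cells.csv", index=False)
        self.clinical.to_csv(outdir / "clinical.csv", index=False)
        truth = {
            "seed": self.spec.seed,
            "tumor_fraction": self.spec.tumor_fraction,
            "infiltration_effect": dict(self.spec.infiltration_effect),
            "covariate_mode": self.spec.covariate_mode,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def _tumor_membership(rng, spec, x, y):
    W, Hgt = spec.tissue_size_um
    if spec.geometry == "disk":
        r = np.sqrt(spec.tumor_fraction * W * Hgt / np.pi)
        return (x - W / 2.0) ** 2 + (y - Hgt / 2.0) ** 2 <= r**2
    # blob: thresholded smoothed noise on a coarse grid, nearest-pixel lookup
    gw = gh = 128
    noise = gaussian_filter(rng.standard_normal((gh, gw)), sigma=12.0)
    thr = np.quantile(noise, 1.0 - spec.tumor_fraction)
    mask = noise > thr
    ix = np.clip((x / W * gw).astype(int), 0, gw - 1)
    iy = np.clip((y / Hgt * gh).astype(int), 0, gh - 1)
    return mask[iy, ix]


def _calibrate_censoring(rng, t_event, rate):
    """Uniform(0, tau) administrative censoring hitting a target rate."""
    if rate <= 0:
        return np.full_like(t_event, np.inf)

    def frac_censored(tau):
        return float(np.mean(np.minimum(t_event / tau, 1.0)))

    lo, hi = 1e-9, float(np.max(t_event)) * 10
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) > rate:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    return rng.uniform(0, tau, size=t_event.size)


def simulate_cohort(spec: CohortSimSpec) -> CohortSim:
    """Simulate a cohort of specimens with linked survival outcomes.

    Each specimen carries a connected tumor region; marker positivity is
    driven by a per-specimen infiltration covariate which enters an
    exponential (optionally Weibull) proportional-hazards model through
    ``infiltration_effect`` log-hazard coefficients. ``truth_*`` columns
    expose every latent quantity.
    """
    master = np.random.default_rng(spec.seed)
    W, Hgt = spec.tissue_size_um
    tables = []
    covariates = np.zeros((spec.n_specimens, len(spec.markers)))
    pos_fracs = np.zeros_like(covariates)

    for s in range(spec.n_specimens):
        rng = np.random.default_rng([spec.seed, s])
        n = spec.cells_per_specimen
        x = rng.uniform(0, W, n)
        y = rng.uniform(0, Hgt, n)
        in_tumor = _tumor_membership(rng, spec, x, y)
        df = pd.DataFrame({
            "specimen_id": f"S{s:03d}",
            "cell_id": np.arange(n),
            "x_um": x,
            "y_um": y,
            "truth_tumor": in_tumor.astype(int),
        })
        for j, m in enumerate(spec.markers):
            mp = spec.intensity_params[m]
            if m in ("panCK", "Ecad"):
                p_cell = np.where(in_tumor, spec.tumor_panck_rate,
                                  spec.stroma_panck_rate)
                frac = float(np.mean(p_cell))
                cov = frac
            else:
                hi = rng.random() < 0.5
                if spec.covariate_mode == "binary":
                    frac = mp.pos_fraction * (
                        1.0 + (spec.infiltration_spread if hi
                               else -spec.infiltration_spread)
                    )
                    cov = float(hi)
                else:
                    latent = rng.normal(0.0, spec.infiltration_spread)
                    frac = float(np.clip(
                        mp.pos_fraction * np.exp(latent), 0.005, 0.95))
                    cov = frac
                frac = float(np.clip(frac, 0.005, 0.95))
                p_cell = np.full(n, frac)
            pos = rng.random(n) < p_cell
            mu = np.where(pos, mp.pos_mu, mp.neg_mu)
            sd = np.where(pos, mp.pos_sigma, mp.neg_sigma)
            df[m] = np.exp(rng.normal(mu, sd))
            df[f"truth_{m}_pos"] = pos.astype(int)
            covariates[s, j] = cov
            pos_fracs[s, j] = float(np.mean(pos))
        tables.append(df)

    # survival draws use the master stream so they are independent of the
    # per-specimen cell streams
    coef = np.array([spec.infiltration_effect.get(m, 0.0)
                     for m in spec.markers])
    lp = covariates @ coef
    hazard = spec.baseline_hazard * np.exp(lp)
    if spec.survival_dist == "weibull":
        u = master.random(spec.n_specimens)
        t_event = (-np.log(u) / hazard) ** (1.0 / spec.weibull_shape)
    else:
        t_event = master.exponential(1.0 / hazard)
    c = _calibrate_censoring(master, t_event, spec.censoring_rate)
    event = (t_event <= c).astype(int)
    pfs = np.minimum(t_event, c)
    clinical = pd.DataFrame({
        "specimen_id": [f"S{s:03d}" for s in range(spec.n_specimens)],
        "pfs_days": pfs,
        "event": event,
        "truth_event_time": t_event,
        "truth_lp": lp,
    })
    for j, m in enumerate(spec.markers):
        clinical[f"truth_x_{m}"] = covariates[:, j]
        clinical[f"truth_frac_{m}"] = pos_fracs[:, j]
    return CohortSim(spec=spec, cells=tables, clinical=clinical)
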