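"""Two-component Gaussian-mixture gating and lineage calling.

Per-cell marker intensities are gated positive/negative by fitting a
two-component Gaussian mixture to log1p intensities; the threshold is the
equal-posterior point between the component means. Lineage labels are then
assigned by walking an ordered rule list (a flattened gating dendrogram);
cells matching no rule are Unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = [
    "GateResult",
    "CellTypeCall",
    "gmm_gate",
    "gate_table",
    "call_cell_types",
    "DEFAULT_LINEAGE_RULES",
]

MIN_CELLS = 100

# Flattened lineage dendrogram for a CRC-style panel, evaluated top to
# bottom; the first matching rule wins. Editable config, not code.
DEFAULT_LINEAGE_RULES = [
    {"label": "Tumor", "any_of": ["panCK", "Ecad"]},
    {"label": "B cell", "all_of": ["CD45", "CD20"]},
    {"label": "T reg", "all_of": ["CD45", "FOXP3"]},
    {"label": "T cell CD8", "all_of": ["CD45", "CD8"], "none_of": ["CD4"]},
    {"label": "T cell CD4", "all_of": ["CD45", "CD4"]},
    {"label": "Macrophage", "all_of": ["CD45"], "any_of": ["CD68", "CD163"]},
    {"label": "Other immune", "all_of": ["CD45"]},
    {"label": "Endothelial", "all_of": ["CD31"]},
    {"label": "Stromal", "all_of": ["aSMA"]},
]

UNASSIGNED = "Unassigned"


@dataclass
class GateResult:
    marker: str
    specimen: str | None
    threshold: float               # on the log1p scale
    positive_fraction: float
    s_to_b: float                  # mean positive / mean negative raw MFI
    per_cell_calls: np.ndarray
    degenerate: bool = False
    means: tuple = (np.nan, np.nan)


def _equal_posterior_threshold(w0, m0, s0, w1, m1, s1):
    """Point between the component means where the posteriors are equal."""

    def f(x):
        return (np.log(w1) + norm.logpdf(x, m1, s1)
                - np.log(w0) - norm.logpdf(x, m0, s0))

    lo, hi = m0, m1
    try:
        if f(lo) * f(hi) < 0:
            return float(brentq(f, lo, hi))
    except ValueError:
        pass
    return float(0.5 * (m0 + m1))


def gmm_gate(intensities, marker: str, specimen: str | None = None,
             seed: int = 0, n_init: int = 10,
             min_weight: float = 0.01) -> GateResult:
    """Gate one marker's intensities into positive/negative cells.

    Fits a 2-component GMM to log1p intensities with ``n_init`` restarts at
    a fixed seed; degenerate fits (a component weight below ``min_weight``,
    or constant input) fall back to an all-negative call with a warning
    flag set.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < MIN_CELLS:
        raise ValueError(f"need at least {MIN_CELLS} cells, got {x.size}")
    if np.any(x < 0):
        raise ValueError("intensities must be nonnegative")
    lx = np.log1p(x)

    if np.ptp(lx) < 1e-12:
        warnings.warn(f"degenerate gate for {marker}: constant intensities")
        return GateResult(marker, specimen, float(lx[0]), 0.0, np.nan,
                          np.zeros(x.size, dtype=bool), degenerate=True)

    gm = GaussianMixture(n_components=2, n_init=n_init, random_state=seed,
                         covariance_type="full")
    gm.fit(lx.reshape(-1, 1))
    means = gm.means_.ravel()
    order = np.argsort(means)
    m0, m1 = means[order]
    w0, w1 = gm.weights_.ravel()[order]
    s0, s1 = np.sqrt(gm.covariances_.ravel()[order])

    if min(w0, w1) < min_weight:
        warnings.warn(f"degenerate gate for {marker}: component weight "
                      f"{min(w0, w1):.4f} < {min_weight}")
        return GateResult(marker, specimen, float(m1), 0.0, np.nan,
                          np.zeros(x.size, dtype=bool), degenerate=True,
                          means=(float(m0), float(m1)))

    thr = _equal_posterior_threshold(w0, m0, s0, w1, m1, s1)
    calls = lx > thr
    if calls.any() and (~calls).any():
        s_to_b = float(x[calls].mean() / x[~calls].mean())
    else:
        s_to_b = np.nan
    return GateResult(
        marker=marker, specimen=specimen, threshold=thr,
        positive_fraction=float(calls.mean()), s_to_b=s_to_b,
        per_cell_calls=calls, means=(float(m0), float(m1)),
    )


def gate_table(df: pd.DataFrame, markers, per_specimen: bool = True,
               seed: int = 0, n_init: int = 10):
    """Gate every marker (per specimen by default) and append call columns.

    Returns ``(gated_df, summary)`` where ``gated_df`` has one ``<m>_pos``
    0/1 column per marker and ``summary`` is a tidy frame of thresholds,
    positive fractions and S:B ratios.
    """
    df = df.copy()
    rows = []
    for m in markers:
        if m not in df.columns:
            raise KeyError(f"marker column {m!r} missing from cell table")
        calls = np.zeros(len(df), dtype=bool)
        groups = df.groupby("specimen_id").indices if per_specimen else {
            None: np.arange(len(df))
        }
        for spec_id, idx in groups.items():
            res = gmm_gate(df[m].values[idx], m, specimen=spec_id,
                           seed=seed, n_init=n_init)
            calls[idx] = res.per_cell_calls
            rows.append({
                "marker": m, "specimen_id": spec_id,
                "threshold": res.threshold,
                "positive_fraction": res.positive_fraction,
                "s_to_b": res.s_to_b, "degenerate": res.degenerate,
            })
        df[f"{m}_pos"] = calls.astype(int)
    return df, pd.DataFrame(rows)


@dataclass
class CellTypeCall:
    labels: pd.Series                  # per-cell lineage label
    unassigned_fraction: pd.Series     # per specimen
    label_fractions: pd.DataFrame = field(default=None)


def _rule_markers(rules):
    out = set()
    for r in rules:
        for key in ("all_of", "any_of", "none_of"):
            out.update(r.get(key, []))
    return out


def call_cell_types(df: pd.DataFrame, rules=None,
                    call_suffix: str = "_pos") -> CellTypeCall:
    """Assign lineage labels by first-match evaluation of the rule list.

    ``df`` must carry a 0/1 ``<marker>_pos`` column for every marker a rule
    references. Cells matching no rule are labeled Unassigned.
    """
    rules = rules if rules is not None else DEFAULT_LINEAGE_RULES
    needed = _rule_markers(rules)
    missing = [m for m in needed if f"{m}{call_suffix}" not in df.columns]
    if missing:
        raise KeyError(f"dendrogram references ungated markers: {missing}")

    def pos(m):
        return df[f"{m}{call_suffix}"].values.astype(bool)

    labels = np.full(len(df), UNASSIGNED, dtype=object)
    unset = np.ones(len(df), dtype=bool)
    for rule in rules:
        match = np.ones(len(df), dtype=bool)
        for m in rule.get("all_of", []):
            match &= pos(m)
        any_of = rule.get("any_of", [])
        if any_of:
            any_mask = np.zeros(len(df), dtype=bool)
            for m in any_of:
                any_mask |= pos(m)
            match &= any_mask
        for m in rule.get("none_of", []):
            match &= ~pos(m)
        take = match & unset
        labels[take] = rule["label"]
        unset &= ~take

    ser = pd.Series(labels, index=df.index, name="cell_type")
    by_spec = ser.groupby(df["specimen_id"]).apply(
        lambda s: float(np.mean(s == UNASSIGNED))
    )
    fracs = (
        pd.crosstab(df["specimen_id"], ser, normalize="index")
        if len(df) else None
    )
    return CellTypeCall(labels=ser, unassigned_fraction=by_spec,
                        label_fractions=fracs)
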