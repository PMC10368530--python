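"""Kaplan-Meier estimation, log-rank testing and O/E hazard ratios.

The two-group hazard ratio is computed from observed and expected event
counts accumulated over the pooled event times::

    HR = (Oa / Ea) / (Ob / Eb)

with a confidence interval of ``exp(log HR +/- z * sqrt(1/Ea + 1/Eb))``.
Group ``a`` is the group with label 0 (or the first label in sorted order),
so ``hr < 1`` means group ``a`` progresses more slowly.

Model-comparison helpers (leave-one-out, bootstrap) are generic: they take
callables mapping a specimen index subset to a scalar (a rank or an HR) so
that any scoring pipeline can be resampled without this module knowing
about it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "SurvivalComparison",
    "ComparisonStudy",
    "km_estimate",
    "logrank_hr",
    "logrank_hr_batch",
    "loo_compare",
    "bootstrap_compare",
    "bh_adjust",
]


@dataclass
class SurvivalComparison:
    """Two-group log-rank comparison with O/E hazard ratio."""

    Oa: float
    Ob: float
    Ea: float
    Eb: float
    hr: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    n_a: int
    n_b: int
    flag: str | None = None

    @property
    def log_hr_se(self) -> float:
        return float(np.sqrt(1.0 / self.Ea + 1.0 / self.Eb))


@dataclass
class ComparisonStudy:
    mode: str
    n_resamples: int
    n_retained: int
    values_a: np.ndarray
    values_b: np.ndarray
    paired_p: float
    adjusted_p: np.ndarray
    fdr: float
    dropped: list = field(default_factory=list)


def _validate_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not np.all(np.isin(events, [0, 1])):
        raise ValueError("event indicators must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events):
    """Product-limit survival estimate.

    Returns ``(t, s)`` where ``s[i]`` is the estimated survival just after
    ``t[i]``; ``t`` contains the distinct event times. Right-censored
    observations are honored.
    """
    times, events = _validate_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    t = kmf.survival_function_.index.values.astype(float)
    s = kmf.survival_function_.iloc[:, 0].values.astype(float)
    keep = t > 0
    return t[keep], s[keep]


def _logrank_tables(times, events, group):
    """Sorted risk tables shared by the scalar and batched paths.

    Returns distinct event times with per-time total deaths ``d``, total at
    risk ``n`` and, per sorted specimen, order/alignment arrays used to
    accumulate group-wise counts.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = group[order]
    return t, e, g, order


def logrank_hr(times, events, group) -> SurvivalComparison:
    """Two-group log-rank test with the O/E hazard ratio.

    ``group`` may be any array with exactly two distinct labels; group "a"
    is the smaller label.
    """
    times, events = _validate_surv(times, events)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.size}")
    ga = group == labels[0]

    t, e, a, _ = _logrank_tables(times, events, ga.astype(int))
    n = t.size
    uniq = np.unique(t[e == 1])
    Oa = Ob = Ea = Eb = V = 0.0
    for u in uniq:
        at_risk = t >= u
        na = float(np.sum(at_risk & (a == 1)))
        nb = float(np.sum(at_risk & (a == 0)))
        nt = na + nb
        dmask = (t == u) & (e == 1)
        d = float(np.sum(dmask))
        da = float(np.sum(dmask & (a == 1)))
        Oa += da
        Ob += d - da
        Ea += d * na / nt
        Eb += d * nb / nt
        if nt > 1:
            V += d * (na / nt) * (nb / nt) * (nt - d) / (nt - 1)

    flag = None
    if Oa == 0 or Ob == 0:
        flag = "event-free-group"
    if Ea > 0 and Eb > 0 and Oa > 0 and Ob > 0:
        hr = (Oa / Ea) / (Ob / Eb)
    else:
        # one-sided bound: substitute half an event for the empty cell
        hr = ((Oa + 0.5) / max(Ea, 0.5)) / ((Ob + 0.5) / max(Eb, 0.5))
    se = np.sqrt(1.0 / max(Ea, 1e-12) + 1.0 / max(Eb, 1e-12))
    ci_low = float(np.exp(np.log(hr) - 1.96 * se))
    ci_high = float(np.exp(np.log(hr) + 1.96 * se))
    chi2 = float((Oa - Ea) ** 2 / V) if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    return SurvivalComparison(
        Oa=Oa, Ob=Ob, Ea=Ea, Eb=Eb,
        hr=float(hr), ci_low=ci_low, ci_high=ci_high,
        chi2=chi2, p=p,
        n_a=int(np.sum(ga)), n_b=int(np.sum(~ga)), flag=flag,
    )


def logrank_hr_batch(times, events, high: np.ndarray):
    """Vectorized O/E log-rank over many binary splits at once.

    ``high`` is an ``(n_specimens, n_models)`` boolean matrix; for each
    column the reported hazard ratio is high (True) vs low (False), i.e.
    ``hr < 1`` when the high class progresses more slowly.

    Returns a dict of arrays ``Oa, Ob, Ea, Eb, hr, chi2, p, valid`` of
    length ``n_models`` (``a`` = high class); ``valid`` is False for
    degenerate splits (a group empty or event-free expected counts).
    """
    times, events = _validate_surv(times, events)
    high = np.asarray(high, dtype=bool)
    if high.shape[0] != times.size:
        raise ValueError("split matrix row count must match specimen count")

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    H = high[order].astype(np.float64)  # (n, m)
    n, m = H.shape

    # at-risk counts at each specimen's time = suffix sums over sorted order
    nb_at = np.cumsum(H[::-1], axis=0)[::-1]          # high-group at risk
    nt_at = np.arange(n, 0, -1, dtype=float)          # total at risk

    uniq, first_idx = np.unique(t, return_index=True)
    # deaths per unique time, overall and per model in the high group
    d_tot = np.zeros(uniq.size)
    d_b = np.zeros((uniq.size, m))
    ev = e == 1
    idx_of_time = np.searchsorted(uniq, t)
    np.add.at(d_tot, idx_of_time[ev], 1.0)
    np.add.at(d_b, idx_of_time[ev], H[ev])

    has_event = d_tot > 0
    nb_u = nb_at[first_idx][has_event]       # (n_event_times, m)
    nt_u = nt_at[first_idx][has_event]       # (n_event_times,)
    d_u = d_tot[has_event]
    db_u = d_b[has_event]

    # group a = the high class, group b = the low class
    Oa = db_u.sum(axis=0)
    Ob = d_u.sum() - Oa
    Ea = (d_u[:, None] * nb_u / nt_u[:, None]).sum(axis=0)
    Eb = d_u.sum() - Ea
    with np.errstate(divide="ignore", invalid="ignore"):
        nt1 = np.maximum(nt_u - 1.0, 1.0)
        V = (
            d_u[:, None]
            * (nb_u / nt_u[:, None])
            * (1.0 - nb_u / nt_u[:, None])
            * (nt_u[:, None] - d_u[:, None])
            / nt1[:, None]
        ).sum(axis=0)
        hr = (Oa / Ea) / (Ob / Eb)
        chi2 = np.where(V > 0, (Oa - Ea) ** 2 / V, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    n_high = high.sum(axis=0)
    valid = (
        (n_high > 0)
        & (n_high < n)
        & (Oa > 0) & (Ob > 0) & (Ea > 0) & (Eb > 0)
        & np.isfinite(hr)
    )
    se = np.sqrt(1.0 / np.maximum(Ea, 1e-12) + 1.0 / np.maximum(Eb, 1e-12))
    with np.errstate(invalid="ignore", divide="ignore"):
        ci_low = np.exp(np.log(hr) - 1.96 * se)
        ci_high = np.exp(np.log(hr) + 1.96 * se)
    return {
        "Oa": Oa, "Ob": Ob, "Ea": Ea, "Eb": Eb,
        "hr": hr, "ci_low": ci_low, "ci_high": ci_high,
        "chi2": chi2, "p": p, "valid": valid,
    }


def _paired_study(mode, vals_a, vals_b, n_requested, dropped, fdr, extra_p=()):
    vals_a = np.asarray(vals_a, dtype=float)
    vals_b = np.asarray(vals_b, dtype=float)
    diffs = vals_a - vals_b
    if vals_a.size < 2 or np.allclose(diffs, 0.0):
        paired_p = 1.0
    else:
        paired_p = float(stats.ttest_rel(vals_a, vals_b).pvalue)
        if np.isnan(paired_p):
            paired_p = 1.0
    pvec = np.concatenate([[paired_p], np.asarray(extra_p, dtype=float)])
    adj = bh_adjust(pvec, fdr=fdr)["adjusted"]
    return ComparisonStudy(
        mode=mode,
        n_resamples=n_requested,
        n_retained=vals_a.size,
        values_a=vals_a,
        values_b=vals_b,
        paired_p=paired_p,
        adjusted_p=adj,
        fdr=fdr,
        dropped=list(dropped),
    )


def loo_compare(
    value_a: Callable[[np.ndarray], float],
    value_b: Callable[[np.ndarray], float],
    n_specimens: int,
    fdr: float = 0.1,
) -> ComparisonStudy:
    """Leave-one-out paired comparison of two per-cohort statistics.

    ``value_a``/``value_b`` map an index array (the retained specimens) to a
    scalar such as a model's rank; resamples where either callable returns
    a non-finite value are dropped and logged.
    """
    if n_specimens < 3:
        raise ValueError("leave-one-out requires a cohort of at least 3")
    all_idx = np.arange(n_specimens)
    va, vb, dropped = [], [], []
    for leave in range(n_specimens):
        keep = all_idx[all_idx != leave]
        a = value_a(keep)
        b = value_b(keep)
        if not (np.isfinite(a) and np.isfinite(b)):
            dropped.append(leave)
            continue
        va.append(a)
        vb.append(b)
    return _paired_study("loo", va, vb, n_specimens, dropped, fdr)


def bootstrap_compare(
    value_a: Callable[[np.ndarray], float],
    value_b: Callable[[np.ndarray], float],
    n_specimens: int,
    n: int = 500,
    seed: int = 0,
    fdr: float = 0.1,
) -> ComparisonStudy:
    """Bootstrap (resample with replacement at cohort size) paired comparison."""
    if n_specimens < 10:
        raise ValueError("bootstrap requires a cohort of at least 10")
    rng = np.random.default_rng(seed)
    va, vb, dropped = [], [], []
    for rep in range(n):
        idx = rng.integers(0, n_specimens, size=n_specimens)
        a = value_a(idx)
        b = value_b(idx)
        if not (np.isfinite(a) and np.isfinite(b)):
            dropped.append(rep)
            continue
        va.append(a)
        vb.append(b)
    return _paired_study("bootstrap", va, vb, n, dropped, fdr)


def bh_adjust(pvalues: Sequence[float], fdr: float = 0.1) -> dict:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``{"adjusted": array, "reject": bool array}`` where
    ``adjusted[i] = min_{j>=i} m * p_(j) / j`` (capped at 1) and the
    rejection set is the standard step-up set at the given FDR.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return {"adjusted": p.copy(), "reject": np.zeros(0, dtype=bool)}
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    passed = p[order] <= fdr * np.arange(1, m + 1) / m
    reject = np.zeros(m, dtype=bool)
    if np.any(passed):
        k = np.max(np.nonzero(passed)[0])
        reject[order[: k + 1]] = True
    return {"adjusted": adj, "reject": reject}
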