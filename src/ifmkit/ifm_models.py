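"""Image-feature models: median-split scoring, exhaustive search, enrichment.

An IFM is a set of exactly four (marker, region) parameters. Each parameter
contributes a binary subscore — 1 when the specimen's marker-positive
fraction in that region strictly exceeds the cohort median, else 0 (ties
score 0). Specimens with total >= 3 form the "high" class and the model's
hazard ratio compares low vs high progression, so protective models have
HR < 1. The exhaustive search scores every 4-of-26 combination and ranks by
ascending HR (descending 1/HR).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .survival_stats import SurvivalComparison, logrank_hr, logrank_hr_batch

__all__ = [
    "IFMDefinition",
    "EnrichmentResult",
    "IFM1_DEFINITION",
    "IFM2_PRESET",
    "REGIONS",
    "IMMUNE_13",
    "enumerate_ifms",
    "param_table",
    "score_definition",
    "compute_ifm1",
    "score_and_rank",
    "select_ifm2",
    "marker_enrichment",
    "compute_ifm3",
    "compute_ifm4",
]

REGIONS = ("CT", "IM")
IMMUNE_13 = [
    "CD3", "CD8", "CD45", "CD45RO", "CD68", "CD163", "CD4",
    "CD20", "aSMA", "FOXP3", "PD1", "PDL1", "CD31",
]


def _param_id(marker: str, region: str) -> str:
    return f"{marker}@{region}"


@dataclass(frozen=True)
class IFMDefinition:
    parameters: tuple  # of (marker, region) pairs, canonically sorted

    def __post_init__(self):
        params = tuple(sorted(tuple(p) for p in self.parameters))
        if len(params) != len(set(params)):
            raise ValueError("duplicate parameters in definition")
        object.__setattr__(self, "parameters", params)
        for _, region in params:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")

    @property
    def id(self) -> str:
        return "+".join(_param_id(m, r) for m, r in self.parameters)

    @property
    def markers(self) -> frozenset:
        return frozenset(m for m, _ in self.parameters)


IFM1_DEFINITION = IFMDefinition((
    ("CD3", "CT"), ("CD3", "IM"), ("CD8", "CT"), ("CD8", "IM"),
))
# Published composition of the second model: alpha-SMA in the tumor center
# plus CD45, PD-L1 and CD4 at the invasive margin.
IFM2_PRESET = IFMDefinition((
    ("aSMA", "CT"), ("CD45", "IM"), ("PDL1", "IM"), ("CD4", "IM"),
))


def enumerate_ifms(markers=None, regions=REGIONS, size: int = 4):
    """All distinct size-4 subsets of the marker x region parameter grid."""
    markers = list(markers) if markers is not None else list(IMMUNE_13)
    params = [(m, r) for m in markers for r in regions]
    return [IFMDefinition(combo)
            for combo in itertools.combinations(sorted(params), size)]


def param_table(region_stats: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy region stats to a specimen x "marker@region" fraction frame."""
    wide = region_stats.pivot_table(
        index="specimen_id", columns=["marker", "region"],
        values="positive_fraction", aggfunc="first", dropna=False,
    )
    wide.columns = [_param_id(m, r) for m, r in wide.columns]
    return wide


def _median_cutoffs(fractions: pd.DataFrame) -> pd.Series:
    # cohort medians ignore specimens with missing fractions (empty regions)
    return fractions.median(axis=0, skipna=True)


def score_definition(fractions: pd.DataFrame, definition: IFMDefinition,
                     medians: pd.Series | None = None) -> pd.DataFrame:
    """Per-specimen subscores/total/class for one model definition.

    ``medians`` may be frozen cutoffs from a training cohort; otherwise the
    cohort medians of ``fractions`` are used. Strictly-above scores 1; a
    tie at the median scores 0. Missing fractions give a missing subscore
    and flag the total.
    """
    cols = [_param_id(m, r) for m, r in definition.parameters]
    missing_cols = [c for c in cols if c not in fractions.columns]
    if missing_cols:
        raise KeyError(f"missing region fractions for {missing_cols}")
    sub = fractions[cols]
    med = (medians[cols] if medians is not None
           else _median_cutoffs(fractions)[cols])
    scores = (sub > med).astype(float)
    scores[sub.isna()] = np.nan
    total = scores.sum(axis=1, skipna=False)
    out = scores.copy()
    out.columns = [f"subscore_{c}" for c in cols]
    out["total"] = total
    out["incomplete"] = total.isna()
    out["binary_class"] = np.where(total >= 3, "high", "low")
    out.loc[total.isna(), "binary_class"] = "NA"
    return out


def compute_ifm1(fractions: pd.DataFrame,
                 medians: pd.Series | None = None) -> pd.DataFrame:
    """IFM1: CD3 and CD8 positive fractions in CT and IM, median-split."""
    usable = fractions[[
        _param_id(m, r) for m, r in IFM1_DEFINITION.parameters
    ]].dropna()
    if len(usable) < 3:
        raise ValueError("need fractions for >= 3 specimens")
    return score_definition(fractions, IFM1_DEFINITION, medians=medians)


@dataclass
class RankedModels:
    table: pd.DataFrame                  # id, hr, ci, p, rank (+flagged rows)
    definitions: list
    high_matrix: np.ndarray              # (n_specimens, n_models) bool
    medians: pd.Series
    specimen_ids: list = field(default_factory=list)

    def result_for(self, model_id: str) -> pd.Series:
        return self.table.set_index("id").loc[model_id]


def score_and_rank(defs, fractions: pd.DataFrame, clinical: pd.DataFrame,
                   medians: pd.Series | None = None) -> RankedModels:
    """Score every definition, compute its HR and rank by ascending HR.

    Degenerate splits (an empty class, event-free expected counts or a
    non-finite HR) are flagged and excluded from the ranking. Ties break by
    smaller log-rank p, then canonical id.
    """
    defs = list(defs)
    clin = clinical.set_index("specimen_id")
    common = fractions.index.intersection(clin.index)
    frac = fractions.loc[common]
    times = clin.loc[common, "pfs_days"].values.astype(float)
    events = clin.loc[common, "event"].values.astype(int)

    med = medians if medians is not None else _median_cutoffs(frac)
    above = frac.gt(med, axis=1)
    above[frac.isna()] = False
    A = above.values  # (n, n_params) specimen above-median indicators
    col_idx = {c: i for i, c in enumerate(frac.columns)}

    n = len(common)
    m = len(defs)
    totals = np.zeros((n, m), dtype=np.int8)
    for j, d in enumerate(defs):
        idx = [col_idx[_param_id(mk, r)] for mk, r in d.parameters]
        totals[:, j] = A[:, idx].sum(axis=1)
    high = totals >= 3

    res = logrank_hr_batch(times, events, high)
    table = pd.DataFrame({
        "id": [d.id for d in defs],
        "hr": res["hr"],
        "ci_low": res["ci_low"],
        "ci_high": res["ci_high"],
        "p": res["p"],
        "flagged": ~res["valid"],
    })
    valid = table.loc[~table["flagged"]].sort_values(
        ["hr", "p", "id"], kind="stable"
    )
    table["rank"] = np.nan
    table.loc[valid.index, "rank"] = np.arange(1, len(valid) + 1)
    return RankedModels(table=table, definitions=defs, high_matrix=high,
                        medians=med, specimen_ids=list(common))


def select_ifm2(ranked: RankedModels,
                exclude_markers=frozenset({"CD3", "CD8"})):
    """First model in the ranking containing none of the excluded markers."""
    if ranked.table.empty:
        raise ValueError("empty ranking")
    by_rank = ranked.table.dropna(subset=["rank"]).sort_values("rank")
    def_by_id = {d.id: d for d in ranked.definitions}
    for _, row in by_rank.iterrows():
        d = def_by_id[row["id"]]
        if not (d.markers & set(exclude_markers)):
            return d, row
    raise ValueError("all ranked models contain excluded markers")


@dataclass
class EnrichmentResult:
    feature: tuple                    # (marker, region)
    es: float
    p: float
    running: np.ndarray
    n_hit: int
    flagged: bool = False


def marker_enrichment(ranked: RankedModels) -> list:
    """GSEA-style running enrichment of each feature over the ranking.

    Walking the ranked list, the running sum gains ``1/n_hit - 1/n_total``
    at models containing the feature and loses ``1/n_total`` otherwise, so
    it ends at 0; ES is the extremum. The p-value is a two-sample KS test
    comparing the rank distributions of containing vs non-containing
    models. Positive ES means the feature concentrates among the
    best-ranked (lowest-HR) models.
    """
    by_rank = ranked.table.dropna(subset=["rank"]).sort_values("rank")
    ids = by_rank["id"].tolist()
    def_by_id = {d.id: d for d in ranked.definitions}
    n_total = len(ids)
    features = sorted({p for d in ranked.definitions for p in d.parameters})
    out = []
    ranks = np.arange(1, n_total + 1)
    for feat in features:
        hit = np.array([feat in def_by_id[i].parameters for i in ids])
        n_hit = int(hit.sum())
        if n_hit == 0 or n_hit == n_total:
            out.append(EnrichmentResult(feature=feat, es=np.nan, p=np.nan,
                                        running=np.zeros(n_total),
                                        n_hit=n_hit, flagged=True))
            continue
        running = np.cumsum(np.where(hit, 1.0 / n_hit, 0.0) - 1.0 / n_total)
        es = float(running[np.argmax(np.abs(running))])
        p = float(ks_2samp(ranks[hit], ranks[~hit]).pvalue)
        out.append(EnrichmentResult(feature=feat, es=es, p=p,
                                    running=running, n_hit=n_hit))
    return out


def _two_class_hr(times, events, is_a) -> SurvivalComparison:
    group = np.where(is_a, 0, 1)
    if is_a.all() or not is_a.any():
        raise ValueError("degenerate split: one class is empty")
    return logrank_hr(times, events, group)


def compute_ifm3(topic_fraction: pd.Series, clinical: pd.DataFrame,
                 percentile: float = 50.0,
                 cutoff: float | None = None):
    """Percentile split of a topic's per-specimen fraction vs survival.

    "High" is strictly above the percentile cutoff of the chosen topic
    fraction. Group a is the low class, so a hazardous topic yields
    HR < 1 (low class progresses more slowly). ``cutoff`` may be frozen
    from a training cohort.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie strictly inside (0, 100)")
    clin = clinical.set_index("specimen_id")
    common = topic_fraction.index.intersection(clin.index)
    f = topic_fraction.loc[common].astype(float)
    if f.nunique() <= 1:
        raise ValueError("degenerate split: constant topic fractions")
    cut = float(np.percentile(f.values, percentile)) if cutoff is None else cutoff
    high = f.values > cut
    comp = _two_class_hr(clin.loc[common, "pfs_days"].values.astype(float),
                         clin.loc[common, "event"].values.astype(int),
                         ~high)
    classes = pd.Series(np.where(high, "high", "low"), index=common,
                        name="ifm3_class")
    return comp, classes, cut


def ifm4_classes(ifm1_class: pd.Series, ifm3_class: pd.Series) -> pd.Series:
    """Composite class: 1 for IFM1-high and IFM3-low, 2 otherwise."""
    common = ifm1_class.index.intersection(ifm3_class.index)
    favorable = (ifm1_class.loc[common] == "high") & (
        ifm3_class.loc[common] == "low")
    return pd.Series(np.where(favorable, 1, 2), index=common,
                     name="ifm4_class")


def compute_ifm4(ifm1_class: pd.Series, ifm3_class: pd.Series,
                 clinical: pd.DataFrame):
    """HR of the composite favorable class (IFM1 high & IFM3 low) vs the rest."""
    cls = ifm4_classes(ifm1_class, ifm3_class)
    clin = clinical.set_index("specimen_id")
    common = cls.index.intersection(clin.index)
    cls = cls.loc[common]
    comp = _two_class_hr(clin.loc[common, "pfs_days"].values.astype(float),
                         clin.loc[common, "event"].values.astype(int),
                         (cls == 1).values)
    return comp, cls
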