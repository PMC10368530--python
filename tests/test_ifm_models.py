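import math

import numpy as np
import pandas as pd
import pytest

from ifmkit import ifm_models as im
from ifmkit.survival_stats import logrank_hr


def _fractions(n=20, seed=0, markers=("CD3", "CD8", "CD4")):
    rng = np.random.default_rng(seed)
    cols = {f"{m}@{r}": rng.random(n)
            for m in markers for r in ("CT", "IM")}
    return pd.DataFrame(cols, index=[f"S{i:03d}" for i in range(n)])


def _clinical(n=20, seed=0, hazard=None):
    rng = np.random.default_rng(seed)
    h = np.full(n, 0.01) if hazard is None else hazard
    t = rng.exponential(1 / h)
    c = rng.uniform(0, np.quantile(t, 0.8), n)
    return pd.DataFrame({
        "specimen_id": [f"S{i:03d}" for i in range(n)],
        "pfs_days": np.minimum(t, c),
        "event": (t <= c).astype(int),
    })


class TestEnumerate:
    def test_13_markers_gives_14950(self):
        defs = im.enumerate_ifms()
        assert len(defs) == 14_950

    def test_two_markers_single_model(self):
        assert len(im.enumerate_ifms(["A", "B"])) == 1

    def test_three_markers_fifteen(self):
        # brute-force oracle: C(6, 4) enumerated by hand is 15
        assert len(im.enumerate_ifms(["A", "B", "C"])) == 15

    @pytest.mark.parametrize("n_markers", [2, 3, 4, 5])
    def test_count_matches_binomial(self, n_markers):
        markers = [f"M{i}" for i in range(n_markers)]
        assert len(im.enumerate_ifms(markers)) == math.comb(2 * n_markers, 4)

    def test_no_duplicates_canonical_order(self):
        defs = im.enumerate_ifms(["A", "B", "C"])
        ids = [d.id for d in defs]
        assert len(set(ids)) == len(ids)
        assert ids == sorted(ids)

    def test_duplicate_params_rejected(self):
        with pytest.raises(ValueError):
            im.IFMDefinition((("CD3", "CT"), ("CD3", "CT"),
                              ("CD8", "CT"), ("CD8", "IM")))


class TestScoreDefinition:
    def test_above_all_medians_scores_four(self):
        fr = _fractions()
        fr.loc["S000"] = 1.0  # above every median
        scores = im.compute_ifm1(fr)
        assert scores.loc["S000", "total"] == 4
        assert scores.loc["S000", "binary_class"] == "high"

    def test_below_all_medians_scores_zero(self):
        fr = _fractions()
        fr.loc["S001"] = 0.0
        scores = im.compute_ifm1(fr)
        assert scores.loc["S001", "total"] == 0
        assert scores.loc["S001", "binary_class"] == "low"

    def test_tie_at_median_scores_zero(self):
        # strict "above" rule: exactly-at-median gives subscore 0
        fr = pd.DataFrame({
            "CD3@CT": [0.1, 0.2, 0.3],
            "CD3@IM": [0.1, 0.2, 0.3],
            "CD8@CT": [0.1, 0.2, 0.3],
            "CD8@IM": [0.1, 0.2, 0.3],
        }, index=["A", "B", "C"])
        scores = im.compute_ifm1(fr)
        assert scores.loc["B", "total"] == 0  # B sits exactly at the median

    def test_iid_cohort_mean_total_two(self):
        totals = []
        for rep in range(30):
            fr = _fractions(n=21, seed=rep)
            totals.append(im.compute_ifm1(fr)["total"].mean())
        assert np.mean(totals) == pytest.approx(2.0, abs=0.15)

    def test_missing_fraction_flags_total(self):
        fr = _fractions()
        fr.loc["S002", "CD3@CT"] = np.nan
        scores = im.compute_ifm1(fr)
        assert scores.loc["S002", "incomplete"]
        assert scores.loc["S002", "binary_class"] == "NA"

    def test_frozen_medians_used_verbatim(self):
        fr = _fractions()
        med = pd.Series(0.0, index=fr.columns)
        scores = im.score_definition(fr, im.IFM1_DEFINITION, medians=med)
        assert (scores["total"] == 4).all()

    def test_specimen_order_invariance(self):
        fr = _fractions()
        a = im.compute_ifm1(fr)
        b = im.compute_ifm1(fr.iloc[::-1])
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestScoreAndRank:
    def test_ifm1_definition_consistency(self):
        fr = _fractions()
        clin = _clinical()
        ranked = im.score_and_rank([im.IFM1_DEFINITION], fr, clin)
        direct = im.compute_ifm1(fr)
        hi = ranked.high_matrix[:, 0]
        assert (direct.loc[ranked.specimen_ids, "binary_class"] == "high"
                ).values.tolist() == hi.tolist()
        scalar = logrank_hr(
            clin.set_index("specimen_id").loc[ranked.specimen_ids,
                                              "pfs_days"].values,
            clin.set_index("specimen_id").loc[ranked.specimen_ids,
                                              "event"].values,
            np.where(hi, 0, 1))
        assert ranked.table["hr"].iloc[0] == pytest.approx(scalar.hr)

    def test_null_hr_centered_at_one(self):
        logs = []
        for rep in range(15):
            fr = _fractions(n=30, seed=rep)
            clin = _clinical(n=30, seed=100 + rep)
            ranked = im.score_and_rank(im.enumerate_ifms(["CD3", "CD8",
                                                          "CD4"]),
                                       fr, clin)
            ok = ranked.table.dropna(subset=["rank"])
            logs.extend(np.log(ok["hr"]))
        assert abs(np.mean(logs)) < 0.2

    def test_ranks_unique_and_ordered(self):
        fr = _fractions()
        clin = _clinical()
        ranked = im.score_and_rank(im.enumerate_ifms(["CD3", "CD8", "CD4"]),
                                   fr, clin)
        ok = ranked.table.dropna(subset=["rank"]).sort_values("rank")
        assert ok["rank"].is_unique
        assert ok["hr"].is_monotonic_increasing


class TestSelectIFM2:
    def _ranked_with(self, marker_sets):
        defs = []
        rows = []
        pool = ["CD3", "CD8", "CD4", "CD45", "PDL1", "aSMA", "CD20", "CD68"]
        for rank, ms in enumerate(marker_sets, start=1):
            params = tuple((m, "CT") for m in ms[:2]) + tuple(
                (m, "IM") for m in ms[2:])
            d = im.IFMDefinition(params)
            defs.append(d)
            rows.append({"id": d.id, "hr": 0.1 * rank, "ci_low": np.nan,
                         "ci_high": np.nan, "p": 0.01, "flagged": False,
                         "rank": float(rank)})
        return im.RankedModels(table=pd.DataFrame(rows), definitions=defs,
                               high_matrix=np.zeros((1, len(defs)),
                                                    dtype=bool),
                               medians=pd.Series(dtype=float))

    def test_skips_models_with_excluded_markers(self):
        ranked = self._ranked_with([
            ["CD3", "CD4", "CD45", "PDL1"],
            ["CD8", "CD4", "CD45", "CD20"],
            ["aSMA", "CD4", "CD45", "PDL1"],
        ])
        d, row = im.select_ifm2(ranked)
        assert row["rank"] == 3.0
        assert not (d.markers & {"CD3", "CD8"})

    def test_empty_exclusion_returns_rank_one(self):
        ranked = self._ranked_with([
            ["CD3", "CD4", "CD45", "PDL1"],
            ["aSMA", "CD4", "CD45", "PDL1"],
        ])
        d, row = im.select_ifm2(ranked, exclude_markers=set())
        assert row["rank"] == 1.0

    def test_all_excluded_raises(self):
        ranked = self._ranked_with([["CD3", "CD4", "CD45", "PDL1"]])
        with pytest.raises(ValueError, match="excluded"):
            im.select_ifm2(ranked,
                           exclude_markers={"CD3", "CD4", "CD45", "PDL1"})


class TestEnrichment:
    def _ranked_top_half(self, n_pairs=20):
        # 2N models; feature ("HIT","CT") appears in exactly the top N
        defs, rows = [], []
        fillers = [f"F{i}" for i in range(200)]
        rank = 1
        for i in range(n_pairs):
            d = im.IFMDefinition((("HIT", "CT"), (fillers[3 * i], "IM"),
                                  (fillers[3 * i + 1], "IM"),
                                  (fillers[3 * i + 2], "IM")))
            defs.append(d)
            rows.append({"id": d.id, "hr": 0.01 * rank, "p": 0.01,
                         "flagged": False, "rank": float(rank)})
            rank += 1
        for i in range(n_pairs):
            j = 100 + 3 * i
            d = im.IFMDefinition(((fillers[j], "CT"), (fillers[j + 1], "IM"),
                                  (fillers[j + 2], "IM"),
                                  (fillers[j], "IM")))
            defs.append(d)
            rows.append({"id": d.id, "hr": 0.01 * rank, "p": 0.01,
                         "flagged": False, "rank": float(rank)})
            rank += 1
        return im.RankedModels(table=pd.DataFrame(rows), definitions=defs,
                               high_matrix=np.zeros((1, len(defs)),
                                                    dtype=bool),
                               medians=pd.Series(dtype=float))

    def test_top_half_feature_es_half(self):
        # closed form: N hits at the head of a 2N list peaks at +0.5
        ranked = self._ranked_top_half()
        enr = {e.feature: e for e in im.marker_enrichment(ranked)}
        assert enr[("HIT", "CT")].es == pytest.approx(0.5)

    def test_reversed_ranking_flips_sign(self):
        ranked = self._ranked_top_half()
        rev = ranked.table.copy()
        rev["rank"] = rev["rank"].max() + 1 - rev["rank"]
        flipped = im.RankedModels(table=rev, definitions=ranked.definitions,
                                  high_matrix=ranked.high_matrix,
                                  medians=ranked.medians)
        a = {e.feature: e.es for e in im.marker_enrichment(ranked)}
        b = {e.feature: e.es for e in im.marker_enrichment(flipped)}
        assert b[("HIT", "CT")] == pytest.approx(-a[("HIT", "CT")])

    def test_uniform_feature_es_near_zero(self):
        rng = np.random.default_rng(0)
        fr = _fractions(n=30, seed=1)
        clin = _clinical(n=30, seed=2)
        ranked = im.score_and_rank(im.enumerate_ifms(["CD3", "CD8", "CD4"]),
                                   fr, clin)
        enr = im.marker_enrichment(ranked)
        # every feature appears symmetrically; |ES| bounded well below 1
        assert all(abs(e.es) < 0.6 for e in enr if not e.flagged)

    def test_ubiquitous_feature_flagged(self):
        defs = [im.IFMDefinition((("A", "CT"), ("B", "CT"),
                                  ("C", "CT"), ("D", "CT")))]
        rows = [{"id": defs[0].id, "hr": 0.5, "p": 0.5, "flagged": False,
                 "rank": 1.0}]
        ranked = im.RankedModels(table=pd.DataFrame(rows), definitions=defs,
                                 high_matrix=np.zeros((1, 1), dtype=bool),
                                 medians=pd.Series(dtype=float))
        enr = im.marker_enrichment(ranked)
        assert all(e.flagged for e in enr)

    def test_es_bounded_by_one(self):
        ranked = self._ranked_top_half()
        for e in im.marker_enrichment(ranked):
            if not e.flagged:
                assert abs(e.es) <= 1.0 + 1e-12


class TestIFM3and4:
    def _topic_cohort(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        frac = rng.random(n)
        hazard = 0.01 * np.exp(np.where(frac > np.median(frac),
                                        np.log(2), 0.0))
        clin = _clinical(n=n, seed=seed + 1, hazard=hazard)
        tf = pd.Series(frac, index=clin["specimen_id"].values)
        return tf, clin

    def test_bad_topic_low_class_protective(self):
        tf, clin = self._topic_cohort()
        comp, classes, cut = im.compute_ifm3(tf, clin, percentile=50)
        assert comp.hr < 1.0

    def test_degenerate_percentile_rejected(self):
        tf, clin = self._topic_cohort()
        with pytest.raises(ValueError):
            im.compute_ifm3(tf, clin, percentile=0)

    def test_constant_fractions_rejected(self):
        tf, clin = self._topic_cohort()
        with pytest.raises(ValueError, match="constant"):
            im.compute_ifm3(pd.Series(0.5, index=tf.index), clin)

    def test_percentile_robustness_50_vs_60(self):
        tf, clin = self._topic_cohort(n=100, seed=3)
        a, _, _ = im.compute_ifm3(tf, clin, percentile=50)
        b, _, _ = im.compute_ifm3(tf, clin, percentile=60)
        assert (a.hr < 1) == (b.hr < 1)
        assert a.ci_low < b.hr < a.ci_high or b.ci_low < a.hr < b.ci_high

    def test_frozen_cutoff_used(self):
        tf, clin = self._topic_cohort()
        comp, classes, cut = im.compute_ifm3(tf, clin, cutoff=0.5)
        assert cut == 0.5
        assert ((tf.loc[classes.index] > 0.5) == (classes == "high")).all()

    def test_ifm4_truth_table(self):
        idx = ["A", "B", "C", "D"]
        c1 = pd.Series(["high", "high", "low", "low"], index=idx)
        c3 = pd.Series(["low", "high", "low", "high"], index=idx)
        cls = im.ifm4_classes(c1, c3)
        assert cls.tolist() == [1, 2, 2, 2]

    def test_ifm4_single_class_raises(self):
        idx = ["A", "B", "C"]
        c1 = pd.Series(["high"] * 3, index=idx)
        c3 = pd.Series(["low"] * 3, index=idx)
        clin = _clinical(n=3).assign(specimen_id=idx)
        with pytest.raises(ValueError, match="degenerate"):
            im.compute_ifm4(c1, c3, clin)

    def test_ifm4_combines_independent_effects(self):
        # Monte-Carlo oracle over replicates: the composite split stratifies
        # at least as strongly as either component in expectation
        gains = []
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            n = 80
            immune = rng.random(n) < 0.5   # protective
            intrinsic = rng.random(n) < 0.5  # hazardous
            hazard = 0.01 * np.exp(
                -1.2 * immune.astype(float) + 1.2 * intrinsic.astype(float))
            clin = _clinical(n=n, seed=rep, hazard=hazard)
            idx = clin["specimen_id"].values
            c1 = pd.Series(np.where(immune, "high", "low"), index=idx)
            c3 = pd.Series(np.where(intrinsic, "high", "low"), index=idx)
            t = clin["pfs_days"].values
            e = clin["event"].values
            h1 = logrank_hr(t, e, np.where(immune, 0, 1)).hr
            h3 = logrank_hr(t, e, np.where(~intrinsic, 0, 1)).hr
            h4, _ = im.compute_ifm4(c1, c3, clin)
            gains.append(abs(np.log(h4.hr))
                         - max(abs(np.log(h1)), abs(np.log(h3))))
        assert np.mean(gains) > 0.0
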