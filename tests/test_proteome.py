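import numpy as np
import pytest

from idrbind.annotations import RegionRecord
from idrbind.proteome import (
    EnrichmentResult,
    ReferenceSet,
    elm_overlap,
    localization_enrichment,
    overlap_significance,
    promiscuity_correlation,
    read_degree_table,
    read_localization_table,
)


class TestReferenceSet:
    def test_empty(self):
        with pytest.raises(ValueError):
            ReferenceSet("ref", set())

    def test_from_file(self, tmp_path):
        p = tmp_path / "ref.txt"
        p.write_text("# comment\nP1\nP2\n\nP3\n")
        ref = ReferenceSet.from_file(p)
        assert ref.ids == {"P1", "P2", "P3"}
        assert ref.name == "ref"


class TestOverlapSignificance:
    def test_prediction_equals_reference_half_proteome(self):
        proteome = {f"P{i}" for i in range(2000)}
        half = {f"P{i}" for i in range(1000)}
        ref = ReferenceSet("ref", set(half))
        res = overlap_significance(half, ref, proteome, seed=0)
        # halves of predictions overlap fully (median 500); random draws of
        # 500 hit the reference at density 1/2 (median ~250) -> ratio ~2
        assert res.ratio == pytest.approx(2.0, rel=0.15)

    def test_disjoint_predictions(self):
        proteome = {f"P{i}" for i in range(100)}
        ref = ReferenceSet("ref", {f"P{i}" for i in range(50)})
        pred = {f"P{i}" for i in range(50, 80)}
        res = overlap_significance(pred, ref, proteome, seed=0)
        assert res.ratio == 0.0
        assert not res.significant

    def test_reference_disjoint_from_proteome(self):
        with pytest.raises(ValueError):
            overlap_significance(
                {"P1"}, ReferenceSet("ref", {"Q1"}), {"P1", "P2"}, seed=0)

    def test_prediction_not_subset(self):
        with pytest.raises(ValueError):
            overlap_significance(
                {"X"}, ReferenceSet("ref", {"P1"}), {"P1"}, seed=0)

    def test_random_predictions_ratio_near_one(self):
        ratios = []
        for run in range(20):
            rng = np.random.default_rng(run)
            proteome = sorted(f"P{i}" for i in range(2000))
            ref = ReferenceSet("ref", set(rng.choice(proteome, 500, replace=False)))
            pred = set(rng.choice(proteome, 400, replace=False))
            res = overlap_significance(pred, ref, set(proteome), seed=run)
            ratios.append(res.ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_id_relabel_invariance(self):
        proteome = {f"P{i}" for i in range(200)}
        ref = ReferenceSet("ref", {f"P{i}" for i in range(60)})
        pred = {f"P{i}" for i in range(40, 100)}
        r1 = overlap_significance(pred, ref, proteome, seed=5)

        def relabel(s):
            return {x.replace("P", "Z") for x in s}

        r2 = overlap_significance(
            relabel(pred), ReferenceSet("ref", relabel(ref.ids)),
            relabel(proteome), seed=5)
        assert r1.ratio == r2.ratio


class TestLocalizationEnrichment:
    def _setup(self, rng):
        proteome = [f"P{i}" for i in range(600)]
        loc = {}
        known = set(proteome[:150])
        for pid in proteome:
            loc[pid] = {"cytoplasm"}
        for pid in known:
            loc[pid] = {"nucleus"}  # known binders exclusively nuclear
        return proteome, loc, known

    def test_exclusive_localization(self, rng):
        proteome, loc, known = self._setup(rng)
        novel = {f"P{i}" for i in range(150, 200)}
        for pid in novel:
            loc[pid] = {"nucleus"}
        res = localization_enrichment(novel, known, loc, set(proteome), seed=0)
        assert "nucleus" in res.enriched_terms
        assert res.overlap_fraction == 1.0

    def test_min_frac_one_filters_everything(self, rng):
        proteome, loc, known = self._setup(rng)
        loc[next(iter(known))] = {"nucleus", "golgi"}  # two terms -> neither is 100%
        res = localization_enrichment(
            {"P300"}, known, loc, set(proteome), min_frac=1.0, seed=0)
        assert res.enriched_terms == []
        assert res.overlap_fraction is None

    def test_empty_table(self):
        with pytest.raises(ValueError):
            localization_enrichment({"a"}, {"b"}, {}, {"a", "b"})


class TestPromiscuity:
    def test_noiseless_linear(self):
        ids = [f"P{i}" for i in range(100)]
        rng = np.random.default_rng(0)
        ks = {p: int(rng.integers(0, 6)) for p in ids}
        degrees = {p: 10.0 * ks[p] for p in ids}
        res = promiscuity_correlation(ks, degrees, seed=0)
        assert res.pcc == pytest.approx(1.0)
        assert res.significant

    def test_per_k_table_oracle(self):
        rng = np.random.default_rng(1)
        ids = [f"P{i}" for i in range(200)]
        ks = {p: int(rng.integers(0, 5)) for p in ids}
        degrees = {p: float(rng.exponential(10)) for p in ids}
        res = promiscuity_correlation(ks, degrees, seed=0)
        for k, (mean_deg, count) in res.per_k_table.items():
            vals = [degrees[p] for p in ids if ks[p] == k]
            assert count == len(vals)
            assert mean_deg == pytest.approx(np.mean(vals))

    def test_pcc_textbook_oracle(self):
        rng = np.random.default_rng(2)
        ids = [f"P{i}" for i in range(150)]
        ks = {p: int(rng.integers(0, 6)) for p in ids}
        degrees = {p: float(rng.exponential(10) + ks[p]) for p in ids}
        res = promiscuity_correlation(ks, degrees, seed=0)
        xs = np.array(sorted(res.per_k_table))
        ys = np.array([res.per_k_table[int(k)][0] for k in xs])
        mx, my = xs.mean(), ys.mean()
        pcc = (np.sum((xs - mx) * (ys - my))
               / np.sqrt(np.sum((xs - mx) ** 2) * np.sum((ys - my) ** 2)))
        assert res.pcc == pytest.approx(pcc, abs=1e-12)

    def test_independent_pcc_near_zero_on_average(self):
        pccs = []
        for run in range(30):
            rng = np.random.default_rng(run)
            ids = [f"P{i}" for i in range(400)]
            ks = {p: int(rng.integers(0, 8)) for p in ids}
            degrees = {p: float(rng.exponential(20)) for p in ids}
            pccs.append(promiscuity_correlation(ks, degrees, seed=run).pcc)
        assert abs(np.mean(pccs)) < 0.15

    def test_too_few_distinct_k(self):
        ids = ["a", "b", "c", "d"]
        with pytest.raises(ValueError):
            promiscuity_correlation({p: 1 for p in ids}, {p: 2.0 for p in ids})

    def test_no_shared_ids(self):
        with pytest.raises(ValueError):
            promiscuity_correlation({"a": 1}, {"b": 2.0})


class TestElmOverlap:
    def test_all_inside(self):
        disorder = [RegionRecord("p", "disorder", 1, 50)]
        elms = [RegionRecord("p", "protein", 5, 10), RegionRecord("p", "protein", 20, 25)]
        pred = [RegionRecord("p", "protein", 1, 50)]
        frac, n = elm_overlap(pred, elms, disorder)
        assert frac == 1.0 and n == 2

    def test_none_in_disorder(self):
        disorder = [RegionRecord("p", "disorder", 40, 50)]
        elms = [RegionRecord("p", "protein", 5, 10)]
        frac, n = elm_overlap([], elms, disorder)
        assert frac is None and n == 0

    def test_three_of_five(self):
        disorder = [RegionRecord("p", "disorder", 1, 100)]
        elms = [RegionRecord("p", "protein", s, s + 4) for s in (1, 20, 40, 60, 80)]
        pred = [
            RegionRecord("p", "protein", 1, 8),
            RegionRecord("p", "protein", 22, 30),
            RegionRecord("p", "protein", 40, 44),
        ]
        frac, n = elm_overlap(pred, elms, disorder)
        assert n == 5
        assert frac == pytest.approx(0.6)


def test_table_readers(tmp_path):
    d = tmp_path / "deg.tsv"
    d.write_text("protein_id\tpartner_count\nP1\t4\nP2\t7.5\n")
    assert read_degree_table(d) == {"P1": 4.0, "P2": 7.5}
    l = tmp_path / "loc.tsv"
    l.write_text("P1\tnucleus\nP1\tcytoplasm\nP2\tnucleus\n")
    assert read_localization_table(l) == {
        "P1": {"nucleus", "cytoplasm"}, "P2": {"nucleus"}}
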