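"""Nearest-prototype classification, sweeps, SS correlations, classical MDS."""

import logging

import numpy as np
import pytest

import taxsim as ts
from taxsim.errors import DomainError


def _triple(name="<1,2,8>"):
    return ts.CombinationTriple.parse(name)


def _proto(label, codes, spec):
    return ts.Prototype(label, tuple((c, 0.0) for c in codes), spec)


YS, YL, OS, OL = ts.DEFAULT_STRATA


class TestTriples:
    def test_standard_preset_names(self):
        names = [t.name for t in ts.STANDARD_TRIPLES]
        assert names == ["<1,2,5>", "<1,2,6>", "<1,2,7>", "<1,2,8>",
                         "<2,2,5>", "<2,2,6>", "<2,2,7>", "<2,2,8>",
                         "<1,3,8>", "<1,4,8>"]

    def test_parse_round_trip(self):
        assert ts.CombinationTriple.parse("<2,3,5>").name == "<2,3,5>"

    def test_li_defaults_in_preset(self):
        li = next(t for t in ts.STANDARD_TRIPLES if t.cs.method_id == "li")
        assert (li.cs.alpha, li.cs.beta) == (0.2, 0.6)


class TestClassify:
    def test_nearer_prototype_wins(self, toy5):
        patient = ts.PatientRecord("p", 30, 10, frozenset({"A1a1"}))
        short = _proto("young_short", ["A1a2"], YS)
        long_ = _proto("young_long", ["B1a"], YL)
        assert ts.classify_patient(toy5, _triple(), patient, short, long_, 1) == "short"
        # identical to the long prototype's set → zero distance wins
        patient2 = ts.PatientRecord("q", 30, 10, frozenset({"B1a"}))
        assert ts.classify_patient(toy5, _triple(), patient2, short, long_, 1) == "long"

    def test_tie_goes_to_short_with_warning(self, toy5, caplog):
        patient = ts.PatientRecord("p", 30, 10, frozenset({"A1a1"}))
        proto = _proto("young_short", ["A1a2"], YS)
        proto_long = _proto("young_long", ["A1a2"], YL)
        with caplog.at_level(logging.WARNING, logger="taxsim"):
            label = ts.classify_patient(toy5, _triple(), patient, proto, proto_long, 1)
        assert label == "short"
        assert any("tie" in rec.message for rec in caplog.records)


class TestEvaluate:
    def _protos(self):
        return {
            "young_short": _proto("young_short", ["A1a1", "A1a2"], YS),
            "young_long": _proto("young_long", ["B1a", "B1"], YL),
            "old_short": _proto("old_short", ["A1a1", "A1b"], OS),
            "old_long": _proto("old_long", ["B1a", "B1"], OL),
        }

    def _patients(self):
        return [
            ts.PatientRecord("s1", 30, 5, frozenset({"A1a1"})),   # short, near short
            ts.PatientRecord("s2", 60, 6, frozenset({"A1a2"})),   # short, near short
            ts.PatientRecord("l1", 30, 30, frozenset({"B1a"})),   # long, near long
            ts.PatientRecord("l2", 60, 30, frozenset({"B1"})),    # long, near long
        ]

    def test_perfectly_separable_confusion(self, toy5):
        res = ts.evaluate(toy5, _triple(), self._patients(), self._protos(), 2)
        assert (res.tp, res.fp, res.fn, res.tn) == (2, 0, 0, 2)
        assert res.fscore == 1.0

    def test_fscore_closed_form(self):
        r = ts.EvaluationResult("<1,2,8>", 1, tp=12, fp=3, fn=8, tn=7)
        assert r.precision == pytest.approx(0.8)
        assert r.recall == pytest.approx(0.6)
        assert r.fscore == pytest.approx(2 * 0.8 * 0.6 / 1.4)
        assert r.n_test == 30

    def test_order_invariance_and_counts(self, toy5):
        a = ts.evaluate(toy5, _triple(), self._patients(), self._protos(), 2)
        b = ts.evaluate(toy5, _triple(), self._patients()[::-1], self._protos(), 2)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)
        assert a.tp + a.fp + a.fn + a.tn == len(self._patients())

    def test_empty_test_set(self, toy5):
        with pytest.raises(DomainError):
            ts.evaluate(toy5, _triple(), [], self._protos(), 1)

    def test_sweep_grid_shape(self, toy5):
        protos = {(_triple().ic, _triple().cs): self._protos()}
        rows = ts.sweep(toy5, [_triple()], self._patients(), protos, [1, 2, 3])
        assert len(rows) == 3
        assert [r.k for r in rows] == [1, 2, 2]  # capped at prototype length


class TestSSCorrelation:
    def test_self_correlation_and_duplicates(self, small_tax):
        leaves = sorted(n for n in small_tax.nodes if small_tax.is_leaf(n))
        pa = ts.Prototype("a", tuple((c, 0.0) for c in leaves[:10]))
        pb = ts.Prototype("b", tuple((c, 0.0) for c in leaves[40:50]))
        methods, corr = ts.ss_correlation(
            small_tax, "path", "wu", pa, pb, ks=[2, 4, 6, 8, 10],
            ss_methods=["allpairs_avg", "allpairs_avg", "bipartite"])
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(1.0)  # duplicate curve

    def test_constant_curve_reported_missing(self, toy5):
        pa = ts.Prototype("a", (("A1a1", 0.0), ("A1a2", 0.0), ("A1b", 0.0)))
        methods, corr = ts.ss_correlation(
            toy5, "path", "binary", pa, pa, ks=[1, 2, 3],
            ss_methods=["allpairs_avg", "bipartite"])
        # bipartite on identical sets is identically 0 → undefined correlation
        i = methods.index(ts.SSMethod.BIPARTITE)
        assert np.isnan(corr[i, i - 1])

    def test_needs_three_ks(self, toy5):
        pa = ts.Prototype("a", (("A1a1", 0.0), ("A1a2", 0.0)))
        with pytest.raises(DomainError):
            ts.ss_correlation(toy5, "path", "wu", pa, pa, ks=[1, 2])


class TestMDS:
    def test_colinear_points_recovered_exactly(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        coords = ts.mds_embed(D, dims=1)
        got = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        assert np.allclose(got, D, atol=1e-9)

    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords = ts.mds_embed(D, dims=2)
        dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        off = dists[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0], atol=1e-9)

    def test_toy5_subtree_clustering(self, toy5):
        codes = ["A1a1", "A1a2", "A1b", "A2a", "B1a", "B1"]
        D = np.array([[ts.concept_distance(toy5, "path", "wu", a, b) for b in codes]
                      for a in codes])
        np.fill_diagonal(D, 0.0)
        coords = ts.mds_embed(D, dims=2)
        emb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        a_idx, b_idx = range(4), range(4, 6)
        within_a = np.mean([emb[i, j] for i in a_idx for j in a_idx if i < j])
        between = np.mean([emb[i, j] for i in a_idx for j in b_idx])
        assert within_a < between

    def test_asymmetric_rejected(self):
        with pytest.raises(DomainError):
            ts.mds_embed([[0.0, 1.0], [0.5, 0.0]], dims=1)
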