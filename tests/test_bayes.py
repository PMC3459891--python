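"""Naive Bayes integration: discretization, CPTs, MI regularization, posterior."""

import itertools
import math

import numpy as np
import pytest

from tissuenet import (EvidenceDataset, GoldStandard, build_network,
                       fit_discretization, learn_cpts, mutual_information,
                       posterior, regularization_weights)
from tissuenet.bayes import NaiveBayesModel


def continuous(did, scores):
    return EvidenceDataset(did, "continuous", scores)


def pair_names(n):
    return [(f"p{i:03d}a", f"p{i:03d}b") for i in range(n)]


class TestDiscretization:
    def test_equal_frequency_five_bins(self):
        pairs = pair_names(100)
        ds = continuous("d", {p: float(v) for p, v in zip(pairs, range(1, 101))})
        spec = fit_discretization(ds, n_bins=5)
        bins = [spec.bin_of(v) for v in range(1, 101)]
        counts = np.bincount(bins, minlength=5)
        assert counts.tolist() == [20, 20, 20, 20, 20]

    def test_binary_passthrough(self):
        ds = EvidenceDataset("b", "binary", {("a", "b"): 1.0, ("a", "c"): 0.0})
        spec = fit_discretization(ds)
        assert spec.n_bins == 2
        assert spec.bin_of(0.0) == 0 and spec.bin_of(1.0) == 1

    def test_constant_dataset_single_bin_zero_llr(self):
        pairs = pair_names(10)
        ds = continuous("c", {p: 1.0 for p in pairs})
        spec = fit_discretization(ds, n_bins=5)
        assert spec.n_bins == 1
        gs = GoldStandard("GLOBAL", set(pairs[:5]), set(pairs[5:]))
        model = learn_cpts([ds], gs, {"c": spec})
        assert model.llr("c", 0) == pytest.approx(0.0)


class TestLearnCpts:
    def test_identical_class_distributions_zero_llr(self):
        pairs = pair_names(8)
        ds = continuous("d", {p: float(i % 2) for i, p in enumerate(pairs)})
        gs = GoldStandard("GLOBAL", set(pairs[:4]), set(pairs[4:]))
        spec = fit_discretization(ds, n_bins=2)
        model = learn_cpts([ds], gs, {"d": spec})
        for b in range(spec.n_bins):
            assert model.llr("d", b) == pytest.approx(0.0)

    def test_laplace_hand_count(self):
        # positives: bin0 x2; negatives: bin1 x2; alpha=1, 2 bins
        # P(bin0 | pos) = (2 + 1) / (2 + 1*2) = 3/4
        pairs = pair_names(4)
        scores = dict(zip(pairs, [0.0, 0.0, 1.0, 1.0]))
        ds = EvidenceDataset("d", "binary", scores)
        gs = GoldStandard("GLOBAL", set(pairs[:2]), set(pairs[2:]))
        model = learn_cpts([ds], gs, {"d": fit_discretization(ds)}, alpha=1.0)
        assert model.cpt["d"][0, 0] == pytest.approx(3 / 4)
        assert model.cpt["d"][1, 1] == pytest.approx(3 / 4)

    def test_prior_is_class_balance(self):
        pos = set(pair_names(30))
        neg = {(f"n{i:03d}a", f"n{i:03d}b") for i in range(270)}
        gs = GoldStandard("GLOBAL", pos, neg)
        ds = EvidenceDataset("d", "binary", {p: 1.0 for p in pos})
        model = learn_cpts([ds], gs, {"d": fit_discretization(ds)})
        assert model.prior == pytest.approx(0.1)

    def test_empty_class_rejected(self):
        pairs = pair_names(4)
        ds = EvidenceDataset("d", "binary", {p: 1.0 for p in pairs})
        with pytest.raises(ValueError, match="negatives"):
            learn_cpts([ds], GoldStandard("GLOBAL", set(pairs), set()),
                       {"d": fit_discretization(ds)})

    def test_cpt_columns_sum_to_one(self, small_bundle):
        from tissuenet import build_global_gold, propagate_annotations
        ann = propagate_annotations(small_bundle.ontology,
                                    small_bundle.direct_annotations)
        gs = build_global_gold(
            ann, max_term_size=small_bundle.config.gold_max_term_size)
        scheme = {d.dataset_id: fit_discretization(d)
                  for d in small_bundle.datasets}
        model = learn_cpts(small_bundle.datasets, gs, scheme)
        for table in model.cpt.values():
            assert np.allclose(table.sum(axis=0), 1.0, atol=1e-9)
            assert (table > 0).all()


class TestMutualInformation:
    def test_identity_i_xx_equals_h(self):
        # I(X, X): diagonal joint table with marginal p
        p = np.array([0.5, 0.3, 0.2])
        joint = np.diag(p)
        h = float(-(p * np.log(p)).sum())
        assert mutual_information(joint) == pytest.approx(h, abs=1e-12)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            joint = rng.random((3, 4))
            mi = mutual_information(joint)
            assert mi >= -1e-12
            assert mi == pytest.approx(mutual_information(joint.T), abs=1e-12)

    def test_independence_gives_zero(self):
        px = np.array([0.6, 0.4])
        py = np.array([0.2, 0.3, 0.5])
        joint = np.outer(px, py)
        assert mutual_information(joint) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_summation_oracle(self):
        # direct double-sum evaluation of sum p(x,y) ln[p(x,y)/(p(x)p(y))]
        joint = np.array([[2.0, 1.0], [1.0, 2.0]])  # 6 shared pairs
        pxy = joint / joint.sum()
        px, py = pxy.sum(axis=1), pxy.sum(axis=0)
        expected = sum(
            pxy[i, j] * math.log(pxy[i, j] / (px[i] * py[j]))
            for i in range(2) for j in range(2))
        assert mutual_information(joint) == pytest.approx(expected, abs=1e-12)


class TestRegularization:
    def test_identical_datasets_get_half_weight(self):
        pairs = pair_names(60)
        vals = {p: float(i % 5) for i, p in enumerate(pairs)}
        a, b = continuous("a", vals), continuous("b", dict(vals))
        scheme = {d.dataset_id: fit_discretization(d, 5) for d in (a, b)}
        report = regularization_weights([a, b], scheme)
        assert report.weight["a"] == pytest.approx(0.5, abs=1e-9)
        assert report.weight["b"] == pytest.approx(0.5, abs=1e-9)

    def test_independent_datasets_keep_full_weight(self):
        pairs = pair_names(64)
        # bin assignments designed independent: a cycles 0..3 slowly, b fast
        va = {p: float(i // 16) for i, p in enumerate(pairs)}
        vb = {p: float(i % 4) for i, p in enumerate(pairs)}
        a, b = continuous("a", va), continuous("b", vb)
        scheme = {d.dataset_id: fit_discretization(d, 4) for d in (a, b)}
        report = regularization_weights([a, b], scheme)
        assert report.weight["a"] == pytest.approx(1.0, abs=1e-9)
        assert report.weight["b"] == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_dataset_warns_weight_one(self):
        pairs = pair_names(10)
        flat = continuous("flat", {p: 0.0 for p in pairs})
        other = continuous("o", {p: float(i % 3) for i, p in enumerate(pairs)})
        scheme = {d.dataset_id: fit_discretization(d, 3) for d in (flat, other)}
        with pytest.warns(UserWarning):
            report = regularization_weights([flat, other], scheme)
        assert report.weight["flat"] == 1.0


def toy_model(prior=0.1, lr=9.0, weight=1.0):
    """One binary dataset with likelihood ratio lr in bin 1."""
    p1 = lr / (1 + lr)
    cpt = {"d": np.array([[1 - p1, 1 - 1 / (1 + lr)], [p1, 1 / (1 + lr)]])}
    # normalize columns exactly
    for k in cpt:
        cpt[k] = cpt[k] / cpt[k].sum(axis=0)
    from tissuenet.bayes import BinSpec
    scheme = {"d": BinSpec("d", "binary", np.array([]))}
    return NaiveBayesModel(prior=prior, scheme=scheme, cpt=cpt,
                           weight={"d": weight})


class TestPosterior:
    def test_no_evidence_returns_prior(self):
        model = toy_model(prior=0.3)
        assert posterior(model, {}) == pytest.approx(0.3, abs=1e-12)

    def test_likelihood_ratio_nine_from_prior_tenth(self):
        # 0.1 * 9 / (0.1 * 9 + 0.9) = 0.5
        model = toy_model(prior=0.1, lr=9.0)
        assert posterior(model, {"d": 1}) == pytest.approx(0.5, abs=1e-9)

    def test_half_weight_closed_form(self):
        # logistic(logit(0.1) + 0.5 * ln 9) = 0.25
        model = toy_model(prior=0.1, lr=9.0, weight=0.5)
        expected = 1 / (1 + math.exp(-(math.log(1 / 9) + 0.5 * math.log(9))))
        assert expected == pytest.approx(0.25, abs=1e-12)
        assert posterior(model, {"d": 1}) == pytest.approx(0.25, abs=1e-9)

    def test_unknown_dataset_rejected(self):
        with pytest.raises(KeyError):
            posterior(toy_model(), {"nope": 0})

    def test_monotone_in_llr(self):
        model = toy_model(prior=0.2, lr=4.0)
        assert posterior(model, {"d": 1}) > posterior(model, {"d": 0})

    def test_brute_force_bayes_oracle_exhaustive(self):
        """Posterior equals explicit-Z Bayes rule on all small instances.

        For every combination of 1..3 datasets x 2..3 bins and several
        priors, P(FR=1 | e) = prior * prod_k P(e_k|1) /
        [prior * prod P(e_k|1) + (1-prior) * prod P(e_k|0)].
        """
        from tissuenet.bayes import BinSpec
        rng = np.random.default_rng(42)
        for n_ds in (1, 2, 3):
            for n_bins in (2, 3):
                cpt, scheme = {}, {}
                for k in range(n_ds):
                    raw = rng.random((n_bins, 2)) + 0.1
                    cpt[f"d{k}"] = raw / raw.sum(axis=0)
                    scheme[f"d{k}"] = BinSpec(
                        f"d{k}", "continuous",
                        np.arange(1, n_bins, dtype=float))
                for prior in (0.05, 0.5, 0.9):
                    model = NaiveBayesModel(
                        prior=prior, scheme=scheme, cpt=cpt,
                        weight={f"d{k}": 1.0 for k in range(n_ds)})
                    for bins in itertools.product(range(n_bins), repeat=n_ds):
                        ev = {f"d{k}": b for k, b in enumerate(bins)}
                        num = prior * math.prod(
                            cpt[f"d{k}"][b, 0] for k, b in enumerate(bins))
                        den = num + (1 - prior) * math.prod(
                            cpt[f"d{k}"][b, 1] for k, b in enumerate(bins))
                        assert posterior(model, ev) == pytest.approx(
                            num / den, abs=1e-12)


class TestBuildNetwork:
    def make(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        ds = EvidenceDataset("d", "binary",
                             {pairs[0]: 1.0, pairs[1]: 0.0, pairs[2]: 1.0})
        gs = GoldStandard("GLOBAL",
                          {("a", "b"), ("b", "c")}, {("a", "c"), ("a", "d")})
        scheme = {"d": fit_discretization(ds)}
        model = learn_cpts([ds], gs, scheme)
        return model, ds

    def test_full_evidence_pair_count(self):
        model, ds = self.make()
        net = build_network(model, [ds], gene_universe=["a", "b", "c"])
        assert len(net.scores) == 3

    def test_scores_match_posterior_reevaluation(self):
        model, ds = self.make()
        net = build_network(model, [ds])
        spec = model.scheme["d"]
        for p, score in net.scores.items():
            ev = {"d": spec.bin_of(ds.scores[p])}
            assert score == pytest.approx(posterior(model, ev), abs=1e-12)

    def test_uninformative_model_scores_at_prior(self):
        pairs = pair_names(8)
        ds = continuous("d", {p: float(i % 2) for i, p in enumerate(pairs)})
        gs = GoldStandard("GLOBAL", set(pairs[:4]), set(pairs[4:]))
        scheme = {"d": fit_discretization(ds, 2)}
        model = learn_cpts([ds], gs, scheme)
        net = build_network(model, [ds])
        for v in net.scores.values():
            assert v == pytest.approx(model.prior, abs=1e-9)

    def test_no_evidence_pairs_included_at_prior_when_asked(self):
        model, ds = self.make()
        net = build_network(model, [ds], gene_universe=["a", "b", "c", "z"],
                            include_no_evidence=True)
        assert net.scores[("a", "z")] == pytest.approx(model.prior)
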