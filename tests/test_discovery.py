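"""Module discovery: screening signs, logistic fits, grouping, recovery."""

import numpy as np
import pandas as pd
import pytest

from assocmod import (
    default_spec,
    discover_modules,
    score_recovery,
    simulate_training_cohort,
)
from assocmod.discovery import (
    AssociationModule,
    DiscoveryConfig,
    EffectorCandidate,
    GeneModel,
    _expected_loglik,
    assemble_modules,
    fit_gene_model,
    screen_candidates,
)
from assocmod.io import validate_annotation
from assocmod.pipeline import preprocess_training
from assocmod.preprocess import trinary_expectation


def _rank_cdf(v):
    v = np.asarray(v, dtype=float)
    return (np.argsort(np.argsort(v)) + 1) / (v.size + 1)


def _screen_setup(rng, r_target, n=60, meth=False, flip_meth=False):
    """One gene correlated at ~r_target with its own arm (chr7p)."""
    ann = validate_annotation(
        pd.DataFrame(
            {"gene_id": ["g1"], "chromosome": ["7"], "arm": ["p"], "position": [1]}
        )
    )
    driver = rng.normal(size=n)
    noise_sd = np.sqrt(1.0 / r_target**2 - 1.0)
    expr = _rank_cdf(driver + rng.normal(0, noise_sd, n))
    arms = pd.DataFrame(
        [driver, rng.normal(size=n)], index=["chr7p", "chr8q"],
        columns=[f"S{i}" for i in range(n)],
    )
    meth_df = None
    if meth:
        sign = 1.0 if flip_meth else -1.0
        meth_df = pd.DataFrame(
            [sign * (driver + rng.normal(0, noise_sd, n))], index=["mg1"],
            columns=arms.columns,
        )
    return ann, expr, arms, meth_df


class TestScreening:
    def test_cis_candidate_retained_above_threshold(self, rng):
        ann, expr, arms, _ = _screen_setup(rng, 0.75)
        cands = screen_candidates("g1", expr, arms, None, ann)
        cis = [c for c in cands if c.kind == "cis_cnv"]
        assert len(cis) == 1 and cis[0].reference == "chr7p" and cis[0].direction == 1
        assert cis[0].screen_score >= 0.5

    def test_below_threshold_not_retained(self, rng):
        ann, expr, arms, _ = _screen_setup(rng, 0.30)
        cands = screen_candidates("g1", expr, arms, None, ann)
        assert not [c for c in cands if c.kind == "cis_cnv"]

    def test_positive_methylation_correlation_rejected_by_sign(self, rng):
        # methylation effectors must be negatively associated with expression
        ann, expr, arms, meth = _screen_setup(rng, 0.85, meth=True, flip_meth=True)
        cands = screen_candidates("g1", expr, arms, meth, ann)
        assert not [c for c in cands if c.kind == "methylation"]

    def test_negative_methylation_correlation_retained(self, rng):
        ann, expr, arms, meth = _screen_setup(rng, 0.85, meth=True)
        cands = screen_candidates("g1", expr, arms, meth, ann)
        m = [c for c in cands if c.kind == "methylation"]
        assert len(m) == 1 and m[0].direction == -1 and m[0].screen_score <= -0.5

    def test_unannotated_gene_has_no_cis_candidate(self, rng):
        ann, expr, arms, _ = _screen_setup(rng, 0.9)
        cands = screen_candidates("unknown", expr, arms, None, ann)
        assert not [c for c in cands if c.kind == "cis_cnv"]
        # the own-arm association now shows up as a trans candidate instead
        assert [c for c in cands if c.kind == "trans_cnv"]

    def test_too_few_samples_rejected(self, rng):
        ann, expr, arms, _ = _screen_setup(rng, 0.9, n=5)
        with pytest.raises(Exception, match="samples"):
            screen_candidates("g1", expr, arms, None, ann)


class TestGeneModelFit:
    def test_noise_free_candidate_matches_grid_oracle(self, rng):
        n = 20
        y_cdf = _rank_cdf(rng.normal(size=n))
        state = trinary_expectation(y_cdf)
        cand = EffectorCandidate("cis_cnv", "chr7p", +1, 0.9)
        model = fit_gene_model("g", y_cdf, [cand], {("cis_cnv", "chr7p"): state})
        assert model.selected and model.selected[0][1] > 0
        assert model.bic < 2 * n * np.log(3.0)  # strictly better than null
        # brute-force 1-D grid search over the weight
        grid = np.linspace(0.0, 20.0, 40001)
        lls = [_expected_loglik(np.array([l]), state[None, :], state) for l in grid]
        lam_grid = grid[int(np.argmax(lls))]
        assert model.selected[0][1] == pytest.approx(lam_grid, abs=1e-3)

    def test_independent_candidate_rejected_in_most_permutations(self):
        rejections = 0
        for s in range(100):
            r = np.random.default_rng(5000 + s)
            y = _rank_cdf(r.normal(size=60))
            x = trinary_expectation(_rank_cdf(r.normal(size=60)))
            m = fit_gene_model(
                "g", y, [EffectorCandidate("cis_cnv", "a", +1, 0.9)], {("cis_cnv", "a"): x}
            )
            rejections += not m.selected
        assert rejections >= 95

    def test_anticorrelated_positive_direction_hits_constraint_boundary(self, rng):
        y = _rank_cdf(rng.normal(size=30))
        x = trinary_expectation(1.0 - y)  # perfectly anti-correlated
        m = fit_gene_model(
            "g", y, [EffectorCandidate("cis_cnv", "a", +1, 0.9)], {("cis_cnv", "a"): x}
        )
        assert not m.selected  # lambda pinned at 0 cannot beat the null BIC

    def test_layer_order_prefers_cis_over_stronger_trans(self, rng):
        y = _rank_cdf(rng.normal(size=40))
        state = trinary_expectation(y)
        cis = EffectorCandidate("cis_cnv", "own", +1, 0.6)
        trans = EffectorCandidate("trans_cnv", "other", +1, 0.99)
        m = fit_gene_model(
            "g", y, [trans, cis], {("cis_cnv", "own"): state, ("trans_cnv", "other"): state}
        )
        assert m.selected[0][0].kind == "cis_cnv"


class TestAssembly:
    def _models(self, pairs):
        out = []
        for gene, effectors in pairs:
            sel = [(EffectorCandidate(kind, ref, +1, 0.8), 1.0) for kind, ref in effectors]
            out.append(GeneModel(gene_id=gene, selected=sel, loglik=0.0, bic=0.0))
        return out

    def test_cis_grouping(self, tiny_annotation):
        ann = validate_annotation(tiny_annotation)
        models = self._models(
            [("g1", [("cis_cnv", "chr7p")]), ("g2", [("cis_cnv", "chr7p")]),
             ("g3", [("cis_cnv", "chr7p")])]
        )
        mods = assemble_modules(models, ann, min_size=3)
        assert len(mods) == 1
        assert mods[0].kind == "cis_cnv" and mods[0].targets == ["g1", "g2", "g3"]

    def test_off_arm_gene_joins_trans_module_with_regulators(self, tiny_annotation):
        ann = validate_annotation(tiny_annotation)
        models = self._models(
            [("g1", [("cis_cnv", "chr7p")]), ("g4", [("trans_cnv", "chr7p")])]
        )
        mods = assemble_modules(models, ann, min_size=1)
        trans = [m for m in mods if m.kind == "trans_cnv"][0]
        assert trans.targets == ["g4"] and trans.regulators == ["g1"]

    def test_min_size_drops_small_modules(self, tiny_annotation):
        ann = validate_annotation(tiny_annotation)
        models = self._models([("g1", [("cis_cnv", "chr7p")]), ("g2", [("cis_cnv", "chr7p")])])
        assert assemble_modules(models, ann, min_size=5) == []


class TestEndToEnd:
    def test_planted_cis_module_recovered(self, training_processed):
        expr_cdf, arm_cnv, meth, annotation, truth = training_processed
        modules, models = discover_modules(expr_cdf, arm_cnv, meth, annotation)
        scores = score_recovery(modules, truth)
        assert scores["precision"][0] >= 0.9 and scores["recall"][0] >= 0.9

    def test_determinism_byte_identical_modules(self, training_processed):
        expr_cdf, arm_cnv, meth, annotation, _ = training_processed
        m1, _ = discover_modules(expr_cdf, arm_cnv, meth, annotation)
        m2, _ = discover_modules(expr_cdf, arm_cnv, meth, annotation)
        assert [(m.module_id, m.kind, m.effectors, m.targets) for m in m1] == [
            (m.module_id, m.kind, m.effectors, m.targets) for m in m2
        ]

    def test_null_data_yields_no_modules(self):
        import dataclasses

        spec = dataclasses.replace(default_spec(seed=9), planted=[])
        bundle, _ = simulate_training_cohort(spec)
        expr_cdf, arm_cnv, meth = preprocess_training(bundle)
        modules, _ = discover_modules(expr_cdf, arm_cnv, meth, bundle.annotation)
        assert modules == []
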