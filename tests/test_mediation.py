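"""Bootstrap mediation: analytic decomposition, classification, screening."""

import numpy as np
import pandas as pd
import pytest

from methlink.datasets import published_mediation_results, published_mediation_table
from methlink.mediation import (
    EffectEstimate, MediationResult, classify_mediation, mediate,
    mediation_screen, probe_mediation, proportion_mediated,
)
from methlink.synthetic import CohortConfig, generate_cohort


def noiseless_phenos(n=60, seed=0):
    """Exact linear system: a = 2, b = 3, c' = 1 with no residual noise.

    The mediator is 2*feh plus a component orthogonal to every design
    column, so the mediator-model fit returns a = 2 exactly while the
    outcome design stays full rank; the outcome is built as feh + 3*me, so
    the outcome fit returns b = 3 and c' = 1 exactly.
    """
    rng = np.random.default_rng(seed)
    feh = rng.integers(34, 71, n).astype(float)
    phenos = pd.DataFrame({
        "feh": feh, "sle": rng.normal(11, 7, n),
        "age": rng.uniform(18, 22, n), "sex": rng.integers(0, 2, n),
        "mds1": rng.normal(size=n), "mds2": rng.normal(size=n),
        "mds3": rng.normal(size=n), "mds4": rng.normal(size=n),
        "tbv": rng.normal(1.2e6, 1.2e5, n),
    }, index=[f"S{i:03d}" for i in range(n)])
    X = np.column_stack([np.ones(n),
                         phenos[["feh", "sle", "age", "sex", "mds1", "mds2",
                                 "mds3", "mds4", "tbv"]].to_numpy()])
    u = rng.standard_normal(n)
    u -= X @ np.linalg.lstsq(X, u, rcond=None)[0]  # orthogonal to the design
    me = pd.Series(2.0 * feh + u, index=phenos.index, name="me")
    phenos["vol"] = 1.0 * feh + 3.0 * me.to_numpy()
    return phenos, me


class TestMediate:
    def test_noiseless_product_of_coefficients(self):
        # a = 2, b = 3, c' = 1, delta = 34 - 70 = -36
        phenos, me = noiseless_phenos()
        res = mediate(phenos, me, "vol", treat_value=34, control_value=70,
                      n_boot=50, seed=1)
        assert res.ide.estimate == pytest.approx(-216.0, abs=1e-6)
        assert res.de.estimate == pytest.approx(-36.0, abs=1e-6)
        assert res.te.estimate == pytest.approx(-252.0, abs=1e-6)

    def test_additivity_holds_in_every_draw(self):
        cfg = CohortConfig(seed=2)
        phenos, latents = generate_cohort(cfg)
        me = latents["module_0"].rename("me")
        res = mediate(phenos, me, cfg.target_region, n_boot=500, seed=3,
                      keep_draws=True)
        total = res.draws["IDE"] + res.draws["DE"]
        np.testing.assert_allclose(total, res.draws["TE"], atol=1e-10)
        assert res.ide.estimate + res.de.estimate == pytest.approx(
            res.te.estimate, abs=1e-10)

    def test_default_contrast_spans_observed_feh_range(self):
        phenos, me = noiseless_phenos()
        res = mediate(phenos, me, "vol", n_boot=20, seed=0)
        assert res.treat_value == phenos["feh"].min()
        assert res.control_value == phenos["feh"].max()

    def test_fixed_seed_reproducible_and_seeds_differ(self):
        cfg = CohortConfig(seed=4)
        phenos, latents = generate_cohort(cfg)
        me = latents["module_0"].rename("me")
        r1 = mediate(phenos, me, cfg.target_region, n_boot=300, seed=7)
        r2 = mediate(phenos, me, cfg.target_region, n_boot=300, seed=7)
        r3 = mediate(phenos, me, cfg.target_region, n_boot=300, seed=8)
        assert r1.ide.ci_lower == r2.ide.ci_lower
        assert r1.ide.ci_upper == r2.ide.ci_upper
        assert r1.ide.ci_lower != r3.ide.ci_lower

    def test_null_a_effect_ide_shrinks_and_covers_zero(self):
        covered = 0
        ides = []
        for seed in range(25):
            cfg = CohortConfig(n_subjects=300, a_effect=0.0, b_effect=60.0,
                               seed=seed)
            phenos, latents = generate_cohort(cfg)
            me = latents["module_0"].rename("me")
            res = mediate(phenos, me, cfg.target_region, n_boot=400, seed=seed)
            ides.append(res.ide.estimate)
            covered += res.ide.ci_lower <= 0.0 <= res.ide.ci_upper
        assert covered >= 21  # ~95% nominal
        assert abs(np.mean(ides)) < 30.0

    def test_degenerate_mediator_rejected(self):
        phenos, me = noiseless_phenos()
        with pytest.raises(ValueError):
            mediate(phenos, pd.Series(1.0, index=phenos.index, name="me"), "vol")

    def test_equal_contrast_rejected(self):
        phenos, me = noiseless_phenos()
        with pytest.raises(ValueError):
            mediate(phenos, me, "vol", treat_value=50, control_value=50)

    def test_bootstrap_p_has_continuity_floor(self):
        phenos, me = noiseless_phenos()
        res = mediate(phenos, me, "vol", n_boot=99, seed=5)
        for eff in ("IDE", "DE", "TE"):
            assert res.effects[eff].p >= 2.0 / 100.0 - 1e-12


class TestClassification:
    def test_published_classifications(self):
        expected = {
            ("Pink4", "right_amygdala"): "full",
            ("Burlywood", "right_hippocampus"): "partial",
            ("Darkolivegreen1", "right_hippocampus"): "partial",
            ("Thistle2", "right_hippocampus"): "partial",
            ("Chocolate2", "right_hippocampus"): "none",
            ("Darkgray", "left_amygdala"): "none",
            ("Lavenderblush2", "left_amygdala"): "none",
        }
        for res in published_mediation_results():
            key = (res.mediator, res.outcome)
            if key in expected:
                assert classify_mediation(res) == expected[key], key

    def test_te_ci_spanning_zero_is_none(self):
        res = MediationResult(
            mediator="m", outcome="o",
            effects={"IDE": EffectEstimate(-50, -90, -10, 0.01),
                     "DE": EffectEstimate(-100, -200, -10, 0.01),
                     "TE": EffectEstimate(-150, -300, 5, 0.06)},
            treat_value=34, control_value=70, n_boot=100, seed=0)
        assert classify_mediation(res) == "none"


class TestProportionMediated:
    def test_published_thirty_percent(self):
        res = next(r for r in published_mediation_results()
                   if r.mediator == "Burlywood")
        assert proportion_mediated(res) == pytest.approx(0.304, abs=0.001)

    def test_published_twenty_four_percent(self):
        res = next(r for r in published_mediation_results()
                   if r.mediator == "Pink4")
        assert proportion_mediated(res) == pytest.approx(0.235, abs=0.001)

    def test_full_mediation_is_unity(self):
        res = MediationResult(
            mediator="m", outcome="o",
            effects={"IDE": EffectEstimate(-100, -150, -50, 0.01),
                     "DE": EffectEstimate(0.0, -20, 20, 0.9),
                     "TE": EffectEstimate(-100, -150, -50, 0.01)},
            treat_value=34, control_value=70, n_boot=100, seed=0)
        assert proportion_mediated(res) == pytest.approx(1.0)

    def test_zero_total_effect_rejected(self):
        res = MediationResult(
            mediator="m", outcome="o",
            effects={"IDE": EffectEstimate(0, -1, 1, 1.0),
                     "DE": EffectEstimate(0, -1, 1, 1.0),
                     "TE": EffectEstimate(0.0, -1, 1, 1.0)},
            treat_value=34, control_value=70, n_boot=100, seed=0)
        with pytest.raises(ZeroDivisionError):
            proportion_mediated(res)

    def test_published_additivity_to_printed_precision(self):
        table = published_mediation_table()
        wide = table.pivot(index=["mediator", "outcome"], columns="effect",
                           values="b")
        gaps = (wide["IDE"] + wide["DE"] - wide["TE"]).abs()
        assert gaps.max() <= 0.2  # one-decimal rounding in the source table


class TestScreens:
    def test_family_sizes(self):
        cfg = CohortConfig(n_subjects=200, a_effect=0.1, b_effect=80.0, seed=6)
        phenos, latents = generate_cohort(cfg)
        mes = (latents / latents.std())
        candidates = [(c, cfg.target_region) for c in mes.columns][:4]
        report, _ = mediation_screen(phenos, mes, candidates, n_boot=100, seed=1)
        assert len(report) == 3 * 4  # IDE/DE/TE per candidate

    def test_empty_candidates_empty_report(self):
        phenos, _ = generate_cohort(CohortConfig(seed=1))
        report, results = mediation_screen(phenos, pd.DataFrame(index=phenos.index),
                                           [], n_boot=10, seed=0)
        assert report.empty and results == []

    def test_planted_mediator_detected_among_decoys(self):
        detected, decoys_clean = 0, 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = CohortConfig(n_subjects=400, a_effect=0.10, b_effect=100.0,
                               c_direct=5.0, seed=seed)
            phenos, latents = generate_cohort(cfg)
            mes = latents / latents.std()
            cands = [(c, cfg.target_region) for c in mes.columns[:3]]
            report, results = mediation_screen(phenos, mes, cands,
                                               n_boot=500, seed=seed)
            cls = {r.mediator: classify_mediation(r) for r in results}
            if cls["module_0"] in ("full", "partial"):
                detected += 1
            if cls["module_1"] == "none" and cls["module_2"] == "none":
                decoys_clean += 1
        assert detected >= int(0.9 * n_rep)
        assert decoys_clean >= int(0.9 * n_rep)

    def test_probe_identical_to_me_reproduces_module_ide(self):
        cfg = CohortConfig(n_subjects=200, a_effect=0.1, b_effect=80.0, seed=9)
        phenos, latents = generate_cohort(cfg)
        me = (latents["module_0"] / latents["module_0"].std()).rename("me")
        module_res = mediate(phenos, me, cfg.target_region, n_boot=400, seed=2)
        probe_frame = pd.DataFrame({"cg_same": me})
        report, results = probe_mediation(probe_frame, phenos, cfg.target_region,
                                          me=me, n_boot=400, seed=3)
        assert len(report) == 3  # BH family = 3 x probe count
        probe_ide = results[0].ide.estimate
        assert probe_ide == pytest.approx(module_res.ide.estimate, rel=1e-6)
        assert report["r_with_me"].iloc[0] == pytest.approx(1.0)

    def test_driver_probe_beats_noise_probe(self, rng):
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = CohortConfig(n_subjects=300, a_effect=0.1, b_effect=80.0,
                               seed=100 + seed)
            phenos, latents = generate_cohort(cfg)
            lat = latents["module_0"]
            local = np.random.default_rng(seed)
            probes = pd.DataFrame({
                "cg_driver": lat + 0.2 * local.standard_normal(len(lat)),
                "cg_noise": local.standard_normal(len(lat)),
            }, index=phenos.index)
            _, results = probe_mediation(probes, phenos, cfg.target_region,
                                         n_boot=200, seed=seed)
            ides = {r.mediator: abs(r.ide.estimate) for r in results}
            wins += ides["cg_driver"] > ides["cg_noise"]
        assert wins >= int(0.9 * n_rep)
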