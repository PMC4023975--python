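"""Generator determinism, control envelope, class geometry, severity model."""

import numpy as np
import pandas as pd
import pytest

import hepamark as hm
from hepamark.simulate import (
    SimulationConfig,
    TreatmentGroup,
    effect_fraction,
    expected_severity,
    p_histopath,
)


def _null_config(seed=0, n_params=40):
    """All effects zero, histopathology impossible, no enzyme coupling."""
    design = (
        TreatmentGroup("S1", "drugA", 10.0, "mg/kg", "p.o.", 24.0, 10),
        TreatmentGroup("S1", "vehicle", 0.0, "mg/kg", "p.o.", 24.0, 10),
    )
    return SimulationConfig(
        seed=seed,
        design=design,
        platform_sizes={"transcripts_liver": n_params},
        severity_potency={"drugA": 0.0},
        alt_ast_coupling=0.0,
        effects=(),
    )


class TestDeterminism:
    def test_identical_config_bitstable(self):
        s1, t1 = hm.generate_study(hm.default_config(7))
        s2, t2 = hm.generate_study(hm.default_config(7))
        for p in s1.matrices:
            pd.testing.assert_frame_equal(
                s1.matrices[p].values, s2.matrices[p].values,
                check_exact=True,
            )
        pd.testing.assert_frame_equal(t1.samples, t2.samples,
                                      check_exact=True)

    def test_adding_parameters_preserves_existing_draws(self):
        """Per-parameter streams: growing a platform keeps old rows identical."""
        small = _null_config(seed=3, n_params=20)
        big = _null_config(seed=3, n_params=35)
        m_small = hm.generate_study(small)[0].matrices["transcripts_liver"]
        m_big = hm.generate_study(big)[0].matrices["transcripts_liver"]
        shared = m_small.values.index
        pd.testing.assert_frame_equal(
            m_big.values.loc[shared], m_small.values, check_exact=True
        )


class TestNullConfiguration:
    def test_all_negative_and_noise_scale(self):
        study, truth = hm.generate_study(_null_config(seed=5, n_params=200))
        assert set(truth.samples["true_class"]) == {"negative"}
        log2 = np.log2(study.matrices["transcripts_liver"].values)
        dev = log2.sub(log2.mean(axis=1), axis=0)
        n = dev.shape[1]
        assert abs(dev.to_numpy().mean()) < 1e-12  # centered by construction
        # subtracting the per-parameter mean shrinks the sd by sqrt((n-1)/n)
        expected_sd = 0.5 * np.sqrt((n - 1) / n)
        assert dev.to_numpy().std() == pytest.approx(expected_sd, rel=0.05)


class TestControlEnvelope:
    def test_large_n_matches_gaussian_tail(self):
        """With sd 0.5 the two-fold fraction approaches P(|N(0,0.5)|<=1)=0.9545."""
        design = (
            TreatmentGroup("S1", "vehicle", 0.0, "mg/kg", "p.o.", 24.0, 400),
            TreatmentGroup("S1", "drugA", 1.0, "mg/kg", "p.o.", 24.0, 2),
        )
        config = SimulationConfig(
            seed=11, design=design,
            platform_sizes={"transcripts_liver": 200},
            severity_potency={"drugA": 0.0},
        )
        study, _ = hm.generate_study(config)
        env = hm.control_envelope(study)
        assert env["within_2fold"] == pytest.approx(0.9545, abs=0.01)
        assert env["within_4fold"] >= env["within_2fold"]

    def test_tiny_noise_puts_everything_within_twofold(self):
        config = _null_config(seed=2)
        config.noise_sd_log2 = 1e-4
        env = hm.control_envelope(hm.generate_study(config)[0])
        assert env["within_2fold"] == 1.0

    def test_no_vehicle_samples_is_error(self):
        config = SimulationConfig(
            seed=0,
            design=(TreatmentGroup("S1", "drugA", 1.0, "mg/kg", "p.o.",
                                   24.0, 5),),
            platform_sizes={"transcripts_liver": 5},
            severity_potency={"drugA": 0.0},
        )
        study, _ = hm.generate_study(config)
        with pytest.raises(ValueError, match="vehicle"):
            hm.control_envelope(study)


class TestDesign:
    def test_default_design_has_280_samples(self, default_study):
        study, truth = default_study
        assert len(study.samples) == 280
        counts = truth.samples["true_class"].value_counts()
        # negative dominates, as in the emulated study (206/39/35)
        assert counts["negative"] > counts["increased"] + counts["positive"]
        assert counts["positive"] > 0 and counts["increased"] > 0

    def test_group_size_below_two_rejected(self):
        config = _null_config()
        config.design = (TreatmentGroup("S1", "vehicle", 0.0, "mg/kg",
                                        "p.o.", 24.0, 1),)
        with pytest.raises(ValueError, match="n=1"):
            hm.generate_study(config)

    def test_effect_on_unknown_parameter_rejected(self):
        config = _null_config()
        config.effects = (
            hm.EffectSpec("nonexistent", "clinical_chemistry", 2.0),
        )
        with pytest.raises(ValueError, match="nonexistent|absent"):
            hm.generate_study(config)

    def test_metabolite_platforms_cover_subset(self, default_study):
        study, _ = default_study
        n_all = len(study.matrices["transcripts_liver"].sample_ids)
        n_met = len(study.matrices["metabolites_serum"].sample_ids)
        assert n_met < n_all == 280


class TestSeverityModel:
    def test_severity_monotone_in_dose_and_time(self):
        config = hm.default_config(0)
        for treatment in ("ANIT", "Phalloidin", "MethyleneDianiline"):
            doses = sorted({g.dose for g in config.design
                            if g.treatment == treatment})
            sevs = [expected_severity(config, treatment, d, 24.0)
                    for d in doses]
            assert sevs == sorted(sevs)
            times = [1.5, 3.0, 6.0, 24.0]
            sevs_t = [expected_severity(config, treatment, doses[-1], t)
                      for t in times]
            assert sevs_t == sorted(sevs_t)

    def test_histopath_probability_monotone(self):
        s = np.linspace(0, 5, 50)
        p = p_histopath(s)
        assert (np.diff(p) >= 0).all()

    def test_effect_fraction_geometry(self):
        """0 at severity 0, the increased fraction at the rule threshold,
        1 at and beyond the histopathology threshold, monotone throughout."""
        assert effect_fraction(0.0, 0.5) == 0.0
        assert effect_fraction(1.0, 0.5) == pytest.approx(0.5)
        assert effect_fraction(2.0, 0.5) == 1.0
        assert effect_fraction(3.5, 0.5) == 1.0
        grid = np.linspace(0, 3, 200)
        vals = [effect_fraction(s, 0.3) for s in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestPlantedEffects:
    def test_planted_shift_recovered_within_3se(self, default_study):
        """Positive-minus-negative mean on the log2 scale matches the planted
        shift for strong markers, within Monte-Carlo tolerance."""
        study, truth = default_study
        cls = truth.samples["true_class"]
        strong = truth.parameters[
            truth.parameters["planted"]
            & (truth.parameters["delta_log2_positive"].abs() >= 2.0)
        ]
        for pid, row in strong.iterrows():
            m = study.matrices[row["platform"]]
            log2 = np.log2(m.values.loc[pid])
            pos = log2[[s for s in log2.index if cls[s] == "positive"]]
            neg = log2[[s for s in log2.index if cls[s] == "negative"]]
            diff = pos.mean() - neg.mean()
            se = np.sqrt(pos.var(ddof=1) / len(pos) +
                         neg.var(ddof=1) / len(neg))
            assert abs(diff - row["delta_log2_positive"]) < 3 * se + 0.15
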