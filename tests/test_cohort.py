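"""Synthetic cohort generator: distributions, effects, reproducibility."""

import numpy as np
import pytest

from oscillometry import (
    ERICParameters,
    FitOptions,
    GroupArchetype,
    InvalidInputError,
    SyntheticCohortConfig,
    apply_effect,
    fit_model,
    generate_cohort,
    sample_subject,
    synthesize_visit,
)
from oscillometry.cohort import DEFAULT_ARCHETYPES, PARAM_NAMES, DegenerateNoiseError


def zero_cv_config(**kwargs) -> SyntheticCohortConfig:
    arch = {
        k: GroupArchetype(
            v.group, dict(v.means), {n: 0.0 for n in PARAM_NAMES}, dict(v.growth), dict(v.bronchodilator)
        )
        for k, v in DEFAULT_ARCHETYPES.items()
    }
    return SyntheticCohortConfig(archetypes=arch, **kwargs)


class TestSampleSubject:
    def test_zero_cv_returns_archetype_means_exactly(self):
        cfg = zero_cv_config()
        p = sample_subject("SAI", cfg, np.random.default_rng(0))
        assert p.Rp == 0.824
        assert p.Cp == 0.045
        h = sample_subject("H", cfg, np.random.default_rng(0))
        assert h.Rp == 0.501
        assert h.Cp == 0.115

    def test_same_seed_gives_identical_draws(self):
        cfg = SyntheticCohortConfig()
        a = sample_subject("SAI", cfg, np.random.default_rng(99))
        b = sample_subject("SAI", cfg, np.random.default_rng(99))
        assert a == b

    def test_lognormal_mean_parameterisation(self):
        # at CV 0.3 the arithmetic sample mean must track the archetype mean
        arch = {
            "SAI": GroupArchetype(
                "SAI",
                dict(DEFAULT_ARCHETYPES["SAI"].means),
                {n: 0.3 for n in PARAM_NAMES},
                dict(DEFAULT_ARCHETYPES["SAI"].growth),
                dict(DEFAULT_ARCHETYPES["SAI"].bronchodilator),
            ),
            "H": DEFAULT_ARCHETYPES["H"],
        }
        cfg = SyntheticCohortConfig(archetypes=arch)
        rng = np.random.default_rng(7)
        draws = [sample_subject("SAI", cfg, rng) for _ in range(10_000)]
        for name in PARAM_NAMES:
            mean = np.mean([getattr(d, name) for d in draws])
            assert mean == pytest.approx(arch["SAI"].means[name], rel=0.03)


class TestApplyEffect:
    def test_identity_multipliers_leave_latent_unchanged(self):
        arch = GroupArchetype(
            "H", {"Rc": 0.35, "I": 0.002, "Rp": 0.5, "Cp": 0.1},
            {n: 0.0 for n in PARAM_NAMES},
            {n: 1.0 for n in PARAM_NAMES},
            {n: 1.0 for n in PARAM_NAMES},
        )
        latent = ERICParameters(0.35, 0.002, 0.5, 0.1)
        assert apply_effect(latent, "growth", arch) == latent

    def test_sai_growth_reproduces_published_trajectory(self):
        latent = ERICParameters(0.40, 0.0018, 0.824, 0.045)
        grown = apply_effect(latent, "growth", DEFAULT_ARCHETYPES["SAI"])
        assert grown.Rp == pytest.approx(0.824 * 0.73)  # -> 0.601 as published
        assert grown.Cp == pytest.approx(0.045 * 1.25)  # -> 0.056 as published
        post = apply_effect(grown, "bronchodilator", DEFAULT_ARCHETYPES["SAI"])
        assert post.Rp == pytest.approx(0.824 * 0.73 * 0.79)  # -> 0.472
        assert post.Cp == pytest.approx(0.045 * 1.25 * 1.35)  # -> 0.076

    def test_zero_multiplier_rejected(self):
        with pytest.raises(InvalidInputError):
            GroupArchetype(
                "H", {"Rc": 0.35, "I": 0.002, "Rp": 0.5, "Cp": 0.1},
                {n: 0.0 for n in PARAM_NAMES},
                {"Rc": 1.0, "I": 1.0, "Rp": 0.0, "Cp": 1.0},
                {n: 1.0 for n in PARAM_NAMES},
            )


class TestSynthesizeVisit:
    GRID = (3.0, 5.0, 10.0, 15.0, 20.0, 25.0, 35.0)

    def test_zero_noise_is_exact_model_output(self):
        latent = ERICParameters(0.40, 0.0018, 0.824, 0.045)
        from oscillometry import eval_eric

        spec = synthesize_visit(latent, self.GRID, 0.0, 0.0, np.random.default_rng(1))
        assert spec == eval_eric(latent, self.GRID)

    def test_fixed_seed_replicate_refits_within_tolerance(self):
        # single-replicate regression: noisy spectrum refit recovers Cp
        latent = ERICParameters(0.40, 0.0018, 0.824, 0.045)
        spec = synthesize_visit(latent, self.GRID, 0.01, 0.01, np.random.default_rng(123))
        again = synthesize_visit(latent, self.GRID, 0.01, 0.01, np.random.default_rng(123))
        assert spec == again
        fit = fit_model(spec, FitOptions(seed=5))
        assert fit.parameters.Cp == pytest.approx(latent.Cp, rel=0.15)

    def test_overwhelming_noise_raises_degenerate_error(self):
        latent = ERICParameters(Rc=0.01, I=0.001, Rp=0.001, Cp=0.1)
        with pytest.raises(DegenerateNoiseError):
            synthesize_visit(latent, self.GRID, 50.0, 0.0, np.random.default_rng(2))


class TestGenerateCohort:
    def test_record_bookkeeping(self):
        ds = generate_cohort(SyntheticCohortConfig(n_H=1, n_SAI=1, seed=0))
        assert len(ds) == 6  # 2 subjects x (2006 preB, 2008 preB, 2008 postB)
        assert not ds.select(visit=2006, condition="postB")
        for sid in ds.subjects():
            recs = [r for r in ds.records if r.subject_id == sid]
            assert {(r.visit, r.condition) for r in recs} == {
                (2006, "preB"), (2008, "preB"), (2008, "postB"),
            }

    def test_reproducible_from_seed(self):
        a = generate_cohort(SyntheticCohortConfig(seed=5, n_H=2, n_SAI=3))
        b = generate_cohort(SyntheticCohortConfig(seed=5, n_H=2, n_SAI=3))
        c = generate_cohort(SyntheticCohortConfig(seed=6, n_H=2, n_SAI=3))
        assert a == b
        assert a.records[0].spectrum != c.records[0].spectrum

    def test_adding_subjects_preserves_existing_draws(self):
        small = generate_cohort(SyntheticCohortConfig(seed=3, n_H=2, n_SAI=2))
        large = generate_cohort(SyntheticCohortConfig(seed=3, n_H=2, n_SAI=5))
        small_by_key = {(r.subject_id, r.visit, r.condition): r for r in small.records}
        for key, rec in small_by_key.items():
            match = [r for r in large.records if (r.subject_id, r.visit, r.condition) == key]
            assert match and match[0].spectrum == rec.spectrum

    def test_degenerate_cohort_recovers_archetype_trajectory_exactly(self):
        # CV 0, noise 0: fitted group-mean Cp follows means x multipliers
        cfg = zero_cv_config(n_H=1, n_SAI=2, noise_sd_R=0.0, noise_sd_X=0.0, seed=0)
        ds = generate_cohort(cfg)
        expected = {(2006, "preB"): 0.045, (2008, "preB"): 0.045 * 1.25, (2008, "postB"): 0.045 * 1.25 * 1.35}
        for (visit, cond), cp in expected.items():
            recs = ds.select(group="SAI", visit=visit, condition=cond)
            fits = [fit_model(r.spectrum, FitOptions(seed=1)).parameters.Cp for r in recs]
            assert np.mean(fits) == pytest.approx(cp, rel=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidInputError):
            SyntheticCohortConfig(n_H=0)
        with pytest.raises(InvalidInputError):
            SyntheticCohortConfig(noise_sd_R=-0.1)


class TestConfigFile:
    def test_key_value_file_overrides_defaults(self, tmp_path):
        from oscillometry.cohort import load_config

        path = tmp_path / "cohort.cfg"
        path.write_text(
            "# synthetic cohort settings\n"
            "n_H = 3\n"
            "n_SAI = 4\n"
            "noise_sd_R = 0.02\n"
            "seed = 12\n"
            "grid = 3 5 10 15 20 25\n"
            "SAI.means.Rp = 0.9\n"
            "H.growth.Cp = 1.5\n"
        )
        cfg = load_config(path)
        assert (cfg.n_H, cfg.n_SAI, cfg.seed) == (3, 4, 12)
        assert cfg.noise_sd_R == 0.02 and cfg.noise_sd_X == 0.01
        assert cfg.grid == (3.0, 5.0, 10.0, 15.0, 20.0, 25.0)
        assert cfg.archetypes["SAI"].means["Rp"] == 0.9
        assert cfg.archetypes["H"].growth["Cp"] == 1.5
        # untouched defaults survive
        assert cfg.archetypes["SAI"].means["Cp"] == 0.045

    def test_unknown_key_names_line(self, tmp_path):
        from oscillometry.cohort import load_config

        path = tmp_path / "bad.cfg"
        path.write_text("n_H = 2\nSAI.means.Qx = 1\n")
        with pytest.raises(InvalidInputError, match="line 2"):
            load_config(path)
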