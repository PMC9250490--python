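"""Synthetic cohort generator: uptake model, nuisance, atypicality, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from tautraj import (CohortConfig, RegionOnsetParams, build_phantom_atlas,
                     default_onset_params, generate_cohort, plant_atypical,
                     regional_uptake, regional_suvr)
from tautraj.atlas import BRAAK_GROUPS


# ---------------------------------------------------------------------------
# regional uptake curve

def test_uptake_at_onset_is_baseline_plus_half_amplitude():
    p = RegionOnsetParams(baseline=1.3, amplitude=0.8, onset=0.4, width=0.07)
    assert regional_uptake(0.4, p) == pytest.approx(1.3 + 0.4)


def test_uptake_with_zero_amplitude_is_baseline():
    p = RegionOnsetParams(baseline=1.0, amplitude=0.0, onset=0.7, width=0.1)
    assert regional_uptake(0.0, p) == pytest.approx(1.0)
    assert regional_uptake(1.0, p) == pytest.approx(1.0)


def test_uptake_matches_independent_logistic_evaluation():
    # sigma(1) = 1 / (1 + e^-1), evaluated independently to high precision
    p = RegionOnsetParams(baseline=1.0, amplitude=2.0, onset=0.5, width=0.1)
    expected = 1.0 + 2.0 / (1.0 + np.exp(-1.0))
    assert regional_uptake(0.6, p) == pytest.approx(expected, abs=1e-12)
    assert regional_uptake(0.6, p) == pytest.approx(2.4621171572600098, abs=1e-9)


def test_uptake_is_nondecreasing_in_progression():
    p = RegionOnsetParams(baseline=1.0, amplitude=1.0, onset=0.5, width=0.08)
    grid = [regional_uptake(s, p) for s in np.linspace(0, 1, 41)]
    assert np.all(np.diff(grid) >= 0)


def test_nonpositive_width_rejected():
    with pytest.raises(ValueError, match="width"):
        RegionOnsetParams(baseline=1.0, amplitude=1.0, onset=0.5, width=0.0)


def test_progression_outside_unit_interval_rejected():
    p = RegionOnsetParams(baseline=1.0, amplitude=1.0, onset=0.5, width=0.1)
    with pytest.raises(ValueError, match="progression"):
        regional_uptake(1.2, p)


# ---------------------------------------------------------------------------
# onset parameter defaults

def test_default_onsets_respect_braak_order(two_region_atlas):
    params = default_onset_params(two_region_atlas)
    group_onsets = {g: [params[r.name].onset
                        for r in two_region_atlas.regions_in_group(g)]
                    for g in BRAAK_GROUPS}
    assert max(group_onsets["I_II"]) < min(group_onsets["III_IV"])
    assert max(group_onsets["III_IV"]) < min(group_onsets["V_VI"])


def test_reference_region_has_zero_amplitude(two_region_atlas):
    params = default_onset_params(two_region_atlas)
    assert params[two_region_atlas.reference_region.name].amplitude == 0.0


def test_left_right_copies_share_parameters(two_region_atlas):
    params = default_onset_params(two_region_atlas)
    for r in two_region_atlas.cortical_regions:
        base = r.name.rsplit("_", 1)[0]
        assert params[f"{base}_L"] == params[f"{base}_R"]


# ---------------------------------------------------------------------------
# cohort generation

def test_noiseless_region_means_match_uptake_formula(clean_cohort):
    atlas = clean_cohort.atlas
    for rec, vol in zip(clean_cohort.records[:5], clean_cohort.volumes[:5]):
        for region in atlas.cortical_regions:
            expected = regional_uptake(rec.true_s,
                                       clean_cohort.onset_params[region.name])
            got = vol[atlas.region_mask(region.name)].mean()
            assert got == pytest.approx(expected, rel=1e-12)


def test_same_seed_gives_byte_identical_cohort_tables(small_atlas, tmp_path):
    cfg = CohortConfig(n=12)
    generate_cohort(small_atlas, cfg, seed=9, out_dir=tmp_path / "a")
    generate_cohort(small_atlas, cfg, seed=9, out_dir=tmp_path / "b")
    assert ((tmp_path / "a" / "cohort.csv").read_bytes()
            == (tmp_path / "b" / "cohort.csv").read_bytes())


def test_cohort_table_has_contract_columns(noisy_cohort):
    assert list(noisy_cohort.table.columns) == [
        "subject_id", "true_s", "diagnosis", "atypical_true", "mmse_like",
        "amyloid_like", "fdg_like", "age", "sex", "apoe4", "volume_path"]
    assert noisy_cohort.table["diagnosis"].isin(["CN", "MCI", "AD"]).all()


def test_monotone_severity_without_noise(clean_cohort):
    """With no nuisance, every cortical region's mean uptake is non-decreasing
    in true progression across subjects."""
    atlas = clean_cohort.atlas
    order = np.argsort(clean_cohort.true_s)
    for region in atlas.cortical_regions:
        mask = atlas.region_mask(region.name)
        means = np.array([v[mask].mean() for v in clean_cohort.volumes])[order]
        assert np.all(np.diff(means) >= -1e-12)


def test_reference_mean_constant_across_subjects_without_nuisance(small_atlas):
    cfg = CohortConfig(n=10, noise_sd=0.0, scale_sd=0.0, atypical_fraction=0.0)
    cohort = generate_cohort(small_atlas, cfg, seed=2)  # default smoothing on
    mask = small_atlas.region_mask("cerebellum_ref")
    ref_means = np.array([v[mask].mean() for v in cohort.volumes])
    assert np.ptp(ref_means) == pytest.approx(0.0, abs=1e-12)


def test_progression_drives_early_region_uptake(small_atlas):
    """Monte-Carlo check of generative monotonicity under full nuisance.

    Atypical subjects deliberately break the progression-uptake link in one
    hemisphere, so the correlation is checked on the typical majority.
    """
    cohort = generate_cohort(small_atlas, CohortConfig(n=300), seed=17)
    mask = (small_atlas.region_mask("i_ii_0_L")
            | small_atlas.region_mask("i_ii_0_R"))
    suvr_like = np.array(
        [v[mask].mean() / v[small_atlas.region_mask("cerebellum_ref")].mean()
         for v in cohort.volumes])
    typical = ~np.array([rec.atypical_true for rec in cohort.records])
    r, _ = pearsonr(cohort.true_s[typical], suvr_like[typical])
    assert r > 0.9


def test_stage_regimes_concentrate_progression(small_atlas):
    cfg = CohortConfig(n=120, stage_regimes=[(0.2, 0.01), (0.8, 0.01)],
                       atypical_fraction=0.0)
    cohort = generate_cohort(small_atlas, cfg, seed=3)
    s = cohort.true_s
    assert np.all((np.abs(s - 0.2) < 0.06) | (np.abs(s - 0.8) < 0.06))


def test_amyloid_must_precede_tau_onsets(small_atlas):
    cfg = CohortConfig(n=8, amyloid_onset=0.5)
    with pytest.raises(ValueError, match="amyloid_onset"):
        generate_cohort(small_atlas, cfg, seed=0)


def test_atypical_fraction_bounds_enforced(small_atlas):
    with pytest.raises(ValueError, match="atypical_fraction"):
        generate_cohort(small_atlas, CohortConfig(n=8, atypical_fraction=0.6),
                        seed=0)


# ---------------------------------------------------------------------------
# atypicality planting

def test_planting_near_unit_factor_approaches_identity(small_atlas, clean_cohort):
    vol = clean_cohort.volumes[0]
    out = plant_atypical(vol, small_atlas, factor=1.0 + 1e-9, side="L")
    assert np.allclose(out, vol, atol=1e-6)


def test_planting_doubles_left_right_ratio(small_atlas, clean_cohort):
    vol = clean_cohort.volumes[1]
    left = small_atlas.hemisphere_cortical_mask("L")
    right = small_atlas.hemisphere_cortical_mask("R")
    out = plant_atypical(vol, small_atlas, factor=2.0, side="L")
    before = vol[left].mean() / vol[right].mean()
    after = out[left].mean() / out[right].mean()
    assert after == pytest.approx(2.0 * before, rel=1e-12)
    assert np.array_equal(out[~left], vol[~left])  # rest untouched


def test_planted_suvr_scales_exactly_by_factor(small_atlas, clean_cohort):
    vol = clean_cohort.volumes[2]
    out = plant_atypical(vol, small_atlas, factor=3.0, side="R")
    for region in small_atlas.cortical_regions:
        ratio = (regional_suvr(out, small_atlas, region.name)
                 / regional_suvr(vol, small_atlas, region.name))
        assert ratio == pytest.approx(3.0 if region.hemisphere == "R" else 1.0,
                                      rel=1e-12)


def test_planting_requires_factor_above_one(small_atlas, clean_cohort):
    with pytest.raises(ValueError, match="factor"):
        plant_atypical(clean_cohort.volumes[0], small_atlas, factor=0.9, side="L")


def test_planting_requires_valid_side(small_atlas, clean_cohort):
    with pytest.raises(ValueError, match="side"):
        plant_atypical(clean_cohort.volumes[0], small_atlas, factor=2.0, side="M")
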