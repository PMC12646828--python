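"""Sex-specific cut-offs, muscle scores, EWGSOP2 classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonomyo import (InvalidParameterError, MissingDataError, ScoreCutoffs,
                     SubjectRecord, compute_cutoffs, derived_anthropometry,
                     ewgsop2_classify, muscle_mass_score,
                     muscle_quality_score, published_cutoffs, save_cutoffs,
                     load_cutoffs, score_cohort)


def record(sex="male", **kw):
    defaults = dict(id="x", sex=sex, rfma_cm2=3.0, rfmt_cm=1.0, mit_pct=46.0,
                    fatit_pct=39.0, nmnfit_pct=15.0, pennation_deg=5.5,
                    handgrip_kg=30.0, asmi=7.5)
    defaults.update(kw)
    return SubjectRecord(**defaults)


class TestSubjectRecord:
    def test_percentage_closure_enforced(self):
        with pytest.raises(InvalidParameterError):
            record(mit_pct=50.0, fatit_pct=40.0, nmnfit_pct=20.0)

    def test_bmi_consistency_enforced(self):
        with pytest.raises(InvalidParameterError):
            record(bmi=30.0, current_weight_kg=60.0, height_m=1.6)
        record(bmi=60.0 / 1.6 ** 2, current_weight_kg=60.0, height_m=1.6)

    def test_unknown_sex_rejected(self):
        with pytest.raises(InvalidParameterError):
            record(sex="other")


class TestCutoffs:
    def test_two_point_median(self):
        df = pd.DataFrame({
            "sex": ["male", "male", "female", "female"],
            "rfma_cm2": [3.0, 4.0, 2.0, 3.0],
            "rfmt_cm": [1.0, 1.2, 0.8, 1.0],
            "mit_pct": [40, 50, 40, 50],
            "fatit_pct": [35, 45, 35, 45],
            "pennation_deg": [5, 7, 4, 6],
        })
        cut = compute_cutoffs(df)
        assert cut.rfma_low["male"] == 3.5
        assert cut.rfma_low["female"] == 2.5
        assert cut.provenance == "computed"

    def test_published_cutoffs_reproduced_from_a_matching_cohort(self, rng):
        pub = published_cutoffs()
        rows = []
        # per sex, place values symmetric around the published medians
        for sex in ("male", "female"):
            for delta in (-0.4, -0.1, 0.1, 0.4):
                rows.append({
                    "sex": sex,
                    "rfma_cm2": pub.rfma_low[sex] + delta,
                    "rfmt_cm": pub.rfmt_low[sex] + delta / 4,
                    "mit_pct": pub.mit_low[sex] + 10 * delta,
                    "fatit_pct": pub.fatit_high[sex] + 10 * delta,
                    "pennation_deg": pub.pennation_low[sex] + delta,
                })
        cut = compute_cutoffs(pd.DataFrame(rows))
        for sex in ("male", "female"):
            assert cut.rfma_low[sex] == pytest.approx(pub.rfma_low[sex])
            assert cut.rfmt_low[sex] == pytest.approx(pub.rfmt_low[sex])
            assert cut.mit_low[sex] == pytest.approx(pub.mit_low[sex])
            assert cut.fatit_high[sex] == pytest.approx(pub.fatit_high[sex])
            assert cut.pennation_low[sex] == pytest.approx(pub.pennation_low[sex])

    def test_below_median_rate_at_most_half_plus_ties(self, rng):
        n = 101
        df = pd.DataFrame({
            "sex": ["male"] * n + ["female"] * n,
            "rfma_cm2": rng.normal(3, 1, 2 * n).clip(0.1),
            "rfmt_cm": rng.normal(1, 0.3, 2 * n).clip(0.1),
            "mit_pct": rng.uniform(20, 70, 2 * n),
            "fatit_pct": rng.uniform(20, 60, 2 * n),
            "pennation_deg": rng.uniform(1, 10, 2 * n),
        })
        cut = compute_cutoffs(df)
        for sex in ("male", "female"):
            sub = df[df.sex == sex]
            assert (sub.rfma_cm2 < cut.rfma_low[sex]).mean() <= 0.5
            assert (sub.fatit_pct > cut.fatit_high[sex]).mean() <= 0.5

    def test_insufficient_data_names_variable_and_sex(self):
        df = pd.DataFrame({
            "sex": ["male", "male", "female"],
            "rfma_cm2": [3.0, 4.0, 2.0],
            "rfmt_cm": [1.0, 1.2, 0.8],
            "mit_pct": [40, 50, 40],
            "fatit_pct": [35, 45, 35],
            "pennation_deg": [5, 7, 4],
        })
        with pytest.raises(MissingDataError, match="female"):
            compute_cutoffs(df)

    def test_yaml_round_trip(self, tmp_path):
        pub = published_cutoffs()
        save_cutoffs(tmp_path / "c.yaml", pub)
        back = load_cutoffs(tmp_path / "c.yaml")
        assert back.rfma_low == pub.rfma_low
        assert back.pennation_low == pub.pennation_low


class TestScores:
    def test_mass_score_on_sarcopenic_means(self):
        cut = published_cutoffs()
        male = record("male", rfma_cm2=2.77, rfmt_cm=0.88)
        assert muscle_mass_score(male, cut) == 2
        female = record("female", rfma_cm2=2.77, rfmt_cm=0.88)
        assert muscle_mass_score(female, cut) == 1  # only RFMT below

    def test_quality_score_on_sarcopenic_means(self):
        cut = published_cutoffs()
        male = record("male", mit_pct=44.99, fatit_pct=40.02,
                      nmnfit_pct=14.99, pennation_deg=4.97)
        assert muscle_quality_score(male, cut) == 3
        female = record("female", mit_pct=44.99, fatit_pct=40.02,
                        nmnfit_pct=14.99, pennation_deg=4.97)
        assert muscle_quality_score(female, cut) == 0

    def test_values_exactly_at_cutoffs_score_zero(self):
        cut = published_cutoffs()
        r = record("male", rfma_cm2=3.48, rfmt_cm=0.89, mit_pct=45.88,
                   fatit_pct=39.41, nmnfit_pct=100 - 45.88 - 39.41,
                   pennation_deg=5.76)
        assert muscle_mass_score(r, cut) == 0
        assert muscle_quality_score(r, cut) == 0

    def test_missing_inputs_raise_with_field_names(self):
        cut = published_cutoffs()
        r = SubjectRecord(id="m", sex="male", rfma_cm2=3.0)
        with pytest.raises(MissingDataError, match="rfmt_cm"):
            muscle_mass_score(r, cut)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.1, 6.0), st.floats(0.1, 2.0), st.floats(0.01, 1.0))
    def test_mass_score_monotone_in_worsening_mass(self, rfma, rfmt, drop):
        cut = published_cutoffs()
        base = muscle_mass_score(record("male", rfma_cm2=rfma, rfmt_cm=rfmt),
                                 cut)
        worse = muscle_mass_score(
            record("male", rfma_cm2=max(rfma - drop, 1e-6),
                   rfmt_cm=max(rfmt - drop, 1e-6)), cut)
        assert worse >= base
        assert base in (0, 1, 2)


class TestEwgsop2:
    def test_male_cohort_means_classify_as_sarcopenia(self):
        res = ewgsop2_classify(record("male", handgrip_kg=26.70, asmi=6.82))
        assert res.category == "sarcopenia"
        assert res.dynapenia

    def test_female_cohort_means_classify_as_none(self):
        res = ewgsop2_classify(record("female", handgrip_kg=17.71, asmi=5.51))
        assert res.category == "none"
        assert not res.dynapenia

    def test_low_strength_preserved_mass_is_probable_sarcopenia(self):
        res = ewgsop2_classify(record("male", handgrip_kg=26.0, asmi=7.5))
        assert res.category == "probable_sarcopenia"
        assert res.dynapenia and not res.low_mass

    def test_low_mass_only(self):
        res = ewgsop2_classify(record("female", handgrip_kg=20.0, asmi=5.0))
        assert res.category == "low_mass_only"

    def test_categories_exhaustive_and_exclusive(self):
        cats = set()
        for hg in (10.0, 30.0):
            for asmi in (5.0, 8.0):
                cats.add(ewgsop2_classify(
                    record("male", handgrip_kg=hg, asmi=asmi)).category)
        assert cats == {"sarcopenia", "probable_sarcopenia", "low_mass_only",
                        "none"}


class TestAnthropometry:
    def test_printed_formulas(self):
        bmi, loss = derived_anthropometry(72.0, 80.0, 1.6)
        assert bmi == pytest.approx(28.125)
        assert loss == pytest.approx(10.0)

    def test_no_loss_and_gain_sign(self):
        assert derived_anthropometry(50.0, 50.0, 1.5)[1] == 0.0
        assert derived_anthropometry(60.0, 50.0, 1.5)[1] == pytest.approx(-20.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            derived_anthropometry(0.0, 50.0, 1.5)


def test_score_cohort_adds_expected_columns():
    from sonomyo import CohortSpec, generate_cohort
    df = generate_cohort(CohortSpec(n_total=200, seed=5))
    scored = score_cohort(df, published_cutoffs())
    assert set(scored.mass_score.unique()) <= {0, 1, 2}
    assert set(scored.quality_score.unique()) <= {0, 1, 2, 3}
    assert ((scored.sarcopenia) == (scored.dynapenia
                                    & scored.low_muscle_mass)).all()
    assert set(scored.ewgsop2_category.unique()) <= {
        "sarcopenia", "probable_sarcopenia", "low_mass_only", "none"}
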