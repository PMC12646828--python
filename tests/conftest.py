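import numpy as np
import pytest

from sonomyo import (CohortSpec, TransverseSceneParams, compute_cutoffs,
                     generate_cohort, plant_outcome, run_model, score_cohort)


def coverage_of_planted_or(planted_or, model_id, outcome, coef_var,
                           intercept, n=2000, reps=200, seed0=0):
    """Empirical 95%-CI coverage of a planted odds ratio.

    Each replicate draws a fresh synthetic cohort, plants a Bernoulli
    outcome with the given log-odds slope on ``coef_var``, refits the
    pre-registered model and checks whether the Wald CI covers truth.
    """
    hits = 0
    for rep in range(reps):
        df = generate_cohort(CohortSpec(n_total=n, seed=seed0 + rep))
        if model_id == 2:
            df = score_cohort(df, compute_cutoffs(df))
        df = plant_outcome(df, {coef_var: np.log(planted_or)},
                           intercept=intercept, seed=seed0 + 10_000 + rep,
                           label=outcome)
        fit = run_model(df, model_id, outcome)
        row = fit.table.loc[coef_var]
        hits += row["ci_low"] <= planted_or <= row["ci_high"]
    return hits / reps


@pytest.fixture
def small_transverse():
    """Factory for fast small-frame transverse scenes."""

    def make(seed=0, fractions=(0.5, 0.3, 0.2), speckle=1.0, **kw):
        defaults = dict(shape=(128, 160), sft_cm=0.15,
                        semi_axis_depth_cm=0.35, semi_axis_width_cm=0.70,
                        class_fractions=fractions, speckle_scale=speckle,
                        seed=seed)
        defaults.update(kw)
        return TransverseSceneParams(**defaults)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
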