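"""Sex-specific muscle mass and quality scores and EWGSOP2 classification.

The ultrasound-based scores assign one point per indicator that falls on
the "worse" side of its sex-specific median cut-off, using strict
inequalities (a value exactly at the cut-off scores no point):

* muscle mass score (0-2):  RFMA below cut-off (1 pt), RFMT below (1 pt);
* muscle quality score (0-3): MiT below (1 pt), FATiT above (1 pt),
  pennation angle below (1 pt).

Cut-offs may be recomputed from a cohort (per-sex medians) or taken from
the published reference values shipped with the package.  EWGSOP2
classification uses the consensus sex-specific thresholds: low strength
handgrip < 27 kg (men) / < 16 kg (women); low mass ASMI < 7 kg/m^2 (men)
/ < 5.5 kg/m^2 (women).  Sarcopenia requires both; low strength alone is
probable sarcopenia, and "dynapenia" denotes low strength regardless of
mass.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, MissingDataError

MALE, FEMALE = "male", "female"

HANDGRIP_CUTOFF_KG = {MALE: 27.0, FEMALE: 16.0}
ASMI_CUTOFF_KG_M2 = {MALE: 7.0, FEMALE: 5.5}

_CUTOFF_VARS = {
    "rfma_low": "rfma_cm2",
    "rfmt_low": "rfmt_cm",
    "mit_low": "mit_pct",
    "fatit_high": "fatit_pct",
    "pennation_low": "pennation_deg",
}


@dataclass(frozen=True)
class SubjectRecord:
    """One patient row; missing optional fields are None."""

    id: str
    sex: str
    age: float | None = None
    height_m: float | None = None
    current_weight_kg: float | None = None
    usual_weight_kg: float | None = None
    bmi: float | None = None
    arm_circ_cm: float | None = None
    calf_circ_cm: float | None = None
    resistance_ohm: float | None = None
    reactance_ohm: float | None = None
    phase_angle_deg: float | None = None
    asmi: float | None = None
    handgrip_kg: float | None = None
    rfmt_cm: float | None = None
    rfma_cm2: float | None = None
    rfmai_cm2_m2: float | None = None
    sft_cm: float | None = None
    mit_pct: float | None = None
    fatit_pct: float | None = None
    nmnfit_pct: float | None = None
    pennation_deg: float | None = None
    sarcopenia: bool | None = None
    dynapenia: bool | None = None
    low_muscle_mass: bool | None = None

    def __post_init__(self):
        if self.sex not in (MALE, FEMALE):
            raise InvalidParameterError(f"sex must be male/female, got {self.sex!r}")
        if self.handgrip_kg is not None and self.handgrip_kg < 0:
            raise InvalidParameterError("handgrip must be >= 0")
        trio = (self.mit_pct, self.fatit_pct, self.nmnfit_pct)
        if all(v is not None for v in trio) and abs(sum(trio) - 100.0) > 0.1:
            raise InvalidParameterError(
                f"echogenicity percentages must sum to 100, got {sum(trio):.3f}")
        if (self.bmi is not None and self.current_weight_kg is not None
                and self.height_m is not None):
            implied = self.current_weight_kg / self.height_m ** 2
            if abs(implied - self.bmi) > 0.1:
                raise InvalidParameterError(
                    f"bmi {self.bmi} inconsistent with weight/height^2 {implied:.2f}")


@dataclass(frozen=True)
class ScoreCutoffs:
    """Per-sex cut-offs for the five score indicators.

    Each field maps sex -> cut-off; 'low' fields give a point when the
    value is strictly below, 'high' when strictly above.
    """

    rfma_low: dict
    rfmt_low: dict
    mit_low: dict
    fatit_high: dict
    pennation_low: dict
    provenance: str = "unspecified"

    def __post_init__(self):
        for name in _CUTOFF_VARS:
            d = getattr(self, name)
            for sex in (MALE, FEMALE):
                if sex not in d or not d[sex] > 0:
                    raise InvalidParameterError(
                        f"cut-off {name}[{sex}] must be present and positive")


@dataclass(frozen=True)
class EwgsopResult:
    low_strength: bool
    low_mass: bool
    category: str = field(init=False)

    def __post_init__(self):
        if self.low_strength and self.low_mass:
            cat = "sarcopenia"
        elif self.low_strength:
            cat = "probable_sarcopenia"
        elif self.low_mass:
            cat = "low_mass_only"
        else:
            cat = "none"
        object.__setattr__(self, "category", cat)

    @property
    def dynapenia(self) -> bool:
        return self.low_strength


def published_cutoffs() -> ScoreCutoffs:
    """The published sample-median cut-offs shipped with the package."""
    text = importlib.resources.files("sonomyo").joinpath(
        "data/published_cutoffs.yaml").read_text()
    raw = yaml.safe_load(text)
    return ScoreCutoffs(provenance="published", **raw)


def load_cutoffs(path) -> ScoreCutoffs:
    raw = yaml.safe_load(open(path))
    raw.setdefault("provenance", str(path))
    return ScoreCutoffs(**raw)


def save_cutoffs(path, cutoffs: ScoreCutoffs) -> None:
    payload = {name: dict(getattr(cutoffs, name)) for name in _CUTOFF_VARS}
    payload["provenance"] = cutoffs.provenance
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def compute_cutoffs(cohort: pd.DataFrame) -> ScoreCutoffs:
    """Per-sex medians of the five indicators over a cohort table.

    Even-n medians are the mean of the two central order statistics
    (numpy convention).  Requires >= 2 non-missing values per sex and
    variable; the error names the first offender.
    """
    out = {name: {} for name in _CUTOFF_VARS}
    for name, col in _CUTOFF_VARS.items():
        if col not in cohort.columns:
            raise MissingDataError(f"cohort lacks column {col!r}")
        for sex in (MALE, FEMALE):
            vals = cohort.loc[cohort["sex"] == sex, col].dropna().to_numpy(float)
            if vals.size < 2:
                raise MissingDataError(
                    f"need >= 2 non-missing {col!r} values for sex {sex!r}, "
                    f"found {vals.size}")
            out[name][sex] = float(np.median(vals))
    return ScoreCutoffs(provenance="computed", **out)


# ---------------------------------------------------------------------------
# Point-counting kernels (vectorised; shared by records, cohorts and the
# score-distribution simulations)
# ---------------------------------------------------------------------------

def _mass_points(rfma, rfmt, rfma_cut, rfmt_cut):
    return ((np.asarray(rfma) < rfma_cut).astype(np.int64)
            + (np.asarray(rfmt) < rfmt_cut).astype(np.int64))


def _quality_points(mit, fatit, pennation, mit_cut, fatit_cut, pennation_cut):
    return ((np.asarray(mit) < mit_cut).astype(np.int64)
            + (np.asarray(fatit) > fatit_cut).astype(np.int64)
            + (np.asarray(pennation) < pennation_cut).astype(np.int64))


def _low_strength(handgrip, is_male):
    cut = np.where(np.asarray(is_male, dtype=bool),
                   HANDGRIP_CUTOFF_KG[MALE], HANDGRIP_CUTOFF_KG[FEMALE])
    return np.asarray(handgrip) < cut


def _low_mass(asmi, is_male):
    cut = np.where(np.asarray(is_male, dtype=bool),
                   ASMI_CUTOFF_KG_M2[MALE], ASMI_CUTOFF_KG_M2[FEMALE])
    return np.asarray(asmi) < cut


def _require(record: SubjectRecord, fields: tuple):
    missing = [f for f in fields if getattr(record, f) is None]
    if missing:
        raise MissingDataError(
            f"record {record.id!r} missing required fields: {', '.join(missing)}")


def muscle_mass_score(record: SubjectRecord, cutoffs: ScoreCutoffs) -> int:
    """0-2 points: one per muscle-mass indicator strictly below cut-off."""
    _require(record, ("rfma_cm2", "rfmt_cm"))
    return int(_mass_points(record.rfma_cm2, record.rfmt_cm,
                            cutoffs.rfma_low[record.sex],
                            cutoffs.rfmt_low[record.sex]))


def muscle_quality_score(record: SubjectRecord, cutoffs: ScoreCutoffs) -> int:
    """0-3 points: low MiT, high FATiT, low pennation angle."""
    _require(record, ("mit_pct", "fatit_pct", "pennation_deg"))
    return int(_quality_points(record.mit_pct, record.fatit_pct,
                               record.pennation_deg,
                               cutoffs.mit_low[record.sex],
                               cutoffs.fatit_high[record.sex],
                               cutoffs.pennation_low[record.sex]))


def ewgsop2_classify(record: SubjectRecord) -> EwgsopResult:
    """EWGSOP2 classification from handgrip strength and BIA-derived ASMI."""
    _require(record, ("handgrip_kg", "asmi"))
    male = record.sex == MALE
    return EwgsopResult(low_strength=bool(_low_strength(record.handgrip_kg, male)),
                        low_mass=bool(_low_mass(record.asmi, male)))


def derived_anthropometry(current_weight_kg: float, usual_weight_kg: float,
                          height_m: float):
    """(BMI, % weight loss) from weights and height.

    BMI = current / height^2; weight loss = (usual - current)/usual x 100
    (negative for weight gain).
    """
    if min(current_weight_kg, usual_weight_kg, height_m) <= 0:
        raise InvalidParameterError("weights and height must be positive")
    bmi = current_weight_kg / height_m ** 2
    loss = (usual_weight_kg - current_weight_kg) / usual_weight_kg * 100.0
    return bmi, loss


def score_cohort(cohort: pd.DataFrame, cutoffs: ScoreCutoffs) -> pd.DataFrame:
    """Add mass_score, quality_score and EWGSOP2 columns to a cohort table."""
    needed = ["sex", "rfma_cm2", "rfmt_cm", "mit_pct", "fatit_pct",
              "pennation_deg", "handgrip_kg", "asmi"]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise MissingDataError(f"cohort lacks columns: {', '.join(missing)}")
    df = cohort.copy()
    male = (df["sex"] == MALE).to_numpy()

    def per_sex(cut):
        return np.where(male, cut[MALE], cut[FEMALE])

    df["mass_score"] = _mass_points(df["rfma_cm2"], df["rfmt_cm"],
                                    per_sex(cutoffs.rfma_low),
                                    per_sex(cutoffs.rfmt_low))
    df["quality_score"] = _quality_points(df["mit_pct"], df["fatit_pct"],
                                          df["pennation_deg"],
                                          per_sex(cutoffs.mit_low),
                                          per_sex(cutoffs.fatit_high),
                                          per_sex(cutoffs.pennation_low))
    low_str = _low_strength(df["handgrip_kg"], male)
    low_mass = _low_mass(df["asmi"], male)
    df["dynapenia"] = low_str
    df["low_muscle_mass"] = low_mass
    df["sarcopenia"] = low_str & low_mass
    df["ewgsop2_category"] = np.select(
        [low_str & low_mass, low_str, low_mass],
        ["sarcopenia", "probable_sarcopenia", "low_mass_only"], default="none")
    return df


# ---------------------------------------------------------------------------
# Score-distribution simulations (latent-Gaussian median dichotomisation)
# ---------------------------------------------------------------------------
# Under a latent-Gaussian model, thresholding each indicator at its
# population median turns the score distribution into orthant
# probabilities of a correlated standard normal:
#   P(2 of 2 points)  = 1/4 + asin(rho)/(2*pi)
#   P(3 of 3 points)  = 1/8 + 3*asin(rho)/(4*pi)   (exchangeable triplet)
# These simulators draw the latents and count points with the same
# kernels the clinical scores use (cut-offs at the median, here 0, with
# the "worse" direction oriented per indicator).

def simulate_mass_score_distribution(n: int, rho: float = 0.93,
                                     seed: int | np.random.Generator = 0):
    """Percentages of subjects scoring 0/1/2 mass points at latent corr rho."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    pts = _mass_points(rfma=z[:, 0], rfmt=z[:, 1], rfma_cut=0.0, rfmt_cut=0.0)
    return 100.0 * np.bincount(pts, minlength=3) / n


def simulate_quality_score_distribution(n: int, rho: float = 0.39,
                                        seed: int | np.random.Generator = 0):
    """Percentages scoring 0..3 quality points at exchangeable corr rho.

    The three latents are equicorrelated "badness" directions; the FATiT
    latent enters the kernel negated so that its point counts values
    above the median, matching the clinical rule.
    """
    rng = np.random.default_rng(seed)
    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    pts = _quality_points(mit=z[:, 0], fatit=-z[:, 1], pennation=z[:, 2],
                          mit_cut=0.0, fatit_cut=0.0, pennation_cut=0.0)
    return 100.0 * np.bincount(pts, minlength=4) / n


def simulate_dynapenia_prevalence(n_cohorts: int = 100,
                                  n_male: int = 295, n_female: int = 352,
                                  male_hg=(26.70, 9.13), female_hg=(17.71, 7.34),
                                  seed: int | np.random.Generator = 0) -> float:
    """Mean % with EWGSOP2 low handgrip strength over simulated cohorts.

    Handgrip is drawn from sex-specific Gaussians (defaults are the
    cohort moments) and classified with the consensus 27/16 kg cut-offs.
    """
    rng = np.random.default_rng(seed)
    prevalences = np.empty(n_cohorts)
    for i in range(n_cohorts):
        hg_m = rng.normal(male_hg[0], male_hg[1], size=n_male)
        hg_f = rng.normal(female_hg[0], female_hg[1], size=n_female)
        low = np.concatenate([_low_strength(hg_m, np.ones(n_male, bool)),
                              _low_strength(hg_f, np.zeros(n_female, bool))])
        prevalences[i] = low.mean()
    return float(100.0 * prevalences.mean())
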