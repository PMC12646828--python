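"""Synthetic morphofunctional cohorts with the statistical structure the
analysis assumes.

Each sex is sampled from a truncated multivariate Gaussian over the
morphofunctional variables, calibrated by default to the printed cohort
moments (n = 647, 295 men / 352 women).  Structural couplings are kept
internally consistent rather than sampled:

* phase angle = arctan(reactance / resistance), in degrees;
* NMNFiT = 100 - MiT - FATiT (echogenicity closure; rows whose residual
  would be negative are clamped to 0 with MiT/FATiT rescaled to 100);
* RFMAI = RFMA / height^2; current weight = BMI x height^2; usual weight
  back-computed from the percent weight loss.

Default correlations (all others zero unless configured):

* corr(RFMT, RFMA) = 0.93 — inverted from the published muscle-mass
  score distribution via the bivariate-normal orthant formula
  P(both below median) = 1/4 + asin(rho)/(2*pi) with P = 0.44;
* the three quality-score indicators share an exchangeable latent
  correlation of 0.39 in their "worse" directions — inverted from
  P(all three worse) = 1/8 + 3*asin(rho)/(4*pi) with P = 0.22 — which
  maps to corr(MiT, FATiT) = -0.39, corr(MiT, pennation) = +0.39,
  corr(FATiT, pennation) = -0.39.

An optional logistic outcome model plants a binary label on the
generated table for parameter-recovery studies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidSpecError
from .score import FEMALE, MALE

# Per-sex (mean, SD) of the sampled variables; cohort defaults.
TABLE_MOMENTS = {
    MALE: {
        "age": (66.44, 14.47),
        "bmi": (23.69, 4.41),
        "arm_circ_cm": (25.63, 3.18),
        "calf_circ_cm": (32.71, 4.09),
        "resistance_ohm": (539.01, 94.69),
        "reactance_ohm": (48.54, 11.21),
        "asmi": (6.82, 1.42),
        "sft_cm": (0.53, 0.27),
        "rfmt_cm": (1.08, 0.31),
        "rfma_cm2": (3.56, 1.21),
        "mit_pct": (47.98, 11.66),
        "fatit_pct": (38.78, 7.81),
        "pennation_deg": (5.79, 2.89),
        "handgrip_kg": (26.70, 9.13),
        # not printed in the reference moments; realistic assumptions
        "height_m": (1.70, 0.07),
        "pct_weight_loss": (8.0, 5.0),
    },
    FEMALE: {
        "age": (63.48, 16.72),
        "bmi": (21.70, 5.17),
        "arm_circ_cm": (23.75, 3.89),
        "calf_circ_cm": (31.24, 3.91),
        "resistance_ohm": (633.53, 109.05),
        "reactance_ohm": (52.92, 12.70),
        "asmi": (5.51, 0.86),
        "sft_cm": (0.98, 0.47),
        "rfmt_cm": (0.90, 0.26),
        "rfma_cm2": (2.72, 0.94),
        "mit_pct": (45.35, 9.85),
        "fatit_pct": (39.71, 6.49),
        "pennation_deg": (4.90, 2.69),
        "handgrip_kg": (17.71, 7.34),
        "height_m": (1.58, 0.06),
        "pct_weight_loss": (8.0, 5.0),
    },
}

_VARIABLES = list(TABLE_MOMENTS[MALE].keys())

# Orthant-derived defaults (see module docstring).
RFMT_RFMA_CORRELATION = 0.93
QUALITY_LATENT_CORRELATION = 0.39

DEFAULT_CORRELATIONS = {
    ("rfmt_cm", "rfma_cm2"): RFMT_RFMA_CORRELATION,
    ("mit_pct", "fatit_pct"): -QUALITY_LATENT_CORRELATION,
    ("mit_pct", "pennation_deg"): QUALITY_LATENT_CORRELATION,
    ("fatit_pct", "pennation_deg"): -QUALITY_LATENT_CORRELATION,
}

# Variables that cannot be negative; offending draws are resampled.
_TRUNCATED_AT_ZERO = [v for v in _VARIABLES if v not in ("pct_weight_loss",)]


@dataclass(frozen=True)
class LogisticOutcomeModel:
    """Planted Bernoulli(logistic(intercept + sum beta*x)) outcome."""

    coefficients: dict
    intercept: float = 0.0
    label: str = "outcome"


@dataclass(frozen=True)
class CohortSpec:
    n_total: int = 647
    male_fraction: float = 295 / 647
    moments: dict = field(default_factory=lambda: TABLE_MOMENTS)
    correlations: dict = field(default_factory=lambda: DEFAULT_CORRELATIONS)
    outcome_model: LogisticOutcomeModel | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 1:
            raise InvalidSpecError("n_total must be positive")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise InvalidSpecError("male_fraction must lie in [0, 1]")
        for sex in (MALE, FEMALE):
            for var, (mu, sd) in self.moments[sex].items():
                if sd <= 0:
                    raise InvalidSpecError(f"SD of {var} ({sex}) must be > 0")

    def correlation_matrix(self) -> np.ndarray:
        n = len(_VARIABLES)
        corr = np.eye(n)
        idx = {v: i for i, v in enumerate(_VARIABLES)}
        for (a, b), rho in self.correlations.items():
            if a not in idx or b not in idx:
                raise InvalidSpecError(f"unknown variable in correlation ({a}, {b})")
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise InvalidSpecError(
                f"correlation matrix not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})")
        return corr

    def content_hash(self) -> str:
        payload = {
            "n_total": self.n_total,
            "male_fraction": self.male_fraction,
            "moments": {s: {k: list(v) for k, v in self.moments[s].items()}
                        for s in (MALE, FEMALE)},
            "correlations": {f"{a}|{b}": rho
                             for (a, b), rho in sorted(self.correlations.items())},
            "outcome_model": (None if self.outcome_model is None else {
                "coefficients": self.outcome_model.coefficients,
                "intercept": self.outcome_model.intercept,
                "label": self.outcome_model.label,
            }),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_cohort_spec(path) -> CohortSpec:
    """Read a CohortSpec from YAML; absent keys keep their defaults."""
    raw = yaml.safe_load(open(path)) or {}
    kwargs = {}
    for key in ("n_total", "male_fraction", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "moments" in raw:
        moments = {s: dict(TABLE_MOMENTS[s]) for s in (MALE, FEMALE)}
        for sex, vars_ in raw["moments"].items():
            for var, pair in vars_.items():
                if var not in moments[sex]:
                    raise InvalidSpecError(f"unknown moment variable {var!r}")
                moments[sex][var] = tuple(float(x) for x in pair)
        kwargs["moments"] = moments
    if "correlations" in raw:
        corr = {}
        for key, rho in raw["correlations"].items():
            a, _, b = key.partition("|")
            corr[(a, b)] = float(rho)
        kwargs["correlations"] = corr
    if "outcome_model" in raw:
        om = raw["outcome_model"]
        kwargs["outcome_model"] = LogisticOutcomeModel(
            coefficients=dict(om["coefficients"]),
            intercept=float(om.get("intercept", 0.0)),
            label=om.get("label", "outcome"))
    return CohortSpec(**kwargs)


def _sample_sex(sex: str, n: int, spec: CohortSpec, corr: np.ndarray,
                rng: np.random.Generator) -> pd.DataFrame:
    chol_corr = _psd_factor(corr)
    mu = np.array([spec.moments[sex][v][0] for v in _VARIABLES])
    sd = np.array([spec.moments[sex][v][1] for v in _VARIABLES])
    trunc_idx = [_VARIABLES.index(v) for v in _TRUNCATED_AT_ZERO]

    z = rng.standard_normal((n, len(_VARIABLES))) @ chol_corr.T
    x = mu + sd * z
    # Resample rows violating the physiological >= 0 truncation.
    for _ in range(200):
        bad = (x[:, trunc_idx] < 0).any(axis=1)
        if not bad.any():
            break
        z = rng.standard_normal((int(bad.sum()), len(_VARIABLES))) @ chol_corr.T
        x[bad] = mu + sd * z
    else:
        raise InvalidSpecError("truncation rejection did not converge; "
                               "moments place too much mass below zero")

    df = pd.DataFrame(x, columns=_VARIABLES)
    df.insert(0, "sex", sex)
    return df


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Matrix F with F F^T = corr, valid for singular PSD matrices."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table from ``spec``; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    corr = spec.correlation_matrix()
    n_male = int(round(spec.n_total * spec.male_fraction))
    n_female = spec.n_total - n_male
    parts = []
    if n_male:
        parts.append(_sample_sex(MALE, n_male, spec, corr, rng))
    if n_female:
        parts.append(_sample_sex(FEMALE, n_female, spec, corr, rng))
    df = pd.concat(parts, ignore_index=True)

    # Echogenicity closure: NMNFiT is the residual of the triplet.
    resid = 100.0 - df["mit_pct"] - df["fatit_pct"]
    neg = resid < 0
    if neg.any():
        scale = 100.0 / (df.loc[neg, "mit_pct"] + df.loc[neg, "fatit_pct"])
        df.loc[neg, "mit_pct"] *= scale
        df.loc[neg, "fatit_pct"] *= scale
        resid[neg] = 0.0
    df["nmnfit_pct"] = resid

    # Structurally derived quantities.
    df["phase_angle_deg"] = np.degrees(
        np.arctan(df["reactance_ohm"] / df["resistance_ohm"]))
    df["rfmai_cm2_m2"] = df["rfma_cm2"] / df["height_m"] ** 2
    df["current_weight_kg"] = df["bmi"] * df["height_m"] ** 2
    df["usual_weight_kg"] = df["current_weight_kg"] * 100.0 / (
        100.0 - df["pct_weight_loss"])
    df.insert(0, "id", [f"S{i:05d}" for i in range(len(df))])

    if spec.outcome_model is not None:
        df = plant_outcome(df, spec.outcome_model.coefficients,
                           spec.outcome_model.intercept, rng=rng,
                           label=spec.outcome_model.label)

    df.attrs["spec_hash"] = spec.content_hash()
    df.attrs["seed"] = spec.seed if seed is None else seed
    return df


def plant_outcome(cohort: pd.DataFrame, coefficients: dict,
                  intercept: float = 0.0, seed: int | None = None,
                  rng: np.random.Generator | None = None,
                  label: str = "outcome") -> pd.DataFrame:
    """Plant a Bernoulli(logistic) binary label on a cohort table.

    ``coefficients`` maps column names to log-odds slopes; the special
    name ``male`` refers to the 0/1 male indicator.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    eta = np.full(len(cohort), float(intercept))
    for var, beta in coefficients.items():
        if var == "male":
            x = (cohort["sex"] == MALE).to_numpy(float)
        elif var in cohort.columns:
            x = cohort[var].to_numpy(float)
        else:
            raise InvalidSpecError(f"unknown outcome-model variable {var!r}")
        eta += float(beta) * x
    p = 1.0 / (1.0 + np.exp(-eta))
    out = cohort.copy()
    out[label] = rng.random(len(cohort)) < p
    out.attrs.update(cohort.attrs)
    return out


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
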