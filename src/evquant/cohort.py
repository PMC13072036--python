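"""Synthetic clinical cohorts for the CD98+ EV Index diagnostic workflow.

Each subject carries the raw ingredients of the index — an ExoCounter-style
CD98+ well count, PBS negative-control well counts from the same disc, and
a total EV concentration from particle tracking — plus demographic and
clinical covariates. The per-group index distribution is log-normal, fitted
to a published median/IQR summary; well counts are Poisson around the
latent truth, so control normalization and concentration normalization can
be exercised end to end with known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

#: standard normal quantile at 0.75: half the IQR of a standard normal
_Z_QUARTILE = float(norm.ppf(0.75))

COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "smoking", "alcohol", "cirrhosis",
    "afp", "tumor_size", "stage", "disc_id", "sample_well_count",
    "control_well_counts", "total_ev_concentration", "true_index",
]


class ParameterizationError(ValueError):
    """No log-normal matches the requested median/IQR."""


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """Fit (mu, sigma) of a log-normal to a target median and interquartile range.

    The median pins ``mu = ln(median)``; sigma solves
    ``median * (exp(z*sigma) - exp(-z*sigma)) = iqr`` with z the 0.75
    standard-normal quantile, by bracketed root finding (|f| < 1e-10).
    """
    if median <= 0 or iqr <= 0:
        raise ParameterizationError("median and iqr must both be positive")
    mu = float(np.log(median))

    def f(sigma: float) -> float:
        return median * (np.exp(_Z_QUARTILE * sigma) - np.exp(-_Z_QUARTILE * sigma)) - iqr

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ParameterizationError("no positive sigma reproduces the target IQR")
    sigma = float(brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16))
    if abs(f(sigma)) > 1e-10:
        raise ParameterizationError("sigma root finding did not converge")
    return mu, sigma


@dataclass(frozen=True)
class GroupSpec:
    """Distributional summary of one subject group."""

    n: int
    index_median: float
    index_iqr: float
    age_median: float
    age_iqr: float
    male_frac: float
    smoking_frac: float
    alcohol_frac: float
    cirrhosis_frac: float = 0.0
    # disease-only annotations (None for healthy controls)
    afp_median: float | None = None
    afp_log_sigma: float | None = None
    tumor_size_median: float | None = None
    tumor_size_log_sigma: float | None = None
    stage1_frac: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for p in (self.male_frac, self.smoking_frac, self.alcohol_frac, self.cirrhosis_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("covariate frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Full generator configuration for a two-group diagnostic cohort.

    ``concentration_scale`` is the constant used by the index definition
    (index = control-subtracted count / (concentration / scale)); the
    latent well count is the inverse of that map plus the control mean.
    ``noise=False`` replaces every Poisson draw by its mean and is used for
    exact round-trip identities.
    """

    healthy: GroupSpec = field(
        default_factory=lambda: GroupSpec(
            n=50,
            index_median=3.548,
            index_iqr=3.821,
            age_median=38.5,
            age_iqr=11.25,
            male_frac=0.560,
            smoking_frac=0.340,
            alcohol_frac=0.200,
            cirrhosis_frac=0.02,
        )
    )
    hcc: GroupSpec = field(
        default_factory=lambda: GroupSpec(
            n=136,
            index_median=9.761,
            index_iqr=16.405,
            age_median=66.0,
            age_iqr=4.75,
            male_frac=0.801,
            smoking_frac=0.478,
            alcohol_frac=0.441,
            cirrhosis_frac=0.30,
            afp_median=20.0,
            afp_log_sigma=2.5,
            tumor_size_median=4.0,
            tumor_size_log_sigma=0.5,
            stage1_frac=0.5,
        )
    )
    control_well_mean: float = 25.0
    n_control_wells: int = 2
    wells_per_disc: int = 16
    concentration_median: float = 2e10  # particles/mL, post-SEC plasma range
    concentration_log_sigma: float = 0.4
    concentration_scale: float = 1e9
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_well_mean < 0 or self.n_control_wells < 1:
            raise ValueError("need control_well_mean >= 0 and >= 1 control well")
        if self.concentration_median <= 0 or self.concentration_scale <= 0:
            raise ValueError("concentrations must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["healthy"] = GroupSpec(**d["healthy"])
        d["hcc"] = GroupSpec(**d["hcc"])
        return cls(**d)


def _simulate_group(
    spec: CohortSpec,
    group: GroupSpec,
    label: str,
    start_id: int,
    start_disc: int,
    rng: np.random.Generator,
) -> list[dict]:
    mu, sigma = lognormal_from_median_iqr(group.index_median, group.index_iqr)
    if spec.noise:
        true_index = rng.lognormal(mu, sigma, size=group.n)
    else:
        true_index = np.full(group.n, group.index_median)

    conc = (
        rng.lognormal(np.log(spec.concentration_median), spec.concentration_log_sigma, group.n)
        if spec.noise
        else np.full(group.n, spec.concentration_median)
    )
    gain = conc / spec.concentration_scale
    latent = true_index * gain + spec.control_well_mean
    if spec.noise:
        sample_counts = rng.poisson(latent)
        controls = rng.poisson(spec.control_well_mean, size=(group.n, spec.n_control_wells))
    else:
        sample_counts = latent
        controls = np.full((group.n, spec.n_control_wells), spec.control_well_mean)

    age_sigma = group.age_iqr / (2.0 * _Z_QUARTILE)
    ages = (
        rng.normal(group.age_median, age_sigma, group.n)
        if spec.noise
        else np.full(group.n, group.age_median)
    )
    male = rng.random(group.n) < group.male_frac
    smoking = rng.random(group.n) < group.smoking_frac
    alcohol = rng.random(group.n) < group.alcohol_frac
    cirrhosis = rng.random(group.n) < group.cirrhosis_frac

    samples_per_disc = spec.wells_per_disc - spec.n_control_wells
    rows = []
    for i in range(group.n):
        row = {
            "subject_id": f"S{start_id + i:04d}",
            "group": label,
            "age": float(np.clip(ages[i], 18.0, 100.0)),
            "sex": "M" if male[i] else "F",
            "smoking": bool(smoking[i]),
            "alcohol": bool(alcohol[i]),
            "cirrhosis": bool(cirrhosis[i]),
            "afp": np.nan,
            "tumor_size": np.nan,
            "stage": "",
            "disc_id": f"D{start_disc + i // samples_per_disc:03d}",
            "sample_well_count": int(round(sample_counts[i])) if spec.noise else float(sample_counts[i]),
            "control_well_counts": "|".join(str(c) for c in controls[i]),
            "total_ev_concentration": float(conc[i]),
            "true_index": float(true_index[i]),
        }
        if label == "hcc":
            row["afp"] = float(
                rng.lognormal(np.log(group.afp_median), group.afp_log_sigma)
            )
            row["tumor_size"] = float(
                rng.lognormal(np.log(group.tumor_size_median), group.tumor_size_log_sigma)
            )
            row["stage"] = "I" if rng.random() < group.stage1_frac else "II"
        rows.append(row)
    return rows


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a two-group cohort as a tidy DataFrame (one row per subject)."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rows = _simulate_group(spec, spec.healthy, "healthy", 0, 0, rng)
    n_discs_healthy = -(-spec.healthy.n // (spec.wells_per_disc - spec.n_control_wells))
    rows += _simulate_group(spec, spec.hcc, "hcc", spec.healthy.n, n_discs_healthy, rng)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def parse_control_counts(value: str) -> np.ndarray:
    """Decode the pipe-separated control-well column of the cohort CSV."""
    return np.array([float(v) for v in str(value).split("|")])


def validate_cohort(df: pd.DataFrame) -> None:
    """Schema check for subject tables entering the diagnostics stage."""
    required = {
        "subject_id", "group", "sample_well_count",
        "control_well_counts", "total_ev_concentration",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    groups = set(df["group"].unique())
    if not groups <= {"healthy", "hcc"}:
        raise ValueError(f"unknown group labels: {sorted(groups - {'healthy', 'hcc'})}")
    if (df["sample_well_count"] < 0).any():
        raise ValueError("well counts must be non-negative")
    if (df["total_ev_concentration"] <= 0).any():
        raise ValueError("total EV concentration must be positive")
    df["control_well_counts"].map(parse_control_counts)


def write_cohort(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_cohort(df)
    return df
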