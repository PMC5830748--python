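"""Synthetic mesocosm experiments.

Generates individual-level specimen records with the statistical structure
the analysis pipeline assumes: treatment-specific bivariate-normal
delta13C-delta15N clouds whose covariance is inflated by a factor kappa
under stress, mesocosm random intercepts nested under treatment, survival
applied as binomial thinning per mesocosm, physiological endpoints (body
mass, C:N, RNA:DNA, parasite presence, Poisson fecundity with
beta-binomial embryo viability) and additive covariate links shifting the
isotope anomalies.

Two default parameterisations are provided:

* experiment 1 — a contaminated- vs reference-sediment exposure
  (7 mesocosms x 25 individuals per treatment, reproductive endpoints,
  ~25% parasite prevalence);
* experiment 2 — four feeding regimes (reference sediment, lignin,
  diatoms, Tetraphyll; 5 mesocosms x 24 individuals), where the
  low-quality treatments (reference, lignin) are the stressed ones.

Both include an additional "initial" group sampled at the start of the
incubation.  Isotope means/sds and physiology summaries follow the
corresponding experimental treatment summaries; delta13C parameters are on
the lipid-corrected scale and the generator back-computes the raw values
so that the pre-processing stage reproduces the intended cloud exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from isoniche.prep import LIPID_CN_THRESHOLD, LIPID_INTERCEPT, LIPID_SLOPE

__all__ = [
    "TreatmentSpec",
    "ExperimentSpec",
    "default_spec",
    "null_spec",
    "variance_inflation_spec",
    "generate_experiment",
]


@dataclass
class TreatmentSpec:
    """Generating parameters for one treatment group."""

    label: str
    stressed: bool = False
    is_initial: bool = False
    mean_d13c: float = -19.0  # permil, lipid-corrected scale
    mean_d15n: float = 10.0  # permil
    cov: tuple[tuple[float, float], tuple[float, float]] = ((0.16, 0.0), (0.0, 0.09))
    kappa: float = 1.0  # covariance inflation applied when stressed
    body_mass_mean: float | None = None  # mg dry weight
    body_mass_sd: float | None = None
    cn_mean: float = 4.5
    cn_sd: float = 0.3
    rna_dna_mean: float | None = None
    rna_dna_sd: float | None = None
    parasite_prevalence: float | None = None
    fecundity_mean: float | None = None  # Poisson mean embryos per female
    viability_mean: float | None = None  # mean proportion viable embryos
    viability_sd: float | None = None  # sd of the proportion (overdispersion)
    survival_mean: float | None = None  # % recovered per mesocosm
    survival_sd: float | None = None

    def effective_cov(self) -> np.ndarray:
        c = np.asarray(self.cov, dtype=float)
        if self.stressed:
            c = c * self.kappa
        return c

    def validate(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ValueError(f"{self.label}: covariance must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(c) <= 0):
            raise ValueError(f"{self.label}: covariance must be positive definite")
        if not (self.kappa > 0):
            raise ValueError(f"{self.label}: kappa must be > 0")
        for name in ("parasite_prevalence", "viability_mean"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.label}: {name} outside [0, 1]")


@dataclass
class ExperimentSpec:
    """Design and link structure for one simulated experiment."""

    experiment: int
    treatments: list[TreatmentSpec]
    n_mesocosms: int = 7
    n_per_mesocosm: int = 25
    n_mesocosms_initial: int = 3
    n_per_mesocosm_initial: int = 5
    #: share of each treatment's total isotope variance placed on the
    #: mesocosm intercept (per axis); the treatment sds stay *total* sds
    mesocosm_var_frac: float = 0.20
    #: absolute per-axis mesocosm-intercept sd override (d13c, d15n)
    mesocosm_sd: tuple[float, float] | None = None
    #: additive covariate->isotope links on the anomaly scale, applied to
    #: within-treatment-centred covariates so treatment means are untouched
    links: dict[str, float] = field(default_factory=dict)
    oxygen_mean: float | None = None  # mm, mesocosm oxygen penetration depth
    oxygen_sd: float | None = None

    def validate(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.n_mesocosms < 2:
            raise ValueError("n_mesocosms must be >= 2")
        if self.n_per_mesocosm < 1:
            raise ValueError("n_per_mesocosm must be >= 1")
        if not (0.0 <= self.mesocosm_var_frac < 1.0):
            raise ValueError("mesocosm_var_frac must be in [0, 1)")
        for t in self.treatments:
            t.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentSpec":
        data = dict(data)
        data["treatments"] = [TreatmentSpec(**t) for t in data["treatments"]]
        return cls(**data)


def _diag_cov(sd_d13c: float, sd_d15n: float) -> tuple:
    return ((sd_d13c**2, 0.0), (0.0, sd_d15n**2))


def default_spec(experiment: int) -> ExperimentSpec:
    """Default generating conditions for experiment 1 or 2."""
    if experiment == 1:
        treatments = [
            TreatmentSpec(
                label="initial",
                is_initial=True,
                mean_d13c=-19.26,
                mean_d15n=10.11,
                cov=_diag_cov(0.31, 0.32),
                body_mass_mean=2.49,
                body_mass_sd=0.74,
                cn_mean=4.57,
                cn_sd=0.54,
            ),
            TreatmentSpec(
                label="reference",
                mean_d13c=-18.89,
                mean_d15n=9.97,
                cov=_diag_cov(0.38, 0.28),
                body_mass_mean=2.78,
                body_mass_sd=0.88,
                cn_mean=4.55,
                cn_sd=0.13,
                parasite_prevalence=0.27,
                fecundity_mean=29.0,
                viability_mean=0.920,
                viability_sd=0.16,
                survival_mean=63.0,
                survival_sd=11.0,
            ),
            TreatmentSpec(
                label="exposure",
                stressed=True,
                mean_d13c=-18.92,
                mean_d15n=10.01,
                cov=_diag_cov(0.56, 0.41),
                body_mass_mean=2.51,
                body_mass_sd=0.77,
                cn_mean=4.58,
                cn_sd=0.25,
                parasite_prevalence=0.25,
                fecundity_mean=23.0,
                viability_mean=0.715,
                viability_sd=0.36,
                survival_mean=74.0,
                survival_sd=13.0,
            ),
        ]
        return ExperimentSpec(
            experiment=1,
            treatments=treatments,
            n_mesocosms=7,
            n_per_mesocosm=25,
            links={
                "body_mass->d15n": 0.10,
                "parasite->d15n": 0.177,
                "viability->d15n": -0.206,
                "body_mass->d13c": -0.10,
            },
        )
    if experiment == 2:
        treatments = [
            TreatmentSpec(
                label="initial",
                is_initial=True,
                mean_d13c=-20.55,
                mean_d15n=8.32,
                cov=_diag_cov(1.45, 1.16),
                body_mass_mean=1.05,
                body_mass_sd=0.35,
                cn_mean=5.93,
                cn_sd=0.74,
                rna_dna_mean=1.54,
                rna_dna_sd=0.64,
            ),
            TreatmentSpec(
                label="reference",
                stressed=True,  # no food supplement: the low-nutrition regime
                mean_d13c=-20.36,
                mean_d15n=9.48,
                cov=_diag_cov(1.50, 1.48),
                body_mass_mean=1.19,
                body_mass_sd=0.43,
                cn_mean=5.63,
                cn_sd=0.91,
                rna_dna_mean=1.45,
                rna_dna_sd=0.08,
                survival_mean=47.0,
                survival_sd=12.0,
            ),
            TreatmentSpec(
                label="lignin",
                stressed=True,
                mean_d13c=-20.62,
                mean_d15n=10.95,
                cov=_diag_cov(1.81, 2.00),
                body_mass_mean=1.18,
                body_mass_sd=0.57,
                cn_mean=5.45,
                cn_sd=1.29,
                rna_dna_mean=1.44,
                rna_dna_sd=0.16,
                survival_mean=41.0,
                survival_sd=12.0,
            ),
            TreatmentSpec(
                label="diatoms",
                mean_d13c=-19.37,
                mean_d15n=10.24,
                cov=_diag_cov(1.02, 0.88),
                body_mass_mean=1.43,
                body_mass_sd=0.38,
                cn_mean=6.67,
                cn_sd=0.42,
                rna_dna_mean=1.85,
                rna_dna_sd=0.15,
                survival_mean=44.0,
                survival_sd=12.0,
            ),
            TreatmentSpec(
                label="tetraphyll",
                mean_d13c=-18.97,
                mean_d15n=9.87,
                cov=_diag_cov(0.76, 0.90),
                body_mass_mean=1.49,
                body_mass_sd=0.62,
                cn_mean=6.16,
                cn_sd=0.50,
                rna_dna_mean=1.84,
                rna_dna_sd=0.21,
                survival_mean=44.0,
                survival_sd=15.0,
            ),
        ]
        return ExperimentSpec(
            experiment=2,
            treatments=treatments,
            n_mesocosms=5,
            n_per_mesocosm=24,
            links={
                "body_mass->d15n": -1.065,
                "mortality->d13c": 0.060,
                "oxygen->d13c": 0.050,
            },
            oxygen_mean=12.3,
            oxygen_sd=2.1,
        )
    raise ValueError("experiment must be 1 or 2")


def null_spec(experiment: int) -> ExperimentSpec:
    """A no-effect variant: every treatment shares the reference
    distribution and all covariate links are zero (labels and design
    structure are kept)."""
    spec = default_spec(experiment)
    ref = next(t for t in spec.treatments if t.label == "reference")
    for t in spec.treatments:
        for f in (
            "mean_d13c", "mean_d15n", "cov", "body_mass_mean", "body_mass_sd",
            "cn_mean", "cn_sd", "rna_dna_mean", "rna_dna_sd",
            "parasite_prevalence", "fecundity_mean", "viability_mean",
            "viability_sd",
        ):
            setattr(t, f, getattr(ref, f))
        t.kappa = 1.0
        t.stressed = t.stressed  # stress labels kept for the classifier
        if not t.is_initial:
            t.survival_mean = ref.survival_mean
            t.survival_sd = ref.survival_sd
    spec.links = {k: 0.0 for k in spec.links}
    return spec


def variance_inflation_spec(kappa: float, experiment: int = 1) -> ExperimentSpec:
    """Pure covariance-inflation variant: stressed treatments get the
    reference covariance times ``kappa`` (total variance, mesocosm share
    included), covariate links are zeroed, means are kept."""
    spec = default_spec(experiment)
    ref = next(t for t in spec.treatments if not t.stressed and not t.is_initial)
    for t in spec.treatments:
        if t.stressed:
            t.cov = ref.cov
            t.kappa = kappa
    spec.links = {k: 0.0 for k in spec.links}
    return spec


# ---------------------------------------------------------------------------
# generation


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, lower: float
) -> np.ndarray:
    v = rng.normal(mean, sd, size=size)
    return np.maximum(v, lower)


def generate_experiment(
    spec: ExperimentSpec,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one full experiment; returns (specimens, mesocosms) frames.

    Per treatment: mesocosm intercepts are drawn per isotope axis with
    variance ``mesocosm_var_frac`` of the treatment's (kappa-inflated)
    total variance, individuals from a bivariate normal carrying the
    remaining variance, physiology from the stated marginals, and survival
    as binomial thinning of the stocked individuals per mesocosm.  A fixed
    seed gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    spec_rows: list[dict] = []
    meso_rows: list[dict] = []
    counter = 0
    for treat in spec.treatments:
        n_meso = spec.n_mesocosms_initial if treat.is_initial else spec.n_mesocosms
        n_per = (
            spec.n_per_mesocosm_initial if treat.is_initial else spec.n_per_mesocosm
        )
        total_cov = treat.effective_cov()
        if spec.mesocosm_sd is not None:
            meso_var = np.asarray(spec.mesocosm_sd, float) ** 2
            if treat.stressed:
                meso_var = meso_var * treat.kappa
        else:
            meso_var = spec.mesocosm_var_frac * np.diag(total_cov)
        ind_cov = total_cov - np.diag(meso_var)
        rows_this_treatment: list[dict] = []
        for m in range(n_meso):
            meso_label = f"{treat.label}_m{m + 1}"
            if treat.survival_mean is not None:
                surv = float(np.clip(
                    rng.normal(treat.survival_mean, treat.survival_sd), 0.0, 100.0
                ))
                n_out = int(rng.binomial(n_per, surv / 100.0))
            else:
                surv = 100.0
                n_out = n_per
            oxygen = None
            if spec.oxygen_mean is not None:
                oxygen = float(
                    max(rng.normal(spec.oxygen_mean, spec.oxygen_sd), 0.1)
                )
            meso_rows.append(
                {
                    "mesocosm": meso_label,
                    "treatment": treat.label,
                    "survival_pct": surv,
                    "oxygen_depth": oxygen,
                }
            )
            if n_out == 0:
                continue
            intercept = rng.normal(0.0, np.sqrt(meso_var), size=2)
            mean = np.array([treat.mean_d13c, treat.mean_d15n]) + intercept
            iso = rng.multivariate_normal(mean, ind_cov, size=n_out)
            cn = _truncated_normal(rng, treat.cn_mean, treat.cn_sd, n_out, 0.5)
            mass = (
                _truncated_normal(
                    rng, treat.body_mass_mean, treat.body_mass_sd, n_out, 0.05
                )
                if treat.body_mass_mean is not None
                else np.full(n_out, np.nan)
            )
            rna = (
                _truncated_normal(
                    rng, treat.rna_dna_mean, treat.rna_dna_sd, n_out, 0.01
                )
                if treat.rna_dna_mean is not None
                else np.full(n_out, np.nan)
            )
            parasite = (
                rng.random(n_out) < treat.parasite_prevalence
                if treat.parasite_prevalence is not None
                else np.full(n_out, np.nan)
            )
            if treat.fecundity_mean is not None:
                fec = rng.poisson(treat.fecundity_mean, size=n_out).astype(float)
                mu, s = treat.viability_mean, treat.viability_sd
                conc = max(mu * (1 - mu) / s**2 - 1.0, 0.5)
                p_viable = rng.beta(mu * conc, (1 - mu) * conc, size=n_out)
                viable = rng.binomial(fec.astype(int), p_viable).astype(float)
            else:
                fec = np.full(n_out, np.nan)
                viable = np.full(n_out, np.nan)
                p_viable = np.full(n_out, np.nan)
            for i in range(n_out):
                counter += 1
                rows_this_treatment.append(
                    {
                        "specimen_id": f"E{spec.experiment}_{counter:04d}",
                        "experiment": spec.experiment,
                        "treatment": treat.label,
                        "mesocosm": meso_label,
                        "_d13c_corr": iso[i, 0],
                        "d15n": iso[i, 1],
                        "cn_ratio": cn[i],
                        "body_mass": mass[i],
                        "rna_dna": rna[i],
                        "fecundity": fec[i],
                        "viable_embryos": viable[i],
                        "parasite": parasite[i],
                        "is_initial": treat.is_initial,
                        "_p_viable": p_viable[i],
                        "_mortality": 100.0 - surv,
                        "_oxygen": oxygen,
                    }
                )
        _apply_links(rows_this_treatment, spec.links)
        spec_rows.extend(rows_this_treatment)

    df = pd.DataFrame(spec_rows)
    # back-compute raw d13c so lipid normalisation reproduces the corrected
    # cloud exactly
    cn = df["cn_ratio"].to_numpy(float)
    corr = df["_d13c_corr"].to_numpy(float)
    raw = np.where(
        cn > LIPID_CN_THRESHOLD, corr - LIPID_INTERCEPT - LIPID_SLOPE * cn, corr
    )
    df["d13c_raw"] = raw
    par = df["parasite"]
    df["parasite"] = [None if pd.isna(v) else bool(v) for v in par]
    df = df.drop(columns=["_d13c_corr", "_p_viable", "_mortality", "_oxygen"])
    from isoniche.io import MESOCOSM_COLUMNS, SPECIMEN_COLUMNS

    df = df.reindex(columns=list(SPECIMEN_COLUMNS))
    meso = pd.DataFrame(meso_rows).reindex(columns=list(MESOCOSM_COLUMNS))
    return df, meso


def _apply_links(rows: list[dict], links: dict[str, float]) -> None:
    """Shift isotope values by covariate links on the anomaly scale.

    Covariates are centred within the treatment before applying the
    coefficient, so the treatment means stay at their specified values and
    only the within-treatment structure (and variance) changes.
    """
    if not rows or not links:
        return
    df = pd.DataFrame(rows)

    def centred(col: str) -> np.ndarray:
        v = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
        if np.all(np.isnan(v)):
            return np.zeros(len(v))
        mean = np.nanmean(v)
        return np.nan_to_num(v - mean)

    source = {
        "body_mass": lambda: centred("body_mass"),
        "parasite": lambda: centred("parasite"),
        "viability": lambda: centred("_p_viable"),
        "mortality": lambda: centred("_mortality"),
        "oxygen": lambda: centred("_oxygen"),
    }
    target_col = {"d13c": "_d13c_corr", "d15n": "d15n"}
    for key, coef in links.items():
        if coef == 0.0:
            continue
        src, dst = key.split("->")
        if src not in source or dst not in target_col:
            raise ValueError(f"unknown link {key!r}")
        shift = coef * source[src]()
        col = target_col[dst]
        for row, s in zip(rows, shift):
            row[col] += float(s)
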