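"""Synthetic multi-site newborn-screening cohorts.

Generates infant-level records with the statistical structure that postnatal
gestational-age (GA) estimation from dried-blood-spot analytes relies on:

* a right-skewed GA distribution (Gaussian term component plus an
  exponential-tail preterm component) whose mean, SD and preterm fraction are
  direct configuration parameters;
* birth weight growing with GA, higher in males, with a growth-restricted
  subpopulation whose weight is decoupled from GA;
* log-normal analyte concentrations whose log-levels drift linearly with GA
  for an "informative" subset and are flat for the rest;
* a fetal/adult hemoglobin triplet (HbF, HbF1, HbA) whose fetal fraction
  declines with maturity on the logit scale;
* screen-positive records with extreme analyte spikes, occasional outliers,
  and blood-spot collection ages that are later for preterm infants;
* site-level batch effects (multiplicative bias, additive log shifts,
  dispersion inflation, panel restriction, collection delays, and
  completed-weeks GA reporting).

Real newborn-screening datasets sit behind data-sharing agreements; these
cohorts stand in for them so the full pipeline is testable end to end.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "AnalyteEffect",
    "BASE_COLUMNS",
    "CHINA_PANEL",
    "CohortParseError",
    "ConfigurationError",
    "HB_COLUMNS",
    "INFORMATIVE_ANALYTES",
    "ONTARIO_PANEL",
    "PHILIPPINES_PANEL",
    "SchemaError",
    "SiteShift",
    "SyntheticConfig",
    "apply_site_shift",
    "default_analyte_effects",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Invalid generative configuration (non-finite values, empty panel...)."""


class SchemaError(ValueError):
    """A cohort table is missing required columns."""


class CohortParseError(ValueError):
    """A cohort file has a malformed cell; message names row and column."""


# Fixed cohort CSV schema, before the per-analyte columns.
BASE_COLUMNS = (
    "id",
    "site",
    "sex",
    "birth_weight_g",
    "ga_weeks",
    "collection_age_hours",
    "screen_positive",
)

HB_COLUMNS = ("HbF1", "HbF", "HbA")

_AMINO_ACIDS = ("ALA", "ARG", "CIT", "GLY", "LEU", "MET", "ORN", "PHE", "TYR", "VAL")

_ACYL_COMMON = (
    "C0", "C2", "C3", "C4", "C5", "C6", "C8", "C10", "C12", "C14", "C16", "C18",
    "C10:1", "C12:1", "C14OH", "C14:1", "C16OH", "C18:1", "C18:2",
    "C3DC", "C4DC", "C4OH", "C5DC", "C5OH", "C6DC", "C8:1",
)

#: Full screening panel of the model-derivation site (hemoglobin fractions,
#: endocrine markers, amino acids, acylcarnitines, enzyme and CF markers).
ONTARIO_PANEL = HB_COLUMNS + ("TSH", "17OHP") + _AMINO_ACIDS + _ACYL_COMMON + (
    "C14:2", "C16:1OH", "C18OH", "C18:1OH", "C5:1", "GALT", "BIO", "IRT",
)

#: External panel that retains hemoglobins but lacks a few acylcarnitines and GALT.
PHILIPPINES_PANEL = HB_COLUMNS + ("TSH", "17OHP") + _AMINO_ACIDS + _ACYL_COMMON + (
    "C16:1OH", "BIO", "IRT",
)

#: External panel with no hemoglobin fractions and no enzyme/CF markers.
CHINA_PANEL = ("TSH", "17OHP") + _AMINO_ACIDS + _ACYL_COMMON + (
    "C14:2", "C18OH", "C5:1",
)

#: Analytes whose log-levels drift with GA by default (besides the hemoglobin
#: ratio, which is informative by construction).
INFORMATIVE_ANALYTES = ("17OHP", "C4DC", "TYR", "ALA", "C5", "C5DC")


@dataclass(frozen=True)
class AnalyteEffect:
    """Log-normal generative parameters for one analyte.

    ``baseline`` is the mean log-concentration at 40 weeks GA; ``slope`` is
    the change in log-concentration per additional week of (latent) GA;
    ``log_sd`` the residual spread on the log scale; ``restricted_shift`` an
    additive log offset applied to growth-restricted infants.
    """

    baseline: float
    slope: float
    log_sd: float
    restricted_shift: float = 0.0


def _null_baseline(name: str) -> float:
    # Deterministic per-name baseline so uninformative analytes still span
    # realistic, heterogeneous concentration scales.
    h = zlib.crc32(name.encode("utf8")) % 10_000
    return -2.0 + 7.0 * h / 10_000.0


def default_analyte_effects(panel: Sequence[str]) -> dict[str, AnalyteEffect]:
    """Default per-analyte effects for ``panel``.

    The six informative analytes get strong GA slopes relative to their
    residual spread (|slope|/log_sd ~ 1.7 per analyte), so that jointly the
    panel carries most of the information about GA; all other (non-hemoglobin)
    analytes are null, with zero slope.
    """
    informative = {
        "17OHP": AnalyteEffect(baseline=math.log(30.0), slope=-0.20, log_sd=0.118),
        "C4DC": AnalyteEffect(baseline=math.log(0.30), slope=-0.20, log_sd=0.118),
        "TYR": AnalyteEffect(baseline=math.log(120.0), slope=0.20, log_sd=0.118),
        "ALA": AnalyteEffect(baseline=math.log(250.0), slope=0.20, log_sd=0.118),
        "C5": AnalyteEffect(baseline=math.log(0.12), slope=0.20, log_sd=0.118),
        "C5DC": AnalyteEffect(baseline=math.log(0.15), slope=-0.20, log_sd=0.118),
    }
    effects: dict[str, AnalyteEffect] = {}
    for name in panel:
        if name in HB_COLUMNS:
            continue
        if name in informative:
            effects[name] = informative[name]
        else:
            effects[name] = AnalyteEffect(
                baseline=_null_baseline(name), slope=0.0, log_sd=0.25
            )
    return effects


@dataclass
class SyntheticConfig:
    """Generative parameters for one site's cohort.

    GA is drawn from a two-component mixture: with probability
    ``preterm_target_fraction`` an exponential tail below 37 weeks
    (scale ``preterm_tail_scale``), otherwise a Gaussian term component
    truncated to [37, ``ga_max``]. The term component's location and spread
    are solved numerically so the mixture's overall mean and SD equal
    ``ga_mean``/``ga_sd``; the preterm fraction is therefore exactly binomial.

    ``bw_curve`` maps (GA, sex) to expected birth weight in grams via
    ``intercept + slope*(ga-40) + curvature*(ga-40)^2 + male_effect*is_male``.

    ``ga_observation_noise_sd`` is Gaussian noise added to the latent GA to
    form the *reported* reference GA (dating error); the latent GA drives the
    biology (birth weight, analytes, collection delays).
    """

    n_infants: int = 10_000
    seed: int = 0
    site_label: str = "site0"
    ga_mean: float = 39.3
    ga_sd: float = 1.6
    preterm_target_fraction: float = 0.056
    ga_min: float = 24.0
    ga_max: float = 43.0
    preterm_tail_scale: float = 2.1
    ga_observation_noise_sd: float = 0.0
    male_fraction: float = 0.493
    bw_curve: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 3460.0,
            "slope": 170.0,
            "curvature": -5.0,
            "male_effect": 120.0,
        }
    )
    bw_log_noise_sd: float = 0.115
    bw_noise_sd: float = 50.0
    growth_restricted_fraction: float = 0.035
    growth_restriction_deficit: float = 0.75
    analyte_panel: Sequence[str] = ONTARIO_PANEL
    analyte_effects: Mapping[str, AnalyteEffect] | None = None
    n_null_analytes: int | None = None
    hb_logit_intercept: float = 1.2
    hb_logit_slope: float = -0.30
    hb_logit_sd: float = 0.18
    hb_total_log_mean: float = math.log(180.0)
    hb_total_log_sd: float = 0.15
    hb_f1_fraction: float = 0.10
    outlier_rate: float = 0.002
    screen_positive_rate: float = 0.008
    collection_age_model: Mapping[str, float] = field(
        default_factory=lambda: {
            "median_hours": 28.0,
            "log_sd": 0.25,
            "preterm_delay_hours": 8.0,
        }
    )

    def __post_init__(self) -> None:
        self.analyte_panel = tuple(self.analyte_panel)
        if self.n_infants < 0:
            raise ConfigurationError("n_infants must be nonnegative")
        if len(self.analyte_panel) == 0:
            raise ConfigurationError("analyte_panel must not be empty")
        props = {
            "preterm_target_fraction": self.preterm_target_fraction,
            "male_fraction": self.male_fraction,
            "growth_restricted_fraction": self.growth_restricted_fraction,
            "outlier_rate": self.outlier_rate,
            "screen_positive_rate": self.screen_positive_rate,
            "hb_f1_fraction": self.hb_f1_fraction,
        }
        for name, value in props.items():
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be a proportion in [0, 1]")
        for name in ("ga_mean", "ga_sd", "ga_min", "ga_max", "bw_log_noise_sd",
                     "bw_noise_sd", "growth_restriction_deficit",
                     "preterm_tail_scale", "ga_observation_noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if not self.ga_min < self.ga_max:
            raise ConfigurationError("ga_min must be < ga_max")
        if 0.0 < self.preterm_target_fraction and not self.ga_min < 37.0:
            raise ConfigurationError("ga_min must be < 37 when preterm infants exist")
        if self.preterm_target_fraction < 1.0 and not self.ga_max > 37.0:
            raise ConfigurationError("ga_max must be > 37 when term infants exist")
        if not 0.0 < self.growth_restriction_deficit <= 1.0:
            raise ConfigurationError("growth_restriction_deficit must be in (0, 1]")
        hb_present = [c for c in HB_COLUMNS if c in self.analyte_panel]
        if hb_present and len(hb_present) != len(HB_COLUMNS):
            raise ConfigurationError(
                "hemoglobin columns must be present all together or not at all"
            )
        if self.analyte_effects is None:
            self.analyte_effects = default_analyte_effects(self.analyte_panel)
        missing = [
            a for a in self.analyte_panel
            if a not in HB_COLUMNS and a not in self.analyte_effects
        ]
        if missing:
            raise ConfigurationError(f"analyte_effects missing entries for {missing}")
        for name, eff in self.analyte_effects.items():
            for v in (eff.baseline, eff.slope, eff.log_sd, eff.restricted_shift):
                if not np.isfinite(v):
                    raise ConfigurationError(f"non-finite effect for analyte {name!r}")
            if eff.log_sd <= 0:
                raise ConfigurationError(f"log_sd must be positive for {name!r}")
        n_null = sum(
            1 for a in self.analyte_panel
            if a not in HB_COLUMNS and self.analyte_effects[a].slope == 0.0
        )
        if self.n_null_analytes is None:
            self.n_null_analytes = n_null
        elif self.n_null_analytes > len(self.analyte_panel):
            raise ConfigurationError("n_null_analytes exceeds panel size")
        elif self.n_null_analytes != n_null:
            raise ConfigurationError(
                f"n_null_analytes={self.n_null_analytes} but effects define {n_null} "
                "null analytes"
            )

    @property
    def has_hemoglobins(self) -> bool:
        return all(c in self.analyte_panel for c in HB_COLUMNS)


# --- GA mixture calibration -------------------------------------------------

_GA_PARAM_CACHE: dict[tuple, tuple[float, float]] = {}


def _preterm_moments(cfg: SyntheticConfig) -> tuple[float, float]:
    """Mean and variance of the preterm GA component (37 minus truncated Exp)."""
    span = 37.0 - cfg.ga_min
    dist = stats.truncexpon(b=span / cfg.preterm_tail_scale, scale=cfg.preterm_tail_scale)
    return 37.0 - dist.mean(), dist.var()


def _term_moments(mu: float, sigma: float, ga_max: float) -> tuple[float, float]:
    a, b = (37.0 - mu) / sigma, (ga_max - mu) / sigma
    dist = stats.truncnorm(a, b, loc=mu, scale=sigma)
    return dist.mean(), dist.var()


def _ga_component_params(cfg: SyntheticConfig) -> tuple[float, float]:
    """Solve the term component's (mu, sigma) so the mixture matches
    ``ga_mean``/``ga_sd`` given the preterm fraction and tail scale."""
    key = (cfg.ga_mean, cfg.ga_sd, cfg.preterm_target_fraction, cfg.ga_min,
           cfg.ga_max, cfg.preterm_tail_scale)
    if key in _GA_PARAM_CACHE:
        return _GA_PARAM_CACHE[key]
    p = cfg.preterm_target_fraction
    if p >= 1.0:
        _GA_PARAM_CACHE[key] = (cfg.ga_mean, cfg.ga_sd)
        return _GA_PARAM_CACHE[key]
    m_pre, v_pre = _preterm_moments(cfg) if p > 0 else (0.0, 0.0)
    target_term_mean = (cfg.ga_mean - p * m_pre) / (1.0 - p)
    if not 37.0 < target_term_mean < cfg.ga_max:
        raise ConfigurationError(
            "ga_mean/preterm_target_fraction imply a term-component mean outside "
            f"(37, ga_max): {target_term_mean:.2f}"
        )

    def solve_mu(sigma: float) -> float:
        # the location can sit far below 37 when sigma is large and the
        # truncated mean must stay close to the lower bound
        lo = 37.0 - 12.0 * sigma - 5.0
        return optimize.brentq(
            lambda mu: _term_moments(mu, sigma, cfg.ga_max)[0] - target_term_mean,
            lo, cfg.ga_max + 8.0 * sigma, xtol=1e-10,
        )

    def sd_gap(sigma: float) -> float:
        mu = solve_mu(sigma)
        m_t, v_t = _term_moments(mu, sigma, cfg.ga_max)
        total_var = ((1 - p) * (v_t + m_t**2) + p * (v_pre + m_pre**2)
                     - cfg.ga_mean**2)
        return math.sqrt(max(total_var, 0.0)) - cfg.ga_sd

    lo, hi = 0.05, 4.0 * cfg.ga_sd
    try:
        sigma = optimize.brentq(sd_gap, lo, hi, xtol=1e-8)
    except ValueError:
        warnings.warn(
            "could not match the requested overall GA SD exactly; using the "
            "term-component SD equal to ga_sd", stacklevel=2)
        sigma = cfg.ga_sd
    mu = solve_mu(sigma)
    _GA_PARAM_CACHE[key] = (mu, sigma)
    return mu, sigma


def _sample_ga(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    p = cfg.preterm_target_fraction
    is_preterm = rng.random(n) < p
    ga = np.empty(n)
    n_pre = int(is_preterm.sum())
    if n_pre:
        span = 37.0 - cfg.ga_min
        tail = stats.truncexpon(b=span / cfg.preterm_tail_scale,
                                scale=cfg.preterm_tail_scale)
        ga[is_preterm] = 37.0 - tail.ppf(rng.random(n_pre))
    if n - n_pre:
        mu, sigma = _ga_component_params(cfg)
        a, b = (37.0 - mu) / sigma, (cfg.ga_max - mu) / sigma
        term = stats.truncnorm(a, b, loc=mu, scale=sigma)
        ga[~is_preterm] = term.ppf(rng.random(n - n_pre))
    return ga


# --- cohort generation ------------------------------------------------------

def _empty_cohort(cfg: SyntheticConfig) -> pd.DataFrame:
    cols = list(BASE_COLUMNS) + list(cfg.analyte_panel)
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    df["id"] = df["id"].astype(str)
    df["site"] = df["site"].astype(str)
    df["sex"] = df["sex"].astype(str)
    df["screen_positive"] = df["screen_positive"].astype(int)
    return df


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate one site's cohort as a DataFrame in the cohort CSV schema.

    Columns are ``id, site, sex, birth_weight_g, ga_weeks,
    collection_age_hours, screen_positive`` followed by one column per panel
    analyte. Fixed ``config.seed`` gives byte-identical output.
    """
    n = config.n_infants
    if n == 0:
        return _empty_cohort(config)
    rng = np.random.default_rng(config.seed)

    latent_ga = _sample_ga(config, rng, n)
    male = rng.random(n) < config.male_fraction
    restricted = rng.random(n) < config.growth_restricted_fraction

    c = config.bw_curve
    d = latent_ga - 40.0
    bw_mean = (c["intercept"] + c["slope"] * d + c.get("curvature", 0.0) * d**2
               + c.get("male_effect", 0.0) * male)
    bw = bw_mean * np.where(restricted, config.growth_restriction_deficit, 1.0)
    bw = bw * np.exp(rng.normal(0.0, config.bw_log_noise_sd, n))
    bw = bw + rng.normal(0.0, config.bw_noise_sd, n)
    bw = np.maximum(bw, 350.0)

    data: dict[str, np.ndarray] = {}
    for name in config.analyte_panel:
        if name in HB_COLUMNS:
            continue
        eff = config.analyte_effects[name]
        log_level = (eff.baseline + eff.slope * d
                     + eff.restricted_shift * restricted
                     + rng.normal(0.0, eff.log_sd, n))
        data[name] = np.exp(log_level)

    if config.has_hemoglobins:
        logit_f = (config.hb_logit_intercept + config.hb_logit_slope * d
                   + rng.normal(0.0, config.hb_logit_sd, n))
        f = special.expit(logit_f)
        total = np.exp(config.hb_total_log_mean
                       + rng.normal(0.0, config.hb_total_log_sd, n))
        fetal = f * total
        data["HbF1"] = config.hb_f1_fraction * fetal
        data["HbF"] = (1.0 - config.hb_f1_fraction) * fetal
        data["HbA"] = (1.0 - f) * total

    analyte_names = [a for a in config.analyte_panel]
    # Screen positives: a few analytes spiked far beyond any plausible fence.
    screen_pos = rng.random(n) < config.screen_positive_rate
    non_hb = [a for a in analyte_names if a not in HB_COLUMNS]
    for i in np.flatnonzero(screen_pos):
        spiked = rng.choice(len(non_hb), size=min(3, len(non_hb)), replace=False)
        for j in spiked:
            data[non_hb[j]][i] *= math.exp(4.0)
    # Milder sporadic outliers that the winsorization step must cap.
    outlier = (rng.random(n) < config.outlier_rate) & ~screen_pos
    for i in np.flatnonzero(outlier):
        j = rng.integers(len(non_hb))
        data[non_hb[j]][i] *= math.exp(2.5)

    cam = config.collection_age_model
    hours = cam["median_hours"] * np.exp(rng.normal(0.0, cam["log_sd"], n))
    hours = hours + cam.get("preterm_delay_hours", 0.0) * (latent_ga < 37.0)
    hours = np.maximum(hours, 1.0)

    obs_ga = latent_ga
    if config.ga_observation_noise_sd > 0:
        obs_ga = latent_ga + rng.normal(0.0, config.ga_observation_noise_sd, n)
        obs_ga = np.clip(obs_ga, 20.0, 45.0)

    df = pd.DataFrame({
        "id": [f"{config.site_label}-{i:06d}" for i in range(n)],
        "site": config.site_label,
        "sex": np.where(male, "M", "F"),
        "birth_weight_g": bw,
        "ga_weeks": obs_ga,
        "collection_age_hours": hours,
        "screen_positive": screen_pos.astype(int),
    })
    for name in analyte_names:
        df[name] = data[name]
    return df


# --- site shifts ------------------------------------------------------------

@dataclass
class SiteShift:
    """Laboratory/site batch effect applied to a generated cohort.

    ``multiplicative_bias`` and ``additive_log_shift`` act on the log scale
    (``log x' = log x + log(bias) + shift``); ``dispersion_factor`` rescales
    the residual spread of each analyte around a linear fit of its
    log-concentration on GA, preserving the GA signal while inflating noise.
    Analytes outside ``panel`` are dropped (a site that does not measure
    them); ``ga_reporting="completed_weeks"`` floors the reference GA.
    """

    site_id: str
    multiplicative_bias: Mapping[str, float] = field(default_factory=dict)
    additive_log_shift: Mapping[str, float] = field(default_factory=dict)
    dispersion_factor: Mapping[str, float] = field(default_factory=dict)
    collection_delay_hours: float = 0.0
    panel: Sequence[str] | None = None
    ga_reporting: str = "decimal_weeks"

    def __post_init__(self) -> None:
        if self.ga_reporting not in ("decimal_weeks", "completed_weeks"):
            raise ConfigurationError(
                "ga_reporting must be 'decimal_weeks' or 'completed_weeks'"
            )
        for name, v in self.dispersion_factor.items():
            if v <= 0:
                raise ConfigurationError(f"dispersion_factor for {name!r} must be > 0")


def apply_site_shift(cohort: pd.DataFrame, shift: SiteShift,
                     seed: int | None = None) -> pd.DataFrame:
    """Apply a site batch effect; returns a new cohort table.

    The transform is deterministic (``seed`` is accepted for interface
    stability but unused). Raises :class:`SchemaError` if ``shift.panel``
    names an analyte absent from the cohort.
    """
    analytes = [c for c in cohort.columns if c not in BASE_COLUMNS]
    panel = list(shift.panel) if shift.panel is not None else analytes
    unknown = [a for a in panel if a not in analytes]
    if unknown:
        raise SchemaError(f"shift panel names analytes absent from cohort: {unknown}")
    for mapping, label in ((shift.multiplicative_bias, "multiplicative_bias"),
                           (shift.additive_log_shift, "additive_log_shift"),
                           (shift.dispersion_factor, "dispersion_factor")):
        bad = [a for a in mapping if a not in analytes]
        if bad:
            raise SchemaError(f"{label} names analytes absent from cohort: {bad}")

    out = cohort[list(BASE_COLUMNS) + panel].copy()
    ga = out["ga_weeks"].to_numpy(float)
    for name in panel:
        x = out[name].to_numpy(float)
        logx = np.log(np.maximum(x, 1e-300))
        dfac = shift.dispersion_factor.get(name, 1.0)
        if dfac != 1.0 and len(out) >= 3 and np.ptp(ga) > 0:
            coef = np.polyfit(ga, logx, 1)
            fitted = np.polyval(coef, ga)
            logx = fitted + dfac * (logx - fitted)
        logx = (logx + math.log(shift.multiplicative_bias.get(name, 1.0))
                + shift.additive_log_shift.get(name, 0.0))
        out[name] = np.exp(logx)
    out["collection_age_hours"] = (
        out["collection_age_hours"] + shift.collection_delay_hours
    )
    if shift.ga_reporting == "completed_weeks":
        out["ga_weeks"] = np.floor(out["ga_weeks"].to_numpy(float))
    out["site"] = shift.site_id
    return out


# --- I/O --------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (missing values as empty cells)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and numeric columns.

    Raises :class:`SchemaError` for missing required columns and
    :class:`CohortParseError` (naming row and column) for non-numeric cells.
    """
    df = pd.read_csv(path, dtype={"id": str, "site": str, "sex": str})
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing columns: {missing}")
    analytes = [c for c in df.columns if c not in BASE_COLUMNS]
    numeric_cols = ["birth_weight_g", "ga_weeks", "collection_age_hours"] + analytes
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row}"
            )
        df[col] = converted
    df["screen_positive"] = pd.to_numeric(
        df["screen_positive"], errors="coerce").fillna(0).astype(int)
    return df
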