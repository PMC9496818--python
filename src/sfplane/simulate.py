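"""Synthetic multi-site cohorts with known ground truth.

The generator emulates the statistical structure the harmonizers assume: each
edge feature is built on the Fisher-z (arctanh) scale as

    z_tjv = base_v + covariate effects + gamma_tv + p_jv + delta_t * eps,

then mapped through tanh into (-1, 1) so the features look like
phase-interaction / correlation values. ``gamma_tv`` are per-site additive
measurement effects (zero-sum across sites, so they double as the traveling
model's measurement bias m_v), ``delta_t`` a per-site noise scale, ``p_jv``
per-subject biological deviations, and the covariate effects protect-worthy
biology: a diagnosis shift on a contiguous block of edges, plus small age and
sex effects. A traveling companion re-scans fresh healthy subjects at every
site with the same gamma.

Everything is deterministic under the config seed. What the generator does
NOT emulate: hemodynamics, scanner physics, spatially structured noise, or
demographic imbalance between sites (each site draws covariates from the same
distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CohortMatrix, PhenotypeTable, SubjectTimeSeries, ValidationError

#: fixed covariate effect sizes on the Fisher-z scale
AGE_SLOPE = 0.002       # per year, all edges
SEX_EFFECT = 0.05       # male-vs-female shift, all edges
#: base connectome distribution on the Fisher-z scale (tanh maps the bulk
#: into roughly 0.1-0.85, straddling the binarization thresholds 0.2-0.8)
BASE_MEAN = 0.55
BASE_SD = 0.35


@dataclass
class SimConfig:
    """Study conditions for one synthetic multi-site cohort."""

    n_sites: int = 4
    subjects_per_site: int = 40
    n_rois: int = 24
    timepoints: int = 200
    tr: float = 2.0
    site_additive_sd: float = 0.2            # sd of gamma_tv, Fisher-z scale
    site_multiplicative_range: tuple = (0.7, 1.4)  # log-uniform delta_t bounds
    diagnosis_effect: float = 0.15           # shift on the designated edge block
    diagnosis_fraction: float = 0.4          # share of patients per site
    noise_sd: float = 0.15                   # scan noise sd (before delta_t)
    subject_factor_sd: float = 0.2           # per-subject biological deviation sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValidationError("need at least 2 sites")
        if self.subjects_per_site < 2:
            raise ValidationError("need at least 2 subjects per site")
        if self.n_rois < 3:
            raise ValidationError("need at least 3 ROIs")
        if self.timepoints < 64:
            raise ValidationError("need at least 64 timepoints for time-series mode")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        lo, hi = self.site_multiplicative_range
        if not (0 < lo <= hi):
            raise ValidationError("site_multiplicative_range must satisfy 0 < lo <= hi")
        for name in ("site_additive_sd", "noise_sd", "subject_factor_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not (0 <= self.diagnosis_fraction <= 1):
            raise ValidationError("diagnosis_fraction must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2


@dataclass
class GroundTruth:
    """Generating parameters, kept for recovery tests."""

    gamma_true: np.ndarray        # (n_sites, V) additive site effects, zero-sum
    delta_true: np.ndarray        # (n_sites,) multiplicative site scales
    m_true: np.ndarray            # (n_sites, V) traveling measurement bias (= gamma)
    diagnosis_edges: np.ndarray   # indices of the diagnosis-affected edge block
    subject_factors: np.ndarray   # (J, V) per-subject deviations
    base: np.ndarray = field(default=None)  # (V,) population connectome, z scale
    site_labels: list = field(default_factory=list)


def _site_labels(n: int) -> list[str]:
    return [f"site{t + 1:02d}" for t in range(n)]


def _draw_sites(cfg: SimConfig, rng: np.random.Generator):
    # scanner effects have a site-wide systematic part (calibration / SNR
    # shifts every edge together) and an edge-specific part; split the
    # variance budget evenly so the total per-edge sd stays site_additive_sd
    part = cfg.site_additive_sd / np.sqrt(2.0)
    offset = rng.normal(0.0, part, size=(cfg.n_sites, 1))
    gamma = offset + rng.normal(0.0, part, size=(cfg.n_sites, cfg.n_features))
    gamma -= gamma.mean(axis=0, keepdims=True)  # identifiable: zero-sum over sites
    lo, hi = cfg.site_multiplicative_range
    delta = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_sites))
    return gamma, delta


def _phenotypes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    labels = _site_labels(cfg.n_sites)
    for t, site in enumerate(labels):
        for j in range(cfg.subjects_per_site):
            rows.append(
                {
                    "subject_id": f"{site}_sub{j + 1:03d}",
                    "site": site,
                    "age": float(np.round(rng.uniform(18.0, 65.0), 1)),
                    "sex": rng.choice(["F", "M"]),
                    "diagnosis": (
                        "patient" if rng.random() < cfg.diagnosis_fraction else "control"
                    ),
                    "tr": cfg.tr,
                }
            )
    return pd.DataFrame(rows)


def _covariate_effects(phen: pd.DataFrame, cfg: SimConfig, diag_edges: np.ndarray) -> np.ndarray:
    j, v = len(phen), cfg.n_features
    eff = np.zeros((j, v))
    age = phen["age"].to_numpy(float)
    eff += AGE_SLOPE * (age - age.mean())[:, None]
    eff += SEX_EFFECT * (phen["sex"] == "M").to_numpy(float)[:, None]
    diag = (phen["diagnosis"] == "patient").to_numpy(float)
    eff[:, diag_edges] += cfg.diagnosis_effect * diag[:, None]
    return eff


def generate_cohort(
    cfg: SimConfig, squash: bool = True
) -> tuple[CohortMatrix, GroundTruth]:
    """Build a multi-site cohort with injected site and covariate effects.

    With ``squash=True`` (default) the features are tanh-mapped into (-1, 1),
    mimicking connectivity values; ``squash=False`` returns the raw Fisher-z
    table on which the generating model is exactly linear.
    """
    rng = np.random.default_rng(cfg.seed)
    v = cfg.n_features
    base = rng.normal(BASE_MEAN, BASE_SD, size=v)
    gamma, delta = _draw_sites(cfg, rng)
    # diagnosis effect on a contiguous 10% block of edges (at least one edge)
    block = max(1, v // 10)
    diag_edges = np.arange(block)

    phen_df = _phenotypes(cfg, rng)
    j = len(phen_df)
    site_idx = np.repeat(np.arange(cfg.n_sites), cfg.subjects_per_site)
    subject_factors = rng.normal(0.0, cfg.subject_factor_sd, size=(j, v))
    noise = rng.normal(0.0, cfg.noise_sd, size=(j, v)) * delta[site_idx, None]

    z = (
        base[None, :]
        + _covariate_effects(phen_df, cfg, diag_edges)
        + gamma[site_idx]
        + subject_factors
        + noise
    )
    features = np.tanh(z) if squash else z
    cohort = CohortMatrix(
        features=features, phenotypes=PhenotypeTable(phen_df), n_rois=cfg.n_rois
    )
    truth = GroundTruth(
        gamma_true=gamma,
        delta_true=delta,
        m_true=gamma,
        diagnosis_edges=diag_edges,
        subject_factors=subject_factors,
        base=base,
        site_labels=_site_labels(cfg.n_sites),
    )
    return cohort, truth


def generate_traveling_companion(
    cfg: SimConfig,
    truth: GroundTruth,
    n_travelers: int = 9,
    squash: bool = True,
) -> CohortMatrix:
    """Scan ``n_travelers`` fresh healthy subjects once at every site.

    The companion shares the main cohort's measurement biases (m_true) and
    noise model; each traveler's biological deviation is constant across
    their scans, which is what lets the regression separate site from subject.
    """
    if n_travelers < 2:
        raise ValidationError("need at least 2 travelers")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 777)))
    v = cfg.n_features
    labels = truth.site_labels or _site_labels(truth.m_true.shape[0])
    n_sites = len(labels)

    p_factors = rng.normal(0.0, cfg.subject_factor_sd, size=(n_travelers, v))
    rows = []
    z_rows = []
    for t, site in enumerate(labels):
        for s in range(n_travelers):
            noise = rng.normal(0.0, cfg.noise_sd, size=v) * truth.delta_true[t]
            z_rows.append(truth.base + truth.m_true[t] + p_factors[s] + noise)
            rows.append(
                {
                    "subject_id": f"trav{s + 1:02d}",
                    "site": site,
                    "age": 30.0,
                    "sex": "M" if s % 2 else "F",
                    "diagnosis": "control",
                    "tr": cfg.tr,
                }
            )
    z = np.vstack(z_rows)
    features = np.tanh(z) if squash else z
    phen = PhenotypeTable(pd.DataFrame(rows), allow_repeated_subjects=True)
    return CohortMatrix(features=features, phenotypes=phen, n_rois=cfg.n_rois)


# ---------------------------------------------------------------------------
# time-series mode


def phase_locked_series(
    lags: np.ndarray,
    timepoints: int,
    tr: float,
    freq: float = 0.055,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Narrowband sinusoids with prescribed per-region phase lags (radians).

    Region i's signal is sin(2 pi f t + lags[i]) plus white noise, so the
    phase-interaction pipeline recovers <P>_ij ~ cos(lags[i] - lags[j]).
    """
    lags = np.asarray(lags, dtype=float)
    t = np.arange(timepoints) * tr
    signals = np.sin(2 * np.pi * freq * t[:, None] + lags[None, :])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    return signals


def generate_time_series_cohort(
    cfg: SimConfig,
) -> tuple[list[SubjectTimeSeries], PhenotypeTable]:
    """Per-subject narrowband ROI signals whose phase lags encode a target
    connectome, with site effects injected as per-site lag perturbations."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 555)))
    labels = _site_labels(cfg.n_sites)
    base_lags = rng.uniform(0.0, 2 * np.pi, size=cfg.n_rois)
    site_pert = rng.normal(0.0, cfg.site_additive_sd, size=(cfg.n_sites, cfg.n_rois))

    phen_df = _phenotypes(cfg, rng)
    series = []
    row = 0
    for t, site in enumerate(labels):
        for _ in range(cfg.subjects_per_site):
            jitter = rng.normal(0.0, cfg.subject_factor_sd, size=cfg.n_rois)
            lags = base_lags + site_pert[t] + jitter
            values = phase_locked_series(
                lags, cfg.timepoints, cfg.tr, noise_sd=cfg.noise_sd, rng=rng
            )
            series.append(
                SubjectTimeSeries(
                    subject_id=phen_df.loc[row, "subject_id"], values=values, tr=cfg.tr
                )
            )
            row += 1
    return series, PhenotypeTable(phen_df)
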