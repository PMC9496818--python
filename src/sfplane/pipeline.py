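"""End-to-end workflows: cohort -> harmonized variants -> plane -> verdicts.

The harmonizers are scale-agnostic, but the default workflow applies them on
the Fisher-z (arctanh) scale and maps back through tanh: correlation-like
edge weights are variance-stabilized by the z transform, additive site
effects are closer to additive there, and the harmonized values land back in
(-1, 1) where the binarization threshold lives.
"""

from __future__ import annotations

import numpy as np

from .assessment import AssessmentResult, assess_cohort
from .core import CohortMatrix, ConnectivityMatrix, FeatureVector, ValidationError, devectorize
from .harmonization import (
    TravelingModel,
    apply_traveling_subject,
    combat,
    covbat,
    fit_traveling_subject,
)
from .netinfo import PlanePoint, shannon_fisher_point

_ATANH_CLIP = 1.0 - 1e-12


def fisher_z(cohort: CohortMatrix) -> CohortMatrix:
    """arctanh-transform the edge features (clipped just inside (-1, 1))."""
    z = np.arctanh(np.clip(cohort.features, -_ATANH_CLIP, _ATANH_CLIP))
    return cohort.with_features(z)


def inverse_fisher_z(cohort: CohortMatrix) -> CohortMatrix:
    return cohort.with_features(np.tanh(cohort.features))


def harmonize_cohort(
    cohort: CohortMatrix,
    method: str,
    covariates: list[str] | None = None,
    traveling: CohortMatrix | None = None,
    var_frac: float = 0.95,
    lambda_l2: float = 0.1,
    on_fisher_z: bool = True,
) -> tuple[CohortMatrix, object]:
    """Harmonize a cohort with one method; returns (cohort, fitted model).

    ``method`` is one of ``unharmonized`` (identity, model None), ``combat``,
    ``covbat`` or ``traveling`` (which requires the companion dataset).
    """
    if method == "unharmonized":
        return cohort, None
    work = fisher_z(cohort) if on_fisher_z else cohort
    if method == "combat":
        out, model = combat(work, covariates)
    elif method == "covbat":
        out, model = covbat(work, covariates, var_frac=var_frac)
    elif method == "traveling":
        if traveling is None:
            raise ValidationError(
                "the traveling-subject method requires an extra dataset of the "
                "same reference subjects scanned at every site"
            )
        trav_work = fisher_z(traveling) if on_fisher_z else traveling
        model = fit_traveling_subject(trav_work, lambda_l2=lambda_l2)
        out = apply_traveling_subject(model, work)
    else:
        raise ValidationError(f"unknown harmonization method {method!r}")
    return (inverse_fisher_z(out) if on_fisher_z else out), model


def cohort_plane_points(cohort: CohortMatrix, threshold: float = 0.5) -> list[PlanePoint]:
    """Devectorize each row, binarize, and place every subject on the plane."""
    points = []
    ids = cohort.phenotypes.subject_ids
    sites = cohort.sites
    for row in range(cohort.n_subjects):
        vec = FeatureVector(
            subject_id=ids[row], features=cohort.features[row], n_rois=cohort.n_rois
        )
        m = _lenient_matrix(vec)
        points.append(shannon_fisher_point(m, threshold=threshold, site=sites[row]))
    return points


def _lenient_matrix(vec: FeatureVector) -> ConnectivityMatrix:
    """Harmonized features may stray outside [-1, 1]; binarization tolerates
    that, so rebuild through the pearson kind (range-unchecked)."""
    return devectorize(vec, kind="pearson")


def run_assessment(
    cohort: CohortMatrix,
    variants: list[str],
    covariates: list[str] | None = None,
    traveling: CohortMatrix | None = None,
    threshold: float = 0.5,
    var_frac: float = 0.95,
    lambda_l2: float = 0.1,
    on_fisher_z: bool = True,
) -> tuple[list[AssessmentResult], dict[str, list[PlanePoint]]]:
    """Harmonize under each requested variant, test site effects on (H, F).

    Returns the flat result list (two rows — SE and FI — per variant) and the
    per-variant plane points for plotting.
    """
    results: list[AssessmentResult] = []
    points_by_variant: dict[str, list[PlanePoint]] = {}
    for variant in variants:
        harmonized, _ = harmonize_cohort(
            cohort,
            variant,
            covariates=covariates,
            traveling=traveling,
            var_frac=var_frac,
            lambda_l2=lambda_l2,
            on_fisher_z=on_fisher_z,
        )
        points = cohort_plane_points(harmonized, threshold=threshold)
        points_by_variant[variant] = points
        results.extend(assess_cohort(points, variant))
    return results, points_by_variant


def threshold_sweep(
    cohort: CohortMatrix,
    variants: list[str],
    thresholds=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    **kwargs,
) -> dict[float, list[AssessmentResult]]:
    """Repeat the assessment across binarization thresholds (robustness check).

    Harmonization is fitted once per variant; only the binarization threshold
    varies across the sweep.
    """
    harmonized_by_variant = {
        variant: harmonize_cohort(cohort, variant, **kwargs)[0] for variant in variants
    }
    sweep: dict[float, list[AssessmentResult]] = {}
    for thr in thresholds:
        results = []
        for variant in variants:
            points = cohort_plane_points(harmonized_by_variant[variant], threshold=thr)
            results.extend(assess_cohort(points, variant))
        sweep[float(thr)] = results
    return sweep
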