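"""Domain containers for multi-site connectome cohorts.

The objects here carry the data through the pipeline: per-subject ROI time
series, per-subject connectivity matrices, the subjects x edge-features table
that harmonization operates on, and the phenotype table holding site labels
and the biological covariates (age, sex, diagnosis) to protect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Connectivity kinds understood by the pipeline.
CONNECTIVITY_KINDS = ("phase_interaction", "pearson")

#: Phenotype columns that may enter a harmonization design matrix.
OPTIONAL_COVARIATES = ("age", "sex", "diagnosis")


class ValidationError(ValueError):
    """An input violates a structural invariant (not a numerical failure)."""


class ParseError(ValueError):
    """A file could not be parsed into a valid domain object."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class SubjectTimeSeries:
    """One subject's ROI signals: a T x N matrix sampled every ``tr`` seconds."""

    subject_id: str
    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "time series")
        if self.values.ndim != 2:
            raise ValidationError("time series must be a 2-D (timepoints x ROIs) array")
        t, n = self.values.shape
        if t < 3:
            raise ValidationError(f"need at least 3 timepoints, got {t}")
        if n < 3:
            raise ValidationError(f"need at least 3 ROIs, got {n}")
        if not (self.tr > 0):
            raise ValidationError(f"tr must be positive, got {self.tr}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeTable:
    """Subject metadata: site label plus covariates used in design matrices.

    Required columns: ``subject_id``, ``site``. Optional: ``age``, ``sex``,
    ``diagnosis``, ``tr``. Any optional covariate column that is present must
    be complete (no missing entries), because it enters a design matrix.

    Traveling-subject cohorts repeat subject ids across sites; pass
    ``allow_repeated_subjects=True`` for those.
    """

    data: pd.DataFrame
    allow_repeated_subjects: bool = False

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).reset_index(drop=True)
        for col in ("subject_id", "site"):
            if col not in df.columns:
                raise ValidationError(f"phenotype table missing required column {col!r}")
        df["subject_id"] = df["subject_id"].astype(str)
        df["site"] = df["site"].astype(str)
        if not self.allow_repeated_subjects and df["subject_id"].duplicated().any():
            dups = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"].unique())
            raise ValidationError(f"duplicate subject ids: {dups}")
        for col in OPTIONAL_COVARIATES:
            if col in df.columns and df[col].isna().any():
                raise ValidationError(f"covariate column {col!r} has missing entries")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].tolist()

    @property
    def sites(self) -> np.ndarray:
        return self.data["site"].to_numpy()

    @property
    def site_labels(self) -> list[str]:
        return sorted(self.data["site"].unique())

    def available_covariates(self) -> list[str]:
        return [c for c in OPTIONAL_COVARIATES if c in self.data.columns]

    def require_min_site_size(self, minimum: int = 2) -> None:
        """Raise unless every site has at least ``minimum`` rows."""
        counts = self.data["site"].value_counts()
        small = sorted(counts.index[counts < minimum])
        if small:
            raise ValidationError(
                f"sites with fewer than {minimum} subjects: {small}"
            )

    def subset(self, row_index) -> "PhenotypeTable":
        return PhenotypeTable(
            self.data.iloc[row_index].reset_index(drop=True),
            allow_repeated_subjects=self.allow_repeated_subjects,
        )


@dataclass
class ConnectivityMatrix:
    """A subject's connectome: symmetric N x N edge weights, unit diagonal."""

    subject_id: str
    weights: np.ndarray
    kind: str = "phase_interaction"

    #: tolerance for the symmetry check
    SYM_TOL = 1e-10

    def __post_init__(self) -> None:
        self.weights = _as_float_array(self.weights, "connectivity weights")
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("connectivity weights must be square")
        if w.shape[0] < 3:
            raise ValidationError("need at least 3 ROIs")
        if self.kind not in CONNECTIVITY_KINDS:
            raise ValidationError(f"unknown connectivity kind {self.kind!r}")
        if np.max(np.abs(w - w.T)) > self.SYM_TOL:
            raise ValidationError("connectivity matrix is not symmetric")
        if not np.allclose(np.diag(w), 1.0, atol=1e-8):
            raise ValidationError("connectivity diagonal must be 1")
        if self.kind == "phase_interaction" and np.max(np.abs(w)) > 1 + 1e-6:
            raise ValidationError("phase-interaction entries must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass
class FeatureVector:
    """Strict upper triangle of a connectivity matrix, row-major order."""

    subject_id: str
    features: np.ndarray
    n_rois: int

    def __post_init__(self) -> None:
        self.features = _as_float_array(np.ravel(self.features), "features")
        expected = self.n_rois * (self.n_rois - 1) // 2
        if self.features.size != expected:
            raise ValidationError(
                f"feature vector has length {self.features.size}, "
                f"expected N(N-1)/2 = {expected} for N = {self.n_rois}"
            )


@dataclass
class CohortMatrix:
    """Subjects x edge-features table with aligned phenotypes.

    Row ``j`` of ``features`` is the vectorized connectome of the subject in
    row ``j`` of ``phenotypes``; column ``v`` is one edge, in strict
    upper-triangle row-major order.
    """

    features: np.ndarray
    phenotypes: PhenotypeTable
    n_rois: int

    def __post_init__(self) -> None:
        self.features = _as_float_array(self.features, "cohort features")
        if self.features.ndim != 2:
            raise ValidationError("cohort features must be 2-D (subjects x features)")
        if self.features.shape[0] != len(self.phenotypes):
            raise ValidationError(
                f"{self.features.shape[0]} feature rows but "
                f"{len(self.phenotypes)} phenotype rows"
            )
        expected = self.n_rois * (self.n_rois - 1) // 2
        if self.features.shape[1] != expected:
            raise ValidationError(
                f"cohort has {self.features.shape[1]} features, expected {expected}"
            )

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def sites(self) -> np.ndarray:
        return self.phenotypes.sites

    def with_features(self, features: np.ndarray) -> "CohortMatrix":
        """Same phenotypes/shape, new feature values (post-harmonization)."""
        return CohortMatrix(features=features, phenotypes=self.phenotypes, n_rois=self.n_rois)


def vectorize_matrix(m: ConnectivityMatrix) -> FeatureVector:
    """Extract the strict upper triangle (i < j, row-major) as a feature vector.

    The diagonal is excluded: self-coherence is identically 1 and carries no
    site information.
    """
    n = m.n_rois
    iu = np.triu_indices(n, k=1)
    return FeatureVector(subject_id=m.subject_id, features=m.weights[iu].copy(), n_rois=n)


def devectorize(v: FeatureVector, kind: str = "phase_interaction") -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_matrix`: rebuild the symmetric matrix."""
    n = v.n_rois
    w = np.eye(n)
    iu = np.triu_indices(n, k=1)
    w[iu] = v.features
    w[(iu[1], iu[0])] = v.features
    return ConnectivityMatrix(subject_id=v.subject_id, weights=w, kind=kind)


def assemble_cohort(vectors: list[FeatureVector], phen: PhenotypeTable) -> CohortMatrix:
    """Stack feature vectors into a cohort, aligned to phenotype row order.

    Alignment is by subject id, never by list position, so the input list may
    arrive in any order. Traveling-subject phenotypes (repeated ids) require
    one vector per phenotype row, matched positionally within each id.
    """
    if not vectors:
        raise ValidationError("no feature vectors supplied")
    n_rois = {v.n_rois for v in vectors}
    if len(n_rois) != 1:
        raise ValidationError(f"mixed ROI counts in feature vectors: {sorted(n_rois)}")
    n = n_rois.pop()

    by_id: dict[str, list[FeatureVector]] = {}
    for v in vectors:
        by_id.setdefault(v.subject_id, []).append(v)

    wanted = phen.subject_ids
    missing = sorted(set(by_id) - set(wanted))
    if missing:
        raise ValidationError(f"feature vectors with no phenotype row: {missing}")

    rows = []
    cursor: dict[str, int] = {}
    for sid in wanted:
        pool = by_id.get(sid)
        idx = cursor.get(sid, 0)
        if pool is None or idx >= len(pool):
            raise ValidationError(f"no feature vector for subject {sid!r}")
        rows.append(pool[idx].features)
        cursor[sid] = idx + 1
    return CohortMatrix(features=np.vstack(rows), phenotypes=phen, n_rois=n)
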