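"""Shared fixtures and independent brute-force oracles.

The oracles re-implement the measures with explicit loops straight from their
definitions, independent of the package's vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from sfplane import CohortMatrix, ConnectivityMatrix, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def weights_from_adjacency(a: np.ndarray) -> ConnectivityMatrix:
    """Lift a 0/1 adjacency to a connectivity matrix that binarizes back to it
    at threshold 0.5 (edges 0.9, non-edges 0.1)."""
    w = np.where(a > 0, 0.9, 0.1).astype(float)
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(subject_id="toy", weights=w)


# ---------------------------------------------------------------------------
# brute-force network-information oracle (explicit loops, no shortcuts)


def brute_walk_probs(a: np.ndarray, i: int) -> list[float]:
    n = a.shape[0]
    k = sum(int(a[i, j]) for j in range(n))
    probs = []
    for j in range(n):
        if j == i:
            continue
        probs.append(0.0 if (k == 0 or a[i, j] == 0) else 1.0 / k)
    return probs


def brute_network_entropy(a: np.ndarray) -> float:
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        probs = brute_walk_probs(a, i)
        if sum(probs) == 0:
            continue  # isolated node: H(i) = 0 by convention
        s = 0.0
        for p in probs:
            if p > 0:
                s -= p * math.log(p)
        total += s / math.log(n - 1)
    return total / n


def brute_network_fisher(a: np.ndarray) -> float:
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        probs = brute_walk_probs(a, i)
        if sum(probs) == 0:
            total += 1.0  # isolated node: F(i) = 1 by convention
            continue
        f = 0.0
        for j in range(len(probs) - 1):
            f += (math.sqrt(probs[j + 1]) - math.sqrt(probs[j])) ** 2
        total += 0.5 * f
    return total / n


# ---------------------------------------------------------------------------
# brute-force single-feature two-site location/scale adjustment


def brute_two_site_location_scale(y: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Closed-form ComBat for one feature, two sites, intercept only, no EB."""
    labels = sorted(set(sites))
    n = np.array([np.sum(sites == lab) for lab in labels])
    site_means = np.array([y[sites == lab].mean() for lab in labels])
    alpha = (n / n.sum()) @ site_means
    resid = y.copy()
    for lab, mu in zip(labels, site_means):
        resid[sites == lab] -= mu
    sigma = math.sqrt((resid**2).mean())
    z = (y - alpha) / sigma
    out = np.empty_like(y)
    for lab in labels:
        mask = sites == lab
        gamma = z[mask].mean()
        delta = z[mask].std(ddof=1)
        out[mask] = (z[mask] - gamma) / delta * sigma + alpha
    return out


# ---------------------------------------------------------------------------
# small cohort builders


def make_cohort(features: np.ndarray, sites, n_rois: int, **phen_cols) -> CohortMatrix:
    j = features.shape[0]
    df = pd.DataFrame(
        {"subject_id": [f"s{i:03d}" for i in range(j)], "site": list(sites), **phen_cols}
    )
    return CohortMatrix(features=features, phenotypes=PhenotypeTable(df), n_rois=n_rois)


def two_site_gaussian_cohort(
    rng, n_per_site: int = 50, n_rois: int = 16, offsets=(0.0, 0.0), noise_sd: float = 0.2
) -> CohortMatrix:
    v = n_rois * (n_rois - 1) // 2
    base = rng.normal(0.5, 0.3, v)
    rows, sites = [], []
    for t, off in enumerate(offsets):
        for _ in range(n_per_site):
            rows.append(base + off + rng.normal(0, noise_sd, v))
            sites.append(f"S{t}")
    return make_cohort(np.vstack(rows), sites, n_rois)
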