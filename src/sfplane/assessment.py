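"""Residual site-effect quantification on the Shannon-Fisher plane.

For each harmonization variant, the Kruskal-Wallis rank test is run twice —
once on the subjects' network Shannon entropies (SE) and once on their network
Fisher informations (FI) — against the null hypothesis that all sites share
the same population median. The p-values are reported as p' = -log10(p), so
p' <= 1.301 corresponds to p >= 0.05: no detectable residual site effect.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .core import ValidationError
from .netinfo import PlanePoint

#: p' value corresponding to p = 0.05
SIGNIFICANCE_P_PRIME = -math.log10(0.05)  # 1.30103...

MEASURES = ("SE", "FI")
VARIANTS = ("unharmonized", "combat", "covbat", "traveling")


@dataclass
class AssessmentResult:
    """One Kruskal-Wallis verdict: a measure under a harmonization variant."""

    measure: str          # "SE" (entropy) or "FI" (Fisher information)
    variant: str          # unharmonized / combat / covbat / traveling
    h_statistic: float
    p_value: float
    p_prime: float
    n_sites: int
    n_subjects: int

    @property
    def significant(self) -> bool:
        """Residual site effect detectable at the 5% level."""
        return self.p_prime > SIGNIFICANCE_P_PRIME


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Requires >= 2 groups with >= 2 observations each. Completely tied data
    (every value identical) carries no evidence against the null and returns
    (0, 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have the same length")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    small = sorted(labels[counts < 2].tolist())
    if small:
        raise ValidationError(f"groups with fewer than 2 observations: {small}")
    samples = [values[groups == lab] for lab in labels]
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def neg_log_transform(p: float) -> float:
    """p' = -log10(p); base 10 so that p = 0.05 maps to p' = 1.301."""
    if not (0 < p <= 1):
        raise ValidationError(f"p-value must lie in (0, 1], got {p}")
    return float(-math.log10(p))


def assess_cohort(points: list[PlanePoint], variant: str) -> list[AssessmentResult]:
    """Run the site-effect test on H (SE) and F (FI) across plane points."""
    if not points:
        raise ValidationError("no plane points supplied")
    sites = np.array([pt.site for pt in points])
    if len(set(sites)) < 2:
        raise ValidationError("assessment needs points from at least 2 sites")
    results = []
    for measure, attr in (("SE", "H"), ("FI", "F")):
        vals = np.array([getattr(pt, attr) for pt in points])
        h, p = kruskal_wallis(vals, sites)
        results.append(
            AssessmentResult(
                measure=measure,
                variant=variant,
                h_statistic=h,
                p_value=p,
                p_prime=neg_log_transform(p),
                n_sites=len(set(sites)),
                n_subjects=len(points),
            )
        )
    return results


def bonferroni(results: list[AssessmentResult]) -> list[AssessmentResult]:
    """Optional multiplicity correction across a result set (off by default
    in reports, matching the uncorrected presentation of the method)."""
    m = len(results)
    out = []
    for r in results:
        p = min(1.0, r.p_value * m)
        out.append(
            AssessmentResult(
                measure=r.measure,
                variant=r.variant,
                h_statistic=r.h_statistic,
                p_value=p,
                p_prime=neg_log_transform(p),
                n_sites=r.n_sites,
                n_subjects=r.n_subjects,
            )
        )
    return out


def write_report(results: list[AssessmentResult], path, dataset: str = "synthetic") -> None:
    """CSV report: one row per (variant, measure) verdict."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["dataset", "variant", "measure", "H_stat", "p", "p_prime", "significant"]
        )
        for r in results:
            writer.writerow(
                [
                    dataset,
                    r.variant,
                    r.measure,
                    f"{r.h_statistic:.6g}",
                    f"{r.p_value:.6g}",
                    f"{r.p_prime:.6g}",
                    r.significant,
                ]
            )


def format_table(results: list[AssessmentResult], dataset: str = "synthetic") -> str:
    """Text table of transformed p-values, one row per measure, variants as
    columns; values at or below 1.301 are the harmonization successes."""
    variants = [v for v in VARIANTS if any(r.variant == v for r in results)]
    by_key = {(r.measure, r.variant): r for r in results}
    width = max(12, *(len(v) for v in variants))
    header = f"{dataset:<12} " + " ".join(f"{v:>{width}}" for v in variants)
    lines = [header, "-" * len(header)]
    for measure in MEASURES:
        cells = []
        for v in variants:
            r = by_key.get((measure, v))
            cells.append(f"{r.p_prime:>{width}.3f}" if r else f"{'-':>{width}}")
        lines.append(f"{measure:<12} " + " ".join(cells))
    return "\n".join(lines)


def make_plane_figure(points: list[PlanePoint], title: str = ""):
    """Build the Shannon-Fisher scatter figure: axes clamped to [0,1]^2, one
    color per site, colors assigned deterministically by sorted site label."""
    if not points:
        raise ValidationError("no plane points to plot")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    site_labels = sorted({pt.site for pt in points})
    cmap = plt.get_cmap("tab20" if len(site_labels) > 10 else "tab10")
    fig, ax = plt.subplots(figsize=(5, 5))
    for i, site in enumerate(site_labels):
        xs = [pt.H for pt in points if pt.site == site]
        ys = [pt.F for pt in points if pt.site == site]
        ax.scatter(xs, ys, s=14, color=cmap(i % cmap.N), label=str(site), alpha=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Normalized Network Shannon Entropy (H)")
    ax.set_ylabel("Normalized Network Fisher Information (F)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=7, title="site")
    fig.tight_layout()
    return fig


def plot_plane(points: list[PlanePoint], out, title: str = "") -> None:
    """Render :func:`make_plane_figure` to a file (deterministic bytes for
    identical input)."""
    import matplotlib.pyplot as plt

    fig = make_plane_figure(points, title=title)
    fig.savefig(Path(out), dpi=120, metadata=_deterministic_metadata(Path(out)))
    plt.close(fig)


def _deterministic_metadata(path: Path) -> dict:
    # strip timestamps so identical inputs give byte-identical files
    if path.suffix.lower() == ".png":
        return {"Software": "sfplane"}
    if path.suffix.lower() == ".svg":
        return {"Date": None}
    return {}


def write_plane_csv(points: list[PlanePoint], path) -> None:
    """Per-subject plane coordinates (subject_id, site, H, F)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "site", "H", "F"])
        for pt in points:
            writer.writerow([pt.subject_id, pt.site, f"{pt.H:.10g}", f"{pt.F:.10g}"])


def read_plane_csv(path) -> list[PlanePoint]:
    points = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            points.append(
                PlanePoint(
                    subject_id=row["subject_id"],
                    site=row["site"],
                    H=float(row["H"]),
                    F=float(row["F"]),
                )
            )
    return points
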