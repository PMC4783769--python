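"""Specimen quality control from left/right anchor symmetry.

A well-mounted specimen has congruent image and object planes, so the left
and right forms of each anchor are near-mirror images and their pairwise
inter-landmark distances agree. For each specimen we pool, over the ventral
and dorsal anchors, the 55 right-minus-left distance residuals (M) and the
left/right mean distances (A), and score

    Q = 100 * 10^(-sqrt(M2 + b2_scaled) / 10)

where M2 is the sum of squared residuals and b2_scaled is the squared OLS
slope of M on A scaled by Sum (A - mean(A))^2 — the regression sum of
squares attributable to the slope, which puts the slope term on the same
order of magnitude as M2. Q is 100 for perfect bilateral symmetry and
decays toward 0 as mounting distortion grows.

Q is deliberately scale-sensitive: M is measured in the input units, so
score distances in micrometres (pass a ``conversion``) to obtain magnitudes
comparable across digitizer calibrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from anchorgm.landmark_io import (
    ANCHOR_TYPES,
    SpecimenRecord,
    UnitConversion,
    pairwise_distances,
)

logger = logging.getLogger(__name__)


@dataclass
class QualityReport:
    """Symmetry diagnostics and quality score for one specimen."""

    M: np.ndarray  # right - left distance residuals, ventral then dorsal (110,)
    A: np.ndarray  # left/right mean distances (110,)
    M2: float  # sum of squared residuals
    b: float  # OLS slope of M on A (with intercept)
    b2_scaled: float  # b^2 * Sum (A - mean(A))^2
    Q: float  # 100 * 10^(-sqrt(M2 + b2_scaled)/10), in [0, 100]


def lr_distance_residuals(spec: SpecimenRecord) -> tuple[np.ndarray, np.ndarray]:
    """Right-minus-left distance residuals M and left/right means A.

    Computed per anchor type over the 55 landmark pairs and concatenated
    (ventral block first), giving vectors of length 110 for 11-landmark
    anchors. Raises ``KeyError`` naming the missing side/type if an anchor
    is absent.
    """
    M_parts, A_parts = [], []
    for anchor_type in ANCHOR_TYPES:
        d_left = pairwise_distances(spec.anchor(anchor_type, "left"))
        d_right = pairwise_distances(spec.anchor(anchor_type, "right"))
        M_parts.append(d_right - d_left)
        A_parts.append((d_right + d_left) / 2.0)
    return np.concatenate(M_parts), np.concatenate(A_parts)


def quality_score(
    spec: SpecimenRecord, conversion: UnitConversion | None = None
) -> QualityReport:
    """Score a specimen's mounting quality; attaches and returns a QualityReport.

    Parameters
    ----------
    spec : SpecimenRecord
        Must carry all four anchors.
    conversion : UnitConversion, optional
        Applied to the pairwise distances before scoring, so that M2 is in
        µm² regardless of digitizer units. Omit to score in raw units.
    """
    M, A = lr_distance_residuals(spec)
    if conversion is not None:
        # the affine offset cancels in M (difference) and shifts A only
        M = conversion.slope * M
        A = conversion.slope * A + conversion.intercept
    if M.size < 3:
        raise ValueError("need at least 3 distance pairs for the slope regression")

    M2 = float(np.sum(M**2))
    A_c = A - A.mean()
    ss_A = float(np.sum(A_c**2))
    if ss_A == 0.0:
        # all mean distances identical: no slope estimable, attribute nothing to b
        b = 0.0
    else:
        b = float(np.sum(A_c * M) / ss_A)
    b2_scaled = b**2 * ss_A
    Q = float(100.0 * 10.0 ** (-np.sqrt(M2 + b2_scaled) / 10.0))
    report = QualityReport(M=M, A=A, M2=M2, b=b, b2_scaled=b2_scaled, Q=Q)
    spec.quality = report
    return report


def filter_by_quality(
    dataset: list[SpecimenRecord],
    threshold: float = 10.0,
    conversion: UnitConversion | None = None,
) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Retain specimens with Q >= threshold (inclusive boundary).

    Scores any unscored specimen. Returns the retained subset and a report
    table with one row per specimen (columns id, species, M2, b, b2_scaled,
    Q, retained) suitable for per-species box plots and retention counts.
    """
    if not dataset:
        logger.warning("filter_by_quality called on an empty dataset")
        return [], pd.DataFrame(columns=["id", "species", "M2", "b", "b2_scaled", "Q", "retained"])

    rows = []
    retained = []
    for spec in dataset:
        rep = spec.quality if isinstance(spec.quality, QualityReport) else quality_score(spec, conversion)
        keep = rep.Q >= threshold
        if keep:
            retained.append(spec)
        rows.append(
            {
                "id": spec.id,
                "species": spec.species,
                "M2": rep.M2,
                "b": rep.b,
                "b2_scaled": rep.b2_scaled,
                "Q": rep.Q,
                "retained": keep,
            }
        )
    report = pd.DataFrame(rows)
    if not retained:
        logger.warning("no specimen reached Q >= %s", threshold)
    return retained, report


def retention_counts(report: pd.DataFrame) -> pd.DataFrame:
    """Per-species totals and retained counts from a filter_by_quality report."""
    g = report.groupby("species")["retained"]
    return pd.DataFrame({"n_total": g.size(), "n_retained": g.sum().astype(int)})
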