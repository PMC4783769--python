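"""Two-stage Generalized Procrustes alignment of anchor configurations.

Stage 1 operates within each species and anchor type: left forms are
reflected (x negated) so both sides share handedness, all of the species'
forms are superimposed by GPA, each specimen's aligned left and right forms
are averaged, and the average is rotated so the curve point (LM7) lies on
the x = 0 line. The LM7 standardization puts every species' configurations
in a common orientation frame, which a per-species GPA alone cannot
guarantee for slide-mounted microscopic material. Stage 2 runs one global
GPA per anchor type over all specimens' stage-1 configurations and
assembles the specimen x 44 shape matrix (22 ventral + 22 dorsal
coordinates, columns V1x, V1y, ..., D11y).

GPA here is partial Procrustes superimposition: every configuration is
centered, scaled to unit centroid size, and rotated (no reflection — the
handedness was normalized explicitly) to an iteratively refined consensus.
No tangent-space projection and no semi-landmark sliding are applied;
downstream statistics use the aligned coordinates directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from anchorgm.landmark_io import ANCHOR_TYPES, LandmarkConfiguration, SpecimenRecord

logger = logging.getLogger(__name__)

LM7_INDEX = 6  # 0-based row of LM7, the curve point


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from their centroid."""
    coords = np.asarray(coords, float)
    return float(np.sqrt(np.sum((coords - coords.mean(axis=0)) ** 2)))


def _optimal_rotation(source: np.ndarray, target: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Orthogonal matrix R minimizing ||source @ R - target||_F (both centered)."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def _center_and_scale(coords: np.ndarray, label: str) -> np.ndarray:
    size = centroid_size(coords)
    if size <= 0:
        raise ValueError(f"configuration {label!r} has zero centroid size")
    return (coords - coords.mean(axis=0)) / size


def gpa(
    configs: list[LandmarkConfiguration] | list[np.ndarray],
    allow_reflection: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes Analysis of 2D landmark configurations.

    Removes translation (centering), size (unit centroid size) and rotation
    (closed-form 2D orthogonal fit to the consensus, iterated to
    convergence). Returns the aligned coordinate arrays and the consensus
    shape (mean of aligned forms, rescaled to unit centroid size).
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    labels = [
        c.id if isinstance(c, LandmarkConfiguration) else f"config{i}"
        for i, c in enumerate(configs)
    ]
    arrays = [
        c.coords if isinstance(c, LandmarkConfiguration) else np.asarray(c, float)
        for c in configs
    ]
    k = arrays[0].shape[0]
    if any(a.shape != (k, 2) for a in arrays):
        raise ValueError("all configurations must share the same landmark count")

    aligned = [_center_and_scale(a, lab) for a, lab in zip(arrays, labels)]
    consensus = aligned[0].copy()
    for _ in range(max_iter):
        aligned = [a @ _optimal_rotation(a, consensus, allow_reflection) for a in aligned]
        new_consensus = np.mean(aligned, axis=0)
        new_consensus = new_consensus / centroid_size(new_consensus)
        change = np.sqrt(np.sum((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break
    aligned = [a @ _optimal_rotation(a, consensus, allow_reflection) for a in aligned]
    return aligned, consensus


def average_left_right(left_aligned: np.ndarray, right_aligned: np.ndarray) -> np.ndarray:
    """Landmark-wise mean of a specimen's two GPA-aligned forms.

    The left form must have been reflected before alignment so both sides
    share handedness; averaging unlike-handed forms is meaningless.
    """
    left_aligned = np.asarray(left_aligned, float)
    right_aligned = np.asarray(right_aligned, float)
    if left_aligned.shape != right_aligned.shape:
        raise ValueError("left and right forms must have identical shapes")
    return (left_aligned + right_aligned) / 2.0


def standardize_orientation(coords: np.ndarray, landmark_index: int = LM7_INDEX) -> np.ndarray:
    """Rotate a centered configuration so the chosen landmark lies on x = 0.

    The rotation is about the origin by the smallest angle that brings the
    landmark (LM7, the curve point, by default) onto the x = 0 line with
    its y-sign preserved; all inter-landmark distances are unchanged.
    Idempotent for already-standardized input.
    """
    coords = np.asarray(coords, float)
    x, y = coords[landmark_index]
    r = np.hypot(x, y)
    if r < 1e-300:
        raise ValueError("reference landmark at the origin; orientation undefined")
    phi = np.arctan2(y, x)
    target = np.pi / 2 if y >= 0 else -np.pi / 2
    delta = target - phi
    # wrap to (-pi, pi] for the minimal rotation
    delta = (delta + np.pi) % (2 * np.pi) - np.pi
    c, s = np.cos(delta), np.sin(delta)
    R = np.array([[c, s], [-s, c]])  # right-multiplication rotates by +delta
    return coords @ R


@dataclass
class ShapeMatrix:
    """Specimens x 44 aligned GPA coordinates (ventral block then dorsal block)."""

    values: pd.DataFrame  # index: specimen ids; columns V1x..V11y, D1x..D11y
    species: pd.Series  # specimen id -> species label
    consensus: dict[str, np.ndarray]  # anchor_type -> (11, 2) stage-2 consensus

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    def block(self, anchor_type: str) -> pd.DataFrame:
        """The 22-column coordinate block for one anchor type."""
        prefix = "V" if anchor_type == "ventral" else "D"
        return self.values[[c for c in self.values.columns if c.startswith(prefix)]]

    def config(self, specimen_id: str, anchor_type: str) -> np.ndarray:
        """One specimen's aligned (11, 2) configuration for an anchor type."""
        return row_to_config(self.block(anchor_type).loc[specimen_id].to_numpy())


def config_to_row(coords: np.ndarray) -> np.ndarray:
    """Flatten an (k, 2) configuration to x1,y1,...,xk,yk."""
    return np.asarray(coords, float).reshape(-1)


def row_to_config(row: np.ndarray) -> np.ndarray:
    """Inverse of :func:`config_to_row`."""
    return np.asarray(row, float).reshape(-1, 2)


def _coordinate_columns(n_landmarks: int = 11) -> list[str]:
    cols = []
    for prefix in ("V", "D"):
        for i in range(1, n_landmarks + 1):
            cols += [f"{prefix}{i}x", f"{prefix}{i}y"]
    return cols


def two_stage_alignment(dataset: list[SpecimenRecord]) -> ShapeMatrix:
    """Run the full two-stage alignment and build the 44-column shape matrix.

    Specimens must carry all four anchors (run quality filtering first).
    Species represented by a single specimen are aligned against their own
    two (left/right) forms only — no within-species consensus across
    specimens — and a warning is logged.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 specimens")
    by_species: dict[str, list[SpecimenRecord]] = {}
    for spec in dataset:
        by_species.setdefault(spec.species, []).append(spec)
    for sp, members in by_species.items():
        if len(members) == 1:
            logger.warning(
                "species %r has a single specimen; stage 1 uses only its own left/right forms", sp
            )

    ids = [s.id for s in dataset]
    blocks: dict[str, np.ndarray] = {}
    consensus: dict[str, np.ndarray] = {}
    for anchor_type in ANCHOR_TYPES:
        stage1: dict[str, np.ndarray] = {}
        for sp, members in by_species.items():
            forms = []
            for m in members:
                right = m.anchor(anchor_type, "right").coords
                left = m.anchor(anchor_type, "left").coords * np.array([-1.0, 1.0])
                forms.append((m.id, left, right))
            flat = []
            for mid, left, right in forms:
                flat.append(LandmarkConfiguration(left, id=f"{mid}:L"))
                flat.append(LandmarkConfiguration(right, id=f"{mid}:R"))
            aligned, _ = gpa(flat)
            for (mid, _, _), la, ra in zip(forms, aligned[0::2], aligned[1::2]):
                avg = average_left_right(la, ra)
                stage1[mid] = standardize_orientation(avg - avg.mean(axis=0))
        aligned2, cons = gpa([LandmarkConfiguration(stage1[i], id=i) for i in ids])
        # canonical frame: rotate the whole aligned set so the consensus LM7
        # sits on the positive x = 0 axis; makes the output independent of
        # specimen order (GPA fixes orientation only up to a global rotation)
        x7, y7 = cons[LM7_INDEX]
        delta = np.pi / 2 - np.arctan2(y7, x7)
        c, s = np.cos(delta), np.sin(delta)
        R = np.array([[c, s], [-s, c]])
        cons = cons @ R
        aligned2 = [a @ R for a in aligned2]
        consensus[anchor_type] = cons
        blocks[anchor_type] = np.stack([config_to_row(a) for a in aligned2])

    values = pd.DataFrame(
        np.hstack([blocks["ventral"], blocks["dorsal"]]),
        index=pd.Index(ids, name="id"),
        columns=_coordinate_columns(),
    )
    species = pd.Series({s.id: s.species for s in dataset}, name="species").loc[ids]
    return ShapeMatrix(values=values, species=species, consensus=consensus)


def species_mean_shapes(shape: ShapeMatrix) -> pd.DataFrame:
    """Per-species arithmetic mean of shape-matrix rows (the species centroids)."""
    return shape.values.groupby(shape.species).mean().sort_index()
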