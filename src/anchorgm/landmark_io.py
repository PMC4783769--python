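"""Landmark configurations, TPS input/output, size variables and unit conversion.

An anchor is digitized as 11 ordered landmarks (LM1-LM11). Six are Type I
(anatomically homologous points: inner root point LM1, groove point LM2,
outer root point LM3, dent point LM5, curve point LM7, tip point LM8); the
remaining five (LM4, LM6, LM9, LM10, LM11) are Type III semi-landmarks
constructed by projection onto the anchor outline. Each specimen carries
four anchors: ventral-left, ventral-right, dorsal-left, dorsal-right.

Coordinates are 2D Cartesian with y increasing upward; if a digitizer uses
an image origin (y downward) the caller is responsible for flipping before
analysis. Raw coordinates are in arbitrary image units; distances can be
converted to micrometres with the shipped affine calibration (0.2 µm per
unit, offset 0.9 µm) or a refitted one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

N_LANDMARKS = 11
N_PAIRS = N_LANDMARKS * (N_LANDMARKS - 1) // 2  # 55

#: 1-based indices of Type I (anatomical) landmarks.
TYPE_I = (1, 2, 3, 5, 7, 8)
#: 1-based indices of Type III (constructed semi-) landmarks.
TYPE_III = (4, 6, 9, 10, 11)

#: Fixed lexicographic ordering of landmark pairs, 1-based: (1,2),(1,3)...(10,11).
PAIR_ORDER = tuple(
    (i, j) for i in range(1, N_LANDMARKS + 1) for j in range(i + 1, N_LANDMARKS + 1)
)

ANCHOR_TYPES = ("ventral", "dorsal")
SIDES = ("left", "right")


class TpsParseError(ValueError):
    """Malformed TPS record or coordinate line."""


@dataclass
class LandmarkConfiguration:
    """Ordered 2D landmark set for one anchor.

    Parameters
    ----------
    coords : (n, 2) array
        Landmark coordinates in digitization order (LM1 first).
    id : str
        Specimen/record identifier.
    side : {"left", "right"}, optional
    anchor_type : {"ventral", "dorsal"}, optional
    """

    coords: np.ndarray
    id: str = ""
    side: str | None = None
    anchor_type: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (n, 2); got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in configuration {self.id!r}")
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}; got {self.side!r}")
        if self.anchor_type is not None and self.anchor_type not in ANCHOR_TYPES:
            raise ValueError(
                f"anchor_type must be one of {ANCHOR_TYPES}; got {self.anchor_type!r}"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def landmark_types(self) -> dict[int, str]:
        """1-based landmark index -> 'I' or 'III' (defined for 11-landmark anchors)."""
        return {i: ("I" if i in TYPE_I else "III") for i in range(1, self.n_landmarks + 1)}

    def landmark(self, index: int) -> np.ndarray:
        """Coordinates of the 1-based landmark ``index``."""
        if not 1 <= index <= self.n_landmarks:
            raise IndexError(f"landmark index {index} out of range 1..{self.n_landmarks}")
        return self.coords[index - 1]

    def replace(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            coords=coords, id=self.id, side=self.side, anchor_type=self.anchor_type
        )


@dataclass
class SpecimenRecord:
    """One specimen: four anchors plus metadata.

    ``anchors`` maps (anchor_type, side) to a :class:`LandmarkConfiguration`,
    e.g. ``("ventral", "left")``.
    """

    id: str
    species: str
    anchors: dict[tuple[str, str], LandmarkConfiguration] = field(default_factory=dict)
    body_length: float | None = None
    body_width: float | None = None
    quality: "object | None" = None  # QualityReport, set by quality_control

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"specimen {self.id!r} has an empty species label")

    def anchor(self, anchor_type: str, side: str) -> LandmarkConfiguration:
        key = (anchor_type, side)
        if key not in self.anchors:
            raise KeyError(f"specimen {self.id!r} is missing the {side} {anchor_type} anchor")
        return self.anchors[key]

    @property
    def complete(self) -> bool:
        return all((a, s) in self.anchors for a in ANCHOR_TYPES for s in SIDES)


@dataclass(frozen=True)
class UnitConversion:
    """Affine calibration from arbitrary digitizer units to micrometres."""

    slope: float = 0.2
    intercept: float = 0.9

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("conversion slope must be positive")

    def __call__(self, d):
        return convert_units(d, self)


# ---------------------------------------------------------------------------
# TPS input/output

_KNOWN_KEYS = {"LM", "ID", "IMAGE", "SCALE"}


def read_tps(path, expected_landmarks: int = N_LANDMARKS) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Accepts the common TPS dialect: an ``LM=n`` line opens each record,
    followed by ``n`` whitespace-separated coordinate lines and optional
    ``ID=``, ``IMAGE=``, ``SCALE=`` keys. ``SCALE=`` is applied
    multiplicatively to the record's coordinates. Unknown keys are skipped
    with a logged warning.

    Raises
    ------
    TpsParseError
        If a record's landmark count differs from ``expected_landmarks``
        (message names the record) or a coordinate is non-numeric (message
        gives the line number).
    """
    with open(path) as fh:
        lines = fh.readlines()

    configs: list[LandmarkConfiguration] = []
    record: dict | None = None

    def finish(rec: dict) -> None:
        rec_id = rec["id"] if rec["id"] is not None else rec.get("image") or f"record{len(configs) + 1}"
        coords = np.asarray(rec["coords"], dtype=float)
        if coords.shape[0] != rec["n"]:
            raise TpsParseError(
                f"record {rec_id!r}: LM={rec['n']} but {coords.shape[0]} coordinate lines"
            )
        if rec["n"] != expected_landmarks:
            raise TpsParseError(
                f"record {rec_id!r}: has {rec['n']} landmarks, expected {expected_landmarks}"
            )
        if rec["scale"] is not None:
            coords = coords * rec["scale"]
        configs.append(LandmarkConfiguration(coords=coords, id=str(rec_id)))

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        key, eq, value = line.partition("=")
        if eq and key.strip().upper().isalpha():
            key = key.strip().upper()
            value = value.strip()
            if key == "LM":
                if record is not None:
                    finish(record)
                try:
                    n = int(value)
                except ValueError as exc:
                    raise TpsParseError(f"line {lineno}: bad LM count {value!r}") from exc
                record = {"n": n, "coords": [], "id": None, "image": None, "scale": None}
            elif record is None:
                raise TpsParseError(f"line {lineno}: key {key}= before any LM= record")
            elif key == "ID":
                record["id"] = value
            elif key == "IMAGE":
                record["image"] = value
            elif key == "SCALE":
                try:
                    record["scale"] = float(value)
                except ValueError as exc:
                    raise TpsParseError(f"line {lineno}: bad SCALE value {value!r}") from exc
            else:
                logger.warning("TPS line %d: ignoring unknown key %s=", lineno, key)
        else:
            if record is None:
                raise TpsParseError(f"line {lineno}: coordinates before any LM= record")
            parts = line.split()
            if len(parts) != 2:
                raise TpsParseError(f"line {lineno}: expected two coordinates, got {line!r}")
            try:
                xy = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TpsParseError(f"line {lineno}: non-numeric coordinate in {line!r}") from exc
            record["coords"].append(xy)

    if record is not None:
        finish(record)
    return configs


def write_tps(configs, path) -> None:
    """Write configurations to a TPS file at full float precision (round-trip safe)."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.n_landmarks}\n")
            for x, y in cfg.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={cfg.id}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read a specimen metadata CSV with columns id, species[, body_length, body_width]."""
    df = pd.read_csv(path, dtype={"id": str, "species": str})
    missing = {"id", "species"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing required columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Size variables

def pairwise_distances(config: LandmarkConfiguration | np.ndarray) -> np.ndarray:
    """All 55 pairwise inter-landmark Euclidean distances of an 11-landmark anchor.

    Distances are ordered lexicographically by 1-based landmark pair:
    (1,2), (1,3), ..., (10,11) — see :data:`PAIR_ORDER`. The vector is
    invariant under rotation, translation and reflection of the input.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return pdist(coords)  # scipy's condensed order == lexicographic pair order


def convert_units(d, conversion: UnitConversion | None = None):
    """Convert distances in arbitrary units to micrometres (elementwise).

    Applies the affine law ``µm = slope * d + intercept`` with the shipped
    calibration slope 0.2 and intercept 0.9 unless another
    :class:`UnitConversion` is supplied. Negative inputs are rejected
    (distances are nonnegative by construction).
    """
    conv = conversion or UnitConversion()
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distances must be nonnegative")
    out = conv.slope * arr + conv.intercept
    return float(out) if np.isscalar(d) or arr.ndim == 0 else out


def fit_unit_conversion(arbitrary, physical) -> UnitConversion:
    """Refit the affine unit calibration by OLS of physical (µm) on arbitrary units."""
    arbitrary = np.asarray(arbitrary, float)
    physical = np.asarray(physical, float)
    if arbitrary.shape != physical.shape or arbitrary.size < 2:
        raise ValueError("need >= 2 paired measurements")
    res = stats.linregress(arbitrary, physical)
    return UnitConversion(slope=float(res.slope), intercept=float(res.intercept))


def log_body_size(length_um: float, width_um: float) -> float:
    """log10(body length x body width), the body-size covariate.

    Intended to be applied to per-species *medians* of length and width
    (medians damp fixation-distortion outliers).
    """
    if length_um <= 0 or width_um <= 0:
        raise ValueError("body length and width must be positive")
    return float(np.log10(length_um * width_um))


def species_log_body_size(meta: pd.DataFrame) -> pd.Series:
    """Per-species log10(median length x median width) from a metadata table."""
    med = meta.groupby("species")[["body_length", "body_width"]].median()
    return pd.Series(
        {sp: log_body_size(r.body_length, r.body_width) for sp, r in med.iterrows()},
        name="log_body_size",
    )
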