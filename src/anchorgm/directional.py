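"""Directional statistics of per-landmark evolutionary shape change.

Each species' mean aligned configuration is compared landmark by landmark
with the estimated root-ancestor configuration; the displacement of a
landmark is summarized by its direction (angle from the +x axis,
counterclockwise) and magnitude. Within a clade, the Rayleigh test asks
whether the displacement directions of a landmark across species deviate
from circular uniformity — a signature of a clade-wide trend. Comparing
per-clade mean directions between landmark pairs drives the screen for new
morphometric characters: a pair whose mean directions diverge in one clade
but converge in the other yields an inter-landmark distance that separates
the clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from anchorgm.landmark_io import TYPE_I
from anchorgm.phylo import Phylogeny, bm_ancestral_states
from anchorgm.procrustes import row_to_config

logger = logging.getLogger(__name__)

_MAG_EPS = 1e-12


def displacement_vectors(
    species_means: pd.DataFrame, ancestor: np.ndarray
) -> pd.DataFrame:
    """Per-species, per-landmark displacement from the ancestral configuration.

    Parameters
    ----------
    species_means : DataFrame
        Species x 2k coordinate matrix (one anchor type; columns
        x1,y1,...,xk,yk order).
    ancestor : (k, 2) array
        Root configuration estimated on the same alignment.

    Returns a long table (species, landmark, angle, magnitude, defined);
    the angle is flagged undefined when the magnitude is below 1e-12.
    Rotating every configuration (species and ancestor alike) by an angle
    phi rotates all defined angles by phi.
    """
    ancestor = np.asarray(ancestor, float)
    k = ancestor.shape[0]
    if species_means.shape[1] != 2 * k:
        raise ValueError(
            f"species means have {species_means.shape[1]} columns; expected {2 * k}"
        )
    rows = []
    for sp, row in species_means.iterrows():
        config = row_to_config(row.to_numpy())
        delta = config - ancestor
        mags = np.hypot(delta[:, 0], delta[:, 1])
        angles = np.arctan2(delta[:, 1], delta[:, 0])
        for i in range(k):
            defined = mags[i] >= _MAG_EPS
            rows.append(
                {
                    "species": sp,
                    "landmark": i + 1,
                    "angle": angles[i] if defined else np.nan,
                    "magnitude": mags[i],
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


def rayleigh_test(
    angles,
    method: str = "approx",
    n_mc: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns (Rbar, p).

    Rbar is the mean resultant length |sum exp(i*theta)| / n. The default
    p uses the standard series approximation

        p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    with Z = n Rbar^2, clamped into (0, 1]. For the small per-clade sample
    sizes typical of this analysis (6-7 species) the approximation is
    rough; ``method="montecarlo"`` replaces it with the exact-null
    proportion of ``n_mc`` uniform-angle draws with Rbar at least as large.
    """
    angles = np.asarray(angles, float)
    angles = angles[np.isfinite(angles)]
    n = angles.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 defined angles")
    Rbar = float(np.abs(np.exp(1j * angles).sum()) / n)
    if method == "montecarlo":
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        sim = rng.uniform(0, 2 * np.pi, size=(n_mc, n))
        Rbar_null = np.abs(np.exp(1j * sim).sum(axis=1)) / n
        p = float((np.sum(Rbar_null >= Rbar) + 1) / (n_mc + 1))
    elif method == "approx":
        Z = n * Rbar**2
        p = float(
            np.exp(-Z)
            * (
                1.0
                + (2 * Z - Z**2) / (4 * n)
                - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n**2)
            )
        )
        p = min(max(p, np.finfo(float).tiny), 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Rbar, p


@dataclass
class CircularSummary:
    """Circular summary of one landmark's displacement directions in a clade."""

    clade: str
    landmark: int
    angles: np.ndarray
    magnitudes: np.ndarray
    n: int
    Rbar: float
    mean_direction: float | None  # radians; None when Rbar == 0
    mean_magnitude: float
    p: float


def clade_directional_summary(
    species_means: pd.DataFrame,
    phylo: Phylogeny,
    clades: dict[str, str] | pd.Series,
    rayleigh_method: str = "approx",
    rng=None,
) -> tuple[list[CircularSummary], pd.DataFrame, np.ndarray]:
    """Per-clade, per-landmark circular summaries against the root ancestor.

    The root configuration is estimated by BM ancestral reconstruction from
    the species mean coordinates; displacement angles are pooled across the
    species of each clade at every landmark and Rayleigh-tested. Returns
    the summaries, a tidy table (for circular plots and wireframe-lollipop
    layers: clade, landmark, n, Rbar, mean_direction, mean_magnitude, p),
    and the ancestral (k, 2) wireframe.
    """
    clades = pd.Series(clades)
    anc = bm_ancestral_states(phylo, species_means)
    root = row_to_config(anc.loc["root"].to_numpy())
    disp = displacement_vectors(species_means, root)
    disp["clade"] = disp["species"].map(clades)
    if disp["clade"].isna().any():
        missing = sorted(disp.loc[disp["clade"].isna(), "species"].unique())
        raise ValueError(f"species without clade assignment: {missing}")

    summaries: list[CircularSummary] = []
    for clade, sub in disp.groupby("clade", sort=True):
        if sub["species"].nunique() < 2:
            raise ValueError(f"clade {clade!r} has fewer than 2 species")
        for lm, lmsub in sub.groupby("landmark", sort=True):
            angles = lmsub.loc[lmsub["defined"], "angle"].to_numpy()
            mags = lmsub["magnitude"].to_numpy()
            if angles.size < 2:
                # landmark essentially at the ancestral position for the clade
                logger.warning(
                    "clade %s LM%d: fewer than 2 defined displacement directions", clade, lm
                )
                summaries.append(
                    CircularSummary(
                        clade=str(clade), landmark=int(lm), angles=angles,
                        magnitudes=mags, n=angles.size, Rbar=np.nan,
                        mean_direction=None, mean_magnitude=float(mags.mean()), p=np.nan,
                    )
                )
                continue
            Rbar, p = rayleigh_test(angles, method=rayleigh_method, rng=rng)
            if Rbar > 0:
                mean_dir = float(np.angle(np.exp(1j * angles).sum()))
            else:
                mean_dir = None
            summaries.append(
                CircularSummary(
                    clade=str(clade),
                    landmark=int(lm),
                    angles=angles,
                    magnitudes=mags,
                    n=angles.size,
                    Rbar=Rbar,
                    mean_direction=mean_dir,
                    mean_magnitude=float(mags.mean()),
                    p=p,
                )
            )
    table = pd.DataFrame(
        [
            {
                "clade": s.clade,
                "landmark": s.landmark,
                "n": s.n,
                "Rbar": s.Rbar,
                "mean_direction": np.nan if s.mean_direction is None else s.mean_direction,
                "mean_magnitude": s.mean_magnitude,
                "p": s.p,
            }
            for s in summaries
        ]
    )
    return summaries, table, root


def _angular_separation(a: float, b: float) -> float:
    """Minor-arc separation between two directions, in radians (0..pi)."""
    d = abs(a - b) % (2 * np.pi)
    return min(d, 2 * np.pi - d)


def divergence_screen(
    summary_table: pd.DataFrame,
    typeI_only: bool = True,
    diverge_min: float = 90.0,
    converge_max: float = 45.0,
) -> pd.DataFrame:
    """Screen landmark pairs for clade-contrasting directional change.

    For each landmark pair the angular separation of the two landmarks'
    mean directions (minor arc) is computed within each of exactly two
    clades; pairs separated by at least ``diverge_min`` degrees in one
    clade and at most ``converge_max`` degrees in the other are flagged —
    their inter-landmark distance is a candidate discrete character. With
    ``typeI_only`` the search is restricted to the 15 pairs of Type I
    landmarks (the ones practical to measure). Pairs are ranked by the
    between-clade separation contrast, descending; pairs with an undefined
    mean direction are skipped with a warning.
    """
    clades = sorted(summary_table["clade"].unique())
    if len(clades) != 2:
        raise ValueError(f"divergence screen needs exactly 2 clades; got {clades}")
    mean_dirs = {
        (row["clade"], int(row["landmark"])): row["mean_direction"]
        for _, row in summary_table.iterrows()
    }
    landmarks = sorted(summary_table["landmark"].unique())
    if typeI_only:
        landmarks = [lm for lm in landmarks if lm in TYPE_I]
    rows = []
    for i, j in combinations(landmarks, 2):
        seps = {}
        skip = False
        for clade in clades:
            di, dj = mean_dirs.get((clade, i), np.nan), mean_dirs.get((clade, j), np.nan)
            if not (np.isfinite(di) and np.isfinite(dj)):
                logger.warning("pair (LM%d, LM%d): undefined mean direction in clade %s; skipped", i, j, clade)
                skip = True
                break
            seps[clade] = np.degrees(_angular_separation(di, dj))
        if skip:
            continue
        s1, s2 = seps[clades[0]], seps[clades[1]]
        flagged = (s1 >= diverge_min and s2 <= converge_max) or (
            s2 >= diverge_min and s1 <= converge_max
        )
        rows.append(
            {
                "landmark_i": i,
                "landmark_j": j,
                f"separation_{clades[0]}": s1,
                f"separation_{clades[1]}": s2,
                "contrast": abs(s1 - s2),
                "flagged": flagged,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values(
        ["flagged", "contrast"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
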