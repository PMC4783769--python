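import numpy as np
import pandas as pd
import pytest

import anchorgm as agm
from anchorgm.procrustes import config_to_row


def _means_frame(configs: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        {sp: config_to_row(c) for sp, c in configs.items()}
    ).T.set_axis([f"c{i}" for i in range(22)], axis=1)


class TestDisplacementVectors:
    def test_zero_displacement_flagged_undefined(self):
        anc = agm.template_anchor().coords
        means = _means_frame({"s1": anc.copy()})
        out = agm.displacement_vectors(means, anc)
        assert not out["defined"].any()
        np.testing.assert_allclose(out["magnitude"], 0.0)

    def test_vertical_displacement_angle(self):
        anc = agm.template_anchor().coords
        moved = anc.copy()
        moved[2] += [0.0, 0.1]
        out = agm.displacement_vectors(_means_frame({"s1": moved}), anc)
        row = out[(out["landmark"] == 3)].iloc[0]
        assert row["angle"] == pytest.approx(np.pi / 2)
        assert row["magnitude"] == pytest.approx(0.1)

    def test_common_rotation_rotates_all_angles(self, rng):
        anc = agm.template_anchor().coords
        moved = anc + rng.normal(0, 1.0, size=(11, 2))
        phi = 0.9
        R = np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
        out1 = agm.displacement_vectors(_means_frame({"s": moved}), anc)
        out2 = agm.displacement_vectors(_means_frame({"s": moved @ R}), anc @ R)
        d = (out2["angle"] - out1["angle"] - phi + np.pi) % (2 * np.pi) - np.pi
        np.testing.assert_allclose(d, 0.0, atol=1e-9)


class TestRayleigh:
    def test_identical_angles_maximal_concentration(self):
        Rbar, p = agm.rayleigh_test([0.3] * 6)
        assert Rbar == pytest.approx(1.0)
        assert p < 0.01

    def test_antipodal_pair_cancels(self):
        Rbar, p = agm.rayleigh_test([0.0, np.pi])
        assert Rbar == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_series_approximation_close_to_monte_carlo_null(self):
        # oracle: exact-null tail probabilities from 100,000 uniform draws, n=6
        rng = np.random.default_rng(123)
        n, n_mc = 6, 100_000
        sims = rng.uniform(0, 2 * np.pi, size=(n_mc, n))
        Rbar_null = np.abs(np.exp(1j * sims).sum(axis=1)) / n
        for Rbar in (0.3, 0.5, 0.7, 0.9):
            Z = n * Rbar**2
            p_approx = np.exp(-Z) * (
                1 + (2 * Z - Z**2) / (4 * n)
                - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n**2)
            )
            p_mc = np.mean(Rbar_null >= Rbar)
            assert abs(p_approx - p_mc) < 0.02

    def test_montecarlo_option_agrees_with_approx(self):
        angles = np.random.default_rng(3).uniform(0, 2 * np.pi, 7)
        _, p_a = agm.rayleigh_test(angles)
        _, p_mc = agm.rayleigh_test(angles, method="montecarlo", n_mc=50_000, rng=1)
        assert abs(p_a - p_mc) < 0.03

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            agm.rayleigh_test([0.1])


def _clade_setup(drift_lm=None, drift=(2.0, 0.0), seed=0):
    """Two 4-species clades around the template; optionally add a common
    drift vector at one landmark (1-based) in clade I."""
    rng = np.random.default_rng(seed)
    tips = [f"s{i}" for i in range(8)]
    tree = agm.Phylogeny.from_newick("(" + ",".join(f"{t}:1" for t in tips) + ");")
    anc = agm.template_anchor().coords
    configs = {}
    for i, sp in enumerate(tips):
        c = anc + rng.normal(0, 0.5, size=(11, 2))
        if drift_lm is not None and i < 4:
            c[drift_lm - 1] += np.asarray(drift)
        configs[sp] = c
    clades = {sp: ("I" if i < 4 else "II") for i, sp in enumerate(tips)}
    return _means_frame(configs), tree, clades


class TestCladeSummary:
    def test_planted_drift_detected_at_target_landmark(self):
        means, tree, clades = _clade_setup(drift_lm=5, drift=(4.0, 0.0), seed=1)
        _, table, _ = agm.clade_directional_summary(means, tree, clades)
        clade1 = table[table["clade"] == "I"].set_index("landmark")
        assert clade1.loc[5, "p"] < 0.05
        assert (clade1.drop(index=5)["p"] > 0.05).mean() > 0.7

    def test_cardinal_directions_cancel(self):
        anc = agm.template_anchor().coords
        tips = [f"s{i}" for i in range(4)]
        tree = agm.Phylogeny.from_newick("(" + ",".join(f"{t}:1" for t in tips) + ");")
        configs = {}
        for sp, d in zip(tips, [(1, 0), (-1, 0), (0, 1), (0, -1)]):
            c = anc.copy()
            c[0] += np.asarray(d, float)
            c[1] += [0.5, 0.5]  # keep other landmarks defined
            configs[sp] = c
        clades = {sp: "I" for sp in tips}
        _, table, _ = agm.clade_directional_summary(_means_frame(configs), tree, clades)
        lm1 = table[(table["clade"] == "I") & (table["landmark"] == 1)].iloc[0]
        assert lm1["Rbar"] == pytest.approx(0.0, abs=1e-9)

    def test_summaries_invariant_to_species_order(self):
        means, tree, clades = _clade_setup(seed=4)
        _, t1, _ = agm.clade_directional_summary(means, tree, clades)
        _, t2, _ = agm.clade_directional_summary(means.iloc[::-1], tree, clades)
        pd.testing.assert_frame_equal(t1, t2)

    def test_small_clade_rejected(self):
        means, tree, clades = _clade_setup(seed=2)
        clades = dict(clades)
        lone = list(clades)[0]
        clades[lone] = "III"
        with pytest.raises(ValueError, match="fewer than 2"):
            agm.clade_directional_summary(means, tree, clades)


class TestDivergenceScreen:
    @staticmethod
    def _table(dirs_1: dict[int, float], dirs_2: dict[int, float]) -> pd.DataFrame:
        rows = []
        for clade, dirs in (("I", dirs_1), ("II", dirs_2)):
            for lm, d in dirs.items():
                rows.append(
                    {"clade": clade, "landmark": lm, "n": 4, "Rbar": 0.9,
                     "mean_direction": d, "mean_magnitude": 1.0, "p": 0.01}
                )
        return pd.DataFrame(rows)

    def test_maximal_contrast_pair_ranked_first(self):
        dirs_1 = {1: 0.0, 2: 0.2, 3: np.pi, 5: 0.1, 7: 0.15, 8: 0.05}
        dirs_2 = {lm: 0.0 for lm in (1, 2, 3, 5, 7, 8)}
        out = agm.divergence_screen(self._table(dirs_1, dirs_2))
        top = out.iloc[0]
        assert {top["landmark_i"], top["landmark_j"]} == {1, 3}
        assert top["flagged"]

    def test_common_direction_flags_nothing(self):
        dirs = {lm: 0.5 for lm in (1, 2, 3, 5, 7, 8)}
        out = agm.divergence_screen(self._table(dirs, dirs))
        assert not out["flagged"].any()

    def test_type_one_restriction_limits_pairs(self):
        dirs = {lm: 0.1 * lm for lm in range(1, 12)}
        out = agm.divergence_screen(self._table(dirs, dirs), typeI_only=True)
        assert len(out) == 15  # C(6, 2) pairs of Type I landmarks
        pairs = set(zip(out["landmark_i"], out["landmark_j"]))
        assert all(i in (1, 2, 3, 5, 7, 8) and j in (1, 2, 3, 5, 7, 8) for i, j in pairs)

    def test_planted_divergent_pairs_recovered_top_ranked(self):
        out = planted_contrast_screen()
        top_pairs = [
            frozenset((int(r["landmark_i"]), int(r["landmark_j"])))
            for _, r in out.head(2).iterrows()
        ]
        assert frozenset((1, 3)) in top_pairs
        assert frozenset((1, 5)) in top_pairs
        assert out.iloc[0]["flagged"] and out.iloc[1]["flagged"]

    def test_wrong_clade_count_rejected(self):
        t = self._table({1: 0.0, 3: 1.0}, {1: 0.0, 3: 1.0})
        with pytest.raises(ValueError):
            agm.divergence_screen(t[t["clade"] == "I"])


def planted_contrast_screen() -> pd.DataFrame:
    """Run the screen on data with a planted clade contrast.

    LM1 diverges from LM3 and LM5 in clade I (near-opposite directions)
    while all three move together in clade II.  The root estimate is a
    weighted mean of the tips, so the contrast is planted in low-weight
    (long-branch) species while high-weight short-branch "anchor" species
    in clade II pin the root at the template.
    """
    rng = np.random.default_rng(9)
    clade1 = [f"c1_{i}" for i in range(6)]  # long branches, divergent drift
    anchors = [f"c2a_{i}" for i in range(6)]  # short branches, no drift
    mobile = [f"c2m_{i}" for i in range(6)]  # long branches, coherent drift
    parts = (
        [f"{t}:25" for t in clade1]
        + [f"{t}:0.04" for t in anchors]
        + [f"{t}:25" for t in mobile]
    )
    tree = agm.Phylogeny.from_newick("(" + ",".join(parts) + ");")
    template = agm.template_anchor().coords

    def drift(angle_deg, mag=6.0):
        a = np.deg2rad(angle_deg)
        return mag * np.array([np.cos(a), np.sin(a)])

    configs = {}
    for sp in clade1 + anchors + mobile:
        c = template + rng.normal(0, 0.3, size=(11, 2))
        if sp in clade1:
            c[0] += drift(180)  # LM1
            c[2] += drift(0)  # LM3
            c[4] += drift(20)  # LM5
            for lm in (1, 6, 7):  # LM2, LM7, LM8 share one direction
                c[lm] += drift(250)
        elif sp in mobile:
            for lm in (0, 2, 4):  # clade II: LM1, LM3, LM5 move together
                c[lm] += drift(100)
            for lm in (1, 6, 7):
                c[lm] += drift(250)
        configs[sp] = c
    clades = {sp: "I" for sp in clade1} | {sp: "II" for sp in anchors + mobile}
    _, table, _ = agm.clade_directional_summary(_means_frame(configs), tree, clades)
    return agm.divergence_screen(table)
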