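"""LD clumping, direction curves, latitudinal clines, adaptive overlap."""

import numpy as np
import pandas as pd
import pytest

from introchron.chronotype import (
    ClumpedLocus,
    adaptive_overlap,
    direction_curve,
    latitudinal_cline,
    ld_clump,
)

from .oracles import pearson_r


def assoc_frame(rows):
    return pd.DataFrame(rows, columns=["variant", "chrom", "pos", "beta", "p"])


class TestLdClump:
    def test_single_variant_is_its_own_locus(self):
        loci = ld_clump(assoc_frame([("v1", "chr1", 100, 0.1, 1e-9)]), {})
        assert len(loci) == 1
        assert loci[0].members == ("v1",)

    def test_greedy_from_smallest_p(self):
        df = assoc_frame(
            [
                ("v1", "chr1", 1000, 0.1, 1e-9),
                ("v2", "chr1", 2000, 0.1, 1e-8),
                ("v3", "chr1", 3000, 0.1, 1e-7),
            ]
        )
        ld = {("v1", "v2"): 0.8, ("v1", "v3"): 0.1, ("v2", "v3"): 0.9}
        loci = ld_clump(df, ld)
        assert [set(l.members) for l in loci] == [{"v1", "v2"}, {"v3"}]
        assert loci[0].index_variant == "v1"

    def test_equal_p_tie_broken_by_position(self):
        df = assoc_frame(
            [("b", "chr1", 2000, 0.1, 1e-8), ("a", "chr1", 1000, 0.1, 1e-8)]
        )
        loci = ld_clump(df, {})
        assert loci[0].index_variant == "a"

    def test_r2_threshold_strict(self):
        df = assoc_frame(
            [("v1", "chr1", 1000, 0.1, 1e-9), ("v2", "chr1", 2000, 0.1, 1e-8)]
        )
        loci = ld_clump(df, {("v1", "v2"): 0.5})  # exactly at threshold: not absorbed
        assert len(loci) == 2

    def test_window_limits_absorption(self):
        df = assoc_frame(
            [("v1", "chr1", 1000, 0.1, 1e-9), ("v2", "chr1", 400_000, 0.1, 1e-8)]
        )
        loci = ld_clump(df, {("v1", "v2"): 0.99})
        assert len(loci) == 2

    def test_loci_partition_input(self, rng):
        n = 60
        df = assoc_frame(
            [
                (f"v{i}", "chr1", 1000 + 5_000 * i, float(rng.normal()),
                 float(rng.uniform(1e-10, 1)))
                for i in range(n)
            ]
        )
        ld = {}
        for i in range(n):
            for j in range(i + 1, n):
                ld[(f"v{i}", f"v{j}")] = float(rng.random())
        loci = ld_clump(df, ld)
        members = [m for l in loci for m in l.members]
        assert sorted(members) == sorted(df["variant"])
        assert len(members) == len(set(members))

    def test_index_has_minimum_p_among_members(self, rng):
        df = assoc_frame(
            [
                (f"v{i}", "chr1", 1000 + 2_000 * i, 0.1, float(rng.uniform(1e-9, 1)))
                for i in range(30)
            ]
        )
        ld = {
            (f"v{i}", f"v{j}"): float(rng.random())
            for i in range(30)
            for j in range(i + 1, 30)
        }
        p_of = dict(zip(df["variant"], df["p"]))
        for locus in ld_clump(df, ld):
            assert locus.p == min(p_of[m] for m in locus.members)


def locus(vid, p, beta, pos=0):
    return ClumpedLocus(vid, "chr1", pos, p, beta, (vid,))


class TestDirectionCurve:
    def test_all_morning_fraction_one(self):
        loci = [locus(f"v{i}", 10.0 ** -(9 - i), 0.2) for i in range(4)]
        curve = direction_curve(loci)
        assert (curve["cum_fraction"] == 1.0).all()

    def test_alternating_signs(self):
        loci = [
            locus("v1", 1e-9, +0.1),
            locus("v2", 1e-8, -0.1),
            locus("v3", 1e-7, +0.1),
            locus("v4", 1e-6, -0.1),
        ]
        curve = direction_curve(loci)
        assert list(curve["cum_fraction"]) == pytest.approx([1.0, 0.5, 2 / 3, 0.5])

    def test_final_rank_equals_overall_fraction(self, rng):
        loci = [
            locus(f"v{i}", float(rng.uniform(1e-9, 1)), float(rng.normal()), pos=i)
            for i in range(50)
        ]
        curve = direction_curve(loci)
        overall = np.mean([l.beta > 0 for l in loci])
        assert curve["cum_fraction"].iloc[-1] == pytest.approx(overall)

    def test_sign_convention_configurable(self):
        loci = [locus("v1", 1e-9, -0.3)]
        assert direction_curve(loci, positive_is_morning=False)["cum_fraction"].iloc[0] == 1.0

    def test_empty_input(self):
        assert len(direction_curve([])) == 0


class TestCline:
    def lat_frame(self, freqs, lats=(6.9, 16.5, 23.2, 40.4, 52.4)):
        return pd.DataFrame(
            {
                "population": [f"P{i}" for i in range(len(lats))],
                "frequency": freqs,
                "latitude": lats,
            }
        )

    def test_exact_linear_cline_passes(self):
        lats = np.array([6.9, 16.5, 23.2, 40.4, 52.4])
        call = latitudinal_cline(self.lat_frame(0.01 * lats))
        assert call.passed
        assert call.result.pearson_r == pytest.approx(1.0)

    def test_constant_frequency_degenerate_fail(self):
        call = latitudinal_cline(self.lat_frame([0.3] * 5))
        assert not call.passed
        assert "constant_frequency" in call.flags

    def test_r_matches_closed_form(self):
        freqs = [0.12, 0.10, 0.22, 0.25, 0.41]
        call = latitudinal_cline(self.lat_frame(freqs))
        expected = pearson_r([6.9, 16.5, 23.2, 40.4, 52.4], freqs)
        assert call.result.pearson_r == pytest.approx(expected, rel=1e-12)

    def test_r_invariant_under_affine_latitude_rescaling(self):
        freqs = [0.12, 0.10, 0.22, 0.25, 0.41]
        base = latitudinal_cline(self.lat_frame(freqs))
        df = self.lat_frame(freqs)
        df["latitude"] = df["latitude"] * 1.8 + 32  # degrees -> odd affine units
        rescaled = latitudinal_cline(df)
        assert rescaled.result.pearson_r == pytest.approx(base.result.pearson_r)

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError):
            latitudinal_cline(self.lat_frame([0.1, 0.2], lats=(10, 20)))


class TestAdaptiveOverlap:
    def regions(self, score):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200], "score": [score]}
        )

    def test_score_at_threshold_included(self):
        out = adaptive_overlap(
            {"v": ("chr1", 150)}, {"v": ["G1"]}, {"cnn_method": self.regions(0.5)}
        )
        assert list(out["gene"]) == ["G1"]

    def test_score_below_threshold_excluded(self):
        out = adaptive_overlap(
            {"v": ("chr1", 150)}, {"v": ["G1"]}, {"cnn_method": self.regions(0.49)}
        )
        assert len(out) == 0

    def test_two_methods_union(self):
        out = adaptive_overlap(
            {"v": ("chr1", 150)},
            {"v": ["G1"]},
            {"cnn_method": self.regions(0.9), "extra_trees_method": self.regions(0.95)},
        )
        assert out.loc[out["gene"] == "G1", "n_methods"].iloc[0] == 2

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adaptive_overlap({}, {}, {"mystery": self.regions(1.0)})
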