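"""Per-core features: entropies, interaction counts, densities, geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from conftest import code, naive_pair_counts
from tmediv.diversity import (
    cd21_area_fraction,
    cell_density,
    count_interactions,
    immune_ratio,
    interaction_entropy,
    phenotype_distribution,
    profile_core,
    shannon_entropy,
)
from tmediv.errors import GeometryError, ValidationError
from tmediv.phenotypes import CD21_ONLY, DAPI_ONLY


class TestPhenotypeDistribution:
    def test_single_label(self, make_core):
        core = make_core([(i * 10.0, 0.0, {"CD8"}) for i in range(10)])
        dist = phenotype_distribution(core)
        assert dist.n_cells == 10
        assert dist.proportions == {code("CD8"): 1.0}

    def test_reserved_classes_excluded(self, make_core):
        core = make_core(
            [(0, 0, set()), (10, 0, set()), (20, 0, {"CD21"}), (30, 0, {"CD4"})]
        )
        dist = phenotype_distribution(core)
        assert dist.n_cells == 1
        assert dist.proportions == {code("CD4"): 1.0}

    def test_proportions_match_multiset(self, make_core):
        rng = np.random.default_rng(42)
        subsets = [set(), {"CD4"}, {"CD8"}, {"CD4", "FOXP3"}, {"CD21"}]
        draws = rng.integers(0, len(subsets), 100)
        core = make_core(
            [(float(i), float(i % 7), subsets[k]) for i, k in enumerate(draws)]
        )
        dist = phenotype_distribution(core)
        # direct counting oracle over the generated multiset
        kept = [k for k in draws if subsets[k] not in (set(), {"CD21"})]
        assert dist.n_cells == len(kept)
        from collections import Counter

        want = Counter(tuple(sorted(subsets[k])) for k in kept)
        got = {
            tuple(sorted(s)): n
            for s, n in (
                (frozenset(m for m in ("CD4", "CD8", "CD68", "FOXP3", "PD-1")
                           if f"{m}+" in lbl), cnt)
                for lbl, cnt in dist.counts.items()
            )
        }
        assert got == {tuple(k): v for k, v in want.items()}


class TestShannonEntropy:
    def test_uniform_32_is_ln32(self):
        p = {f"lab{i}": 1 / 32 for i in range(32)}
        assert shannon_entropy(p) == pytest.approx(math.log(32), abs=1e-12)

    def test_single_class_zero(self, make_core):
        core = make_core([(0, 0, {"CD4"}), (10, 0, {"CD4"})])
        assert shannon_entropy(phenotype_distribution(core)) == 0.0

    def test_hand_value_half_quarter_quarter(self):
        got = shannon_entropy({"a": 0.5, "b": 0.25, "c": 0.25})
        want = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))  # = 1.0397...
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(1.0397, abs=1e-4)

    def test_degenerate_cores_zero(self, make_core):
        assert shannon_entropy(phenotype_distribution(make_core([]))) == 0.0
        one = make_core([(0, 0, {"CD8"})])
        assert shannon_entropy(phenotype_distribution(one)) == 0.0


class TestInteractions:
    def test_single_cross_pair(self, make_core):
        core = make_core([(0, 0, {"CD4"}), (20, 0, {"CD8"})])
        ic = count_interactions(core, 30.0)
        assert ic.counts == {(code("CD4"), code("CD8")): 1}

    def test_three_mutually_close_same_label(self, make_core):
        core = make_core([(0, 0, {"CD8"}), (10, 0, {"CD8"}), (5, 5, {"CD8"})])
        ic = count_interactions(core, 30.0)
        assert ic.counts == {(code("CD8"), code("CD8")): 3}

    def test_exact_radius_is_counted(self, make_core):
        core = make_core([(0.0, 0.0, {"CD4"}), (30.0, 0.0, {"CD8"})])
        assert count_interactions(core, 30.0).n_pairs == 1
        assert count_interactions(core, 29.999).n_pairs == 0

    def test_dapi_only_ignored_but_cd21_only_included(self, make_core):
        core = make_core([(0, 0, set()), (10, 0, {"CD4"}), (20, 0, {"CD21"})])
        ic = count_interactions(core, 30.0)
        assert tuple(sorted((code("CD4"), CD21_ONLY))) in ic.counts
        assert all(DAPI_ONLY not in k for k in ic.counts)

    def test_nonpositive_radius_rejected(self, make_core):
        with pytest.raises(ValidationError):
            count_interactions(make_core([(0, 0, {"CD4"})]), 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_all_pairs_oracle(self, make_core, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 120))
        subsets = [{"CD4"}, {"CD8"}, {"CD68"}, {"CD4", "PD-1"}, set(), {"CD21"}]
        specs = [
            (float(rng.uniform(0, 300)), float(rng.uniform(0, 300)),
             subsets[rng.integers(len(subsets))])
            for _ in range(n)
        ]
        core = make_core(specs)
        ic = count_interactions(core, 30.0)
        kept = core.cells[core.cells["phenotype"] != DAPI_ONLY]
        want = naive_pair_counts(
            kept[["x_um", "y_um"]].to_numpy(), kept["phenotype"].tolist(), 30.0
        )
        assert dict(ic.counts) == want

    def test_translation_and_rotation_invariance(self, make_core):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 200, (60, 2))
        labels = [{"CD4"} if i % 2 else {"CD8"} for i in range(60)]
        base = count_interactions(
            make_core([(x, y, s) for (x, y), s in zip(pts, labels)]), 30.0
        )
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([1000.0, -500.0])
        other = count_interactions(
            make_core([(x, y, s) for (x, y), s in zip(moved, labels)], side=1.0), 30.0
        )
        # rotation+translation preserves the pair-count multiset (floating
        # point can flip ties only at exactly the radius, absent here)
        assert dict(base.counts) == dict(other.counts)


class TestInteractionEntropy:
    def test_single_pair_type_zero(self, make_core):
        core = make_core([(0, 0, {"CD8"}), (10, 0, {"CD8"}), (5, 5, {"CD8"})])
        assert interaction_entropy(count_interactions(core, 30.0)) == 0.0

    def test_hand_value(self, make_core):
        # pair counts {XY:2, XX:1, YY:1} -> proportions (.5,.25,.25)
        core = make_core(
            [(0, 0, {"CD4"}), (10, 0, {"CD4"}), (100, 0, {"CD8"}), (110, 0, {"CD8"}),
             (5, 20, {"CD8"})]
        )
        # pairs within 30: (0,10)=XX, (100,110)=YY, (0,(5,20))=XY, (10,(5,20))=XY
        ic = count_interactions(core, 30.0)
        assert sorted(ic.counts.values()) == [1, 1, 2]
        assert interaction_entropy(ic) == pytest.approx(1.0397, abs=1e-4)

    def test_equal_counts_ln_k(self, make_core):
        core = make_core(
            [(0, 0, {"CD4"}), (10, 0, {"CD8"}), (200, 200, {"CD68"}), (210, 200, {"FOXP3"})]
        )
        ic = count_interactions(core, 30.0)
        assert ic.n_pairs == 2
        assert interaction_entropy(ic) == pytest.approx(math.log(2), abs=1e-12)

    def test_no_pairs_zero(self, make_core):
        core = make_core([(0, 0, {"CD4"}), (500, 500, {"CD8"})])
        assert interaction_entropy(count_interactions(core, 30.0)) == 0.0


class TestDensitiesAndRatios:
    def test_simple_density(self, make_core, panel):
        # 1000x1000 μm square = 1 mm²; 8 CD8+ cells -> 8 cells/mm²
        core = make_core([(i * 10.0, 5.0, {"CD8"}) for i in range(8)])
        assert cell_density(core, "CD8+", panel) == pytest.approx(8.0)

    def test_marker_subset_ignores_other_markers(self, make_core, panel):
        core = make_core([(0, 0, {"CD68"}), (10, 0, {"CD68", "CD8"})])
        assert cell_density(core, "CD68+", panel) == pytest.approx(2.0)

    def test_negative_term_excludes(self, make_core, panel):
        core = make_core([(0, 0, {"CD4"}), (10, 0, {"CD4", "CD68"})])
        assert cell_density(core, "CD4+CD68-", panel) == pytest.approx(1.0)

    def test_density_counting_oracle(self, make_core, panel):
        rng = np.random.default_rng(11)
        subsets = [set(), {"CD4"}, {"CD68"}, {"CD4", "CD68"}, {"CD8", "PD-1"}]
        picks = rng.integers(0, len(subsets), 200)
        core = make_core(
            [(float(rng.uniform(0, 900)), float(rng.uniform(0, 900)), subsets[k])
             for k in picks]
        )
        want = sum(1 for k in picks if "CD68" in subsets[k])
        assert cell_density(core, "CD68+", panel) == pytest.approx(want / 1.0)

    def test_immune_ratio(self, make_core):
        specs = [(i * 10.0, 0.0, {"CD4"}) for i in range(5)]
        specs += [(i * 10.0, 50.0, set()) for i in range(10)]
        specs += [(i * 10.0, 100.0, {"CD21"}) for i in range(3)]  # in neither term
        assert immune_ratio(make_core(specs)) == pytest.approx(0.5)

    def test_immune_ratio_zero_numerator(self, make_core):
        core = make_core([(i * 10.0, 0.0, set()) for i in range(10)])
        assert immune_ratio(core) == 0.0

    def test_immune_ratio_undefined_without_dapi_only(self, make_core):
        with pytest.raises(ValidationError):
            immune_ratio(make_core([(0, 0, {"CD4"})]))


class TestCd21Area:
    def test_no_polygons_zero(self, make_core):
        assert cd21_area_fraction(make_core([(0, 0, set())])) == 0.0

    def test_full_coverage_one(self, make_core):
        full = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        core = make_core([(0, 0, set())], cd21_polys=[full])
        assert cd21_area_fraction(core) == pytest.approx(1.0)

    def test_overlapping_squares_union(self, make_core):
        a = Polygon([(0, 0), (200, 0), (200, 200), (0, 200)])
        b = Polygon([(100, 0), (300, 0), (300, 200), (100, 200)])
        core = make_core([(0, 0, set())], cd21_polys=[a, b])
        # union area = 300x200 = 60000 μm² of the 10^6 μm² tissue square
        assert cd21_area_fraction(core) == pytest.approx(0.06)

    def test_self_intersecting_polygon_raises(self, make_core):
        bowtie = Polygon([(0, 0), (100, 100), (100, 0), (0, 100)])
        core = make_core([(0, 0, set())], cd21_polys=[bowtie])
        with pytest.raises(GeometryError):
            cd21_area_fraction(core)


class TestProfile:
    def _specs(self, rng, n=80):
        subsets = [set(), {"CD4"}, {"CD8"}, {"CD68"}, {"CD4", "FOXP3"}, {"CD21"}]
        return [
            (float(rng.uniform(0, 900)), float(rng.uniform(0, 900)),
             subsets[rng.integers(len(subsets))])
            for _ in range(n)
        ]

    def test_deterministic_and_order_invariant(self, make_core, panel):
        rng = np.random.default_rng(5)
        specs = self._specs(rng)
        a = profile_core(make_core(specs), panel)
        b = profile_core(make_core(specs), panel)
        shuffled = list(specs)
        np.random.default_rng(6).shuffle(shuffled)
        c = profile_core(make_core(shuffled), panel)
        for x in (b, c):
            assert x.phenotype_entropy == a.phenotype_entropy
            assert x.interaction_entropy == a.interaction_entropy
            assert x.density == a.density
            assert x.immune_ratio == a.immune_ratio

    def test_entropy_matches_generator_within_se(self, make_core, panel):
        # sampling oracle: plug-in entropy of a known mixture, bootstrap SE
        rng = np.random.default_rng(17)
        mix = [({"CD4"}, 0.5), ({"CD8"}, 0.25), ({"CD4", "FOXP3"}, 0.25)]
        probs = [p for _, p in mix]
        true_h = -sum(p * math.log(p) for p in probs)
        n = 600
        draws = rng.choice(len(mix), size=n, p=probs)
        specs = [
            (float(rng.uniform(0, 900)), float(rng.uniform(0, 900)), mix[k][0])
            for k in draws
        ]
        # tumour-like DAPI-only cells are excluded from the entropy but make
        # the immune ratio well-defined
        specs += [(float(rng.uniform(0, 900)), float(rng.uniform(0, 900)), set())
                  for _ in range(50)]
        prof = profile_core(make_core(specs), panel)
        boots = []
        for _ in range(200):
            res = draws[rng.integers(0, n, n)]
            counts = np.bincount(res, minlength=len(mix)) / n
            nz = counts[counts > 0]
            boots.append(-np.sum(nz * np.log(nz)))
        se = np.std(boots, ddof=1)
        assert abs(prof.phenotype_entropy - true_h) < 3 * se + 1e-9
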