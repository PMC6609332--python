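import io

import numpy as np
import pytest
from shapely.geometry import Polygon

import nprrquant as q
from nprrquant.emsim import CapacityError
from nprrquant.stereology import NM2_PER_UM2, filter_gold_aggregates

from ._oracles import assign_compartments_oracle


def _square_annotation(**kw):
    """2 um x 2 um image with a 1 um x 1 um bouton at its center."""
    defaults = dict(
        image_id="t",
        image_area_um2=4.0,
        gold=np.empty((0, 2)),
        dcv_centers=np.empty((0, 2)),
        bouton_outline=np.array(
            [[500, 500], [1500, 500], [1500, 1500], [500, 1500]], float
        ),
    )
    defaults.update(kw)
    return q.EMImageAnnotation(**defaults)


class TestAssignGoldCompartments:
    def test_priority_examples(self):
        ann = _square_annotation(
            dcv_centers=np.array([[1000.0, 1000.0]]),
            gold=np.array([
                [1000.0, 1000.0],   # at a DCV center -> dcv
                [1000.0, 1070.0],   # 70 nm from center, interior -> cytoplasm
                [1000.0, 510.0],    # 10 nm inside the outline -> membrane
                [1000.0, 490.0],    # 10 nm outside the outline -> membrane
                [100.0, 100.0],     # far outside -> outside
            ]),
        )
        labels = list(q.assign_gold_compartments(ann))
        assert labels == ["dcv", "cytoplasm", "membrane", "membrane", "outside"]

    def test_dcv_wins_over_membrane(self):
        # DCV disc touching the band: a particle in both regions is dcv
        ann = _square_annotation(dcv_centers=np.array([[560.0, 1000.0]]),
                                 gold=np.array([[515.0, 1000.0]]))
        assert list(q.assign_gold_compartments(ann)) == ["dcv"]

    def test_matches_brute_force_oracle_on_random_annotations(self):
        rng = np.random.default_rng(21)
        for seed in range(5):
            ann = q.simulate_em_annotation(q.EMSimParams(
                density_dcv=25, density_cytoplasm=8, density_membrane_band=20,
                density_outside=4, seed=seed))
            # add fully random positions to probe all regions
            extra = rng.uniform(0, 2000, size=(60, 2))
            ann = q.EMImageAnnotation(
                image_id=ann.image_id, image_area_um2=ann.image_area_um2,
                gold=np.vstack([ann.gold, extra]),
                dcv_centers=ann.dcv_centers,
                bouton_outline=ann.bouton_outline,
            )
            got = list(q.assign_gold_compartments(ann))
            assert got == assign_compartments_oracle(ann)

    def test_counts_partition_total(self):
        ann = q.simulate_em_annotation(q.EMSimParams(seed=3))
        labels = q.assign_gold_compartments(ann)
        assert len(labels) == len(ann.gold)
        rep = q.density_report([ann])
        assert sum(rep.counts.values()) == len(ann.gold)


class TestGridAreaEstimate:
    def test_empty_region_zero(self):
        assert q.grid_area_estimate(Polygon(), 50.0) == 0.0

    def test_unit_square_at_50nm(self):
        sq = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        est = q.grid_area_estimate(sq, 50.0)
        assert est == pytest.approx(1.0, rel=0.05)

    def test_spacing_larger_than_region_warns(self):
        sq = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        with pytest.warns(UserWarning, match="spacing"):
            q.grid_area_estimate(sq, 500.0)

    def test_halving_spacing_never_worsens_mean_error(self):
        rng = np.random.default_rng(5)
        polys = []
        while len(polys) < 20:
            n = 10
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(300, 900, n)
            p = Polygon(np.column_stack([1000 + rad * np.cos(ang),
                                         1000 + rad * np.sin(ang)]))
            if p.is_valid:
                polys.append(p)
        spacings = [200.0, 100.0, 50.0, 25.0]
        mean_err = [
            np.mean([abs(q.grid_area_estimate(p, s) - p.area / NM2_PER_UM2)
                     for p in polys])
            for s in spacings
        ]
        assert all(a >= b for a, b in zip(mean_err, mean_err[1:]))


class TestEMSimulation:
    def test_all_densities_zero_no_gold(self):
        ann = q.simulate_em_annotation(q.EMSimParams(
            density_dcv=0, density_cytoplasm=0, density_membrane_band=0,
            density_outside=0, seed=1))
        assert len(ann.gold) == 0

    def test_dcv_centers_respect_min_distance(self):
        ann = q.simulate_em_annotation(q.EMSimParams(n_dcv=15, seed=2))
        c = ann.dcv_centers
        d = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * ann.dcv_disc_radius

    def test_capacity_error_when_discs_cannot_fit(self):
        with pytest.raises(CapacityError):
            q.simulate_em_annotation(q.EMSimParams(
                image_area_um2=0.25, bouton_fraction=0.1, n_dcv=200, seed=0))

    def test_deterministic_given_seed(self):
        a = q.simulate_em_annotation(q.EMSimParams(seed=9))
        b = q.simulate_em_annotation(q.EMSimParams(seed=9))
        np.testing.assert_array_equal(a.gold, b.gold)
        np.testing.assert_array_equal(a.dcv_centers, b.dcv_centers)

    def test_mean_dcv_gold_matches_poisson_mean(self):
        """Across 200 seeds the mean DCV-disc gold count sits within 3 standard
        errors of density x total disc area."""
        params = q.EMSimParams(density_dcv=30.0, density_cytoplasm=0,
                               density_membrane_band=0, density_outside=0)
        counts = []
        for s in range(200):
            ann = q.simulate_em_annotation(params.with_(seed=s))
            counts.append(
                int((q.assign_gold_compartments(ann) == "dcv").sum())
            )
        lam = 30.0 * params.n_dcv * np.pi * params.dcv_disc_radius**2 / NM2_PER_UM2
        se = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) <= 3 * se


class TestDensityReport:
    def test_uniform_density_ratio_near_one(self):
        params = q.EMSimParams(density_dcv=10, density_cytoplasm=10,
                               density_membrane_band=10, density_outside=10)
        anns = [q.simulate_em_annotation(params.with_(seed=s)) for s in range(100)]
        rep = q.density_report(anns, grid_spacing=None)
        lam_d = 10 * rep.areas["dcv"]
        lam_c = 10 * rep.areas["cytoplasm"]
        half = 1.96 * np.sqrt(1 / lam_d + 1 / lam_c)
        assert np.exp(-half) <= rep.dcv_over_bouton_ratio <= np.exp(half)

    def test_area_partition_bound(self):
        ann = q.simulate_em_annotation(q.EMSimParams(seed=4))
        rep = q.density_report([ann], grid_spacing=None)
        poly_area = ann.polygon().area / NM2_PER_UM2
        outer_band = (ann.polygon().exterior.length
                      * ann.membrane_band_halfwidth / NM2_PER_UM2)
        lhs = rep.areas["dcv"] + rep.areas["cytoplasm"] + rep.areas["membrane"]
        assert lhs <= poly_area + outer_band + 1e-9 * poly_area

    def test_zero_cytoplasm_count_flags_infinite(self):
        ann = _square_annotation(dcv_centers=np.array([[1000.0, 1000.0]]),
                                 gold=np.array([[1000.0, 1000.0]]))
        rep = q.density_report([ann], grid_spacing=None)
        assert rep.counts["cytoplasm"] == 0
        assert np.isinf(rep.dcv_over_bouton_ratio)

    def test_summary_table_arithmetic(self):
        """Densities from a per-micrograph count table follow the counting
        formulas exactly (synthetic table, hand-checked numbers)."""
        csv = io.StringIO(
            "image_id,image_area_um2,n_dcv,gold_dcv,gold_cytoplasm,"
            "gold_membrane,gold_outside,bouton_area_um2\n"
            "a,4.0,10,30,10,5,2,1.0\n"
            "b,4.0,20,60,10,5,2,2.0\n"
        )
        import pandas as pd

        df = pd.read_csv(csv)
        rep = q.density_report_from_counts(df)
        dcv_area = 30 * np.pi * 50**2 / NM2_PER_UM2  # 30 discs pooled
        cyto_area = 3.0 - dcv_area
        expect = (90 / dcv_area) / (20 / cyto_area)
        assert rep.dcv_over_bouton_ratio == pytest.approx(expect)
        unsub = (90 / dcv_area) / (20 / 3.0)
        assert rep.ratio_unsubtracted == pytest.approx(unsub)


class TestBackgroundDensity:
    def test_zero_gold(self):
        dens, below = q.background_density([_square_annotation()])
        assert dens == 0.0 and below

    def test_simulated_control_within_poisson_ci(self):
        params = q.EMSimParams(density_dcv=0.3, density_cytoplasm=0.3,
                               density_membrane_band=0.3, density_outside=0.3)
        anns = [q.simulate_em_annotation(params.with_(seed=s)) for s in range(50)]
        dens, below = q.background_density(anns)
        area = sum(a.image_area_um2 for a in anns)
        lam = 0.3 * area
        half = 1.96 * np.sqrt(lam) / area
        assert abs(dens - 0.3) <= half + 0.3 * 0.05
        assert below  # under the 0.6 gold/um^2 ceiling

    def test_zero_area_raises(self):
        with pytest.raises(ValueError):
            q.background_density([])


class TestAggregateFilter:
    def test_cluster_collapses_to_centroid(self):
        cluster = np.array([[0, 0], [5, 0], [0, 5], [5, 5], [2, 2]], float)
        lone = np.array([[500.0, 500.0]])
        out = filter_gold_aggregates(np.vstack([cluster, lone]), k=4, d=15.0)
        assert len(out) == 2
        assert any(np.allclose(p, cluster.mean(axis=0)) for p in out)
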