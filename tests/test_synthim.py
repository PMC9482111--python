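"""Synthetic phantom generator: determinism, ground-truth fidelity, design."""

import numpy as np
import pytest
from scipy import stats as sps

from fibroquant import (
    CellPhantomParams,
    NucleusPhantomParams,
    StudyConfig,
    ccp,
    generate_study,
    measure_anisotropy,
    render_cell,
    render_nucleus,
)
from fibroquant.morphometry import project_max
from fibroquant.synthim import GROUPS, TIMEPOINTS, sample_axial_vonmises, write_study


class TestAxialSampling:
    def test_uniform_when_kappa_zero(self):
        rng = np.random.default_rng(0)
        th = sample_axial_vonmises(0.3, 0.0, 2000, rng)
        assert ((th >= 0) & (th < np.pi)).all()
        assert sps.kstest(th / np.pi, "uniform").pvalue > 0.01

    def test_point_mass_when_kappa_infinite(self):
        rng = np.random.default_rng(0)
        th = sample_axial_vonmises(2.0, np.inf, 50, rng)
        assert np.allclose(th, 2.0)

    def test_axial_mean_recovered(self):
        rng = np.random.default_rng(1)
        mu = 1.1
        th = sample_axial_vonmises(mu, 8.0, 5000, rng)
        # axial mean via the doubled-angle resultant
        mean_hat = 0.5 * np.angle(np.exp(2j * th).mean()) % np.pi
        assert abs(mean_hat - mu) < 0.02


class TestRenderCell:
    def test_deterministic(self):
        p = CellPhantomParams(orientation_kappa=2.0)
        img1, m1 = render_cell(p, seed=11)
        img2, m2 = render_cell(p, seed=11)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(m1.pixels, m2.pixels)
        img3, _ = render_cell(p, seed=12)
        assert not np.array_equal(img1.pixels, img3.pixels)

    def test_isotropic_vs_parallel_limits(self):
        iso, m_iso = render_cell(CellPhantomParams(orientation_kappa=0.0), seed=5)
        par, m_par = render_cell(
            CellPhantomParams(orientation_kappa=np.inf, mean_orientation=0.9), seed=5
        )
        a_iso = measure_anisotropy(iso, m_iso).value
        a_par = measure_anisotropy(par, m_par).value
        assert a_iso < 0.25  # near-isotropic up to finite-fibre sampling
        assert a_par > 0.9
        assert a_par > a_iso + 0.5

    def test_orientation_recovered(self):
        p = CellPhantomParams(orientation_kappa=10.0, mean_orientation=1.2)
        img, mask = render_cell(p, seed=3)
        s = measure_anisotropy(img, mask)
        diff = abs(s.mean_orientation - 1.2) % np.pi
        assert min(diff, np.pi - diff) < 0.15  # finite-fibre sampling error

    def test_oversized_phantom_rejected(self):
        with pytest.raises(ValueError):
            render_cell(CellPhantomParams(semi_major=300.0), seed=0, canvas=512)

    def test_zstack_mode_projects_back(self):
        p = CellPhantomParams(orientation_kappa=3.0, noise_sd=0.0)
        stack, mask = render_cell(p, seed=7, n_slices=8)
        assert stack.pixels.shape == (8, 512, 512)
        plane, _ = render_cell(p, seed=7, n_slices=1)
        proj = project_max(stack)
        # the focal envelope peaks mid-stack below 1, so the projection is a
        # dimmed copy of the single-plane render
        corr = np.corrcoef(
            proj.pixels[mask.pixels].astype(float),
            plane.pixels[mask.pixels].astype(float),
        )[0, 1]
        assert corr > 0.99


class TestRenderNucleus:
    def test_deterministic(self):
        p = NucleusPhantomParams(n_foci=20)
        a, _ = render_nucleus(p, seed=2)
        b, _ = render_nucleus(p, seed=2)
        assert np.array_equal(a.pixels, b.pixels)

    def test_no_foci_no_noise_is_flat(self):
        p = NucleusPhantomParams(n_foci=0, noise_sd=0.0)
        img, mask = render_nucleus(p, seed=0)
        assert ccp(img, mask).value == 0.0

    def test_doubling_foci_raises_ccp(self):
        vals = []
        for nf in (12, 24):
            accum = []
            for seed in range(3):
                img, mask = render_nucleus(NucleusPhantomParams(n_foci=nf), seed=seed)
                accum.append(ccp(img, mask).value)
            vals.append(np.mean(accum))
        assert vals[1] > vals[0] * 1.3


@pytest.fixture(scope="module")
def small_study():
    cfg = StudyConfig(
        n_per_group=2,
        canvas_cell=256,
        canvas_nucleus=128,
        cell_params=CellPhantomParams(semi_major=80, semi_minor=40),
        nucleus_params=NucleusPhantomParams(semi_major=30, semi_minor=22),
    )
    return cfg, generate_study(cfg, seed=99)


class TestGenerateStudy:
    def test_counts_and_enums(self, small_study):
        cfg, (records, design, truth) = small_study
        assert len(records) == 9 * cfg.n_per_group
        assert len(design) == len(records)
        assert len(truth) == len(records)
        assert set(design["group"]) == set(GROUPS)
        assert set(design["timepoint"]) == set(TIMEPOINTS)
        per_cell = design.groupby(["group", "timepoint"]).size()
        assert (per_cell == cfg.n_per_group).all()

    def test_deterministic_regeneration(self, small_study):
        cfg, (records, design, truth) = small_study
        records2, design2, truth2 = generate_study(cfg, seed=99)
        assert design.equals(design2)
        assert truth.equals(truth2)
        for a, b in zip(records, records2):
            assert np.array_equal(a.cell_image.pixels, b.cell_image.pixels)
            assert np.array_equal(a.nucleus_image.pixels, b.nucleus_image.pixels)

    def test_effect_template_orders_truth_means(self, small_study):
        cfg, (_, _, truth) = small_study
        kap = truth.groupby(["group", "timepoint"])["orientation_kappa"].mean()
        foci = truth.groupby(["group", "timepoint"])["n_foci"].mean()
        assert kap["physiological", "1h"] > kap["unloaded", "1h"]
        assert kap["pathological", "24h"] > kap["unloaded", "24h"]
        assert foci["pathological", "1h"] > foci["unloaded", "1h"]

    def test_write_study_round_trips(self, small_study, tmp_path):
        import tifffile

        cfg, (records, design, truth) = small_study
        out = write_study(records[:3], design.head(3), truth.head(3), tmp_path)
        assert (out / "design.csv").exists()
        assert (out / "truth.csv").exists()
        arr = tifffile.imread(out / "images" / f"{records[0].image_id}_cell.tif")
        assert np.array_equal(arr, records[0].cell_image.pixels)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            StudyConfig(n_per_group=1)
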