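import numpy as np
import pytest
from scipy.stats import norm

from arrowplot.kde import (
    DegenerateSampleError,
    DensityEstimate,
    bandwidth_adaptive,
    bandwidth_normal_reference,
    kde_grid,
)


class TestBandwidth:
    def test_closed_form_unit_spread(self, rng):
        """h = (4/3)^(1/5) * n^(-1/5) when s = 1 and IQR/1.34 >= 1."""
        v = rng.uniform(0, 1, 1024)
        v = (v - v.mean()) / v.std(ddof=1)  # exact unit sample sd
        q75, q25 = np.quantile(v, [0.75, 0.25])
        assert (q75 - q25) / 1.34 >= 1.0  # uniform: IQR/1.34 > s
        h = bandwidth_adaptive(v)
        assert h == pytest.approx((4 / 3) ** 0.2 * 1024 ** (-0.2), abs=1e-12)
        assert h == pytest.approx(0.26480, abs=1e-5)

    def test_matches_brute_force_recomputation(self, rng):
        for _ in range(100):
            n = rng.integers(5, 200)
            v = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 4), n)
            s = np.std(v, ddof=1)
            r = np.subtract(*np.percentile(v, [75, 25]))
            expected = (4 / 3) ** 0.2 * min(s, r / 1.34) * n ** (-0.2)
            assert bandwidth_adaptive(v) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            bandwidth_adaptive([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(DegenerateSampleError):
            bandwidth_normal_reference(np.full(10, -1.5))

    def test_scale_equivariance(self, rng):
        v = rng.normal(0, 1, 50)
        for c in (0.1, 2.0, 37.5):
            assert bandwidth_adaptive(c * v) == pytest.approx(
                c * bandwidth_adaptive(v), rel=1e-12
            )

    def test_zero_iqr_falls_back_to_sd(self):
        # heavy central ties: IQR = 0 but sd > 0
        v = np.array([0.0] * 20 + [5.0, -5.0])
        h = bandwidth_adaptive(v)
        assert h == pytest.approx((4 / 3) ** 0.2 * np.std(v, ddof=1) * v.size ** (-0.2))

    def test_normal_reference_uses_sd_only(self, rng):
        v = rng.normal(0, 2, 100)
        expected = (4 / 3) ** 0.2 * np.std(v, ddof=1) * 100 ** (-0.2)
        assert bandwidth_normal_reference(v) == pytest.approx(expected, rel=1e-12)


class TestKdeGrid:
    def test_single_kernel_closed_form(self):
        """One observation with h = 1 reproduces the standard normal pdf."""
        d = kde_grid([0.0], bandwidth=1.0, n_grid=17)
        i = np.argmin(np.abs(d.x))
        assert d.x[i] == pytest.approx(0.0, abs=1e-12)
        assert d.y[i] == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-12)
        assert np.allclose(d.y, norm.pdf(d.x), atol=1e-12)

    def test_integrates_to_one(self, rng):
        for _ in range(25):
            v = rng.normal(rng.uniform(-3, 3), rng.uniform(0.2, 3), rng.integers(5, 300))
            assert kde_grid(v).integral == pytest.approx(1.0, abs=0.01)

    def test_shift_equivariance(self, rng):
        v = rng.normal(0, 1, 40)
        d0 = kde_grid(v)
        d1 = kde_grid(v + 10.0)
        assert np.allclose(d1.x, d0.x + 10.0, atol=1e-9)
        assert np.allclose(d1.y, d0.y, atol=1e-12)

    def test_deterministic(self, rng):
        v = rng.normal(0, 1, 30)
        a, b = kde_grid(v), kde_grid(v.copy())
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert a.bandwidth == b.bandwidth

    def test_grid_span_and_size(self, rng):
        v = rng.normal(0, 1, 30)
        d = kde_grid(v, n_grid=256, cut=4.0)
        assert d.x.size == 256
        assert d.x[0] == pytest.approx(v.min() - 4 * d.bandwidth)
        assert d.x[-1] == pytest.approx(v.max() + 4 * d.bandwidth)

    @pytest.mark.parametrize(
        "kwargs", [{"bandwidth": 0.0}, {"bandwidth": -1.0}, {"n_grid": 8}]
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            kde_grid([0.0, 1.0, 2.0], **kwargs)

    def test_missing_values_dropped(self):
        v = [1.0, np.nan, 2.0, np.inf, 3.0]
        d = kde_grid(v)
        assert d.x[0] == pytest.approx(1.0 - 3 * d.bandwidth)
        assert d.x[-1] == pytest.approx(3.0 + 3 * d.bandwidth)

    def test_matches_r_density_oracle(self, rng, tmp_path):
        """Ordinates agree with R's density() at matched bandwidth/grid
        (R approximates the kernel sum by FFT binning, hence the 2e-3 slack)."""
        import shutil
        import subprocess

        assert shutil.which("Rscript"), "Rscript expected on PATH"
        samples = [
            rng.normal(0, 1, 30),
            np.concatenate([rng.normal(-5, 1, 15), rng.normal(5, 1, 15)]),
            rng.normal(2, 0.5, 60),
        ]
        rows = [np.concatenate([[bandwidth_adaptive(v)], v]) for v in samples]
        sample_file = tmp_path / "samples.txt"
        out_file = tmp_path / "ry.txt"
        width = max(len(r) for r in rows)
        padded = np.full((len(rows), width), np.nan)
        for i, r in enumerate(rows):
            padded[i, : len(r)] = r
        np.savetxt(sample_file, padded)
        r_code = (
            f'm <- as.matrix(read.table("{sample_file}")); '
            "out <- c(); "
            "for (i in 1:nrow(m)) { h <- m[i,1]; v <- m[i,-1]; v <- v[!is.na(v)]; "
            "d <- density(v, bw=h, n=512, cut=3); out <- c(out, d$y) }; "
            f'write(out, "{out_file}", ncolumns=1)'
        )
        subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
        ry = np.loadtxt(out_file).reshape(len(samples), 512)
        for v, row, ref in zip(samples, rows, ry):
            mine = kde_grid(v, bandwidth=row[0])
            assert np.abs(mine.y - ref).max() < 2e-3


class TestDensityEstimate:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            DensityEstimate(x=np.array([0.0, 0.0, 1.0]), y=np.zeros(3), bandwidth=1.0)
        with pytest.raises(ValueError):
            DensityEstimate(x=np.array([0.0, 1.0]), y=np.array([1.0, -0.1]), bandwidth=1.0)
        with pytest.raises(ValueError):
            DensityEstimate(x=np.array([0.0, 1.0]), y=np.ones(2), bandwidth=0.0)
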