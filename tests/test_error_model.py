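"""Error-model fitting and the Z statistic."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from actikin import SdCurve, SimConfig, simulate_null
from actikin.error_model import ErrorModel, compute_z, fit_error_model, loess


def _design(n_controls=6, timepoints=(1, 4, 8, 24), reps=3):
    ids = [f"ctrl_{i}" for i in range(n_controls)]
    labels = [0] * n_controls
    for t in timepoints:
        for r in range(reps):
            ids.append(f"t{t}_r{r}")
            labels.append(t)
    return pd.Series(labels, index=pd.Index(ids, name="sample_id"))


def _controls_with_sd(means, sd):
    """Six control columns whose per-row sample SD (ddof=1) is exactly sd."""
    delta = sd * np.sqrt(5.0 / 6.0)
    offsets = np.array([-1, 1, -1, 1, -1, 1]) * delta
    values = np.asarray(means)[:, None] + offsets[None, :]
    return pd.DataFrame(
        values,
        index=[f"ps{i}" for i in range(len(means))],
        columns=[f"ctrl_{i}" for i in range(6)],
    )


class TestFit:
    def test_constant_sd_recovered_exactly(self):
        """Controls engineered to SD=0.5 at every mean give a flat curve."""
        means = np.linspace(4, 14, 200)
        expr = _controls_with_sd(means, 0.5)
        design = pd.Series(0, index=expr.columns)
        model = fit_error_model(expr, design)
        grid = np.linspace(4, 14, 50)
        assert np.allclose(model(grid), 0.5, atol=1e-6)

    def test_recovers_generating_curve(self):
        """Loess fit tracks the generating SD curve within 15% centrally."""
        curve = SdCurve(a=0.1, b=1.5, c=0.35)
        cfg = SimConfig(n_genes=5000, multi_probeset_frac=0.0, seed=3,
                        sd_curve=curve)
        ds = simulate_null(cfg)
        model = fit_error_model(ds.expression, ds.design)
        lo, hi = 4 + 0.05 * 10, 14 - 0.05 * 10  # central 90% of the mean range
        grid = np.linspace(lo, hi, 40)
        rel = np.abs(model(grid) - curve(grid)) / curve(grid)
        assert rel.max() < 0.15

    def test_degenerate_support_constant_extrapolation(self):
        """All probe sets at one mean: that SD is returned everywhere."""
        expr = _controls_with_sd(np.full(100, 8.0), 0.3)
        design = pd.Series(0, index=expr.columns)
        model = fit_error_model(expr, design)
        assert model.support == (8.0, 8.0)
        assert np.allclose(model([0.0, 8.0, 20.0]), 0.3, atol=1e-9)

    def test_requires_two_controls(self):
        expr = _controls_with_sd(np.linspace(4, 14, 60), 0.5).iloc[:, :1]
        design = pd.Series(0, index=expr.columns)
        with pytest.raises(ValueError, match="control"):
            fit_error_model(expr, design)

    def test_few_probe_sets_warns(self):
        expr = _controls_with_sd(np.linspace(4, 14, 10), 0.5)
        design = pd.Series(0, index=expr.columns)
        with pytest.warns(UserWarning, match="probe sets"):
            fit_error_model(expr, design)

    def test_json_round_trip(self, tmp_path):
        expr = _controls_with_sd(np.linspace(4, 14, 100), 0.4)
        design = pd.Series(0, index=expr.columns)
        model = fit_error_model(expr, design)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ErrorModel.from_json(path)
        grid = np.linspace(2, 16, 30)
        assert np.array_equal(model(grid), back(grid))


class TestLoessAgainstReference:
    def test_matches_r_loess_on_smooth_data(self, tmp_path):
        """The local-quadratic smoother agrees with R stats::loess defaults."""
        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(0, 10, 300))
        y = np.sin(x) + 0.5 * x + rng.normal(0, 0.1, x.size)
        grid = np.linspace(0.5, 9.5, 25)
        ours = loess(x, y, grid, span=0.75, degree=2)
        data = tmp_path / "xy.tsv"
        pd.DataFrame({"x": x, "y": y}).to_csv(data, sep="\t", index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            d <- read.delim("{data}")
            fit <- loess(y ~ x, data = d, span = 0.75, degree = 2,
                         surface = "direct")
            grid <- seq(0.5, 9.5, length.out = 25)
            cat(predict(fit, newdata = data.frame(x = grid)), sep = "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        theirs = np.array([float(v) for v in out.stdout.split()])
        assert np.max(np.abs(ours - theirs)) < 1e-5


class TestComputeZ:
    def test_direct_arithmetic(self):
        """mean0=8, mean1h=9, sd(8)=0.2 gives Z=5."""
        model = ErrorModel(grid_mean=[8.0], grid_sd=[0.2])
        expr = pd.DataFrame(
            {"c1": [8.0], "c2": [8.0], "t1": [9.0]}, index=["ps0"]
        )
        design = pd.Series([0, 0, 1], index=expr.columns)
        z = compute_z(expr, design, model)
        assert z.z.loc["ps0", 1] == pytest.approx(5.0)

    def test_no_change_gives_zero_row(self):
        model = ErrorModel(grid_mean=[8.0], grid_sd=[0.2])
        expr = pd.DataFrame(
            {"c1": [8.0, 6.0], "c2": [8.0, 6.0],
             "t1": [8.0, 6.0], "t4": [8.0, 6.0]},
            index=["ps0", "ps1"],
        )
        design = pd.Series([0, 0, 1, 4], index=expr.columns)
        z = compute_z(expr, design, model)
        assert (z.z.to_numpy() == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_gene_brute_force(self, seed):
        """Vectorised Z equals a one-gene-at-a-time reference to 1e-10."""
        rng = np.random.default_rng(seed)
        n = 40
        design = _design()
        expr = pd.DataFrame(
            rng.uniform(4, 14, size=(n, len(design))),
            index=[f"ps{i}" for i in range(n)],
            columns=design.index,
        )
        model = ErrorModel(
            grid_mean=np.linspace(3, 15, 20),
            grid_sd=rng.uniform(0.1, 0.8, 20),
        )
        z = compute_z(expr, design, model)
        controls = design.index[design == 0]
        for ps in expr.index:  # brute-force reference, one gene at a time
            row = expr.loc[ps]
            m0 = row[controls].mean()
            sd = float(model(m0))
            for t in z.timepoints:
                mt = row[design.index[design == t]].mean()
                assert abs(z.z.loc[ps, t] - (mt - m0) / sd) < 1e-10

    def test_monotone_in_timepoint_mean(self):
        model = ErrorModel(grid_mean=[8.0], grid_sd=[0.2])
        design = pd.Series([0, 0, 1], index=["c1", "c2", "t1"])
        base = pd.DataFrame({"c1": [8.0], "c2": [8.0], "t1": [9.0]}, index=["ps0"])
        bumped = base.copy()
        bumped.loc["ps0", "t1"] += 0.5
        z0 = compute_z(base, design, model).z.loc["ps0", 1]
        z1 = compute_z(bumped, design, model).z.loc["ps0", 1]
        assert z1 > z0

    def test_sign_symmetry(self):
        """Swapping treated and control values negates Z."""
        model = ErrorModel(grid_mean=[4.0, 14.0], grid_sd=[0.5, 0.5])
        design = pd.Series([0, 0, 1, 1], index=["c1", "c2", "t1", "t2"])
        expr = pd.DataFrame(
            {"c1": [8.0], "c2": [8.2], "t1": [9.0], "t2": [9.4]}, index=["ps0"]
        )
        swapped = expr.rename(columns={"c1": "t1", "t1": "c1", "c2": "t2", "t2": "c2"})
        z = compute_z(expr, design, model).z.loc["ps0", 1]
        zs = compute_z(swapped[expr.columns], design, model).z.loc["ps0", 1]
        assert zs == pytest.approx(-z, abs=1e-12)

    def test_null_z_dispersion_matches_design(self):
        """On null data the Z spread per timepoint is near sqrt(1/3+1/6)."""
        cfg = SimConfig(n_genes=5000, multi_probeset_frac=0.0, seed=7)
        ds = simulate_null(cfg)
        model = fit_error_model(ds.expression, ds.design)
        z = compute_z(ds.expression, ds.design, model)
        expected = np.sqrt(1.0 / 3.0 + 1.0 / 6.0)
        for t in z.timepoints:
            # the model's curve is fitted, not the generating truth, so a
            # 10% band around the design value is the calibration check
            assert z.z[t].std() == pytest.approx(expected, rel=0.10)

    def test_empty_timepoint_errors(self):
        model = ErrorModel(grid_mean=[8.0], grid_sd=[0.2])
        expr = pd.DataFrame({"c1": [8.0], "c2": [8.0]}, index=["ps0"])
        design = pd.Series([0, 0], index=expr.columns)
        with pytest.raises(ValueError, match="timepoint"):
            compute_z(expr, design, model)
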