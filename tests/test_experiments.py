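"""Species presets, configuration files and the command-line surface."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from coraltherm import experiments as E
from coraltherm.cli import main as cli_main
from coraltherm.config import load_config
from coraltherm.geometry import CYLINDER, HEMISPHERE
from coraltherm.properties import MaterialSet


class TestPresets:
    def test_five_species(self):
        presets = E.make_presets()
        assert len(presets) == 5
        assert {p.name for p in presets} == {
            "P. lobata", "S. pistillata", "Favia sp.", "C. serailia", "S. hystrix",
        }

    def test_dimensions_and_porosities(self):
        by = {p.name: p for p in E.make_presets()}
        assert by["P. lobata"].coral.kind == HEMISPHERE
        assert by["P. lobata"].coral.diameter == pytest.approx(0.035)
        assert by["P. lobata"].skeletal_porosity == 0.475
        assert by["S. pistillata"].coral.kind == CYLINDER
        assert by["S. pistillata"].coral.diameter == pytest.approx(0.006)
        assert by["S. pistillata"].coral.height == pytest.approx(0.006)
        assert by["S. pistillata"].skeletal_porosity == 0.431
        assert by["C. serailia"].coral.diameter == pytest.approx(0.050)
        assert by["S. hystrix"].coral.diameter == pytest.approx(0.003)
        assert by["S. hystrix"].skeletal_porosity == 0.405

    def test_assumed_porosities_flagged(self):
        by = {p.name: p for p in E.make_presets()}
        assert by["C. serailia"].porosity_assumed
        assert by["C. serailia"].skeletal_porosity == 0.500
        assert not by["S. hystrix"].porosity_assumed

    def test_reynolds_numbers_match_tabulated(self):
        """U*d/nu reproduces the tabulated Re (6-468) within 15%."""
        nu = MaterialSet().fluid.nu
        for p in E.make_presets():
            for u, re_ref in ((E.LOW_FLOW, p.re_low), (E.HIGH_FLOW, p.re_high)):
                if re_ref is None:
                    continue
                assert E.get_preset(p.name).reynolds(u, nu) == pytest.approx(
                    re_ref, rel=0.15
                ), f"{p.name} at {u} m/s"

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            E.get_preset("A. millepora")

    def test_bulk_density_consistent_with_porosity(self):
        p = E.get_preset("S. hystrix")
        assert p.bulk_density == pytest.approx(1.7493, abs=2e-4)


class TestConfig:
    def test_roundtrip(self, tmp_path):
        cfg = {
            "scenario": "steady-sweep",
            "species": "P. lobata",
            "irradiances": [500, 700, 950],
            "solver": {"dt": 0.5, "tol": 1e-4},
        }
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump(cfg))
        loaded = load_config(path)
        assert loaded["species"] == "P. lobata"
        assert loaded["solver"]["dt"] == 0.5

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("scenario: steady-sweep\nspeed: 3\n")
        with pytest.raises(ValueError, match="unknown configuration keys"):
            load_config(path)

    def test_unknown_scenario_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("scenario: warp-drive\n")
        with pytest.raises(ValueError, match="scenario"):
            load_config(path)

    def test_unknown_solver_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("solver: {warp: 9}\n")
        with pytest.raises(ValueError, match="solver"):
            load_config(path)


class TestCli:
    def test_lumped_subcommand_reports_consistent_numbers(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out"
        result = runner.invoke(
            cli_main, ["lumped", "--species", "C. serailia", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert "A/V = 180" in result.output
        assert (out / "lumped.csv").exists()

    def test_export_mesh_writes_vtk(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out"
        result = runner.invoke(
            cli_main, ["export-mesh", "--species", "P. lobata", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        vtks = list(out.glob("*.vtk"))
        assert len(vtks) == 1
        head = vtks[0].read_text().splitlines()
        assert head[0].startswith("# vtk DataFile")
        assert any("RECTILINEAR_GRID" in line for line in head[:6])


class TestCalibration:
    def test_absorptivity_clipped_to_plausible_range(self, lobata_low):
        # an absurdly large target cannot push alpha beyond 0.28
        with pytest.warns(UserWarning, match="clipping"):
            alpha = E.calibrate_absorptivity(lobata_low.case, 600.0, 5.0)
        assert alpha == E.ABSORPTIVITY_RANGE[1]

    def test_calibration_reproduces_target(self, lobata_low):
        # a target generated with alpha = 0.2 calibrates back to 0.2
        alpha = E.calibrate_absorptivity(lobata_low.case, 600.0,
                                         0.2 * 600.0 * lobata_low.unit_max)
        assert alpha == pytest.approx(0.2, rel=1e-6)


class TestResidualLog:
    def test_residual_history_recorded_and_converged(self, lobata_low):
        df = lobata_low.case.residual_frame()
        assert list(df.columns) == ["iteration", "continuity_residual"]
        assert df.continuity_residual.iloc[-1] < 1e-4
        assert df.continuity_residual.iloc[-1] < df.continuity_residual.iloc[0]


class TestSteadySweep:
    def test_single_irradiance_skips_fit(self, lobata_low):
        table, fit = E.run_steady_sweep(
            "P. lobata", irradiances=(600.0,), case=lobata_low.case
        )
        assert len(table) == 1
        assert fit is None

    def test_sweep_monotone_in_irradiance(self, lobata_low):
        table, fit = E.run_steady_sweep("P. lobata", case=lobata_low.case)
        assert table.dT_mean_K.is_monotonic_increasing
        assert fit is not None
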