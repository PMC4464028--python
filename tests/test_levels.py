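import json

import numpy as np
import pytest

from cscflow._errors import DomainError
from cscflow.ensemble import TimeGrid, outputs_at_time, simulate_ensemble
from cscflow.levels import (
    assign_level,
    assign_levels,
    colored_scatter,
    colored_traces,
    combine_columns,
    format_bound,
    partition_range,
)
from cscflow.models import fixture_model
from cscflow.sampling import ParameterSpec, SampleDesign, lhs_sample


class TestPartitionRange:
    # the four published worked examples: (min, max, printed interior bounds)
    TABLE = [
        ("serum", 0.01, 5.99, (1.50, 3.00, 4.49)),
        ("stress", 0.01, 0.99, (0.25, 0.50, 0.75)),
        ("BCL2T", 56.00, 103.99, (68.00, 80.00, 91.99)),
        ("P_sy", 0.00, 1.00, (0.25, 0.50, 0.75)),
    ]

    @pytest.mark.parametrize("name,lo,hi,printed", TABLE)
    def test_published_partitions_at_printed_precision(self, name, lo, hi, printed):
        """Interior boundaries agree with the published 2-decimal tables to
        the printed precision (the tables mix truncation and rounding, so
        exact string equality is not well defined; half a printed unit is)."""
        part = partition_range(lo, hi, 4, parameter=name)
        assert np.allclose(part.boundaries, printed, atol=0.005 + 1e-12)

    def test_exact_interior_boundaries(self):
        part = partition_range(0.01, 5.99, 4)
        assert part.boundaries == pytest.approx([1.505, 3.000, 4.495], abs=1e-12)
        assert partition_range(0.0, 1.0, 4).boundaries == pytest.approx([0.25, 0.5, 0.75])

    def test_equal_widths_to_machine_precision(self):
        part = partition_range(-3.7, 11.2, 7)
        widths = np.diff([part.min, *part.boundaries, part.max])
        assert widths.max() - widths.min() < 1e-12 * (part.max - part.min)

    def test_default_color_order(self):
        assert partition_range(0, 1, 4).labels == ("black", "blue", "red", "green")
        assert len(partition_range(0, 1, 6).labels) == 6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            partition_range(2.0, 2.0, 4)
        with pytest.raises(DomainError):
            partition_range(0.0, 1.0, 1)

    def test_legend_rounding_half_up(self):
        assert format_bound(0.25) == "0.25"
        assert format_bound(79.995) == "80.00"  # stored float is just above
        assert format_bound(1.0) == "1.00"


class TestAssignLevel:
    @pytest.fixture(scope="class")
    def unit_partition(self):
        return partition_range(0.0, 1.0, 4)

    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 1), (0.25, 1), (0.250001, 2), (0.5, 2), (0.75, 3), (0.750001, 4), (1.0, 4)],
    )
    def test_bracket_convention(self, unit_partition, value, expected):
        """First interval closed, the rest left-open right-closed."""
        assert assign_level(value, unit_partition) == expected

    def test_out_of_range_rejected(self, unit_partition):
        with pytest.raises(DomainError):
            assign_level(1.0001, unit_partition)

    def test_assignment_monotone_and_exhaustive(self, unit_partition, rng):
        values = np.sort(rng.uniform(0, 1, 500))
        levels = assign_levels(values, unit_partition)
        assert np.all(np.diff(levels) >= 0)
        assert set(np.unique(levels)) <= {1, 2, 3, 4}


class TestCombineColumns:
    @pytest.fixture(scope="class")
    def design(self):
        import pandas as pd

        specs = [
            ParameterSpec("P_sy", bounds=(0, 1)),
            ParameterSpec("omega_CSC", bounds=(0, 3)),
            ParameterSpec("eta_1", bounds=(0, 1)),
        ]
        matrix = pd.DataFrame(
            {"P_sy": [0.5, 1.0], "omega_CSC": [0.5, 2.0], "eta_1": [0.1, 0.5]}
        )
        return SampleDesign(specs=specs, n=2, seed=0, matrix=matrix)

    def test_product(self, design):
        assert combine_columns("P_sy*omega_CSC", design) == pytest.approx([0.25, 2.0])

    def test_product_minus_rate(self, design):
        got = combine_columns("P_sy*omega_CSC-eta_1", design)
        assert got == pytest.approx([0.15, 1.5])

    def test_parentheses_and_unary_minus(self, design):
        got = combine_columns("-(P_sy - eta_1)", design)
        assert got == pytest.approx([-0.4, -0.5])

    def test_division_rejected(self, design):
        with pytest.raises(DomainError, match="disallowed|parse"):
            combine_columns("P_sy/omega_CSC", design)

    def test_power_rejected(self, design):
        with pytest.raises(DomainError):
            combine_columns("P_sy**2", design)

    def test_unknown_identifier_named(self, design):
        with pytest.raises(DomainError, match="omega"):
            combine_columns("P_sy*omega", design)

    def test_function_calls_rejected(self, design):
        with pytest.raises(DomainError):
            combine_columns("__import__('os')", design)


class TestColoredFigures:
    @pytest.fixture(scope="class")
    def run(self):
        m = fixture_model("logistic")
        design = lhs_sample([ParameterSpec("r", bounds=(0.5, 1.5))], 8, seed=6)
        Y = simulate_ensemble(m, design, TimeGrid.uniform(0.0, 10.0, 11))
        part = partition_range(0.5, 1.5, 4, parameter="r")
        return design, Y, part

    def test_traces_color_partition(self, run, tmp_path):
        """Each polyline takes its level color; the sidecar records the
        per-level counts, which sum to n."""
        design, Y, part = run
        paths = colored_traces(Y, design.column("r"), part, tmp_path)
        sidecar = json.loads(paths["N"].with_suffix(".json").read_text())
        assert sum(sidecar["counts_per_level"]) == 8
        levels = assign_levels(design.column("r"), part)
        for lvl in range(1, 5):
            assert sidecar["counts_per_level"][lvl - 1] == int(np.sum(levels == lvl))

    def test_traces_write_files_and_close_figures(self, run, tmp_path):
        import matplotlib.pyplot as plt

        design, Y, part = run
        paths = colored_traces(Y, design.column("r"), part, tmp_path)
        assert all(p.exists() for p in paths.values())
        assert plt.get_fignums() == []

    def test_log_scale_clipping_recorded(self, run, tmp_path):
        design, Y, part = run
        Yc = Y
        Yc.values[0, 0, 0] = 0.0  # force one non-positive point
        paths = colored_traces(Yc, design.column("r"), part, tmp_path, scale="log")
        sidecar = json.loads(paths["N"].with_suffix(".json").read_text())
        assert sidecar["clipped_points"] == 1
        Yc.values[0, 0, 0] = 1.0

    def test_single_level_degenerate_still_four_legend_entries(self, run, tmp_path):
        design, Y, part = run
        key = np.full(8, 0.6)  # all samples in level 1
        paths = colored_traces(Y, key, part, tmp_path / "one")
        sidecar = json.loads(paths["N"].with_suffix(".json").read_text())
        assert sidecar["counts_per_level"] == [8, 0, 0, 0]
        assert len(part.legend_entries()) == 4

    def test_scatter_sidecar_and_derived_axis(self, run, tmp_path):
        design, Y, part = run
        table, t_used = outputs_at_time(Y, 10.0)
        path = colored_scatter(table, design.column("r"), part, "N", tmp_path,
                               time=t_used)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        assert sum(sidecar["counts_per_level"]) == 8
        # derived columns are accepted identically to raw parameter columns
        derived = combine_columns("r*r", design)
        path2 = colored_scatter(table, derived, part, "N", tmp_path,
                                time=t_used, x_label="r*r",
                                color_values=design.column("r"))
        assert path2.exists()

    def test_unknown_variable_rejected(self, run, tmp_path):
        design, Y, part = run
        table, _ = outputs_at_time(Y, 10.0)
        with pytest.raises(DomainError, match="nope"):
            colored_scatter(table, design.column("r"), part, "nope", tmp_path)
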