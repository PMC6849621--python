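"""Nestedness temperature: packing, fill line, surprises, 0-100 scale."""

import subprocess
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import spearmanr

from coredisorder.core import CoreSeries
from coredisorder import disorder as dis
from coredisorder.synthetic import ScenarioConfig, generate_core, generate_matrix


def quadrature_area(p):
    """Independent numerical-quadrature oracle for the fill-line area."""
    return quad(lambda x: (1 - (1 - x) ** p) ** (1 / p), 0, 1, epsabs=1e-12)[0]


def tiny_core(cells, dates=None):
    m, n = np.asarray(cells).shape
    frame = pd.DataFrame(
        np.asarray(cells, dtype=float) * 10.0, columns=[f"sp{j}" for j in range(n)]
    )
    return CoreSeries(dates=dates if dates is not None else np.arange(m, dtype=float),
                      abundances=frame)


class TestBuildIncidence:
    def test_identical_sections_fill_everything(self):
        core = tiny_core(np.tile([1, 1, 0, 1], (15, 1)))
        mat = dis.build_incidence(core, end_index=14)
        assert mat.n == 3  # absent species' column dropped
        assert mat.fill == 1.0

    def test_rare_species_has_single_incidence(self):
        cells = np.ones((15, 4), dtype=int)
        cells[:, 3] = 0
        cells[7, 3] = 1
        mat = dis.build_incidence(tiny_core(cells), end_index=14)
        col = mat.col_labels.index("sp3")
        assert mat.cells[:, col].sum() == 1

    def test_empty_window_rejected(self):
        core = tiny_core(np.zeros((15, 3), dtype=int))
        with pytest.raises(ValueError):
            dis.build_incidence(core, end_index=14)

    def test_short_core_rejected(self):
        core = tiny_core(np.ones((10, 3), dtype=int))
        with pytest.raises(ValueError):
            dis.build_incidence(core, end_index=9, window=15)

    def test_abundance_threshold_optional(self):
        cells = np.ones((15, 2), dtype=int)
        core = tiny_core(cells)
        core.abundances.iloc[:, 1] = 0.3  # below a 0.5% cutoff
        mat = dis.build_incidence(core, 14, min_abundance=0.5)
        assert mat.n == 1


class TestPack:
    def test_packed_matrix_is_fixed_point(self):
        mat = generate_matrix("nested", 10, 12, 0.5, seed=1)
        packed = dis.pack(mat)
        again = dis.pack(packed.matrix)
        assert np.array_equal(again.cells, packed.cells)

    def test_row_and_column_shuffles_cancel(self, rng):
        for seed in range(5):
            mat = generate_matrix("random", 12, 15, 0.4, seed=seed)
            packed = dis.pack(mat)
            rp, cp = rng.permutation(12), rng.permutation(15)
            shuffled = dis.IncidenceMatrix(
                cells=mat.cells[np.ix_(rp, cp)],
                row_labels=mat.row_labels[rp],
                col_labels=[mat.col_labels[j] for j in cp],
            )
            assert np.array_equal(dis.pack(shuffled).cells, packed.cells)

    def test_marginals_non_increasing_matches_sort_oracle(self):
        for seed in range(5):
            mat = generate_matrix("random", 15, 20, 0.5, seed=seed)
            packed = dis.pack(mat)
            rows = packed.cells.sum(axis=1)
            cols = packed.cells.sum(axis=0)
            assert np.array_equal(rows, np.sort(mat.cells.sum(axis=1))[::-1])
            assert np.array_equal(cols, np.sort(mat.cells.sum(axis=0))[::-1])


class TestFillLine:
    def test_half_fill_is_the_diagonal(self):
        assert dis.fill_line_exponent(0.5).p == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("fill", [0.05, 0.2, 0.35, 0.5, 0.65, 0.8, 0.95])
    def test_exponent_inverts_quadrature_area(self, fill):
        line = dis.fill_line_exponent(fill)
        assert quadrature_area(line.p) == pytest.approx(fill, abs=1e-8)
        assert line.area() == pytest.approx(fill, abs=1e-8)

    def test_area_strictly_increasing_in_exponent(self):
        grid = np.logspace(-1, 1, 15)
        areas = [quadrature_area(p) for p in grid]
        assert np.all(np.diff(areas) > 0)

    @pytest.mark.parametrize("fill", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_fill_rejected(self, fill):
        with pytest.raises(ValueError):
            dis.fill_line_exponent(fill)


def staircase(richnesses, n):
    cells = np.zeros((len(richnesses), n), dtype=np.uint8)
    for i, r in enumerate(richnesses):
        cells[i, :r] = 1
    return dis.IncidenceMatrix(
        cells=cells,
        row_labels=np.arange(len(richnesses), dtype=float),
        col_labels=[f"sp{j:02d}" for j in range(n)],
    )


class TestSurprises:
    def test_perfectly_nested_has_empty_surprise_set(self):
        mat = staircase([6, 5, 4, 3, 2, 1], 6)
        packed = dis.pack(mat)
        line = dis.fill_line_exponent(mat.fill)
        mask, sq = dis.surprises(packed, line)
        assert not mask.any()
        assert sq.sum() == 0.0

    def test_lone_outlying_presence_is_the_single_surprise(self):
        """A staircase plus one far bottom-right presence: exactly one
        surprise, with a large normalised deviation."""
        mat = staircase([6, 5, 4, 3, 2, 1], 6)
        cells = mat.cells.copy()
        cells[5, 5] = 1
        noisy = dis.IncidenceMatrix(cells, mat.row_labels, mat.col_labels)
        packed = dis.pack(noisy)
        line = dis.fill_line_exponent(noisy.fill)
        mask, sq = dis.surprises(packed, line)
        assert mask.sum() == 1
        assert sq.max() > 0.05  # far from the fill line

    def test_flipping_expected_absence_into_surprise_grows_deviation_sum(self):
        """Adding a disordered presence never lowers the surprise load."""
        mat = staircase([8, 7, 6, 5, 4, 3, 2, 1], 8)
        packed = dis.pack(mat)
        line = dis.fill_line_exponent(mat.fill)
        _, base = dis.surprises(packed, line)
        cells = packed.cells.copy()
        cells[6, 6] = 1  # outside the fill line, below absences
        flipped = dis.PackedMatrix(
            matrix=dis.IncidenceMatrix(cells, packed.matrix.row_labels,
                                       packed.matrix.col_labels),
            row_perm=packed.row_perm,
            col_perm=packed.col_perm,
        )
        _, after = dis.surprises(flipped, line)
        assert after.sum() >= base.sum()

    def test_corner_deviation_near_maximal(self):
        d = dis._diagonal_deviation(np.array([0.975]), np.array([0.975]), p=1.0)
        assert d[0] == pytest.approx(0.475, abs=1e-6)


class TestTemperature:
    @pytest.mark.parametrize("fill,seed", [(0.3, 0), (0.5, 1), (0.65, 2), (0.8, 3)])
    def test_subset_chain_scores_zero(self, fill, seed):
        mat = generate_matrix("nested", 15, 20, fill, seed=seed)
        assert dis.temperature(mat).t == 0.0

    def test_full_matrix_is_perfectly_ordered(self):
        mat = staircase([4, 4, 4], 4)
        assert dis.temperature(mat).t == 0.0

    def test_empty_matrix_rejected(self):
        mat = dis.IncidenceMatrix(np.zeros((3, 1), dtype=np.uint8),
                                  np.arange(3.0), ["a"])
        mat.cells[:] = 0
        with pytest.raises(ValueError):
            dis.temperature(mat)

    def test_permutation_invariance(self, rng):
        mat = generate_matrix("random", 15, 20, 0.5, seed=9)
        base = dis.temperature(mat).t
        for _ in range(5):
            rp, cp = rng.permutation(15), rng.permutation(20)
            shuffled = dis.IncidenceMatrix(
                cells=mat.cells[np.ix_(rp, cp)],
                row_labels=mat.row_labels[rp],
                col_labels=[mat.col_labels[j] for j in cp],
            )
            assert dis.temperature(shuffled).t == base

    def test_checkerboard_hotter_than_any_equal_fill_nested(self):
        checker = dis.temperature(generate_matrix("checkerboard", 10, 10)).t
        nested = max(
            dis.temperature(generate_matrix("nested", 10, 10, 0.5, seed=s)).t
            for s in range(10)
        )
        assert checker > nested
        assert checker > 50.0

    def test_agrees_with_vegan_reference_by_rank(self, tmp_path):
        """Rank correlation > 0.95 against R vegan's nestedtemp on assorted
        matrices (independent reference implementation)."""
        mats = []
        for i in range(8):
            mats.append(generate_matrix("random", 15, 20, 0.3 + 0.05 * i, seed=i))
        for i in range(8):
            base = generate_matrix("nested", 15, 20, 0.35 + 0.05 * i, seed=i)
            cells = base.cells.copy()
            flip = np.random.default_rng(i).integers(0, 300, size=12 + 6 * i)
            cells.flat[flip] = 1 - cells.flat[flip]
            if 0 < cells.sum() < 300:
                mats.append(dis.IncidenceMatrix(cells, base.row_labels,
                                                base.col_labels))
        mine = [dis.temperature(m).t for m in mats]
        lines = "\n".join(
            ";".join(",".join(str(int(v)) for v in row) for row in m.cells)
            for m in mats
        )
        (tmp_path / "mats.txt").write_text(lines)
        rscript = (
            'suppressMessages(library(vegan));'
            f'lines <- readLines("{tmp_path / "mats.txt"}");'
            'out <- sapply(lines, function(ln) {'
            '  rows <- strsplit(ln, ";")[[1]];'
            '  mat <- do.call(rbind, lapply(rows, function(r) '
            '    as.integer(strsplit(r, ",")[[1]])));'
            '  nestedtemp(mat)$statistic });'
            'writeLines(sprintf("%.6f", out))'
        )
        proc = subprocess.run(["Rscript", "-e", rscript],
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr[-800:]
        reference = [float(x) for x in proc.stdout.split()]
        assert len(reference) == len(mine)
        assert spearmanr(mine, reference).statistic > 0.95


class TestDisorderSeries:
    def test_minimum_core_yields_single_value(self):
        core = generate_core(ScenarioConfig(seed=1), n_sections=30)
        short = CoreSeries(core.dates[:15], core.abundances.iloc[:15].reset_index(drop=True))
        series = dis.disorder_series(short, window=15)
        assert len(series) == 1

    def test_values_bounded(self, anti_phase_core):
        series = dis.disorder_series(anti_phase_core)
        assert series["t"].between(0.0, 100.0).all()
        assert len(series) == anti_phase_core.n_sections - 14

    def test_ordered_phase_cooler_than_disordered_phase(self):
        """With 15-section phases, windows inside an ordered-accumulation
        phase are cooler than windows inside disordered-loss churn."""
        cfg = ScenarioConfig(phase="anti-phase", phase_length=15, seed=7)
        core = generate_core(cfg, n_sections=90)
        series = dis.disorder_series(core, window=15)
        # a window ending at the last section of phase k lies wholly inside
        # that phase and sits at series index 15k; even phases are ordered
        t = series["t"].to_numpy()
        ordered_idx = [30, 60]
        disordered_idx = [15, 45, 75]
        assert np.mean(t[disordered_idx]) > np.mean(t[ordered_idx])
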