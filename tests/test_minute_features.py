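import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cardiophase.exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)
from cardiophase.minute_features import (
    PressureSeries,
    beat_minutes,
    build_feature_table,
    fit_phase_plane,
    minute_average,
    relative_pulse_amplitude,
)
from cardiophase.pmld_core import DiscriminantSeries

from conftest import make_beats


def _pressures(n_load, n_rec, sys0=115.0, dia0=80.0):
    n = n_load + n_rec
    return PressureSeries(
        minute=np.arange(1, n + 1),
        systolic=np.linspace(sys0, sys0 + 40, n),
        diastolic=np.full(n, dia0),
        phase=np.array(["load"] * n_load + ["recovery"] * n_rec, dtype=object),
    )


class TestMinuteAssignment:
    def test_cumulative_rr_places_beats_in_minutes(self):
        # beat j ends at j seconds -> beats 1..60 in minute 1, 61..120 in 2
        beats = make_beats(np.full(120, 1000.0), np.full(120, 300.0))
        minutes = beat_minutes(beats)
        assert minutes[0] == 1 and minutes[59] == 1
        assert minutes[60] == 2 and minutes[119] == 2

    def test_minute_means_match_bruteforce_assignment(self):
        rng = np.random.default_rng(8)
        rr = rng.uniform(400, 1100, 300)
        beats = make_beats(rr, np.full(300, 250.0), n_load=200)
        k_index = np.arange(8, 294)
        s = rng.uniform(0, 2, k_index.size)
        disc = DiscriminantSeries(k_index=k_index, s=s, phase=beats.phase[k_index - 1])
        table = minute_average(disc, beats)
        t = np.cumsum(rr)
        expected = {}
        for k, val in zip(k_index, s):
            m = int(np.ceil(t[k - 1] / 60000.0))
            expected.setdefault(m, []).append(val)
        assert list(table["minute"]) == sorted(expected)
        for _, row in table.iterrows():
            assert row["mean_disc"] == pytest.approx(
                np.mean(expected[row["minute"]]), rel=1e-12
            )

    def test_constant_series_means_are_constant(self):
        beats = make_beats(np.full(200, 900.0), np.full(200, 300.0))
        disc = DiscriminantSeries(
            k_index=np.arange(8, 194),
            s=np.full(186, 5.0),
            phase=np.full(186, "load", dtype=object),
        )
        table = minute_average(disc, beats)
        assert (table["mean_disc"] == 5.0).all()

    def test_empty_discriminant_gives_empty_table(self):
        beats = make_beats(np.full(20, 900.0), np.full(20, 300.0))
        disc = DiscriminantSeries(k_index=[], s=[], phase=[])
        assert minute_average(disc, beats).empty

    def test_misaligned_discriminant_rejected(self):
        beats = make_beats(np.full(20, 900.0), np.full(20, 300.0))
        disc = DiscriminantSeries(
            k_index=[50], s=[1.0], phase=np.array(["load"], dtype=object)
        )
        with pytest.raises(ValidationError, match="aligned"):
            minute_average(disc, beats)


class TestRelativePulseAmplitude:
    def test_reference_pressures(self):
        p = PressureSeries(
            minute=[1, 2],
            systolic=[115.0, 150.0],
            diastolic=[80.0, 90.0],
            phase=np.array(["load", "load"], dtype=object),
        )
        rel = relative_pulse_amplitude(p)["rel_pulse"]
        assert rel[0] == pytest.approx(35 / 115)
        assert rel[1] == pytest.approx(0.4)

    @pytest.mark.parametrize("sys_, dia", [(100.0, 100.0), (90.0, 95.0), (80.0, 0.0)])
    def test_nonpositive_pulse_pressure_rejected(self, sys_, dia):
        with pytest.raises(ValidationError, match="minute 1"):
            PressureSeries(
                minute=[1],
                systolic=[sys_],
                diastolic=[dia],
                phase=np.array(["load"], dtype=object),
            )

    def test_recovery_before_load_rejected(self):
        with pytest.raises(ValidationError, match="precede"):
            PressureSeries(
                minute=[1, 2],
                systolic=[120.0, 120.0],
                diastolic=[80.0, 80.0],
                phase=np.array(["recovery", "load"], dtype=object),
            )


class TestPhasePlaneRegression:
    def _features(self, x, y, phase="load"):
        return pd.DataFrame(
            {
                "minute": np.arange(1, len(x) + 1),
                "rel_pulse": x,
                "mean_disc": y,
                "phase": phase,
            }
        )

    def test_exact_line_recovered(self):
        fit = fit_phase_plane(self._features([0.1, 0.2, 0.3], [1.0, 3.0, 5.0]), "load")
        assert fit.slope == pytest.approx(20.0)
        assert fit.intercept == pytest.approx(-1.0)
        assert fit.spearman_rho == pytest.approx(1.0)

    def test_antitone_points_have_rho_minus_one(self):
        fit = fit_phase_plane(self._features([0.1, 0.2, 0.3], [5.0, 3.0, 1.0]), "load")
        assert fit.spearman_rho == pytest.approx(-1.0)

    def test_matches_closed_form_and_rank_correlation(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0.2, 0.6, 12)
        y = rng.normal(0, 1, 12)
        fit = fit_phase_plane(self._features(x, y), "load")
        xc, yc = x - x.mean(), y - y.mean()
        assert fit.slope == pytest.approx((xc @ yc) / (xc @ xc), abs=1e-12)
        assert fit.intercept == pytest.approx(y.mean() - fit.slope * x.mean(), abs=1e-12)
        rho_ranks = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert fit.spearman_rho == pytest.approx(rho_ranks, abs=1e-12)

    def test_too_few_points_and_degenerate_x(self):
        with pytest.raises(InsufficientDataError):
            fit_phase_plane(self._features([0.3], [1.0]), "load")
        with pytest.raises(DegenerateFitError):
            fit_phase_plane(self._features([0.3, 0.3, 0.3], [1.0, 2.0, 3.0]), "load")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        shift_x=st.floats(-5, 5),
        shift_y=st.floats(-5, 5),
        scale_y=st.floats(0.1, 10),
    )
    def test_slope_affine_equivariance(self, seed, shift_x, shift_y, scale_y):
        """Slope is invariant under shifts of either axis and scales
        linearly with a rescaling of the response."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 8)
        x[0] += 0.5  # guarantee spread
        y = rng.normal(0, 1, 8)
        base = fit_phase_plane(self._features(x, y), "load").slope
        moved = fit_phase_plane(
            self._features(x + shift_x, scale_y * y + shift_y), "load"
        ).slope
        assert moved == pytest.approx(scale_y * base, rel=1e-8, abs=1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_spearman_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 0.9, 10)
        y = rng.normal(0, 1, 10)
        base = fit_phase_plane(self._features(x, y), "load").spearman_rho
        warped = fit_phase_plane(
            self._features(np.exp(3 * x), y**3 + 2 * y), "load"
        ).spearman_rho
        assert warped == pytest.approx(base, abs=1e-12)


def test_feature_table_joins_on_common_minutes():
    rng = np.random.default_rng(21)
    n = 600
    rr = np.full(n, 1000.0)
    beats = make_beats(rr, np.full(n, 280.0), n_load=300)
    k_index = np.arange(8, n - 6)
    disc = DiscriminantSeries(
        k_index=k_index,
        s=rng.uniform(0, 1, k_index.size),
        phase=beats.phase[k_index - 1],
    )
    pressures = _pressures(5, 3)  # only 8 pressure minutes for 10 beat minutes
    table = build_feature_table(disc, beats, pressures)
    assert list(table["minute"]) == list(range(1, 9))
    assert set(table.columns) == {"minute", "rel_pulse", "mean_disc", "phase"}
    assert (table["rel_pulse"] > 0).all() and (table["rel_pulse"] < 1).all()
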