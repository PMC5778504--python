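"""Trace selection (bleach steps, blinking, brightness) and classification."""

import numpy as np
import pytest

import bubblefret as bf
from bubblefret.qc import QcConfig, _blink_runs


def noisy(level, n, rng, sd=10.0):
    return np.clip(rng.normal(level, sd, n), 0, None)


def build_trace(dd, da, aa):
    return bf.AlexTrace(dd, da, aa, 0.01, "m0")


class TestStepDetection:
    def test_constant_series_has_no_steps(self):
        rng = np.random.default_rng(0)
        steps = bf.detect_bleach_steps(noisy(500, 1000, rng))
        big = [s for s in steps if abs(s[1]) > 125]
        assert big == []

    def test_single_bleach_step_located(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([noisy(500, 150, rng), noisy(0, 350, rng)])
        steps = bf.detect_bleach_steps(y)
        down = [(f, s) for f, s in steps if s < -200]
        assert len(down) == 1
        assert abs(down[0][0] - 150) <= 1

    def test_staircase_reports_two_steps(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([
            noisy(500, 300, rng), noisy(250, 300, rng), noisy(0, 300, rng),
        ])
        steps = bf.detect_bleach_steps(y)
        down = [(f, s) for f, s in steps if s < -100]
        assert len(down) == 2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bf.detect_bleach_steps(np.zeros(10))


class TestSelection:
    def _static_trace(self, rng, n=1000, acceptor_bleach=None, donor_bleach=None,
                      level=228.0, blink=None):
        """Hand-built E*~0.45 molecule with controllable bleach/blink frames."""
        dd = noisy(level * 1.2, n, rng, 25)
        da = noisy(level, n, rng, 25)
        aa = noisy(level, n, rng, 20)
        if acceptor_bleach is not None:
            dd[acceptor_bleach:] = noisy(level * 2.2, n - acceptor_bleach, rng, 25)
            da[acceptor_bleach:] = noisy(15, n - acceptor_bleach, rng, 10)
            aa[acceptor_bleach:] = noisy(15, n - acceptor_bleach, rng, 10)
        if donor_bleach is not None:
            dd[donor_bleach:] = noisy(15, n - donor_bleach, rng, 10)
            da[donor_bleach:] = noisy(15, n - donor_bleach, rng, 10)
        if blink is not None:
            lo, hi = blink
            aa[lo:hi] = noisy(15, hi - lo, rng, 10)
        return build_trace(dd, da, aa)

    def test_clean_trace_with_late_bleach_accepted(self):
        rng = np.random.default_rng(3)
        trace = self._static_trace(rng, acceptor_bleach=400)
        report = bf.apply_selection(trace)
        assert report.accepted
        assert abs(report.acceptor_bleach_frame - 400) <= 1

    def test_early_bleach_rejected_too_short(self):
        rng = np.random.default_rng(4)
        trace = self._static_trace(rng, acceptor_bleach=50)
        report = bf.apply_selection(trace)
        assert not report.accepted
        assert "too_short" in report.rejection_reasons

    def test_acceptor_dark_interval_with_recovery_is_blink(self):
        rng = np.random.default_rng(5)
        trace = self._static_trace(rng, acceptor_bleach=700, blink=(200, 210))
        report = bf.apply_selection(trace)
        assert "acceptor_blink" in report.rejection_reasons

    def test_short_fluctuation_is_not_blinking(self):
        # dark intervals shorter than 3 frames are permitted fluctuations
        rng = np.random.default_rng(6)
        trace = self._static_trace(rng, acceptor_bleach=700, blink=(200, 202))
        report = bf.apply_selection(trace)
        assert report.accepted

    def test_staircase_rejected_multi_step(self):
        rng = np.random.default_rng(7)
        n = 900
        dd = np.concatenate([
            noisy(250, 300, rng), noisy(125, 300, rng), noisy(10, 300, rng),
        ])
        da = np.concatenate([
            noisy(250, 300, rng), noisy(125, 300, rng), noisy(10, 300, rng),
        ])
        aa = np.concatenate([noisy(250, 800, rng), noisy(10, 100, rng)])
        report = bf.apply_selection(build_trace(dd, da, aa))
        assert "multi_step_bleach" in report.rejection_reasons

    def test_brightness_band_enforced(self):
        rng = np.random.default_rng(8)
        trace = self._static_trace(rng, acceptor_bleach=500)
        report = bf.apply_selection(trace, median_intensity=5000.0)
        assert "intensity_out_of_range" in report.rejection_reasons

    def test_no_bleach_requires_flag(self):
        rng = np.random.default_rng(9)
        trace = self._static_trace(rng)
        assert bf.apply_selection(trace).accepted
        strict = bf.apply_selection(trace, config=QcConfig(require_bleach=True))
        assert "no_bleach_observed" in strict.rejection_reasons

    def test_accepts_simulated_traces_with_comfortable_bleach_times(self):
        cfg = bf.load_scenario("wt_dsDNA_22C", n_molecules=60, seed=101)
        ds = bf.simulate_dataset(cfg)
        eligible = accepted = 0
        for trace, truth in zip(ds.traces, ds.truths):
            first = min(
                f for f in (truth.donor_bleach_frame,
                            truth.acceptor_bleach_frame, len(trace))
                if f is not None
            )
            if first < 210:
                continue
            eligible += 1
            if bf.apply_selection(trace).accepted:
                accepted += 1
        assert eligible >= 30
        assert accepted / eligible >= 0.95


class TestBlinkRuns:
    def test_detects_recovered_dark_interval_only(self):
        rng = np.random.default_rng(10)
        y = noisy(250, 300, rng, 20)
        y[100:110] = noisy(5, 10, rng, 3)
        assert _blink_runs(y, 5.0, 3) >= 3
        # dark run touching the region end is truncation, not a blink
        y2 = noisy(250, 300, rng, 20)
        y2[290:] = 0.0
        assert _blink_runs(y2, 5.0, 3) == 0


class TestClassification:
    def _classify_simulated(self, scheme, seed, params=None, label=""):
        params = params or bf.PhotophysicsParams(
            donor_bleach_rate=0.0, acceptor_bleach_rate=0.0
        )
        from bubblefret.simulate import simulate_alex_trace, simulate_state_path

        events = simulate_state_path(scheme, 10.0, seed)
        fret, _, _ = bf.discretize_path(events, 0.01, scheme)
        trace, _ = simulate_alex_trace(fret, params, 0.01, seed + 1)
        bg = {k: params.background_per_channel for k in ("DD", "DA", "AA")}
        series = bf.compute_fret_series(trace, background=bg)
        model = bf.select_model(series, seed=seed)
        path = bf.decode_path(model, series)
        return bf.classify_trace(series, model, path, trace=trace)

    @pytest.mark.parametrize(
        "fret,expected",
        [(0.45, "static_open"), (0.35, "static_intermediate"),
         (0.2, "static_closed")],
    )
    def test_static_levels(self, fret, expected):
        scheme = bf.KineticScheme.from_rates(
            ["s"], [fret], [expected.replace("static_", "")], {}
        )
        cls = self._classify_simulated(scheme, seed=21)
        assert cls.label == expected

    def test_interconverting_trace_is_dynamic(self, wt_dynamic_scheme):
        cls = self._classify_simulated(wt_dynamic_scheme, seed=22)
        assert cls.label == "dynamic"
        assert cls.n_transitions >= 1
        assert cls.anticorrelation < -0.5

    def test_classification_recall_on_balanced_dataset(self):
        """Per-class recall >= 0.9 against ground truth at default noise."""
        mk = bf.KineticScheme.from_rates
        scheme_closed = mk(["c"], [0.2], ["closed"], {})
        scheme_mid = mk(["i"], [0.35], ["intermediate"], {})
        scheme_open = mk(["o"], [0.45], ["open"], {})
        dyn = bf.load_scenario("wt_dsDNA_22C").subpopulations[3].scheme
        config = bf.ScenarioConfig(
            name="balanced", n_molecules=48, max_duration_s=10.0, seed=303,
            photophysics=bf.PhotophysicsParams(
                donor_bleach_rate=0.0, acceptor_bleach_rate=0.0
            ),
            subpopulations=(
                bf.Subpopulation("static_closed", 0.25, scheme_closed),
                bf.Subpopulation("static_intermediate", 0.25, scheme_mid),
                bf.Subpopulation("static_open", 0.25, scheme_open),
                bf.Subpopulation("dynamic", 0.25, dyn),
            ),
        )
        ds = bf.simulate_dataset(config)
        bg = {k: 20.0 for k in ("DD", "DA", "AA")}
        hits: dict[str, list[bool]] = {}
        for i, (trace, truth) in enumerate(zip(ds.traces, ds.truths)):
            series = bf.compute_fret_series(trace, background=bg)
            model = bf.select_model(series, seed=1000 + i)
            path = bf.decode_path(model, series)
            cls = bf.classify_trace(series, model, path, trace=trace)
            hits.setdefault(truth.true_class, []).append(
                cls.label == truth.true_class
            )
        for label, outcomes in hits.items():
            assert np.mean(outcomes) >= 0.9, (label, outcomes)


class TestPopulationTable:
    def test_single_class(self):
        table = bf.population_table(["static_open"] * 5)
        assert table.loc["static_open", "fraction"] == 1.0

    def test_even_split(self):
        table = bf.population_table(["dynamic"] * 5 + ["static_open"] * 5)
        assert table["fraction"].tolist() == [0.5, 0.5]
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bf.population_table([])
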