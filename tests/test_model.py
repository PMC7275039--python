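"""Background-model fitting, intercept correction, prediction field."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from hotscan.features import (
    BINARY_OVERLAY, EPIGENETIC, FeatureAssembler, FeatureSpec,
    default_snv_specs, sample_burden,
)
from hotscan.io import GenomeSequence, GenomicTrack, RegionSet
from hotscan.model import (
    BackgroundModel, ProbabilityField, fit_background, predict_probability,
    zvalue_table,
)
from hotscan.sampling import Standardizer, build_design_matrix, sample_sites
from hotscan.simulate import SimulationConfig, TrackConfig, generate_genome, \
    generate_tracks, simulate_catalog


def _manual_model(coefs: dict, offset=0.0, scales=None):
    names = ["intercept"] + [k for k in coefs if k != "intercept"]
    series = pd.Series({**{"intercept": 0.0}, **coefs}).reindex(names)
    return BackgroundModel(
        coefficients=series,
        standard_errors=pd.Series(0.1, index=names),
        offset_correction=offset,
        variant_class="SNV",
        column_categories={k: EPIGENETIC for k in names if k != "intercept"},
        standardizer=Standardizer(scales or {}),
    )


class TestFitBackground:
    def test_recovers_binary_effect(self):
        """Single binary feature, truth beta=(-9, 1.5), 200k balanced rows.

        Cases and controls are drawn retrospectively from the exact
        conditional laws P(x|y) implied by the logistic truth with
        P(x=1)=0.3; case-control logistic regression is consistent for the
        slope, so the fitted coefficient must recover 1.5.
        """
        b0, b1, px = -9.0, 1.5, 0.3
        p1, p0 = expit(b0 + b1), expit(b0)
        px_case = px * p1 / (px * p1 + (1 - px) * p0)
        px_ctl = px * (1 - p1) / (px * (1 - p1) + (1 - px) * (1 - p0))
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = 100_000
            x = np.concatenate([
                (rng.random(m) < px_case), (rng.random(m) < px_ctl)
            ]).astype(float)[:, None]
            y = np.concatenate([np.ones(m), np.zeros(m)])
            model = fit_background(x, y, ["track"], {"track": EPIGENETIC},
                                   (1.0, 1e-4))
            errs.append(abs(model.coefficients["track"] - b1))
        assert max(errs) < 0.1

    def test_intercept_correction_closed_form(self, rng):
        """Balanced no-feature sample: corrected intercept ~ population
        log-odds."""
        n_pop = 500_000
        pi = 1e-3
        y_full = (rng.random(n_pop) < pi).astype(float)
        cases = np.flatnonzero(y_full == 1)
        controls = rng.choice(np.flatnonzero(y_full == 0), size=len(cases),
                              replace=False)
        y = np.concatenate([np.ones(len(cases)), np.zeros(len(cases))])
        x = rng.random(2 * len(cases))[:, None]  # irrelevant covariate
        f1, f0 = 1.0, len(cases) / (n_pop - len(cases))
        model = fit_background(x, y, ["junk"], {"junk": EPIGENETIC}, (f1, f0))
        assert model.corrected_intercept == pytest.approx(
            logit(pi), abs=0.15
        )

    def test_all_zero_column_dropped(self, rng, caplog):
        X = np.column_stack([rng.normal(size=1000), np.zeros(1000)])
        y = (rng.random(1000) < expit(X[:, 0])).astype(float)
        with caplog.at_level("WARNING", logger="hotscan"):
            model = fit_background(
                X, y, ["good", "dead"], {"good": EPIGENETIC, "dead": EPIGENETIC},
                (1.0, 1.0),
            )
        assert "dead" in caplog.text
        assert "dead" in model.dropped_columns
        assert "dead" not in model.coefficients.index

    def test_aliased_column_dropped(self, rng):
        x = rng.normal(size=2000)
        X = np.column_stack([x, 2 * x])
        y = (rng.random(2000) < expit(x)).astype(float)
        model = fit_background(
            X, y, ["a", "b"], {"a": EPIGENETIC, "b": EPIGENETIC}, (1.0, 1.0)
        )
        assert len(model.dropped_columns) == 1

    def test_separation_falls_back_to_ridge(self, caplog):
        X = np.concatenate([np.zeros(50), np.ones(50)])[:, None]
        y = np.concatenate([np.zeros(50), np.ones(50)])
        with caplog.at_level("WARNING", logger="hotscan"):
            model = fit_background(X, y, ["sep"], {"sep": EPIGENETIC},
                                   (1.0, 1.0))
        assert np.isfinite(model.coefficients["sep"])
        assert np.isfinite(model.standard_errors["sep"])

    def test_offset_invariance_to_control_count(self, rng):
        """Doubling the control draw changes the fitted intercept but not
        corrected predictions (within fitting noise)."""
        n_pop = 400_000
        x_pop = (rng.random(n_pop) < 0.3).astype(float)
        p = expit(-7 + 1.0 * x_pop)
        y_pop = (rng.random(n_pop) < p).astype(float)
        cases = np.flatnonzero(y_pop == 1)
        ctl_pool = np.flatnonzero(y_pop == 0)
        preds = []
        for mult in (1, 2):
            controls = rng.choice(ctl_pool, size=mult * len(cases), replace=False)
            idx = np.concatenate([cases, controls])
            X = x_pop[idx][:, None]
            y = y_pop[idx]
            f1 = 1.0
            f0 = mult * len(cases) / len(ctl_pool)
            m = fit_background(X, y, ["t"], {"t": EPIGENETIC}, (f1, f0))
            preds.append(m.predict(np.array([[0.0], [1.0]]), ["t"]))
        assert np.allclose(preds[0], preds[1], rtol=0.1)


class TestPrediction:
    def test_logistic_of_zero(self):
        m = _manual_model({"f": 0.0})
        assert m.predict(np.array([[1.0]]), ["f"])[0] == pytest.approx(0.5)

    def test_inverse_logit_arithmetic(self):
        m = _manual_model({"f": 0.0})
        m.coefficients["intercept"] = -np.log(999)
        assert m.predict(np.array([[0.0]]), ["f"])[0] == pytest.approx(0.001)

    def test_burden_linearity(self):
        gamma = 0.7
        m = _manual_model({"f": 1.0, "log_burden": gamma})
        x1 = np.array([[0.3, 1.0]])
        x2 = np.array([[0.3, 2.5]])
        lp1 = m.linear_predictor(x1, ["f", "log_burden"])[0]
        lp2 = m.linear_predictor(x2, ["f", "log_burden"])[0]
        assert lp2 - lp1 == pytest.approx(gamma * 1.5)


class TestZValueTable:
    def test_definition_and_order(self):
        m = _manual_model({"a": 0.5, "b": 0.32})
        m.standard_errors[:] = 0.1
        tab = zvalue_table(m)
        assert tab["feature"].tolist() == ["a", "b"]
        assert tab["zvalue"].tolist() == pytest.approx([5.0, 3.2])

    def test_dropped_column_absent(self, rng):
        X = np.column_stack([rng.normal(size=500), np.zeros(500)])
        y = (rng.random(500) < 0.5).astype(float)
        m = fit_background(X, y, ["x", "z"], {"x": EPIGENETIC, "z": EPIGENETIC},
                           (1.0, 1.0))
        assert "z" not in zvalue_table(m)["feature"].tolist()


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        m = _manual_model({"f": 1.2, "g": -0.4}, offset=-8.1,
                          scales={"g": 2.0})
        path = tmp_path / "model.json"
        m.to_json(path)
        back = BackgroundModel.from_json(path)
        pd.testing.assert_series_equal(m.coefficients, back.coefficients)
        assert back.offset_correction == m.offset_correction
        assert back.standardizer.scales == m.standardizer.scales
        x = np.array([[0.5, 1.5]])
        assert back.predict(x, ["f", "g"])[0] == m.predict(x, ["f", "g"])[0]


@pytest.fixture(scope="module")
def fitted_field():
    genome = generate_genome(200_000, 1, 0.42, seed=21)
    tracks = generate_tracks(
        genome, [TrackConfig("open", "binary", coverage_fraction=0.25)], seed=22
    )
    cfg = SimulationConfig(
        genome_length=200_000, n_samples=12, intercept=float(logit(2e-4)),
        betas={"open": 1.0},
        tracks=[TrackConfig("open", "binary", coverage_fraction=0.25)],
        burden_log_sd=0.3,
    )
    catalog, truth = simulate_catalog(genome, tracks, cfg, seed=23)
    mask = RegionSet([("chr1", 0, 200_000)])
    specs = [
        FeatureSpec("open", EPIGENETIC, BINARY_OVERLAY, "user_track",
                    tracks["open"]),
    ]
    burden = sample_burden(catalog)
    asm = FeatureAssembler(genome, specs, burden)
    table = sample_sites(catalog, mask, genome, seed=24, assembler=asm)
    X, y, names, std = build_design_matrix(table, asm)
    model = fit_background(
        X, y, names, dict(zip(names, asm.column_categories)),
        table.sampling_fractions, std,
    )
    field = ProbabilityField(model, asm, mask)
    return genome, catalog, truth, mask, model, field


class TestProbabilityField:
    def test_deterministic_evaluation(self, fitted_field):
        *_, field = fitted_field
        a = field.window_success("chr1", 1000, 1021)
        b = field.window_success("chr1", 1000, 1021)
        assert np.array_equal(a, b)

    def test_unknown_sample_errors(self, fitted_field):
        *_, field = fitted_field
        with pytest.raises(KeyError):
            field.probability("NOT_A_SAMPLE", "chr1", 100)

    def test_masked_position_errors(self, fitted_field):
        genome, catalog, truth, mask, model, field = fitted_field
        small_mask = RegionSet([("chr1", 0, 1000)])
        f2 = ProbabilityField(model, field.assembler, small_mask)
        with pytest.raises(ValueError, match="outside"):
            f2.probability(field.samples[0], "chr1", 5000)

    def test_probabilities_near_truth(self, fitted_field):
        genome, catalog, truth, mask, model, field = fitted_field
        rng = np.random.default_rng(0)
        pos = rng.integers(10, 199_990, size=200)
        s = field.samples[0]
        pred = np.array([field.probability(s, "chr1", int(p)) for p in pos])
        true = truth.true_probability(s, "chr1", pos)
        # agreement in aggregate (log scale within ~40%)
        assert np.mean(np.log(pred) - np.log(true)) == pytest.approx(0, abs=0.4)

    def test_decile_calibration(self, fitted_field):
        """Binning positions by predicted p, observed mutation frequency per
        decile matches the mean prediction within 3 Monte-Carlo SDs."""
        genome, catalog, truth, mask, model, field = fitted_field
        eta = field._positional_eta("chr1")
        events = {}
        for rec in catalog.records:
            if rec.variant_class == "SNV":
                events.setdefault(rec.sample_id, set()).add(rec.position - 1)
        ok = np.isfinite(eta)
        pos_ok = np.flatnonzero(ok)
        P, O = [], []
        for i, s in enumerate(field.samples):
            p = expit(eta[pos_ok] + field.sample_offsets[i])
            y = np.zeros(len(pos_ok))
            hit = np.array(sorted(events.get(s, ())), dtype=np.int64)
            y[np.isin(pos_ok, hit)] = 1.0
            P.append(p)
            O.append(y)
        P = np.concatenate(P)
        O = np.concatenate(O)
        deciles = np.quantile(P, np.linspace(0, 1, 11))
        deciles[0], deciles[-1] = -np.inf, np.inf
        which = np.digitize(P, deciles[1:-1])
        for d in range(10):
            sel = which == d
            if sel.sum() == 0:
                continue
            exp_mean = P[sel].mean()
            obs_mean = O[sel].mean()
            mc_sd = np.sqrt((P[sel] * (1 - P[sel])).sum()) / sel.sum()
            assert abs(obs_mean - exp_mean) <= 3 * mc_sd + 1e-12

    def test_predict_probability_wrapper(self, fitted_field):
        *_, field = fitted_field
        s = field.samples[0]
        assert predict_probability(field, s, "chr1", 101) == field.probability(
            s, "chr1", 100
        )
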