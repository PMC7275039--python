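"""Canonical synthetic validation studies.

These functions define the package's reference study conditions — fully
synthetic cohorts with known truth — and measure how well the method
recovers that truth: numerical exactness of the Poisson-binomial tail and
padded BH correction, recovery of planted feature effects by stability
selection, false-discovery calibration on null cohorts, power on spiked
hotspots, probability calibration, genome/region mode consistency, and
bitwise determinism.  Problem sizes are desk-scale (1-10 Mb genomes, 30
samples); docs/methods.md discusses what they do and do not demonstrate.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from . import features as ft
from .io import RegionSet
from .lasso import stability_select
from .model import ProbabilityField, fit_background
from .sampling import build_design_matrix, sample_sites
from .scan import bh_correct, call_hotspots, poisson_binomial_tail
from .simulate import (
    SimulationConfig, Spike, TrackConfig, choose_spike_windows,
    generate_genome, generate_tracks, simulate_catalog,
)


# ---------------------------------------------------------------------------
# 1. Poisson-binomial exactness
# ---------------------------------------------------------------------------

def pb_exactness_study(seed: int = 0, n_vectors: int = 100) -> dict:
    """Max |DP tail - 2^N brute force| over N<=12 and all k, plus the
    homogeneous-q comparison against the binomial survival function."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 13))
        q = rng.random(n)
        outcomes = np.array(list(itertools.product([0, 1], repeat=n)))
        probs = np.prod(np.where(outcomes, q, 1 - q), axis=1)
        counts = outcomes.sum(axis=1)
        for k in range(n + 1):
            brute = probs[counts >= k].sum()
            err = abs(poisson_binomial_tail(q, k) - brute)
            max_err = max(max_err, err)
    max_err_binom = 0.0
    for n in (10, 100, 500):
        p = float(rng.uniform(0.001, 0.05))
        q = np.full(n, p)
        for k in (1, 2, 3, max(1, n // 50)):
            err = abs(poisson_binomial_tail(q, k) - stats.binom.sf(k - 1, n, p))
            max_err_binom = max(max_err_binom, err)
    return {"max_abs_err_exact": max_err, "max_abs_err_binomial": max_err_binom,
            "n_vectors": n_vectors}


# ---------------------------------------------------------------------------
# 2. BH padded equivalence
# ---------------------------------------------------------------------------

def bh_padding_study(seed: int = 0, n_cases: int = 100) -> dict:
    """Max |bh_correct - textbook BH on the explicitly padded vector|."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(1, 60))
        pad = int(rng.integers(0, 2000))
        p = rng.random(n) ** rng.uniform(0.5, 4.0)
        ours = bh_correct(p, n + pad)
        _, ref, _, _ = multipletests(
            np.concatenate([p, np.ones(pad)]), method="fdr_bh"
        )
        max_err = max(max_err, float(np.max(np.abs(ours - ref[:n]))))
    return {"max_abs_err": max_err, "n_cases": n_cases}


# ---------------------------------------------------------------------------
# 3. Planted-support recovery
# ---------------------------------------------------------------------------

TRUE_BETAS = {"track00": 1.2, "track01": -1.0, "track02": 0.8}
N_CANDIDATE_TRACKS = 20


def _recovery_inputs(seed: int):
    cfgs = [
        TrackConfig(f"track{i:02d}", "binary", coverage_fraction=0.3,
                    interval_length=1000)
        for i in range(N_CANDIDATE_TRACKS)
    ]
    genome = generate_genome(10_000_000, 1, 0.41, seed=seed)
    tracks = generate_tracks(genome, cfgs, seed=seed + 1)
    sim = SimulationConfig(
        genome_length=10_000_000, n_samples=30,
        intercept=float(logit(2.5e-4)),
        betas=dict(TRUE_BETAS), tracks=cfgs,
    )
    catalog, truth = simulate_catalog(genome, tracks, sim, seed=seed + 2)
    return genome, tracks, cfgs, catalog, truth


def recovery_run(seed: int, n_boot: int = 20, n_folds: int = 5,
                 n_lambdas: int = 25, lambda_min_ratio: float = 1e-2) -> dict:
    """One seeded run: stability selection over 20 candidate tracks on
    ~200k training rows, then the unpenalized refit on the selected set."""
    genome, tracks, cfgs, catalog, truth = _recovery_inputs(seed * 1000 + 1)
    mask = RegionSet([("chr1", 0, genome.lengths["chr1"])])
    specs = [
        ft.FeatureSpec(c.name, ft.EPIGENETIC, ft.BINARY_OVERLAY,
                       "user_track", tracks[c.name])
        for c in cfgs
    ]
    burden = ft.sample_burden(catalog)
    asm = ft.FeatureAssembler(genome, specs, burden)
    table = sample_sites(catalog, mask, genome, max_mutated=100_000,
                         seed=seed * 1000 + 3, assembler=asm)
    X, y, names, std = build_design_matrix(table, asm)
    n_pos = len(asm.position_columns)
    sel = stability_select(
        X[:, :n_pos], y, asm.position_columns, asm.position_categories,
        n_boot=n_boot, seed=seed * 1000 + 4, n_folds=n_folds,
        n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio,
        min_rows_warn=0,
    )
    keep = sel.selected + asm.sample_columns
    idx = [names.index(c) for c in keep]
    model = fit_background(
        X[:, idx], y, keep,
        dict(zip(asm.column_names, asm.column_categories)),
        table.sampling_fractions, std,
    )
    beta_err = {
        name: abs(float(model.coefficients.get(name, 0.0)) - b)
        for name, b in TRUE_BETAS.items()
    }
    return {
        "selected": sel.selected,
        "support_exact": set(sel.selected) == set(TRUE_BETAS),
        "max_beta_err": max(beta_err.values()),
        "n_rows": len(table),
    }


def recovery_study(seed: int = 0, n_runs: int = 10) -> dict:
    runs = [recovery_run(seed * 100 + r) for r in range(n_runs)]
    return {
        "n_runs": n_runs,
        "support_exact_runs": sum(r["support_exact"] for r in runs),
        "max_beta_err": max(r["max_beta_err"] for r in runs),
        "runs": runs,
    }


# ---------------------------------------------------------------------------
# 4/5. FDR calibration (null) and spike-in power
# ---------------------------------------------------------------------------

LOW_TMB = dict(
    genome_length=10_000_000,
    n_samples=30,
    rate=1.5e-7,        # ~0.15 mutations / Mb / sample: a low-burden cohort
    n_spikes=10,
    spike_prob=0.15,
)


def _scan_run(seed: int, spiked: bool) -> dict:
    """Simulate one cohort (optionally with spiked hotspots), fit the
    background model on it, scan, and compare calls against the truth."""
    L = LOW_TMB["genome_length"]
    genome = generate_genome(L, 1, 0.41, seed=seed)
    sim = SimulationConfig(
        genome_length=L, n_samples=LOW_TMB["n_samples"],
        intercept=float(logit(LOW_TMB["rate"])),
    )
    if spiked:
        sim.spikes = choose_spike_windows(
            genome, LOW_TMB["n_spikes"], success_prob=LOW_TMB["spike_prob"],
            seed=seed + 1,
        )
    catalog, truth = simulate_catalog(genome, {}, sim, seed=seed + 2)
    mask = ft.build_mask(genome)
    burden = ft.sample_burden(catalog)
    asm = ft.FeatureAssembler(genome, [], sample_covariates=burden)
    table = sample_sites(catalog, mask, genome, seed=seed + 3, assembler=asm)
    X, y, names, std = build_design_matrix(table, asm)
    # homogeneous simulated cohort: intercept-only background model
    model = fit_background(
        np.empty((len(y), 0)), y, [], {}, table.sampling_fractions, std,
    )
    field = ProbabilityField(model, asm, mask)
    calls = call_hotspots(field, catalog, mask, fdr_threshold=0.05,
                          genome_lengths=genome.lengths)
    spike_spans = truth.spike_windows()

    def hits_spike(call):
        return any(
            call.contig == c and call.start < e and call.end > s
            for c, s, e in spike_spans
        )

    n_true = sum(hits_spike(c) for c in calls)
    n_false = len(calls) - n_true
    recalled = sum(
        any(c.contig == sc and c.start < se and c.end > ss for c in calls)
        for sc, ss, se in spike_spans
    )
    return {
        "n_calls": len(calls),
        "n_false_calls": n_false,
        "spikes_recalled": recalled,
        "fdp": n_false / len(calls) if calls else 0.0,
    }


def fdr_null_study(seed: int = 0, n_runs: int = 20) -> dict:
    runs = [_scan_run(seed * 100 + 10 * r, spiked=False) for r in range(n_runs)]
    return {
        "n_runs": n_runs,
        "mean_fdp": float(np.mean([r["fdp"] for r in runs])),
        "zero_call_runs": sum(r["n_calls"] == 0 for r in runs),
        "total_false_calls": sum(r["n_false_calls"] for r in runs),
    }


def spike_power_study(seed: int = 0, n_runs: int = 10) -> dict:
    runs = [_scan_run(seed * 100 + 10 * r + 5, spiked=True) for r in range(n_runs)]
    return {
        "n_runs": n_runs,
        "median_recall": float(np.median([r["spikes_recalled"] for r in runs])),
        "n_spikes": LOW_TMB["n_spikes"],
        "mean_fdp": float(np.mean([r["fdp"] for r in runs])),
        "total_false_calls": sum(r["n_false_calls"] for r in runs),
    }


# ---------------------------------------------------------------------------
# 6. Model calibration
# ---------------------------------------------------------------------------

def calibration_study(seed: int = 0) -> dict:
    """Decile-binned predicted vs observed mutation frequency.

    Returns the worst deviation in Monte-Carlo-SD units across deciles.
    """
    cfgs = [
        TrackConfig("open", "binary", coverage_fraction=0.25),
        TrackConfig("timing", "continuous", period=200_000),
    ]
    genome = generate_genome(1_000_000, 1, 0.41, seed=seed)
    tracks = generate_tracks(genome, cfgs, seed=seed + 1)
    sim = SimulationConfig(
        genome_length=1_000_000, n_samples=30,
        intercept=float(logit(2e-4)),
        betas={"open": 1.0, "timing": -0.5}, tracks=cfgs,
        burden_log_sd=0.4,
    )
    catalog, truth = simulate_catalog(genome, tracks, sim, seed=seed + 2)
    mask = ft.build_mask(genome)
    specs = [
        ft.FeatureSpec("open", ft.EPIGENETIC, ft.BINARY_OVERLAY,
                       "user_track", tracks["open"]),
        ft.FeatureSpec("timing", ft.EPIGENETIC, ft.CONTINUOUS_ENC,
                       "user_track", tracks["timing"]),
    ]
    burden = ft.sample_burden(catalog)
    asm = ft.FeatureAssembler(genome, specs, burden)
    table = sample_sites(catalog, mask, genome, seed=seed + 3, assembler=asm)
    X, y, names, std = build_design_matrix(table, asm)
    model = fit_background(
        X, y, names, dict(zip(names, asm.column_categories)),
        table.sampling_fractions, std,
    )
    field = ProbabilityField(model, asm, mask)
    eta = field._positional_eta("chr1")
    ok = np.flatnonzero(np.isfinite(eta))
    events: dict[str, np.ndarray] = {}
    for rec in catalog.records:
        events.setdefault(rec.sample_id, []).append(rec.position - 1)
    P, O = [], []
    for i, s in enumerate(field.samples):
        p = expit(eta[ok] + field.sample_offsets[i])
        hit = np.zeros(len(ok))
        pos = np.array(sorted(set(events.get(s, []))), dtype=np.int64)
        hit[np.isin(ok, pos)] = 1.0
        P.append(p)
        O.append(hit)
    P = np.concatenate(P)
    O = np.concatenate(O)
    edges = np.quantile(P, np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf
    which = np.digitize(P, edges[1:-1])
    worst = 0.0
    deciles = []
    for d in range(10):
        sel = which == d
        if sel.sum() == 0:
            continue
        exp_mean = float(P[sel].mean())
        obs_mean = float(O[sel].mean())
        mc_sd = float(np.sqrt((P[sel] * (1 - P[sel])).sum()) / sel.sum())
        zdev = abs(obs_mean - exp_mean) / mc_sd if mc_sd > 0 else 0.0
        deciles.append({"expected": exp_mean, "observed": obs_mean,
                        "sd_units": zdev})
        worst = max(worst, zdev)
    return {"max_sd_units": worst, "deciles": deciles}


# ---------------------------------------------------------------------------
# 7. Genome vs region mode consistency
# ---------------------------------------------------------------------------

def mode_consistency_study(seed: int = 0) -> dict:
    genome = generate_genome(500_000, 1, 0.41, seed=seed)
    sim = SimulationConfig(
        genome_length=500_000, n_samples=20, intercept=float(logit(5e-5)),
        spikes=[Spike("chr1", 100_000, 100_021, 0.4),
                Spike("chr1", 300_000, 300_021, 0.4)],
    )
    catalog, _ = simulate_catalog(genome, {}, sim, seed=seed + 1)
    mask = ft.build_mask(genome)
    burden = ft.sample_burden(catalog)
    asm = ft.FeatureAssembler(genome, [], sample_covariates=burden)
    table = sample_sites(catalog, mask, genome, seed=seed + 2, assembler=asm)
    X, y, names, std = build_design_matrix(table, asm)
    model = fit_background(np.empty((len(y), 0)), y, [], {},
                           table.sampling_fractions, std)
    field = ProbabilityField(model, asm, mask)
    regions = RegionSet([("chr1", 50_000, 350_000)])
    kw = dict(fdr_threshold=1.0 - 1e-9, merge_overlapping=False,
              genome_lengths=genome.lengths)
    g_calls = call_hotspots(field, catalog, mask, **kw)
    r_calls = call_hotspots(field, catalog, mask, mode="region",
                            regions=regions, **kw)
    g_by_center = {c.center: c for c in g_calls}
    n_shared = 0
    p_equal = True
    fdr_ratio_consistent = True
    m_genome = mask.total_length
    m_region = mask.intersect(regions).total_length
    for rc in r_calls:
        gc = g_by_center.get(rc.center)
        if gc is None:
            p_equal = False
            continue
        n_shared += 1
        if rc.pvalue != gc.pvalue:
            p_equal = False
    return {
        "n_shared_windows": n_shared,
        "pvalues_identical": p_equal,
        "m_genome": int(m_genome),
        "m_region": int(m_region),
    }


# ---------------------------------------------------------------------------
# 8. Determinism
# ---------------------------------------------------------------------------

def determinism_study(seed: int = 0, tmpdir=None) -> dict:
    """Two end-to-end pipeline runs (different thread counts) must produce
    byte-identical hotspot tables."""
    import tempfile
    from pathlib import Path

    from .pipeline import RunConfig, run_pipeline
    from .simulate import write_fixture_dir

    with tempfile.TemporaryDirectory(dir=tmpdir) as td:
        td = Path(td)
        sim = SimulationConfig(
            genome_length=200_000, n_samples=15,
            intercept=float(logit(5e-5)),
            tracks=[TrackConfig("open", "binary", coverage_fraction=0.25)],
            betas={"open": 1.0},
            spikes=[Spike("chr1", 50_000, 50_021, 0.5)],
        )
        files = write_fixture_dir(td / "fix", sim, seed=seed)
        digests = []
        for i, threads in enumerate((1, 3, 1)):
            cfg = RunConfig(
                genome=files["genome"], mutations=files["mutations"],
                output_dir=str(td / f"run{i}"),
                binary_tracks={"open": files["tracks"]["open"]},
                context="nopenta", run_selection=False,
                seed=seed, n_threads=threads,
            )
            run_pipeline(cfg)
            digests.append((td / f"run{i}" / "hotspots.tsv").read_bytes())
    return {
        "byte_identical": digests[0] == digests[1] == digests[2],
        "n_runs": 3,
    }
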