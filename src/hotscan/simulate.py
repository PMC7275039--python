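"""Fully in-silico fixtures: genome, covariate tracks, and cohort mutation
catalogs drawn from a known logistic background model with optional spiked
hotspots.

The generative model matches the model family fitted by the package: each
(sample, position) pair is an independent Bernoulli trial with

    p = logistic(intercept + sum_t beta_t * x_t(position) + b_sample)

where ``b_sample`` is a per-sample log-odds offset (burden heterogeneity).
Spiked windows override the per-sample *window* success probability: each
sample is mutated somewhere in the window with the configured probability,
independently of the background.  Generation is Bernoulli-per-position, not
Poisson thinning, so parameter-recovery tests are exact in-family checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .io import (
    BINARY, CONTINUOUS, GenomeSequence, GenomicTrack, MutationCatalog,
    MutationRecord,
)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TrackConfig:
    name: str
    kind: str = BINARY                  # binary | continuous
    coverage_fraction: float = 0.2      # binary tracks
    interval_length: int = 1000         # binary tracks
    period: int = 200_000               # continuous tracks (sinusoid)
    noise_sd: float = 0.3               # continuous tracks
    bin_width: int = 1000               # continuous tracks


@dataclass
class Spike:
    contig: str
    start: int                          # 0-based half-open window
    end: int
    success_prob: float                 # per-sample window success probability


@dataclass
class SimulationConfig:
    genome_length: int = 1_000_000
    n_contigs: int = 1
    gc_fraction: float = 0.41
    n_samples: int = 30
    intercept: float = logit(1e-5)
    betas: dict[str, float] = field(default_factory=dict)
    tracks: list[TrackConfig] = field(default_factory=list)
    burden_log_sd: float = 0.0          # sd of per-sample log-odds offsets
    spikes: list[Spike] = field(default_factory=list)
    indel_fraction: float = 0.0


@dataclass
class TruthSet:
    """Everything the generator knew: spiked windows, coefficients, and a
    queryable per-(sample, position) true background probability."""

    config: SimulationConfig
    spikes: list[Spike]
    betas: dict[str, float]
    intercept: float
    sample_ids: list[str]
    burden_offsets: np.ndarray          # per-sample log-odds offsets
    eta_pos: dict[str, np.ndarray]      # positional linear predictor per contig

    def true_probability(
        self, sample_id: str, contig: str, positions0: np.ndarray
    ) -> np.ndarray:
        i = self.sample_ids.index(sample_id)
        eta = self.eta_pos[contig][np.asarray(positions0, dtype=np.int64)]
        return expit(eta + self.burden_offsets[i])

    def spike_windows(self) -> list[tuple[str, int, int]]:
        return [(s.contig, s.start, s.end) for s in self.spikes]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_genome(
    length: int, n_contigs: int = 1, gc_fraction: float = 0.41, seed: int = 0
) -> GenomeSequence:
    """I.i.d. bases at the stated GC content, split evenly across contigs."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    per = [length // n_contigs] * n_contigs
    per[-1] += length - sum(per)
    lut = np.frombuffer(b"ACGT", dtype="S1")
    contigs = {}
    for i, contig_len in enumerate(per):
        codes = rng.choice(4, size=contig_len, p=probs)
        contigs[f"chr{i + 1}"] = lut[codes].tobytes().decode("ascii")
    return GenomeSequence(contigs)


def generate_tracks(
    genome: GenomeSequence, configs: list[TrackConfig], seed: int = 0
) -> dict[str, GenomicTrack]:
    """Binary tracks cover the configured genome fraction in random
    non-overlapping intervals; continuous tracks are a standardized smooth
    profile (sinusoid + noise), a stand-in for e.g. replication timing."""
    rng = np.random.default_rng(seed)
    out: dict[str, GenomicTrack] = {}
    for cfg in configs:
        ivals = {}
        for contig, length in genome.lengths.items():
            if cfg.kind == BINARY:
                slot = cfg.interval_length
                n_slots = length // slot
                n_take = int(round(cfg.coverage_fraction * length / slot))
                n_take = min(n_take, n_slots)
                if n_take == 0:
                    continue
                chosen = np.sort(rng.choice(n_slots, size=n_take, replace=False))
                starts = chosen * slot
                ends = starts + slot
                ivals[contig] = (starts, ends, None)
            else:
                edges = np.arange(0, length + cfg.bin_width, cfg.bin_width)
                edges[-1] = min(edges[-1], length)
                if edges[-1] == edges[-2]:
                    edges = edges[:-1]
                starts, ends = edges[:-1], edges[1:]
                mid = (starts + ends) / 2
                vals = np.sin(2 * np.pi * mid / cfg.period)
                vals = vals + rng.normal(0, cfg.noise_sd, size=len(vals))
                vals = (vals - vals.mean()) / vals.std()
                ivals[contig] = (starts, ends, vals)
        out[cfg.name] = GenomicTrack(
            cfg.kind, ivals, default_value=0.0, name=cfg.name
        )
    return out


def positional_linear_predictor(
    genome: GenomeSequence,
    tracks: dict[str, GenomicTrack],
    betas: dict[str, float],
    intercept: float,
) -> dict[str, np.ndarray]:
    """intercept + sum beta_t x_t(pos) per contig; -inf at N bases."""
    out = {}
    for contig, length in genome.lengths.items():
        eta = np.full(length, float(intercept))
        pos = np.arange(length, dtype=np.int64)
        for name, beta in betas.items():
            if beta == 0.0:
                continue
            eta += beta * tracks[name].values_at(contig, pos)
        eta[genome.encoded(contig) == 4] = -np.inf
        out[contig] = eta
    return out


def simulate_catalog(
    genome: GenomeSequence,
    tracks: dict[str, GenomicTrack],
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[MutationCatalog, TruthSet]:
    """Draw a cohort SNV (and optionally indel) catalog from the logistic
    model, then overlay spiked hotspot windows."""
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    burden_offsets = (
        rng.normal(0, config.burden_log_sd, size=config.n_samples)
        if config.burden_log_sd > 0
        else np.zeros(config.n_samples)
    )
    eta_pos = positional_linear_predictor(
        genome, tracks, config.betas, config.intercept
    )
    max_p = max(
        (expit(e[np.isfinite(e)]).max() if np.isfinite(e).any() else 0.0)
        for e in eta_pos.values()
    ) * expit(burden_offsets.max()) / expit(0)
    if max_p > 0.5:
        import logging

        logging.getLogger("hotscan").warning(
            "background mutation probability exceeds 0.5 outside spikes"
        )

    records: list[MutationRecord] = []
    uniform_burden = np.allclose(burden_offsets, burden_offsets[0])
    for contig, eta in eta_pos.items():
        enc = genome.encoded(contig)
        seq = genome.contigs[contig]
        p_shared = expit(eta + burden_offsets[0]) if uniform_burden else None
        for i, sample in enumerate(sample_ids):
            p = p_shared if uniform_burden else expit(eta + burden_offsets[i])
            hits = np.flatnonzero(rng.random(len(p)) < p)
            for pos0 in hits.tolist():
                records.append(
                    _make_record(rng, seq, enc, contig, pos0, sample, config)
                )

    for spike in config.spikes:
        enc = genome.encoded(spike.contig)
        seq = genome.contigs[spike.contig]
        valid = np.flatnonzero(enc[spike.start : spike.end] != 4) + spike.start
        if len(valid) == 0:
            raise ValueError(f"spike window {spike} contains only N bases")
        for i, sample in enumerate(sample_ids):
            if rng.random() < spike.success_prob:
                pos0 = int(rng.choice(valid))
                records.append(
                    _make_record(
                        rng, seq, enc, spike.contig, pos0, sample, config,
                        snv_only=True,
                    )
                )

    catalog = MutationCatalog(records)
    truth = TruthSet(
        config=config,
        spikes=list(config.spikes),
        betas=dict(config.betas),
        intercept=float(config.intercept),
        sample_ids=sample_ids,
        burden_offsets=burden_offsets,
        eta_pos=eta_pos,
    )
    return catalog, truth


def _make_record(
    rng, seq, enc, contig, pos0, sample, config, snv_only=False
) -> MutationRecord:
    ref = seq[pos0]
    if not snv_only and config.indel_fraction > 0 and rng.random() < config.indel_fraction:
        if rng.random() < 0.5 and pos0 + 1 < len(seq) and enc[pos0 + 1] != 4:
            # deletion of the next base
            return MutationRecord(contig, pos0 + 1, seq[pos0 : pos0 + 2], ref, sample)
        ins = _BASES[rng.integers(4)]
        return MutationRecord(contig, pos0 + 1, ref, ref + ins, sample)
    alts = [b for b in _BASES if b != ref]
    alt = alts[rng.integers(3)]
    return MutationRecord(contig, pos0 + 1, ref, alt, sample)


def choose_spike_windows(
    genome: GenomeSequence,
    n_spikes: int,
    window: int = 21,
    success_prob: float = 0.15,
    min_gap: int = 10_000,
    seed: int = 0,
) -> list[Spike]:
    """Evenly spaced, N-free spike windows on the first contig."""
    rng = np.random.default_rng(seed)
    contig = next(iter(genome.contigs))
    length = genome.lengths[contig]
    enc = genome.encoded(contig)
    spikes = []
    slots = np.linspace(min_gap, length - min_gap - window, n_spikes).astype(int)
    for base in slots:
        start = int(base + rng.integers(0, min(1000, min_gap)))
        for _ in range(100):
            if (enc[start : start + window] != 4).all():
                break
            start += window
        spikes.append(Spike(contig, start, start + window, success_prob))
    return spikes


# ---------------------------------------------------------------------------
# Fixture directory
# ---------------------------------------------------------------------------

def write_fixture_dir(outdir, config: SimulationConfig, seed: int = 0) -> dict:
    """Emit a complete ready-to-run dataset: FASTA genome, mutation TSV,
    track BED/bedGraph files, and a truth JSON.  Returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(
        config.genome_length, config.n_contigs, config.gc_fraction, seed
    )
    tracks = generate_tracks(genome, config.tracks, seed + 1)
    catalog, truth = simulate_catalog(genome, tracks, config, seed + 2)

    files = {"genome": str(outdir / "genome.fa"), "mutations": str(outdir / "mutations.tsv")}
    genome.to_fasta(files["genome"])
    catalog.to_tsv(files["mutations"])
    track_dir = outdir / "tracks"
    track_dir.mkdir(exist_ok=True)
    files["tracks"] = {}
    for cfg in config.tracks:
        track = tracks[cfg.name]
        if cfg.kind == BINARY:
            path = track_dir / f"{cfg.name}.bed"
            with open(path, "wt") as fh:
                for contig in genome.contigs:
                    starts, ends, _ = track._ivals.get(contig, ([], [], None))
                    for s, e in zip(starts, ends):
                        fh.write(f"{contig}\t{s}\t{e}\n")
        else:
            path = track_dir / f"{cfg.name}.bedGraph"
            with open(path, "wt") as fh:
                for contig in genome.contigs:
                    starts, ends, vals = track._ivals.get(contig, ([], [], []))
                    for s, e, v in zip(starts, ends, vals):
                        fh.write(f"{contig}\t{s}\t{e}\t{v:.6f}\n")
        files["tracks"][cfg.name] = str(path)
    truth_json = {
        "intercept": truth.intercept,
        "betas": truth.betas,
        "samples": truth.sample_ids,
        "burden_offsets": truth.burden_offsets.tolist(),
        "spikes": [
            {"contig": s.contig, "start": s.start, "end": s.end,
             "success_prob": s.success_prob}
            for s in truth.spikes
        ],
    }
    files["truth"] = str(outdir / "truth.json")
    with open(files["truth"], "wt") as fh:
        json.dump(truth_json, fh, indent=1)
    return files
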