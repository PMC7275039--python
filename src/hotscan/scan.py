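"""Window scan for mutation recurrence.

Every genome position is in principle a hypothesis: a candidate window of
length ``l`` (default 21) centered on it.  In practice only centers whose
window holds mutations from at least ``n`` distinct samples (default 2) are
evaluated; all other positions carry p = 1 and enter the Benjamini-Hochberg
correction as padding, so the number of hypotheses is the number of
analyzable nucleotides (genome mode) or the analyzable nucleotides of the
regions of interest (region mode).

The test statistic is the number of distinct mutated samples in the window;
its null distribution is Poisson-binomial with per-sample window success
probabilities derived from the background model.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .io import MutationCatalog, RegionSet, SNV

logger = logging.getLogger("hotscan")


@dataclass
class CandidateWindow:
    contig: str
    start: int                     # 0-based half-open
    end: int
    center: int
    mutated_samples: frozenset
    mutation_count: int


@dataclass
class HotspotCall:
    contig: str
    start: int
    end: int
    center: int
    mutated_samples: frozenset
    mutation_count: int
    pvalue: float
    fdr: float
    mean_background_prob: float
    rank: int = 0

    @property
    def k_obs(self) -> int:
        return len(self.mutated_samples)


# ---------------------------------------------------------------------------
# Poisson-binomial tail
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(q: np.ndarray) -> np.ndarray:
    """Exact pmf of the number of successes by dynamic-programming
    convolution; support {0..N}."""
    q = np.asarray(q, dtype=np.float64)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("success probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for qi in q:
        new = np.empty(len(pmf) + 1)
        new[0] = pmf[0] * (1 - qi)
        new[1:-1] = pmf[1:] * (1 - qi) + pmf[:-1] * qi
        new[-1] = pmf[-1] * qi
        pmf = new
    return pmf


def poisson_binomial_tail(q: np.ndarray, k_obs: int) -> float:
    """P(K >= k_obs) for the Poisson-binomial count K.

    Exactly 1 for k_obs = 0; clipped below at 1e-300 for numerical floor.
    """
    q = np.asarray(q, dtype=np.float64)
    if k_obs > len(q):
        raise ValueError(f"k_obs={k_obs} exceeds the number of trials {len(q)}")
    if k_obs <= 0:
        return 1.0
    pmf = poisson_binomial_pmf(q)
    tail = float(pmf[k_obs:].sum())
    return min(1.0, max(tail, 1e-300))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg with P=1 padding
# ---------------------------------------------------------------------------

def bh_correct(pvalues: np.ndarray, m_total: int) -> np.ndarray:
    """BH q-values for the evaluated windows among ``m_total`` hypotheses.

    Identical to textbook BH on the evaluated p-values concatenated with
    (m_total - n_evaluated) padding hypotheses at p = 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    n = len(p)
    if m_total < n:
        raise ValueError("m_total smaller than the number of evaluated windows")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    scaled = p[order] * m_total / ranks
    # padding hypotheses all have p=1: their BH value is >= 1, so the
    # step-up running minimum from the right starts at 1
    q_sorted = np.minimum.accumulate(np.concatenate([scaled, [1.0]])[::-1])[::-1][:-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(
    catalog: MutationCatalog,
    mask: RegionSet,
    l: int = 21,
    n: int = 2,
    variant_class: str = SNV,
    regions: RegionSet | None = None,
    genome_lengths: dict[str, int] | None = None,
) -> list[CandidateWindow]:
    """Candidate centers whose l-bp window holds >= n distinct mutated samples.

    Centers must lie in the analyzable mask (and in ``regions`` for region
    mode) with the full window inside the contig.  The recurrence count is
    sample-distinct: several mutations from one sample count once.
    """
    if l % 2 == 0:
        raise ValueError("window length l must be odd (center undefined)")
    if n < 1:
        raise ValueError("recurrence parameter n must be >= 1")
    h = l // 2
    per_contig: dict[str, list[tuple[int, str]]] = {}
    for rec in catalog.records:
        if rec.variant_class == variant_class:
            per_contig.setdefault(rec.contig, []).append(
                (rec.position - 1, rec.sample_id)
            )
    out: list[CandidateWindow] = []
    for contig in sorted(per_contig):
        events = per_contig[contig]
        pos = np.array([e[0] for e in events], dtype=np.int64)
        sample_names = sorted({e[1] for e in events})
        scode = {s: i for i, s in enumerate(sample_names)}
        samp = np.array([scode[e[1]] for e in events], dtype=np.int64)
        # each event covers centers pos-h .. pos+h
        offsets = np.arange(-h, h + 1, dtype=np.int64)
        centers = (pos[:, None] + offsets[None, :]).ravel()
        csamp = np.repeat(samp, l)
        pairs = np.unique(np.stack([centers, csamp], axis=1), axis=0)
        uc, first, counts = np.unique(
            pairs[:, 0], return_index=True, return_counts=True
        )
        ok = counts >= n
        if genome_lengths and contig in genome_lengths:
            length = genome_lengths[contig]
            ok &= (uc >= h) & (uc <= length - h - 1)
        else:
            ok &= uc >= h
        sel_centers = uc[ok]
        if len(sel_centers) == 0:
            continue
        in_mask = mask.contains(contig, sel_centers)
        if regions is not None:
            in_mask &= regions.contains(contig, sel_centers)
        sel_centers = sel_centers[in_mask]
        if len(sel_centers) == 0:
            continue
        # per-center sample sets and raw mutation counts
        order = np.argsort(pairs[:, 0], kind="stable")
        sorted_pairs = pairs[order]
        idx = np.searchsorted(sorted_pairs[:, 0], sel_centers, side="left")
        idx_hi = np.searchsorted(sorted_pairs[:, 0], sel_centers, side="right")
        pos_sorted = np.sort(pos)
        for c, a, b in zip(sel_centers, idx, idx_hi):
            sams = frozenset(sample_names[s] for s in sorted_pairs[a:b, 1])
            lo = np.searchsorted(pos_sorted, c - h, side="left")
            hi = np.searchsorted(pos_sorted, c + h, side="right")
            out.append(
                CandidateWindow(
                    contig=contig,
                    start=int(c - h),
                    end=int(c + h + 1),
                    center=int(c),
                    mutated_samples=sams,
                    mutation_count=int(hi - lo),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Window success probabilities
# ---------------------------------------------------------------------------

def window_success_probs(field, window: CandidateWindow) -> np.ndarray:
    """Per-sample window success probabilities from a probability field.

    ``field`` exposes ``samples`` and ``window_success(contig, start, end)``.
    """
    return field.window_success(window.contig, window.start, window.end)


# ---------------------------------------------------------------------------
# End-to-end calling
# ---------------------------------------------------------------------------

def _evaluate(field, windows: list[CandidateWindow]):
    sample_index = {s: i for i, s in enumerate(field.samples)}
    pvals = np.empty(len(windows))
    mean_q = np.empty(len(windows))
    for i, w in enumerate(windows):
        q = field.window_success(w.contig, w.start, w.end)
        known = [s for s in w.mutated_samples if s in sample_index]
        pvals[i] = poisson_binomial_tail(q, len(known))
        mean_q[i] = float(q.mean()) if len(q) else 0.0
    return pvals, mean_q


def call_hotspots(
    field,
    catalog: MutationCatalog,
    mask: RegionSet,
    l: int = 21,
    n: int = 2,
    fdr_threshold: float = 0.05,
    mode: str = "genome",
    regions: RegionSet | None = None,
    variant_class: str = SNV,
    merge_overlapping: bool = True,
    n_threads: int = 1,
    genome_lengths: dict[str, int] | None = None,
) -> list[HotspotCall]:
    """Scan, test, BH-correct and report hotspots below the FDR threshold.

    Genome mode counts |mask| hypotheses; region mode restricts candidates
    to the regions and counts |mask intersect regions| hypotheses.  Results
    are independent of ``n_threads``.
    """
    if mode not in ("genome", "region"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "region":
        if regions is None:
            raise ValueError("region mode requires a region set")
        m_total = mask.intersect(regions).total_length
    else:
        regions = None
        m_total = mask.total_length
    windows = enumerate_candidates(
        catalog, mask, l=l, n=n, variant_class=variant_class,
        regions=regions, genome_lengths=genome_lengths,
    )
    if not windows:
        return []
    if n_threads > 1:
        # contiguous chunks, deterministically reassembled in order
        chunks = np.array_split(np.arange(len(windows)), n_threads * 4)
        chunks = [c for c in chunks if len(c)]
        with ThreadPoolExecutor(max_workers=n_threads) as pool:
            parts = list(
                pool.map(
                    lambda c: _evaluate(field, [windows[i] for i in c]), chunks
                )
            )
        pvals = np.concatenate([p for p, _ in parts])
        mean_q = np.concatenate([m for _, m in parts])
    else:
        pvals, mean_q = _evaluate(field, windows)
    fdr = bh_correct(pvals, m_total)
    calls = [
        HotspotCall(
            contig=w.contig, start=w.start, end=w.end, center=w.center,
            mutated_samples=w.mutated_samples, mutation_count=w.mutation_count,
            pvalue=float(pvals[i]), fdr=float(fdr[i]),
            mean_background_prob=float(mean_q[i]),
        )
        for i, w in enumerate(windows)
        if fdr[i] < fdr_threshold
    ]
    calls.sort(key=lambda c: (c.pvalue, c.contig, c.start))
    if merge_overlapping:
        calls = merge_calls(calls, catalog, variant_class)
    for r, c in enumerate(calls, 1):
        c.rank = r
    return calls


def merge_calls(
    calls: list[HotspotCall],
    catalog: MutationCatalog,
    variant_class: str = SNV,
) -> list[HotspotCall]:
    """Merge overlapping significant windows that share a mutated position.

    The merged hotspot spans the union, keeps the minimum p-value (and its
    window as representative center), and recounts samples/mutations over
    the union span.
    """
    if not calls:
        return []
    events: dict[str, list[tuple[int, str]]] = {}
    for rec in catalog.records:
        if rec.variant_class == variant_class:
            events.setdefault(rec.contig, []).append((rec.position - 1, rec.sample_id))

    def mut_positions(contig, start, end):
        return {p for p, _ in events.get(contig, []) if start <= p < end}

    ordered = sorted(calls, key=lambda c: (c.contig, c.start))
    groups: list[list[HotspotCall]] = []
    for call in ordered:
        if (
            groups
            and groups[-1][0].contig == call.contig
            and call.start < max(c.end for c in groups[-1])
            and mut_positions(call.contig, call.start, call.end)
            & mut_positions(
                call.contig,
                min(c.start for c in groups[-1]),
                max(c.end for c in groups[-1]),
            )
        ):
            groups[-1].append(call)
        else:
            groups.append([call])
    merged = []
    for grp in groups:
        best = min(grp, key=lambda c: (c.pvalue, c.contig, c.start))
        start = min(c.start for c in grp)
        end = max(c.end for c in grp)
        samples = frozenset()
        count = 0
        for p, s in events.get(best.contig, []):
            if start <= p < end:
                samples |= {s}
                count += 1
        merged.append(
            HotspotCall(
                contig=best.contig, start=start, end=end, center=best.center,
                mutated_samples=samples, mutation_count=count,
                pvalue=best.pvalue, fdr=best.fdr,
                mean_background_prob=best.mean_background_prob,
            )
        )
    merged.sort(key=lambda c: (c.pvalue, c.contig, c.start))
    return merged


# ---------------------------------------------------------------------------
# Baseline rate models
# ---------------------------------------------------------------------------

class RateField:
    """Per-sample per-position flat or covariate-modulated rate field.

    Used by the baseline strategies; mirrors the ProbabilityField interface
    (``samples``, ``window_success``).
    """

    def __init__(self, samples, rates_fn, mask: RegionSet):
        self.samples = list(samples)
        self._rates_fn = rates_fn          # (contig, positions0) -> (S, P) rates
        self.mask = mask

    def window_success(self, contig: str, start: int, end: int) -> np.ndarray:
        pos = np.arange(start, end, dtype=np.int64)
        ok = self.mask.contains(contig, pos)
        pos = pos[ok]
        if len(pos) == 0:
            return np.zeros(len(self.samples))
        rates = self._rates_fn(contig, pos)
        rates = np.clip(rates, 0.0, 1 - 1e-12)
        return -np.expm1(np.log1p(-rates).sum(axis=1))


BASELINE_VARIANTS = ("binomial_avg", "poibin_sample", "poibin_rt", "poibin_rt_local")


def baseline_field(
    catalog: MutationCatalog,
    mask: RegionSet,
    variant: str,
    rt_track=None,
    local_rate_track=None,
    variant_class: str = SNV,
    n_rt_bins: int = 5,
) -> RateField:
    """Build the rate field for one baseline strategy.

    1. ``binomial_avg``: one shared rate, total mutations / (mask x samples).
    2. ``poibin_sample``: per-sample rate burden_i / mask size.
    3. ``poibin_rt``: per-sample rate modulated by the relative mutation
       rate of replication-timing quantile bins.
    4. ``poibin_rt_local``: additionally modulated by the relative rate of
       the local (100-kb) mutation-rate bin.
    """
    if variant not in BASELINE_VARIANTS:
        raise ValueError(f"unknown baseline variant {variant!r}")
    samples = sorted(catalog.samples)
    mask_size = mask.total_length
    events = [
        (r.contig, r.position - 1, r.sample_id)
        for r in catalog.records
        if r.variant_class == variant_class
    ]
    total = len(events)
    burden = {s: 0 for s in samples}
    for _, _, s in events:
        burden[s] += 1
    shared_rate = total / (mask_size * len(samples))
    if variant == "binomial_avg":
        base = np.full(len(samples), shared_rate)
    else:
        base = np.array([burden[s] / mask_size for s in samples])

    rt_edges = rt_rel = None
    if variant in ("poibin_rt", "poibin_rt_local"):
        if rt_track is None:
            raise ValueError(f"variant {variant!r} needs a replication-timing track")
        rt_edges, rt_rel = _relative_rate_by_quantile(
            rt_track, events, mask, n_rt_bins
        )
    local_rel_fn = None
    if variant == "poibin_rt_local":
        if local_rate_track is None:
            raise ValueError("variant 'poibin_rt_local' needs the local-rate track")

        def local_rel_fn(contig, pos):
            local = local_rate_track.values_at(contig, pos)
            return np.where(shared_rate > 0, local / shared_rate, 1.0)

    def rates_fn(contig, pos):
        mult = np.ones(len(pos))
        if rt_rel is not None:
            vals = rt_track.values_at(contig, pos)
            bins = np.clip(np.searchsorted(rt_edges, vals, side="right") - 1,
                           0, len(rt_rel) - 1)
            mult = mult * rt_rel[bins]
        if local_rel_fn is not None:
            mult = mult * local_rel_fn(contig, pos)
        return base[:, None] * mult[None, :]

    return RateField(samples, rates_fn, mask)


def _relative_rate_by_quantile(track, events, mask: RegionSet, n_bins: int):
    """Quantile-bin a track over the mask; relative mutation rate per bin."""
    rng = np.random.default_rng(0)  # fixed probe grid, deterministic
    vals = []
    sizes = []
    for contig in mask.contigs:
        starts, ends = mask.arrays(contig)
        for s, e in zip(starts, ends):
            step = max(1, (e - s) // 1000)
            pos = np.arange(s, e, step)
            vals.append(track.values_at(contig, pos))
            sizes.append(np.full(len(pos), step))
    vals = np.concatenate(vals)
    sizes = np.concatenate(sizes).astype(float)
    edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))[:-1]
    edges[0] = -np.inf
    probe_bins = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
    bin_bases = np.zeros(n_bins)
    np.add.at(bin_bases, probe_bins, sizes)
    ev_vals = np.concatenate([
        track.values_at(contig, np.array([p]))
        for contig, p, _ in events
    ]) if events else np.zeros(0)
    ev_bins = np.clip(np.searchsorted(edges, ev_vals, side="right") - 1, 0, n_bins - 1)
    bin_counts = np.zeros(n_bins)
    np.add.at(bin_counts, ev_bins, 1)
    overall = bin_counts.sum() / bin_bases.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(
            bin_bases > 0, (bin_counts / bin_bases) / overall, 1.0
        )
    rel[~np.isfinite(rel)] = 1.0
    return edges, rel


def baseline_models(
    catalog: MutationCatalog,
    mask: RegionSet,
    variant: str,
    rt_track=None,
    local_rate_track=None,
    l: int = 21,
    n: int = 2,
    fdr_threshold: float = 0.05,
    variant_class: str = SNV,
    genome_lengths: dict[str, int] | None = None,
) -> list[HotspotCall]:
    """Run the scan under one of the four baseline background strategies."""
    field = baseline_field(
        catalog, mask, variant,
        rt_track=rt_track, local_rate_track=local_rate_track,
        variant_class=variant_class,
    )
    return call_hotspots(
        field, catalog, mask, l=l, n=n, fdr_threshold=fdr_threshold,
        variant_class=variant_class, genome_lengths=genome_lengths,
    )
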