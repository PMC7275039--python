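"""Balanced training-set sampling and design-matrix assembly.

Model fitting operates on a case-control sample: up to one million mutated
(position, sample) events plus an equal number of non-mutated
position-sample pairs drawn uniformly over the analyzable mask.  The
sampling fractions of both classes are recorded so the fitted intercept can
be corrected back to the genome-wide prior scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .features import FeatureAssembler
from .io import SNV, GenomeSequence, MutationCatalog, RegionSet

logger = logging.getLogger("hotscan")


@dataclass
class SiteTable:
    """Sampled training sites with labels and sampling fractions.

    ``f1`` = drawn / total in-mask mutated events; ``f0`` = drawn / total
    analyzable non-mutated position-sample pairs.
    """

    contigs: np.ndarray          # per-row contig name
    positions0: np.ndarray       # 0-based positions
    sample_ids: np.ndarray
    labels: np.ndarray           # 1 mutated, 0 non-mutated
    f1: float
    f0: float

    @property
    def n_mutated(self) -> int:
        return int(self.labels.sum())

    @property
    def n_unmutated(self) -> int:
        return int((1 - self.labels).sum())

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def sampling_fractions(self) -> tuple[float, float]:
        return (self.f1, self.f0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.contigs,
                "pos0": self.positions0,
                "sample": self.sample_ids,
                "label": self.labels,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _mask_sampler(mask: RegionSet):
    """Uniform 0-based position sampler over a RegionSet."""
    contigs = mask.contigs
    per_contig = []
    for contig in contigs:
        starts, ends = mask.arrays(contig)
        per_contig.append((contig, starts, ends, np.cumsum(ends - starts)))
    sizes = np.array([pc[3][-1] for pc in per_contig], dtype=np.int64)
    cum_sizes = np.cumsum(sizes)
    total = int(cum_sizes[-1])

    def draw(rng: np.random.Generator, k: int):
        offs = rng.integers(0, total, size=k)
        which = np.searchsorted(cum_sizes, offs, side="right")
        out_contig = np.empty(k, dtype=object)
        out_pos = np.empty(k, dtype=np.int64)
        for ci, (contig, starts, ends, cum) in enumerate(per_contig):
            sel = which == ci
            if not sel.any():
                continue
            local = offs[sel] - (cum_sizes[ci] - sizes[ci])
            ival = np.searchsorted(cum, local, side="right")
            within = local - np.where(ival > 0, cum[ival - 1], 0)
            out_contig[sel] = contig
            out_pos[sel] = starts[ival] + within
        return out_contig, out_pos

    return draw, total


def sample_sites(
    catalog: MutationCatalog,
    mask: RegionSet,
    genome: GenomeSequence,
    variant_class: str = SNV,
    max_mutated: int = 1_000_000,
    seed: int = 0,
    assembler: FeatureAssembler | None = None,
) -> SiteTable:
    """Draw the balanced mutated / non-mutated training sample.

    Mutated rows are (position, sample) mutation events inside the mask
    (one row per event, uniformly subsampled to ``max_mutated`` if needed).
    Non-mutated rows are equal in number: positions uniform over the mask,
    each paired with a uniformly drawn cohort sample and verified
    non-mutated there.  When an ``assembler`` with sequence-context features
    is given, rows without a valid 5-mer context are excluded up front.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if mask.total_length == 0:
        raise ValueError("empty analyzable mask")
    samples = sorted(catalog.samples)
    if not samples:
        raise ValueError("catalog has no samples")

    events = [
        (r.contig, r.position - 1, r.sample_id)
        for r in catalog.records
        if r.variant_class == variant_class
    ]
    if not events:
        raise ValueError(f"no {variant_class} mutations in catalog")
    ev_contig = np.array([e[0] for e in events], dtype=object)
    ev_pos = np.array([e[1] for e in events], dtype=np.int64)
    ev_sample = np.array([e[2] for e in events], dtype=object)
    in_mask = np.zeros(len(events), dtype=bool)
    for contig in np.unique(ev_contig):
        sel = ev_contig == contig
        ok = mask.contains(contig, ev_pos[sel])
        if assembler is not None:
            ok &= assembler.context_available(contig, ev_pos[sel])
        in_mask[sel] = ok
    ev_contig, ev_pos, ev_sample = (
        ev_contig[in_mask], ev_pos[in_mask], ev_sample[in_mask]
    )
    n_events = len(ev_pos)
    if n_events == 0:
        raise ValueError("no in-mask mutations to train on")

    n_mut = min(max_mutated, n_events)
    if n_mut < n_events:
        pick = rng.choice(n_events, size=n_mut, replace=False)
        pick.sort()
        mut_contig, mut_pos, mut_sample = (
            ev_contig[pick], ev_pos[pick], ev_sample[pick]
        )
    else:
        mut_contig, mut_pos, mut_sample = ev_contig, ev_pos, ev_sample

    mutated_pairs = set(zip(ev_contig.tolist(), ev_pos.tolist(), ev_sample.tolist()))
    draw, mask_total = _mask_sampler(mask)
    total_pairs = mask_total * len(samples)
    if total_pairs - n_events < n_mut:
        raise ValueError("mask too small for the requested non-mutated draw")

    need = n_mut
    nm_contig: list = []
    nm_pos: list = []
    nm_sample: list = []
    sample_arr = np.array(samples, dtype=object)
    max_rounds = 100
    while need > 0 and max_rounds > 0:
        k = int(need * 1.2) + 16
        c, p = draw(rng, k)
        s = sample_arr[rng.integers(0, len(sample_arr), size=k)]
        keep = np.ones(k, dtype=bool)
        if assembler is not None:
            for contig in pd.unique(c):
                sel = c == contig
                keep[sel] &= assembler.context_available(contig, p[sel])
        for i in range(k):
            if not keep[i]:
                continue
            if (c[i], int(p[i]), s[i]) in mutated_pairs:
                keep[i] = False
        idx = np.flatnonzero(keep)[:need]
        nm_contig.extend(c[idx].tolist())
        nm_pos.extend(p[idx].tolist())
        nm_sample.extend(s[idx].tolist())
        need = n_mut - len(nm_pos)
        max_rounds -= 1
    if need > 0:
        raise ValueError("could not draw enough non-mutated sites from the mask")

    contigs = np.concatenate([mut_contig, np.array(nm_contig, dtype=object)])
    positions0 = np.concatenate([mut_pos, np.array(nm_pos, dtype=np.int64)])
    sample_ids = np.concatenate([mut_sample, np.array(nm_sample, dtype=object)])
    labels = np.concatenate(
        [np.ones(n_mut, dtype=np.int8), np.zeros(n_mut, dtype=np.int8)]
    )
    f1 = n_mut / n_events
    f0 = n_mut / (total_pairs - n_events)
    return SiteTable(contigs, positions0, sample_ids, labels, f1, f0)


@dataclass
class Standardizer:
    """Per-column scale factors for continuous features.

    Continuous covariates are divided by their training-sample standard
    deviation before penalized fitting (mean-shifts fold into the intercept,
    so only scaling is applied; this keeps one-hot blocks sparse).
    """

    scales: dict[str, float]

    def transform(self, X: sp.csr_matrix, column_names: list[str]) -> sp.csr_matrix:
        if not self.scales:
            return X
        factors = np.array(
            [1.0 / self.scales.get(c, 1.0) for c in column_names]
        )
        return X @ sp.diags(factors) if sp.issparse(X) else X * factors


def build_design_matrix(
    table: SiteTable,
    assembler: FeatureAssembler,
    standardizer: Standardizer | None = None,
) -> tuple[sp.csr_matrix, np.ndarray, list[str], Standardizer]:
    """Assemble the sparse design matrix for a SiteTable.

    Returns ``(X, y, column_names, standardizer)``.  When no standardizer
    is supplied, scale factors for continuous columns are estimated from
    this table (the training sample) and returned for reuse at prediction.
    """
    X = assembler.assemble(table.contigs, table.positions0, table.sample_ids)
    names = assembler.column_names
    if standardizer is None:
        cont = set(assembler.continuous_columns)
        scales = {}
        if cont:
            col_idx = {c: i for i, c in enumerate(names)}
            Xc = sp.csc_matrix(X)
            for c in cont:
                col = np.asarray(Xc[:, col_idx[c]].todense()).ravel()
                sd = float(col.std())
                scales[c] = sd if sd > 0 else 1.0
        standardizer = Standardizer(scales)
    X = sp.csr_matrix(standardizer.transform(X, names))
    y = table.labels.astype(np.float64)
    return X, y, names, standardizer
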