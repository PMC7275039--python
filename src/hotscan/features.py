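"""Position- and sample-addressable covariates for the background mutation model.

Covariate families:

* sequence context of the site (center-base class, 1/2-bp flanks, tri- and
  pentanucleotide), strand-collapsed so the center base is reported on the
  pyrimidine strand — the standard mutation-signature convention;
* a homopolymer-run indicator for indel sites;
* binary/continuous user tracks (chromatin marks, TF binding, replication
  timing, APOBEC-site overlays, ...);
* the cohort's local mutation rate in fixed-width genomic bins;
* sample-level covariates (log mutation burden, optional user columns such
  as signature proportions).

The :class:`FeatureAssembler` turns (contig, position, sample) triples into
design-matrix rows; one-hot groups are emitted sparse with the
lexicographically-first level dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CONTINUOUS, SNV, GenomeSequence, GenomicTrack, MutationCatalog, RegionSet,
)

logger = logging.getLogger("hotscan")

SEQUENCE = "sequence"
EPIGENETIC = "epigenetic"
STRUCTURAL = "structural"
SAMPLE_LEVEL = "sample_level"

_BASES = "ACGT"
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


class ContextUnavailable(ValueError):
    """Raised when a position has no valid 5-mer context (N or contig edge)."""


# ---------------------------------------------------------------------------
# Analysis mask
# ---------------------------------------------------------------------------

def genome_mask_arrays(genome: GenomeSequence) -> dict[str, np.ndarray]:
    """Per-contig boolean arrays, True at non-N bases."""
    return {c: genome.encoded(c) != 4 for c in genome.contigs}


def build_mask(
    genome: GenomeSequence,
    mappability_mask: RegionSet | None = None,
    blacklist: RegionSet | None = None,
    coding_regions: RegionSet | None = None,
) -> RegionSet:
    """Analyzable positions: whole genome minus exclusion sets minus N runs.

    Exclusion intervals on contigs absent from the genome are ignored with a
    warning.
    """
    masks = genome_mask_arrays(genome)
    lengths = genome.lengths
    for excl in (mappability_mask, blacklist, coding_regions):
        if excl is None:
            continue
        for contig in excl.contigs:
            if contig not in lengths:
                logger.warning(
                    "mask contig %r absent from genome; intervals ignored", contig
                )
                continue
            cov = excl.coverage_mask(contig, lengths[contig])
            masks[contig] &= ~cov
    return RegionSet.from_mask(masks, label="analyzable")


# ---------------------------------------------------------------------------
# Sequence context
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceContext:
    center_base_class: str      # "A/T" or "C/G"
    pentanucleotide: str        # strand-collapsed 5-mer, center = C or T
    trinucleotide: str          # center slice of the pentanucleotide
    left1: str
    right1: str
    left2: str
    right2: str


def collapsed_context_codes(
    genome: GenomeSequence, contig: str, positions0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-collapsed 5-mer base codes around 0-based center positions.

    Returns ``(codes, available)`` where ``codes`` is (n, 5) uint8 with the
    center base collapsed to the pyrimidine strand (purine centers are
    reverse-complemented), and ``available`` marks positions with full 2-bp
    flanks and no N in the window.
    """
    enc = genome.encoded(contig)
    n = len(enc)
    positions0 = np.asarray(positions0, dtype=np.int64)
    available = (positions0 >= 2) & (positions0 <= n - 3)
    safe = np.clip(positions0, 2, max(2, n - 3))
    idx = safe[:, None] + np.arange(-2, 3)[None, :]
    codes = enc[idx]
    available &= (codes != 4).all(axis=1)
    center = codes[:, 2]
    purine = (center == 0) | (center == 2)  # A or G -> take reverse complement
    rc = _COMP[codes[:, ::-1]]
    codes = np.where(purine[:, None], rc, codes)
    return codes, available


def _codes_to_kmer(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def sequence_context_at(
    genome: GenomeSequence, contig: str, position: int
) -> SequenceContext:
    """Strand-collapsed context at a 1-based position.

    Raises :class:`ContextUnavailable` at contig edges or when the 5-mer
    contains N.
    """
    codes, avail = collapsed_context_codes(
        genome, contig, np.array([position - 1])
    )
    if not avail[0]:
        raise ContextUnavailable(
            f"no valid 5-mer context at {contig}:{position}"
        )
    c = codes[0]
    penta = _codes_to_kmer(c)
    return SequenceContext(
        center_base_class="C/G" if penta[2] == "C" else "A/T",
        pentanucleotide=penta,
        trinucleotide=penta[1:4],
        left1=penta[1],
        right1=penta[3],
        left2=penta[0:2],
        right2=penta[3:5],
    )


# Context one-hot groups: (group name, slice of the collapsed 5-mer, levels)
def _kmers(k: int, center_pyrimidine: bool = False) -> list[str]:
    if center_pyrimidine:
        assert k % 2 == 1
        mid = k // 2
        out = []
        for combo in product(_BASES, repeat=k):
            if combo[mid] in "CT":
                out.append("".join(combo))
        return sorted(out)
    return sorted("".join(c) for c in product(_BASES, repeat=k))


CONTEXT_GROUPS: dict[str, dict] = {
    "center_class": {"slice": (2, 3), "levels": ["A/T", "C/G"]},
    "left1": {"slice": (1, 2), "levels": _kmers(1)},
    "right1": {"slice": (3, 4), "levels": _kmers(1)},
    "left2": {"slice": (0, 2), "levels": _kmers(2)},
    "right2": {"slice": (3, 5), "levels": _kmers(2)},
    "trinucleotide": {"slice": (1, 4), "levels": _kmers(3, center_pyrimidine=True)},
    "pentanucleotide": {"slice": (0, 5), "levels": _kmers(5, center_pyrimidine=True)},
}


def context_group_ranks(
    codes: np.ndarray, group: str
) -> np.ndarray:
    """Rank of each row's k-mer within the group's sorted level list."""
    lo, hi = CONTEXT_GROUPS[group]["slice"]
    sub = codes[:, lo:hi].astype(np.int64)
    k = hi - lo
    idx = np.zeros(len(codes), dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + sub[:, j]
    if group == "center_class":
        # center collapsed to C(1) or T(3): C -> "C/G"(rank 1), T -> "A/T"(rank 0)
        return (sub[:, 0] == 1).astype(np.int64)
    if group in ("trinucleotide", "pentanucleotide"):
        levels = CONTEXT_GROUPS[group]["levels"]
        valid_idx = np.array(
            [_kmer_index(l) for l in levels], dtype=np.int64
        )
        return np.searchsorted(valid_idx, idx)
    return idx


def _kmer_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _BASES.index(ch)
    return idx


# ---------------------------------------------------------------------------
# Indel homopolymer feature
# ---------------------------------------------------------------------------

def homopolymer_run_lengths(genome: GenomeSequence, contig: str) -> np.ndarray:
    """Length of the mononucleotide run containing each base (cached per call)."""
    enc = genome.encoded(contig)
    n = len(enc)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    boundaries = np.flatnonzero(enc[1:] != enc[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    lengths = ends - starts
    return np.repeat(lengths, lengths)


def indel_homopolymer_feature(
    genome: GenomeSequence, contig: str, position: int, ref_span: int = 1
) -> int:
    """1 iff a mononucleotide run longer than 5 bp overlaps the indel site.

    ``position`` is 1-based; the site spans the reference allele
    (``ref_span`` bases).  N runs never count.
    """
    run_len = homopolymer_run_lengths(genome, contig)
    enc = genome.encoded(contig)
    lo = position - 1
    hi = min(lo + max(1, ref_span), len(enc))
    span = slice(max(0, lo), hi)
    return int(np.any((run_len[span] > 5) & (enc[span] != 4)))


# ---------------------------------------------------------------------------
# Local mutation rate
# ---------------------------------------------------------------------------

class LocalRateTrack(GenomicTrack):
    """Cohort mutation rate (mutations / base / sample) in fixed-width bins."""

    def __init__(self, intervals, bin_width: int, name: str = "local_rate"):
        super().__init__(CONTINUOUS, intervals, default_value=0.0, name=name)
        self.bin_width = int(bin_width)


def compute_local_rate(
    catalog: MutationCatalog,
    genome: GenomeSequence,
    bin_width: int = 100_000,
    variant_class: str = SNV,
    n_samples: int | None = None,
) -> LocalRateTrack:
    """Per-bin mutation rate; the last bin of a contig is truncated.

    rate = (#mutations of the class in the bin) / (effective bin width x
    number of cohort samples).
    """
    if n_samples is None:
        n_samples = len(catalog.samples)
    if n_samples == 0:
        raise ValueError("empty cohort: no samples in catalog")
    per_contig_pos: dict[str, list[int]] = {}
    for rec in catalog.records:
        if rec.variant_class == variant_class:
            per_contig_pos.setdefault(rec.contig, []).append(rec.position - 1)
    ivals = {}
    for contig, length in genome.lengths.items():
        edges = np.arange(0, length + bin_width, bin_width, dtype=np.int64)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        starts, ends = edges[:-1], edges[1:]
        counts = np.zeros(len(starts), dtype=np.int64)
        pos = per_contig_pos.get(contig)
        if pos:
            binned = np.asarray(pos, dtype=np.int64) // bin_width
            np.add.at(counts, np.clip(binned, 0, len(counts) - 1), 1)
        rates = counts / ((ends - starts) * n_samples)
        ivals[contig] = (starts, ends, rates)
    return LocalRateTrack(ivals, bin_width=bin_width)


# ---------------------------------------------------------------------------
# Sample-level covariates
# ---------------------------------------------------------------------------

class SampleCovariates:
    """Per-sample covariates: mutation burden plus optional user columns.

    Burden enters the model as ln(count + 1), centered on the cohort mean;
    the centering constant is stored so prediction matches fitting.
    """

    def __init__(self, table: pd.DataFrame):
        if "mutation_count" not in table.columns:
            raise ValueError("sample covariate table needs a mutation_count column")
        self.table = table.copy()
        log_burden = np.log1p(self.table["mutation_count"].to_numpy(dtype=float))
        self.burden_center = float(log_burden.mean()) if len(table) else 0.0

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def column_names(self) -> list[str]:
        extras = [c for c in self.table.columns if c != "mutation_count"]
        return ["log_burden"] + extras

    def design_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        sub = self.table.loc[list(sample_ids)]
        log_burden = (
            np.log1p(sub["mutation_count"].to_numpy(dtype=float))
            - self.burden_center
        )
        extras = [c for c in sub.columns if c != "mutation_count"]
        cols = [log_burden] + [sub[c].to_numpy(dtype=float) for c in extras]
        return np.column_stack(cols)


def sample_burden(
    catalog: MutationCatalog,
    variant_class: str = SNV,
    samples: Iterable[str] | None = None,
    extra: pd.DataFrame | None = None,
) -> SampleCovariates:
    """Per-sample mutation count of one variant class (0 for absent classes)."""
    samples = sorted(samples) if samples is not None else sorted(catalog.samples)
    counts = {s: 0 for s in samples}
    for rec in catalog.records:
        if rec.variant_class == variant_class and rec.sample_id in counts:
            counts[rec.sample_id] += 1
    table = pd.DataFrame({"mutation_count": [counts[s] for s in samples]}, index=samples)
    if extra is not None:
        table = table.join(extra, how="left")
    return SampleCovariates(table)


# ---------------------------------------------------------------------------
# Feature specs and assembly
# ---------------------------------------------------------------------------

ONEHOT_CONTEXT = "onehot_context"
BINARY_OVERLAY = "binary_overlay"
CONTINUOUS_ENC = "continuous"


@dataclass
class FeatureSpec:
    """Declarative description of one background-model covariate."""

    name: str
    category: str                 # sequence | epigenetic | structural | sample_level
    encoding: str                 # onehot_context | binary_overlay | continuous
    source: str = "computed"      # computed | user_track
    track: GenomicTrack | None = None

    def __post_init__(self):
        if self.category not in (SEQUENCE, EPIGENETIC, STRUCTURAL, SAMPLE_LEVEL):
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.encoding == ONEHOT_CONTEXT and self.name not in CONTEXT_GROUPS:
            raise ValueError(f"unknown context group {self.name!r}")


def default_snv_specs(include_pentanucleotide: bool = True) -> list[FeatureSpec]:
    """Computed sequence-context specs mirroring the default SNV covariates."""
    groups = ["center_class", "left1", "right1", "left2", "right2", "trinucleotide"]
    if include_pentanucleotide:
        groups.append("pentanucleotide")
    return [FeatureSpec(g, SEQUENCE, ONEHOT_CONTEXT) for g in groups]


def default_indel_specs() -> list[FeatureSpec]:
    return [FeatureSpec("homopolymer", SEQUENCE, BINARY_OVERLAY, source="computed")]


class FeatureAssembler:
    """Maps (contig, 0-based position, sample) rows to design-matrix rows.

    A pure function of (genome, tracks, specs): re-invocation on the same
    inputs yields identical matrices, and reordering the spec list permutes
    columns without changing values.
    """

    def __init__(
        self,
        genome: GenomeSequence,
        specs: Sequence[FeatureSpec],
        sample_covariates: SampleCovariates | None = None,
    ):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique within a model")
        self.genome = genome
        self.specs = list(specs)
        self.sample_covariates = sample_covariates
        self._homopolymer_cache: dict[str, np.ndarray] = {}
        cols: list[str] = []
        cats: list[str] = []
        cont: list[str] = []
        for spec in self.specs:
            if spec.encoding == ONEHOT_CONTEXT:
                levels = CONTEXT_GROUPS[spec.name]["levels"]
                cols.extend(f"{spec.name}={lv}" for lv in levels[1:])
                cats.extend([spec.category] * (len(levels) - 1))
            else:
                cols.append(spec.name)
                cats.append(spec.category)
                if spec.encoding == CONTINUOUS_ENC:
                    cont.append(spec.name)
        self.position_columns = cols
        self.position_categories = cats
        self.continuous_columns = cont
        self.sample_columns = (
            sample_covariates.column_names if sample_covariates else []
        )

    @property
    def column_names(self) -> list[str]:
        return self.position_columns + self.sample_columns

    @property
    def column_categories(self) -> list[str]:
        return self.position_categories + [SAMPLE_LEVEL] * len(self.sample_columns)

    def _needs_context(self) -> bool:
        return any(s.encoding == ONEHOT_CONTEXT for s in self.specs)

    def context_available(self, contig: str, positions0: np.ndarray) -> np.ndarray:
        if not self._needs_context():
            return np.ones(len(positions0), dtype=bool)
        _, avail = collapsed_context_codes(self.genome, contig, positions0)
        return avail

    def position_matrix(self, contig: str, positions0: np.ndarray) -> sp.csr_matrix:
        """Sparse (n x n_position_columns) block for one contig.

        All positions must have valid contexts when context specs are present.
        """
        positions0 = np.asarray(positions0, dtype=np.int64)
        n = len(positions0)
        blocks: list[sp.spmatrix] = []
        codes = avail = None
        if self._needs_context():
            codes, avail = collapsed_context_codes(self.genome, contig, positions0)
            if not avail.all():
                raise ContextUnavailable(
                    f"{(~avail).sum()} positions on {contig} lack a valid 5-mer "
                    "context; filter rows upstream"
                )
        for spec in self.specs:
            if spec.encoding == ONEHOT_CONTEXT:
                levels = CONTEXT_GROUPS[spec.name]["levels"]
                ranks = context_group_ranks(codes, spec.name)
                keep = ranks > 0  # reference level dropped
                block = sp.csr_matrix(
                    (
                        np.ones(int(keep.sum())),
                        (np.flatnonzero(keep), ranks[keep] - 1),
                    ),
                    shape=(n, len(levels) - 1),
                )
                blocks.append(block)
            elif spec.name == "homopolymer" and spec.source == "computed":
                if contig not in self._homopolymer_cache:
                    self._homopolymer_cache[contig] = homopolymer_run_lengths(
                        self.genome, contig
                    )
                run_len = self._homopolymer_cache[contig]
                enc = self.genome.encoded(contig)
                vals = (
                    (run_len[positions0] > 5) & (enc[positions0] != 4)
                ).astype(np.float64)
                blocks.append(sp.csr_matrix(vals[:, None]))
            else:
                if spec.track is None:
                    raise ValueError(f"feature {spec.name!r} has no track attached")
                vals = spec.track.values_at(contig, positions0)
                blocks.append(sp.csr_matrix(vals[:, None]))
        if not blocks:
            return sp.csr_matrix((n, 0))
        return sp.hstack(blocks, format="csr")

    def assemble(
        self,
        contigs: Sequence[str],
        positions0: np.ndarray,
        sample_ids: Sequence[str],
    ) -> sp.csr_matrix:
        """Full design rows (position block + sample covariates), row-aligned."""
        positions0 = np.asarray(positions0, dtype=np.int64)
        order_blocks = []
        contigs = np.asarray(contigs)
        row_parts: list[sp.spmatrix] = []
        row_index: list[np.ndarray] = []
        for contig in pd.unique(contigs):
            sel = np.flatnonzero(contigs == contig)
            row_parts.append(self.position_matrix(contig, positions0[sel]))
            row_index.append(sel)
        if row_parts:
            stacked = sp.vstack(row_parts, format="csr")
            inv = np.empty(len(positions0), dtype=np.int64)
            inv[np.concatenate(row_index)] = np.arange(len(positions0))
            X_pos = stacked[inv]
        else:
            X_pos = sp.csr_matrix((0, len(self.position_columns)))
        if self.sample_covariates is not None:
            X_s = sp.csr_matrix(self.sample_covariates.design_columns(sample_ids))
            return sp.hstack([X_pos, X_s], format="csr")
        return X_pos

    def assemble_feature_row(
        self, contig: str, position: int, sample_id: str | None = None
    ) -> np.ndarray:
        """Single dense row at a 1-based position (convenience wrapper)."""
        if self.sample_covariates is not None and sample_id is None:
            raise ValueError("sample_id required when sample covariates are present")
        X = self.assemble([contig], np.array([position - 1]), [sample_id])
        return np.asarray(X.todense())[0]
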