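"""Readers and writers for on-disk artifacts, with strict coordinate conventions.

All interval-like objects (:class:`RegionSet`, :class:`GenomicTrack`, hotspot
output) use 0-based half-open coordinates, the BED convention.  Mutation
positions (:class:`MutationRecord`) are 1-based, the VCF convention.  Every
conversion between the two happens inside this module.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hotscan")

_VALID_BASES = set("ACGTN")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

class GenomeSequence:
    """An in-memory reference genome: ordered contig -> uppercase DNA string.

    Alphabet is restricted to A/C/G/T/N.  Encoded (uint8) views of each
    contig are cached for vectorized feature extraction.
    """

    def __init__(self, contigs: dict[str, str]):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            if name in self.contigs:
                raise ValueError(f"duplicate contig name {name!r}")
            self.contigs[name] = seq
        self._encoded: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def encoded(self, contig: str) -> np.ndarray:
        """uint8 codes A=0,C=1,G=2,T=3,N=4 for one contig (cached)."""
        if contig not in self._encoded:
            raw = np.frombuffer(self.contigs[contig].encode("ascii"), dtype=np.uint8)
            lut = np.full(128, 4, dtype=np.uint8)
            for base, code in _BASE_CODE.items():
                lut[ord(base)] = code
            self._encoded[contig] = lut[raw]
        return self._encoded[contig]

    def base_at(self, contig: str, position: int) -> str:
        """Base at a 1-based position."""
        return self.contigs[contig][position - 1]

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "wt") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_genome(path) -> GenomeSequence:
    """Load a FASTA file into memory, uppercasing sequence; N is allowed."""
    from Bio import SeqIO

    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            raise ValueError(f"no sequences found in {path}")
        if first != ">":
            raise ValueError(
                f"malformed FASTA {path}: first line does not start with '>'"
            )
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
            contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return GenomeSequence(contigs)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

SNV = "SNV"
INDEL = "indel"


@dataclass(frozen=True)
class MutationRecord:
    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    sample_id: str

    @property
    def variant_class(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return SNV
        return INDEL


class MutationCatalog:
    """Deduplicated per-sample somatic variants for one cohort."""

    def __init__(self, records: Iterable[MutationRecord]):
        seen = set()
        unique: list[MutationRecord] = []
        for rec in records:
            key = (rec.contig, rec.position, rec.alt_allele, rec.sample_id)
            if key in seen:
                continue
            seen.add(key)
            unique.append(rec)
        unique.sort(key=lambda r: (r.contig, r.position, r.sample_id, r.alt_allele))
        self.records: list[MutationRecord] = unique
        self.samples: set[str] = {r.sample_id for r in unique}

    def __len__(self) -> int:
        return len(self.records)

    def of_class(self, variant_class: str) -> "MutationCatalog":
        return MutationCatalog(
            r for r in self.records if r.variant_class == variant_class
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.contig for r in self.records],
                "pos": [r.position for r in self.records],
                "ref": [r.ref_allele for r in self.records],
                "alt": [r.alt_allele for r in self.records],
                "sample": [r.sample_id for r in self.records],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_REQUIRED_COLS = ("chrom", "pos", "ref", "alt", "sample")


def _validate_records(
    rows: Iterable[MutationRecord], genome: GenomeSequence
) -> list[MutationRecord]:
    kept = []
    n_bad_contig = 0
    n_ref_mismatch = 0
    lengths = genome.lengths
    for rec in rows:
        if rec.contig not in lengths:
            n_bad_contig += 1
            continue
        end = rec.position - 1 + len(rec.ref_allele)
        if rec.position < 1 or end > lengths[rec.contig]:
            n_ref_mismatch += 1
            continue
        expected = genome.contigs[rec.contig][rec.position - 1 : end]
        if expected != rec.ref_allele:
            n_ref_mismatch += 1
            continue
        kept.append(rec)
    if n_bad_contig:
        logger.warning("dropped %d records on contigs absent from genome", n_bad_contig)
    if n_ref_mismatch:
        logger.warning(
            "dropped %d records with ref allele mismatching the genome", n_ref_mismatch
        )
    return kept


def read_mutations(path, genome: GenomeSequence) -> MutationCatalog:
    """Read somatic mutations from a 5-column TSV or a VCF.

    TSV columns: chrom, pos (1-based), ref, alt, sample.  VCF records take
    the sample identifier from the per-record ``SAMPLE`` INFO field, or from
    the single genotype column name if present.  Records on unknown contigs
    or whose ref allele mismatches the genome are dropped with logged counts.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz"):
        rows = _read_vcf_rows(path)
    else:
        rows = _read_tsv_rows(path)
    return MutationCatalog(_validate_records(rows, genome))


def _read_tsv_rows(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation TSV {path} missing required columns: {missing}")
    return [
        MutationRecord(
            contig=str(r.chrom),
            position=int(r.pos),
            ref_allele=str(r.ref).upper(),
            alt_allele=str(r.alt).upper(),
            sample_id=str(r.sample),
        )
        for r in df.itertuples(index=False)
    ]


def _read_vcf_rows(path) -> list[MutationRecord]:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        genotype_samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.info.get("SAMPLE") is not None:
                sample = str(rec.info["SAMPLE"])
                samples = [sample]
            elif genotype_samples:
                samples = genotype_samples
            else:
                raise ValueError(
                    f"VCF {path}: no SAMPLE INFO field and no genotype columns"
                )
            for alt in rec.alts or ():
                for sample in samples:
                    rows.append(
                        MutationRecord(
                            contig=rec.chrom,
                            position=rec.pos,
                            ref_allele=rec.ref.upper(),
                            alt_allele=str(alt).upper(),
                            sample_id=sample,
                        )
                    )
    return rows


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

class RegionSet:
    """A sorted, merged set of 0-based half-open genomic intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = (), label: str = ""):
        self.label = label
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty or inverted interval ({contig},{start},{end})")
            per_contig.setdefault(contig, []).append((int(start), int(end)))
        self._ivals: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, pairs in per_contig.items():
            arr = np.array(sorted(pairs), dtype=np.int64)
            starts, ends = _merge_sorted(arr[:, 0], arr[:, 1])
            self._ivals[contig] = (starts, ends)

    # -- construction helpers -------------------------------------------

    @classmethod
    def _from_arrays(
        cls, ivals: dict[str, tuple[np.ndarray, np.ndarray]], label: str = ""
    ) -> "RegionSet":
        obj = cls.__new__(cls)
        obj.label = label
        obj._ivals = {
            c: (s.copy(), e.copy()) for c, (s, e) in ivals.items() if len(s) > 0
        }
        return obj

    @property
    def contigs(self) -> list[str]:
        return sorted(self._ivals)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in self.contigs:
            starts, ends = self._ivals[contig]
            out.extend((contig, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def arrays(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        return self._ivals.get(
            contig, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        )

    @property
    def total_length(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self._ivals.values())
        )

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._ivals.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals() == other.intervals()

    # -- set algebra ------------------------------------------------------

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(list(self.intervals()) + list(other.intervals()))

    def subtract(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig in self.contigs:
            s1, e1 = self.arrays(contig)
            s2, e2 = other.arrays(contig)
            out[contig] = _subtract_sorted(s1, e1, s2, e2)
        return RegionSet._from_arrays(out, label=self.label)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig in self.contigs:
            s1, e1 = self.arrays(contig)
            s2, e2 = other.arrays(contig)
            out[contig] = _intersect_sorted(s1, e1, s2, e2)
        return RegionSet._from_arrays(out, label=self.label)

    def contains(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership of 0-based positions."""
        starts, ends = self.arrays(contig)
        positions = np.asarray(positions, dtype=np.int64)
        if len(starts) == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(positions.shape, dtype=bool)
        res[ok] = positions[ok] < ends[idx[ok]]
        return res

    def coverage_mask(self, contig: str, length: int) -> np.ndarray:
        """Boolean array of the given length, True where covered."""
        mask = np.zeros(length, dtype=bool)
        starts, ends = self.arrays(contig)
        for s, e in zip(starts, ends):
            mask[max(0, s) : min(length, e)] = True
        return mask

    @classmethod
    def from_mask(cls, masks: dict[str, np.ndarray], label: str = "") -> "RegionSet":
        """Build from per-contig boolean coverage arrays."""
        ivals: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, mask in masks.items():
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                continue
            diff = np.diff(mask.astype(np.int8))
            starts = np.flatnonzero(diff == 1) + 1
            ends = np.flatnonzero(diff == -1) + 1
            if mask[0]:
                starts = np.concatenate([[0], starts])
            if mask[-1]:
                ends = np.concatenate([ends, [len(mask)]])
            ivals[contig] = (starts.astype(np.int64), ends.astype(np.int64))
        return cls._from_arrays(ivals, label=label)

    def to_bed(self, path) -> None:
        with open(path, "wt") as fh:
            for contig, start, end in self.intervals():
                fh.write(f"{contig}\t{start}\t{end}\n")


def _merge_sorted(starts: np.ndarray, ends: np.ndarray):
    """Merge sorted possibly-overlapping intervals (book-ended merged too)."""
    if len(starts) == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _subtract_sorted(s1, e1, s2, e2):
    if len(s1) == 0 or len(s2) == 0:
        return s1.copy(), e1.copy()
    out_s, out_e = [], []
    j = 0
    for a, b in zip(s1, e1):
        cur = a
        while j < len(s2) and e2[j] <= cur:
            j += 1
        k = j
        while k < len(s2) and s2[k] < b:
            if s2[k] > cur:
                out_s.append(int(cur))
                out_e.append(int(s2[k]))
            cur = max(cur, e2[k])
            if e2[k] >= b:
                break
            k += 1
        if cur < b:
            out_s.append(int(cur))
            out_e.append(int(b))
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _intersect_sorted(s1, e1, s2, e2):
    out_s, out_e = [], []
    i = j = 0
    while i < len(s1) and j < len(s2):
        lo = max(s1[i], s2[j])
        hi = min(e1[i], e2[j])
        if lo < hi:
            out_s.append(int(lo))
            out_e.append(int(hi))
        if e1[i] < e2[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def read_regions(path, label: str = "") -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a merged RegionSet.

    Records with start >= end are rejected with a warning.
    """
    intervals = []
    n_rejected = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                n_rejected += 1
                logger.warning(
                    "%s:%d: rejected degenerate interval (%s,%d,%d)",
                    path, lineno, contig, start, end,
                )
                continue
            intervals.append((contig, start, end))
    return RegionSet(intervals, label=label or Path(path).stem)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

BINARY = "binary"
CONTINUOUS = "continuous"


class GenomicTrack:
    """A genome-wide covariate: binary (interval membership) or continuous.

    Point queries resolve at every position; uncovered positions return
    ``default_value`` (0 for binary tracks).
    """

    def __init__(
        self,
        kind: str,
        intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray | None]],
        default_value: float = 0.0,
        name: str = "",
    ):
        if kind not in (BINARY, CONTINUOUS):
            raise ValueError(f"unknown track kind {kind!r}")
        self.kind = kind
        self.name = name
        self.default_value = float(default_value)
        self._ivals = {}
        for contig, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            if np.any(starts[1:] < ends[:-1]):
                if kind == CONTINUOUS:
                    raise ValueError(
                        f"track {name!r}: overlapping intervals on {contig}"
                    )
            if kind == BINARY:
                starts, ends = _merge_sorted(starts, ends)
                values = None
            else:
                values = np.asarray(values, dtype=np.float64)[order]
                if not np.all(np.isfinite(values)):
                    raise ValueError(f"track {name!r}: non-finite values on {contig}")
            self._ivals[contig] = (starts, ends, values)

    def values_at(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized point query at 0-based positions."""
        positions = np.asarray(positions, dtype=np.int64)
        default = 0.0 if self.kind == BINARY else self.default_value
        out = np.full(positions.shape, default, dtype=np.float64)
        if contig not in self._ivals:
            return out
        starts, ends, values = self._ivals[contig]
        if len(starts) == 0:
            return out
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        if self.kind == BINARY:
            out[ok] = 1.0
        else:
            out[ok] = values[idx[ok]]
        return out

    def value_at(self, contig: str, position: int) -> float:
        return float(self.values_at(contig, np.array([position]))[0])


def read_track(path, kind: str, default_value: float = 0.0, name: str = "") -> GenomicTrack:
    """Read a binary track from BED or a continuous track from bedGraph.

    Overlapping bedGraph intervals with conflicting values are an error.
    bigWig input (.bw/.bigwig) is accepted when pyBigWig is importable.
    """
    path = Path(path)
    name = name or path.stem
    if path.suffix.lower() in (".bw", ".bigwig"):
        return _read_bigwig(path, default_value, name)
    per_contig: dict[str, list] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if kind == CONTINUOUS:
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: bedGraph line has <4 columns")
                contig, start, end, value = (
                    parts[0], int(parts[1]), int(parts[2]), float(parts[3]),
                )
            else:
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
                contig, start, end, value = parts[0], int(parts[1]), int(parts[2]), None
            if start >= end:
                logger.warning("%s:%d: degenerate interval skipped", path, lineno)
                continue
            per_contig.setdefault(contig, []).append((start, end, value))
    ivals = {}
    for contig, rows in per_contig.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        if kind == CONTINUOUS:
            values = np.array([r[2] for r in rows], dtype=np.float64)
            overlap = starts[1:] < ends[:-1]
            if np.any(overlap & (values[1:] != values[:-1])):
                raise ValueError(
                    f"{path}: overlapping bedGraph intervals with conflicting "
                    f"values on {contig}"
                )
            if np.any(overlap):
                # equal-valued overlaps: clip to disjoint
                ends[:-1][overlap] = starts[1:][overlap]
            ivals[contig] = (starts, ends, values)
        else:
            ivals[contig] = (starts, ends, None)
    return GenomicTrack(kind, ivals, default_value=default_value, name=name)


def _read_bigwig(path, default_value: float, name: str) -> GenomicTrack:
    import pyBigWig  # optional; bedGraph is the reference path

    bw = pyBigWig.open(str(path))
    try:
        ivals = {}
        for contig in bw.chroms():
            entries = bw.intervals(contig)
            if not entries:
                continue
            starts = np.array([e[0] for e in entries], dtype=np.int64)
            ends = np.array([e[1] for e in entries], dtype=np.int64)
            values = np.array([e[2] for e in entries], dtype=np.float64)
            ivals[contig] = (starts, ends, values)
    finally:
        bw.close()
    return GenomicTrack(CONTINUOUS, ivals, default_value=default_value, name=name)


# ---------------------------------------------------------------------------
# Hotspot table
# ---------------------------------------------------------------------------

HOTSPOT_COLUMNS = [
    "chrom", "start", "end", "length", "n_mutated_samples", "n_mutations",
    "pvalue", "fdr", "mean_background_prob",
]


def hotspots_to_frame(calls: Sequence) -> pd.DataFrame:
    rows = [
        (
            c.contig, c.start, c.end, c.end - c.start,
            len(c.mutated_samples), c.mutation_count,
            c.pvalue, c.fdr, c.mean_background_prob,
        )
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=HOTSPOT_COLUMNS)
    return df.sort_values(
        ["pvalue", "chrom", "start"], kind="stable"
    ).reset_index(drop=True)


def write_hotspots(calls: Sequence, path) -> None:
    """Write hotspot calls as TSV, sorted by p-value then coordinates."""
    df = hotspots_to_frame(calls)
    with open(path, "wt") as fh:
        fh.write("\t".join(HOTSPOT_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.length}\t"
                f"{row.n_mutated_samples}\t{row.n_mutations}\t"
                f"{row.pvalue:.6e}\t{row.fdr:.6e}\t{row.mean_background_prob:.6e}\n"
            )


def read_hotspots(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
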