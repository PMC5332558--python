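"""Normalized strand-specific coverage and gene-window profiles.

GRO-seq processing chain: reads are extended to 250 bp in their 3'
direction, piled up per strand, and the track is scaled so every sample
corresponds to a depth of 20 million mapped reads. Per-gene windows run
from 2 kb upstream to 120 kb downstream of the TSS, re-oriented so that
increasing offset always means sense-direction travel; meta-gene profiles
are per-bp 5% trimmed means over a cohort of windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .annotation import TranscriptModel, longest_per_gene

WINDOW_UPSTREAM = 2_000
WINDOW_DOWNSTREAM = 120_000
WINDOW_LENGTH = WINDOW_UPSTREAM + WINDOW_DOWNSTREAM + 1  # 122,001 bp

DEFAULT_EXTENSION = 250
DEFAULT_TARGET_DEPTH = 20_000_000


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read: 0-based half-open genomic interval plus strand."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


def read_bed6(path) -> pd.DataFrame:
    """Load BED6 alignments into the DataFrame layout used internally."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["contig", "start", "end", "strand"],
        dtype={"contig": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return df


def _as_frame(alignments) -> pd.DataFrame:
    if isinstance(alignments, pd.DataFrame):
        return alignments
    rows = [(a.contig, a.start, a.end, a.strand) for a in alignments]
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand"])


@dataclass
class CoverageTrack:
    """Per-contig, per-strand normalized read depth.

    ``depth[(contig, strand)]`` is a float vector of per-bp depth after
    read extension and scaling by ``target_depth / total_reads``.
    """

    depth: Dict[Tuple[str, str], np.ndarray]
    total_reads: int
    scale: float
    extension: int
    clipped_reads: int = 0

    def contig_length(self, contig: str) -> int:
        for (c, _), v in self.depth.items():
            if c == contig:
                return v.size
        raise KeyError(contig)


def build_coverage(
    alignments,
    extension: int = DEFAULT_EXTENSION,
    target_depth: int = DEFAULT_TARGET_DEPTH,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> CoverageTrack:
    """Extend each read to ``extension`` bp from its 5' start in the 3'
    direction, pile up per strand, and normalize to ``target_depth`` reads.

    Extension past a contig boundary is clipped (counted in
    ``clipped_reads``). Raises ``ValueError`` on an empty alignment set.
    """
    df = _as_frame(alignments)
    if df.empty:
        raise ValueError("no mapped reads: cannot build coverage")
    total = len(df)
    scale = target_depth / total

    lengths: Dict[str, int] = dict(contig_lengths or {})
    for contig, sub in df.groupby("contig", sort=False):
        need = int(sub["end"].max()) + extension
        lengths[contig] = max(lengths.get(str(contig), 0), need)

    depth: Dict[Tuple[str, str], np.ndarray] = {}
    clipped = 0
    for (contig, strand), sub in df.groupby(["contig", "strand"], sort=False):
        n = lengths[str(contig)]
        if strand == "+":
            starts = sub["start"].to_numpy()
            ends = starts + extension
        else:
            five_prime = sub["end"].to_numpy()  # exclusive end = 5' base + 1
            starts = five_prime - extension
            ends = five_prime
        clipped += int((ends > n).sum() + (starts < 0).sum())
        starts = np.clip(starts, 0, n)
        ends = np.clip(ends, 0, n)
        diff = np.zeros(n + 1, dtype=np.float64)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        depth[(str(contig), str(strand))] = np.cumsum(diff[:-1]) * scale

    for contig, n in lengths.items():
        for strand in "+-":
            depth.setdefault((contig, strand), np.zeros(n, dtype=np.float64))

    return CoverageTrack(
        depth=depth,
        total_reads=total,
        scale=scale,
        extension=extension,
        clipped_reads=clipped,
    )


def select_transcripts(
    annotation: Iterable[TranscriptModel], min_length: int = 30_000
) -> list:
    """Largest transcript per gene, kept only if it is at least
    ``min_length`` bp (very long transcripts are the ones whose
    elongation wave is observable inside the analysis window)."""
    return [t for t in longest_per_gene(annotation) if t.length >= min_length]


@dataclass
class GeneWindowCoverage:
    """Strand-oriented per-bp depth over offsets −2 kb .. +120 kb from the TSS."""

    gene_id: str
    depth: np.ndarray  # length WINDOW_LENGTH
    sample: object = None
    truncated: bool = False

    @property
    def offsets(self) -> np.ndarray:
        if self.depth.size == WINDOW_LENGTH:
            return np.arange(-WINDOW_UPSTREAM, WINDOW_DOWNSTREAM + 1)
        return np.arange(self.depth.size)

    def downstream(self) -> np.ndarray:
        """Depth over offsets >= 0 (the wave-calling region). Windows of
        non-standard length are taken to start at the TSS."""
        if self.depth.size == WINDOW_LENGTH:
            return self.depth[WINDOW_UPSTREAM:]
        return self.depth


def gene_window(
    track: CoverageTrack, transcript: TranscriptModel, sample=None
) -> GeneWindowCoverage:
    """Slice the transcript's sense-strand depth over −2 kb..+120 kb from
    its TSS, reversed for − strand genes so offsets increase 5'→3'.
    Out-of-contig stretches are zero-filled and flagged."""
    key = (transcript.contig, transcript.strand)
    if key not in track.depth:
        raise KeyError(f"no coverage for {key}")
    vec = track.depth[key]
    tss = transcript.tss
    out = np.zeros(WINDOW_LENGTH, dtype=np.float64)
    truncated = False
    if transcript.strand == "+":
        lo, hi = tss - WINDOW_UPSTREAM, tss + WINDOW_DOWNSTREAM + 1
        src_lo, src_hi = max(lo, 0), min(hi, vec.size)
        if src_lo > lo or src_hi < hi:
            truncated = True
        out[src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
    else:
        # offsets o map to genomic tss - o; build then reverse
        lo, hi = tss - WINDOW_DOWNSTREAM, tss + WINDOW_UPSTREAM + 1
        src_lo, src_hi = max(lo, 0), min(hi, vec.size)
        if src_lo > lo or src_hi < hi:
            truncated = True
        tmp = np.zeros(WINDOW_LENGTH, dtype=np.float64)
        tmp[src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
        out = tmp[::-1].copy()
    return GeneWindowCoverage(
        gene_id=transcript.gene_id, depth=out, sample=sample, truncated=truncated
    )


def window_from_start_counts(
    gene_id: str, start_counts: np.ndarray, sample=None, scale: float = 1.0
) -> GeneWindowCoverage:
    """Build a window directly from per-bp read-start counts over offsets
    0..120 kb (as produced by the simulator), i.e. extension 1 and a given
    scale factor. Bypasses BED serialization for large simulations."""
    out = np.zeros(WINDOW_LENGTH, dtype=np.float64)
    n = min(start_counts.size, WINDOW_DOWNSTREAM + 1)
    out[WINDOW_UPSTREAM : WINDOW_UPSTREAM + n] = start_counts[:n] * scale
    return GeneWindowCoverage(gene_id=gene_id, depth=out, sample=sample)


@dataclass
class MetaProfile:
    """Per-offset trimmed-mean depth across a cohort of gene windows."""

    offsets: np.ndarray
    depth: np.ndarray
    trim: float
    n_genes: int
    sample: object = None


def metagene(
    windows: Sequence[GeneWindowCoverage], trim: float = 0.05, sample=None
) -> MetaProfile:
    """Symmetric trimmed mean (default 5% per tail) of depth at each offset.

    ``floor(n * trim)`` genes are dropped from each tail of the per-offset
    depth distribution before averaging.
    """
    if not windows:
        raise ValueError("metagene requires at least one window")
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim fraction must be in [0, 0.5), got {trim}")
    mat = np.stack([w.depth for w in windows])
    prof = stats.trim_mean(mat, proportiontocut=trim, axis=0) if trim > 0 else mat.mean(axis=0)
    return MetaProfile(
        offsets=windows[0].offsets,
        depth=np.asarray(prof, dtype=np.float64),
        trim=trim,
        n_genes=len(windows),
        sample=sample,
    )


def single_gene_profile(window: GeneWindowCoverage, bin_size: int = 500):
    """Binned, spline-smoothed profile of log2(1 + depth) for one gene.

    Returns ``(bin_centers, raw_bin_means, smoothed)``; the smoothing
    spline's penalty is chosen by generalized cross-validation. A trailing
    partial bin is kept.
    """
    if window.depth.size < bin_size:
        raise ValueError("window shorter than one bin")
    logd = np.log2(1.0 + window.depth)
    n_bins = int(np.ceil(logd.size / bin_size))
    means = np.empty(n_bins)
    centers = np.empty(n_bins)
    off0 = -WINDOW_UPSTREAM
    for i in range(n_bins):
        a, b = i * bin_size, min((i + 1) * bin_size, logd.size)
        means[i] = logd[a:b].mean()
        centers[i] = off0 + (a + b - 1) / 2.0
    if np.allclose(means, means[0]):
        smoothed = np.full_like(means, means[0])
    elif n_bins < 5:  # too few bins to fit a smoothing spline
        smoothed = means.copy()
    else:
        spline = make_smoothing_spline(centers, means)
        smoothed = spline(centers)
    return centers, means, smoothed


def rpkm(alignments, interval: Tuple[str, int, int], total_mapped_reads: int) -> float:
    """Reads per kilobase per million mapped reads over a genomic interval.

    Counts alignment records overlapping the (0-based half-open) interval;
    RPKM = n_overlap * 1e9 / (interval_length * total_mapped_reads).
    """
    contig, lo, hi = interval
    if hi <= lo:
        raise ValueError("zero-length interval")
    df = _as_frame(alignments)
    sub = df[df["contig"] == contig]
    n = int(((sub["start"] < hi) & (sub["end"] > lo)).sum())
    return n * 1e9 / ((hi - lo) * total_mapped_reads)


def rpkm_from_window(
    window: GeneWindowCoverage,
    offset_lo: int,
    offset_hi: int,
    total_mapped_reads: int,
    scale: float = 1.0,
    extension: int = 1,
) -> float:
    """RPKM of a window sub-region, estimated from normalized depth.

    The read count over the region is recovered as sum(depth) / (scale ×
    extension); exact when reads fall entirely inside the region (always
    true for 1 bp reads with extension 1).
    """
    if offset_hi <= offset_lo:
        raise ValueError("zero-length region")
    a = offset_lo + WINDOW_UPSTREAM
    b = offset_hi + WINDOW_UPSTREAM
    a, b = max(a, 0), min(b, window.depth.size)
    reads = window.depth[a:b].sum() / (scale * extension)
    return reads * 1e9 / ((offset_hi - offset_lo) * total_mapped_reads)


def downstream_recovery(
    windows_by_sample: Mapping[object, Sequence[GeneWindowCoverage]],
    untreated: object,
    region: Tuple[int, int] = (90_000, 120_000),
) -> Dict[object, float]:
    """Mean depth over a far-downstream region (default +90..+120 kb) per
    sample, normalized to the untreated sample. Recovery of signal here
    tracks restoration of full-length transcription."""
    if untreated not in windows_by_sample:
        raise ValueError(f"untreated sample {untreated!r} missing")
    lo = region[0] + WINDOW_UPSTREAM
    hi = region[1] + WINDOW_UPSTREAM + 1

    def region_mean(ws):
        return float(np.mean([w.depth[lo:hi].mean() for w in ws]))

    ref = region_mean(windows_by_sample[untreated])
    if ref == 0:
        raise ValueError("untreated region mean is zero")
    return {s: region_mean(ws) / ref for s, ws in windows_by_sample.items()}
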