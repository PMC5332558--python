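"""Per-gene wave-front calling, gene filters, and elongation rates.

After release from a DRB block, transcriptionally engaged RNAPII advances
into genes as a synchronized wave. The caller scans each gene's window
from the TSS downstream: stretches of normalized depth at or above a
threshold (default 3 reads/bp) are "islands" of elongation, and when the
depth first stays below the threshold for a halt gap (default 5,000
consecutive bp) after at least one island, elongation is taken to have
halted there — the front is the last above-threshold base before that
gap. The halt gap filters background noise and independent downstream
transcription; bases inside annotated internal exons are masked out
entirely (mature-mRNA contamination there can neither extend nor break
an island).

Elongation rates follow as front displacement over time, either pairwise
between consecutive time points or as the slope of an ordinary
least-squares line through median fronts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotation import TranscriptModel
from .coverage import GeneWindowCoverage, WINDOW_DOWNSTREAM, WINDOW_UPSTREAM


@dataclass
class AnalysisConfig:
    """Thresholds of the wave-calling and gene-filtering pipeline.

    depth_threshold : normalized reads/bp at or above which a base extends
        an island.
    halt_gap : consecutive sub-threshold bp that mark a halt.
    max_masked_exon : internal exons longer than this are not masked
        (they are no longer "short" exonic spikes).
    min_transcript_length : transcript-length filter for the long-gene cohort.
    rpkm_threshold : expression filter over TSS..+250 bp (recovery mode).
    sustained_region : offsets, relative to (TSS, TTS), over which
        sustained signal is required in recovery mode: +30 kb from the TSS
        to 1 kb past the TTS.
    strict_monotonic : require strictly increasing fronts over time.
    """

    depth_threshold: float = 3.0
    halt_gap: int = 5_000
    max_masked_exon: int = 5_000
    min_transcript_length: int = 30_000
    rpkm_threshold: float = 0.3
    expression_region: Tuple[int, int] = (0, 250)
    sustained_from_tss: int = 30_000
    sustained_past_tts: int = 1_000
    trim: float = 0.05
    strict_monotonic: bool = True

    def __post_init__(self):
        if self.depth_threshold <= 0 or self.halt_gap <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class WaveFrontCall:
    """Called front for one gene in one sample.

    ``position`` is bp downstream of the TSS, present iff status is
    "called". ``reached_window_end`` flags fronts where no qualifying halt
    gap occurred before +120 kb (the TTS filter downstream removes such
    calls when they pass the termination site).
    """

    gene_id: str
    sample: object
    position: Optional[int] = None
    status: str = "called"
    reached_window_end: bool = False


def exon_mask_offsets(
    transcript: TranscriptModel, max_exon: int = 5_000
) -> np.ndarray:
    """Boolean mask over offsets 0..120 kb: True where the base lies in a
    short internal exon and must be ignored by the caller."""
    mask = np.zeros(WINDOW_DOWNSTREAM + 1, dtype=bool)
    for a, b in transcript.internal_exon_offsets():
        if b - a > max_exon:
            continue
        a, b = max(a, 0), min(b, mask.size)
        if a < b:
            mask[a:b] = True
    return mask


def call_wavefront(
    window: GeneWindowCoverage,
    config: AnalysisConfig = None,
    exon_mask: Optional[np.ndarray] = None,
) -> WaveFrontCall:
    """Call the wave-front for one gene window.

    Masked positions are transparent: they neither extend an island nor
    count toward the halt gap. If no island exists the status is
    "no_island"; if an island runs to the window end without a qualifying
    gap, the front is the last above-threshold position and the call is
    flagged ``reached_window_end``.
    """
    config = config or AnalysisConfig()
    depth = window.downstream()
    n = depth.size
    if exon_mask is None:
        unmasked = np.ones(n, dtype=bool)
    else:
        if exon_mask.size != n:
            raise ValueError("exon mask length does not match window")
        unmasked = ~exon_mask
    if not unmasked.any():
        raise ValueError("entire window is exon-masked")

    pos = np.flatnonzero(unmasked)
    above = depth[pos] >= config.depth_threshold
    if not above.any():
        return WaveFrontCall(window.gene_id, window.sample, None, "no_island")

    first = int(np.argmax(above))
    # run-length encode the above/below sequence beyond the first island
    a = above[first:]
    p = pos[first:]
    change = np.flatnonzero(np.diff(a.view(np.int8))) + 1
    bounds = np.concatenate(([0], change, [a.size]))
    front = None
    reached_end = True
    last_above = None
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        if a[lo]:
            last_above = int(p[hi - 1])
        else:
            # gap length counts only unmasked positions, i.e. run length
            if hi - lo >= config.halt_gap and last_above is not None:
                front = last_above
                reached_end = False
                break
    if front is None:
        front = last_above
    return WaveFrontCall(
        window.gene_id, window.sample, front, "called", reached_window_end=reached_end
    )


def median_wavefront(calls: Iterable[WaveFrontCall]) -> float:
    """Median called front position for one sample (even count: mean of
    the central pair)."""
    pos = [c.position for c in calls if c.status == "called"]
    if not pos:
        raise ValueError("no called fronts")
    return float(np.median(pos))


def pairwise_rate(p1: float, p2: float, dt: float) -> float:
    """Elongation rate between two front positions: (p2 − p1) bp over dt
    minutes, reported in kb/min."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return (p2 - p1) / 1000.0 / dt


@dataclass
class ElongationRateEstimate:
    scope: str  # "gene" or "cohort"
    rate: float  # kb/min
    method: str  # "pairwise" | "best_fit" | "mathematical"
    interval: Optional[Tuple[float, float]] = None
    intercept: Optional[float] = None  # bp, for best-fit lines
    r_squared: Optional[float] = None


def fit_rate(
    times_min: Sequence[float], positions_bp: Sequence[float], scope: str = "cohort"
) -> ElongationRateEstimate:
    """Ordinary least-squares line through (time, front position); the
    slope is the elongation rate in kb/min."""
    t = np.asarray(times_min, dtype=float)
    p = np.asarray(positions_bp, dtype=float)
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need at least two distinct time points")
    res = stats.linregress(t, p)
    return ElongationRateEstimate(
        scope=scope,
        rate=res.slope / 1000.0,
        method="best_fit",
        interval=(float(t.min()), float(t.max())),
        intercept=res.intercept,
        r_squared=res.rvalue**2,
    )


# ---------------------------------------------------------------------------
# Gene-set filters
# ---------------------------------------------------------------------------

def _overlaps_window(t: TranscriptModel, other: TranscriptModel) -> bool:
    if t.contig != other.contig:
        return False
    if t.strand == "+":
        lo, hi = t.tss - WINDOW_UPSTREAM, t.tss + WINDOW_DOWNSTREAM + 1
    else:
        lo, hi = t.tss - WINDOW_DOWNSTREAM, t.tss + WINDOW_UPSTREAM + 1
    return other.start < hi and other.end > lo


def filter_gene_set(
    calls: Sequence[WaveFrontCall],
    transcripts: Mapping[str, TranscriptModel],
    config: AnalysisConfig = None,
    mode: str = "drb",
    rpkm_tss: Optional[Mapping[str, float]] = None,
    rpkm_body: Optional[Mapping[str, float]] = None,
    untreated_condition: Optional[str] = None,
    all_transcripts: Optional[Sequence[TranscriptModel]] = None,
) -> Tuple[List[str], Dict[str, List[str]]]:
    """Apply the cohort filters to per-gene × per-sample front calls.

    Samples are ``(condition, time)`` pairs. A gene is retained when:

    * a front was called in every sample present in ``calls``;
    * fronts increase over time within each condition (strictly, by
      default);
    * no front lies downstream of the transcription termination site;
    * no other annotated gene overlaps its analysis window (automated
      surrogate for manual curation of antisense/convergent
      interference), checked when ``all_transcripts`` is given;

    and additionally in ``mode="recovery"``:

    * TSS-proximal RPKM ≥ the expression threshold (``rpkm_tss``);
    * sustained signal over +30 kb..TTS+1 kb (``rpkm_body`` ≥ threshold);
    * every UV front upstream of the untreated front (reduction in
      response to UV), when ``untreated_condition`` is given.

    Returns the retained gene ids and, per excluded gene, the list of
    failed rules.
    """
    config = config or AnalysisConfig()
    by_gene: Dict[str, Dict[object, WaveFrontCall]] = {}
    samples = set()
    for c in calls:
        by_gene.setdefault(c.gene_id, {})[c.sample] = c
        samples.add(c.sample)
    samples = sorted(samples)
    missing = {
        g: [s for s in samples if s not in d] for g, d in by_gene.items()
    }
    missing = {g: m for g, m in missing.items() if m}
    if missing:
        raise ValueError(f"calls missing for samples: {missing}")

    reasons: Dict[str, List[str]] = {}
    retained: List[str] = []
    for gene_id in sorted(by_gene):
        d = by_gene[gene_id]
        t = transcripts.get(gene_id)
        why: List[str] = []
        if t is None:
            why.append("no_annotation")
        uncalled = [s for s in samples if d[s].status != "called"]
        if uncalled:
            why.append("uncalled:" + ",".join(map(str, uncalled)))
        else:
            by_cond: Dict[str, List[Tuple[float, int]]] = {}
            for (cond, time) in samples:
                by_cond.setdefault(cond, []).append((time, d[(cond, time)].position))
            for cond, series in by_cond.items():
                series.sort()
                pos = [p for _, p in series]
                ok = (
                    all(b > a for a, b in zip(pos, pos[1:]))
                    if config.strict_monotonic
                    else all(b >= a for a, b in zip(pos, pos[1:]))
                )
                if len(pos) > 1 and not ok:
                    why.append(f"non_monotonic:{cond}")
            # TTS sits at offset length-1; anything past it is downstream
            if t is not None and any(
                d[s].position > t.length - 1 for s in samples
            ):
                why.append("front_beyond_tts")
            if mode == "recovery":
                if rpkm_tss is not None and rpkm_tss.get(gene_id, 0.0) < config.rpkm_threshold:
                    why.append("not_expressed")
                if rpkm_body is not None and rpkm_body.get(gene_id, 0.0) < config.rpkm_threshold:
                    why.append("no_sustained_signal")
                if untreated_condition is not None:
                    ref = [
                        d[s].position for s in samples if s[0] == untreated_condition
                    ]
                    uv = [
                        d[s].position for s in samples if s[0] != untreated_condition
                    ]
                    if ref and uv and not max(uv) < min(ref):
                        why.append("no_uv_reduction")
        if t is not None and all_transcripts is not None:
            for other in all_transcripts:
                if other.gene_id != gene_id and _overlaps_window(t, other):
                    why.append("overlapping_gene")
                    break
        if why:
            reasons[gene_id] = why
        else:
            retained.append(gene_id)
    return retained, reasons


def cohort_rates(
    calls: Sequence[WaveFrontCall],
    gene_set: Optional[Sequence[str]] = None,
) -> Tuple[Dict[object, float], List[ElongationRateEstimate]]:
    """Median front per sample (over a retained gene set) and pairwise
    rates between consecutive time points within each condition."""
    if gene_set is not None:
        keep = set(gene_set)
        calls = [c for c in calls if c.gene_id in keep]
    by_sample: Dict[object, List[WaveFrontCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample, []).append(c)
    medians = {s: median_wavefront(cs) for s, cs in sorted(by_sample.items())}
    rates: List[ElongationRateEstimate] = []
    by_cond: Dict[str, List[Tuple[float, float]]] = {}
    for (cond, time), m in medians.items():
        by_cond.setdefault(cond, []).append((time, m))
    for cond, series in sorted(by_cond.items()):
        series.sort()
        for (t1, p1), (t2, p2) in zip(series, series[1:]):
            rates.append(
                ElongationRateEstimate(
                    scope=f"cohort:{cond}",
                    rate=pairwise_rate(p1, p2, t2 - t1),
                    method="pairwise",
                    interval=(t1, t2),
                )
            )
    return medians, rates
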