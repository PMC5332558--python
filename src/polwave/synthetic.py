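"""Synthetic data with known ground truth.

Emulates the structure of a DRB-release GRO-seq experiment and of
alternative-last-exon (ALE) RNA-seq count tables, so that every downstream
stage — coverage, wave-front calling, rate estimation, splicing indices,
assay statistics — can be tested against configured truth without any
external sequencing data.

The nascent-transcription model per gene and sample is a sum of

* a promoter-proximal peak: ``promoter_height`` expected read starts per bp
  over ``[TSS, TSS + promoter_width)``;
* an elongation-wave plateau: ``plateau_height`` per bp over
  ``[TSS, TSS + front)`` where the front position is the time-integral of
  the configured wave speed;
* uniform background over the whole downstream window;
* optional mature-mRNA contamination spikes over internal exons
  (exercises the wave-front caller's exon-exclusion rule).

Reads are emitted as single-bp 5' start positions on the gene's strand;
the 250 bp extension applied in real GRO-seq processing is the consumer's
job (see :mod:`polwave.coverage`). With the noise model ``"none"`` the
per-bp start count is exactly the (rounded) expectation; with
``"poisson"`` it is a Poisson draw with that mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, write_bed12, write_gtf

WINDOW_DOWNSTREAM = 120_000  # bp downstream of the TSS covered by gene windows

SpeedSpec = Union[float, Sequence[float]]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class WaveKineticsConfig:
    """Ground-truth kinetics of the elongation wave per condition.

    Speeds are kb/min. A scalar speed means constant velocity, so the
    front at time *t* sits at ``1000 * v * t`` bp downstream of the TSS.
    A sequence gives one speed per inter-timepoint interval (the first
    interval runs from release at t=0 to the first time point), and the
    front is the piecewise integral. ``float("inf")`` marks a
    steady-state sample whose plateau fills the entire window (e.g. an
    untreated, non-DRB reference).
    """

    conditions: Sequence[str] = ("UN", "UV")
    time_points: Sequence[float] = (10.0, 25.0, 40.0)  # minutes after release
    speeds: Mapping[str, SpeedSpec] = field(
        default_factory=lambda: {"UN": 1.7, "UV": (1.0, 0.47, 0.25)}
    )
    promoter_height: float = 20.0  # expected read starts / bp
    promoter_width: int = 600  # bp; DRB restricts RNAPII to ~first 600 bp
    plateau_height: Union[float, Mapping[str, float]] = 5.0
    background: float = 0.0
    exon_contamination: float = 0.0  # extra starts/bp over internal exons
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("poisson", "none"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        for c in self.conditions:
            if c not in self.speeds:
                raise ConfigError(f"no speed configured for condition {c!r}")
        for c, v in self.speeds.items():
            vals = [v] if np.isscalar(v) else list(v)
            if any(x < 0 for x in vals):
                raise ConfigError("wave speeds must be >= 0")
        if min(self.promoter_height, self.background, self.exon_contamination) < 0:
            raise ConfigError("heights and rates must be >= 0")
        if any(t <= 0 for t in self.time_points) or list(self.time_points) != sorted(
            self.time_points
        ):
            raise ConfigError("time points must be positive and increasing")

    def plateau(self, condition: str) -> float:
        if isinstance(self.plateau_height, Mapping):
            return float(self.plateau_height[condition])
        return float(self.plateau_height)

    def front_position(self, condition: str, time: float) -> float:
        """True wave-front position (bp downstream of TSS) at ``time`` min."""
        v = self.speeds[condition]
        if np.isscalar(v):
            if np.isinf(v):
                return float("inf")
            return 1000.0 * float(v) * time
        times = list(self.time_points)
        if time not in times:
            raise ConfigError(f"time {time} not in configured time points")
        k = times.index(time)
        speeds = list(v)
        if len(speeds) != len(times):
            raise ConfigError(
                "per-interval speeds must have one entry per time point"
            )
        pos = 0.0
        prev = 0.0
        for i in range(k + 1):
            pos += 1000.0 * speeds[i] * (times[i] - prev)
            prev = times[i]
        return pos

    def samples(self) -> list:
        return [(c, t) for c in self.conditions for t in self.time_points]


@dataclass
class IsoformMixConfig:
    """Ground truth for two-isoform ALE read-count simulation.

    ``psi_true`` maps condition → fraction of transcripts using the
    TSS-proximal (short) terminal exon. Counts per replicate are Poisson
    draws whose means are the product of a per-bp sequencing depth
    (library_size / total effective length), the isoform fraction, and
    the region's effective length.
    """

    psi_true: Mapping[str, float] = field(
        default_factory=lambda: {"UN": 0.3, "UV": 0.8}
    )
    library_size: int = 10_000
    n_replicates: int = 2  # two biological replicates
    len_shared: int = 5_000  # gene-body (shared exons) effective length, bp
    len_proximal: int = 1_000
    len_distal: int = 1_000
    contamination: float = 0.0  # misassignment fraction between isoforms
    seed: int = 0

    def __post_init__(self):
        for c, p in self.psi_true.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"psi_true[{c!r}]={p} outside [0, 1]")
        if self.library_size < 0 or self.n_replicates < 1:
            raise ConfigError("library_size >= 0 and n_replicates >= 1 required")


# ---------------------------------------------------------------------------
# Annotation generator
# ---------------------------------------------------------------------------

_CONTIG = "synth1"
_INTERGENIC = 130_000  # bp between gene ends and the next TSS
_ALE_POSITION = 0.30  # proximal terminal exon sits at ~30% of gene length
_ALE_EXON = 800  # bp, proximal (unique) terminal exon
_FIRST_EXON = 300
_INTERNAL_EXON = 150
_INTERNAL_SPACING = 10_000
_LAST_EXON = 1_000


def make_annotation(
    n_genes: int,
    length_range=(80_000, 110_000),
    ale_fraction: float = 0.0,
    seed: int = 0,
    gtf_path=None,
    bed12_path=None,
) -> list:
    """Generate a synthetic gene annotation.

    Genes are laid head-to-tail on one contig with ``_INTERGENIC`` bp of
    spacing (wider than the analysis window, so no gene intrudes on
    another's window), random strand, and a fixed exon skeleton: a 300 bp
    first exon, 150 bp internal exons every 10 kb, and a 1 kb last exon.
    A Bernoulli(``ale_fraction``) draw per gene adds a second, short
    isoform that shares the 5' exons and ends in a unique TSS-proximal
    terminal exon at ~30% of the gene length.

    Returns the transcript list; optionally also writes GTF and BED12.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if not 0.0 <= ale_fraction <= 1.0:
        raise ConfigError(f"ale_fraction={ale_fraction} outside [0, 1]")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 1000 or hi < lo:
        raise ConfigError(f"invalid length_range {length_range}")

    rng = np.random.default_rng(seed)
    transcripts = []
    cursor = _INTERGENIC
    for i in range(n_genes):
        gid = f"G{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        is_ale = rng.random() < ale_fraction

        start = cursor
        end = cursor + length
        cursor = end + _INTERGENIC

        if strand == "+":
            tss = start
            off2gen = lambda a, b: (tss + a, tss + b)  # noqa: E731
        else:
            tss = end - 1
            off2gen = lambda a, b: (tss - b + 1, tss - a + 1)  # noqa: E731

        exon_offs = [(0, _FIRST_EXON)]
        pos = _INTERNAL_SPACING
        while pos + _INTERNAL_EXON < length - _LAST_EXON:
            exon_offs.append((pos, pos + _INTERNAL_EXON))
            pos += _INTERNAL_SPACING
        exon_offs.append((length - _LAST_EXON, length))

        exons = tuple(sorted(off2gen(a, b) for a, b in exon_offs))
        transcripts.append(
            TranscriptModel(gid, f"{gid}.long", _CONTIG, strand, start, end, exons)
        )

        if is_ale:
            ale_start = int(round(_ALE_POSITION * length))
            short_offs = [(a, b) for a, b in exon_offs if b <= ale_start]
            short_offs.append((ale_start, ale_start + _ALE_EXON))
            short_len = ale_start + _ALE_EXON
            s_exons = tuple(sorted(off2gen(a, b) for a, b in short_offs))
            if strand == "+":
                s_span = (start, start + short_len)
            else:
                s_span = (end - short_len, end)
            transcripts.append(
                TranscriptModel(
                    gid, f"{gid}.short", _CONTIG, strand, s_span[0], s_span[1], s_exons
                )
            )

    if gtf_path is not None:
        write_gtf(transcripts, gtf_path)
    if bed12_path is not None:
        write_bed12(transcripts, bed12_path)
    return transcripts


def contig_length(transcripts: Sequence[TranscriptModel]) -> int:
    return max(t.end for t in transcripts) + _INTERGENIC


# ---------------------------------------------------------------------------
# GRO-seq simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGroSeq:
    """Per-sample, per-gene read-start counts plus the generating truth.

    ``counts[(condition, time)][gene_id]`` is an integer array over
    offsets ``0 .. WINDOW_DOWNSTREAM`` (inclusive) downstream of the TSS:
    the number of read 5' starts at each bp.
    """

    annotation: list
    config: WaveKineticsConfig
    counts: dict

    def sample_labels(self) -> list:
        return list(self.counts)

    def total_reads(self, sample) -> int:
        return int(sum(int(c.sum()) for c in self.counts[sample].values()))

    def to_bed(self, sample, path) -> None:
        """Write the sample's reads as BED6 single-bp 5' start positions."""
        genes = {t.gene_id: t for t in self.annotation if t.transcript_id.endswith(".long")}
        frames = []
        for gid, cnt in self.counts[sample].items():
            t = genes[gid]
            offs = np.repeat(np.arange(cnt.size), cnt)
            starts = t.tss + offs if t.strand == "+" else t.tss - offs
            frames.append(
                pd.DataFrame(
                    {
                        "contig": t.contig,
                        "start": starts,
                        "end": starts + 1,
                        "name": gid,
                        "score": 0,
                        "strand": t.strand,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        df.sort_values(["contig", "start"], kind="stable").to_csv(
            path, sep="\t", header=False, index=False
        )


def expected_start_rate(
    transcript: TranscriptModel, config: WaveKineticsConfig, condition: str, time: float
) -> np.ndarray:
    """Closed-form expected read-start count per bp over offsets 0..120 kb."""
    n = WINDOW_DOWNSTREAM + 1
    rate = np.full(n, config.background, dtype=float)
    rate[: min(config.promoter_width, n)] += config.promoter_height
    front = config.front_position(condition, time)
    wave_end = n if np.isinf(front) else min(int(round(front)), n)
    wave_end = min(wave_end, transcript.length)  # the wave cannot pass the TTS
    rate[:wave_end] += config.plateau(condition)
    if config.exon_contamination > 0:
        for a, b in transcript.internal_exon_offsets():
            a, b = max(a, 0), min(b, n)
            if a < b:
                rate[a:b] += config.exon_contamination
    return rate


def simulate_groseq(
    annotation: Sequence[TranscriptModel],
    kinetics: WaveKineticsConfig,
    reads_target: Optional[int] = None,
) -> SimulatedGroSeq:
    """Simulate GRO-seq read starts for every gene and sample.

    ``reads_target``, when given, rescales all rates so the expected
    total read count per sample equals it; by default the configured
    per-bp heights are used as-is.
    """
    if reads_target is not None and reads_target < 0:
        raise ConfigError("reads_target must be >= 0")
    genes = [t for t in annotation if t.transcript_id.endswith(".long")]
    if not genes:  # annotation from elsewhere: take longest per gene
        from .annotation import longest_per_gene

        genes = longest_per_gene(annotation)
    rng = np.random.default_rng(kinetics.seed)
    counts: dict = {}
    for condition, time in kinetics.samples():
        per_gene = {}
        rates = {
            t.gene_id: expected_start_rate(t, kinetics, condition, time) for t in genes
        }
        if reads_target is not None:
            total = sum(r.sum() for r in rates.values())
            scale = reads_target / total if total > 0 else 0.0
            rates = {g: r * scale for g, r in rates.items()}
        for t in genes:
            rate = rates[t.gene_id]
            if kinetics.noise == "poisson":
                per_gene[t.gene_id] = rng.poisson(rate).astype(np.int64)
            else:
                per_gene[t.gene_id] = np.round(rate).astype(np.int64)
        counts[(condition, time)] = per_gene
    return SimulatedGroSeq(annotation=list(annotation), config=kinetics, counts=counts)


# ---------------------------------------------------------------------------
# ALE RNA-seq count simulation
# ---------------------------------------------------------------------------

def simulate_rnaseq_counts(
    n_events: int,
    mix: IsoformMixConfig,
    tsv_path=None,
) -> pd.DataFrame:
    """Simulate two-isoform ALE count tables for two conditions.

    One row per (event, replicate) with proximal / distal terminal-exon
    and gene-body (shared-exon) counts per condition, in the tidy layout
    consumed by :mod:`polwave.splicing`.
    """
    rng = np.random.default_rng(mix.seed)
    total_len = mix.len_shared + mix.len_proximal + mix.len_distal
    depth = mix.library_size / total_len  # expected reads per bp
    conditions = list(mix.psi_true)
    rows = []
    for i in range(n_events):
        eid = f"ALE{i:04d}"
        for rep in range(1, mix.n_replicates + 1):
            row = {"event_id": eid, "type": "ALE", "gene_id": f"G{i:04d}", "replicate": rep,
                   "len_proximal": mix.len_proximal, "len_distal": mix.len_distal}
            for cond in conditions:
                psi = mix.psi_true[cond]
                p_eff = psi * (1 - mix.contamination) + (1 - psi) * mix.contamination
                mu_prox = depth * p_eff * mix.len_proximal
                mu_dist = depth * (1 - p_eff) * mix.len_distal
                mu_gene = depth * mix.len_shared
                row[f"proximal_{cond}"] = int(rng.poisson(mu_prox))
                row[f"distal_{cond}"] = int(rng.poisson(mu_dist))
                row[f"gene_{cond}"] = int(rng.poisson(mu_gene))
            rows.append(row)
    df = pd.DataFrame(rows)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Assay-table simulation (qPCR CT values, per-nucleus intensities)
# ---------------------------------------------------------------------------

def simulate_assay_tables(
    seed: int = 0,
    fold_change: float = 4.0,
    n_ct_replicates: int = 3,
    ct_sd: float = 0.0,
    n_nuclei: int = 10_000,
    low_weight: float = 0.4,
    control_low_weight: float = 0.2,
    low_mean: float = 200.0,
    low_sd: float = 30.0,
    high_mean: float = 1000.0,
    high_sd: float = 120.0,
    ct_path=None,
    intensity_path=None,
):
    """Emit a qPCR CT table and a per-nucleus EU-intensity table.

    The CT table encodes a known target fold change between UV and UN
    conditions against a constant reference gene. The intensity table is a
    two-component Gaussian mixture per sample: ``low_weight`` is the
    probability of the low-transcription component for the test sample,
    ``control_low_weight`` for the control.
    """
    rng = np.random.default_rng(seed)
    ct_ref, ct_target_un = 18.0, 26.0
    ct_target_uv = ct_target_un - np.log2(fold_change)
    ct_rows = []
    for rep in range(1, n_ct_replicates + 1):
        for cond, ct_t in (("UN", ct_target_un), ("UV", ct_target_uv)):
            ct_rows.append(
                {
                    "sample": cond,
                    "replicate": rep,
                    "ct_target": ct_t + rng.normal(0, ct_sd),
                    "ct_reference": ct_ref + rng.normal(0, ct_sd),
                }
            )
    ct_df = pd.DataFrame(ct_rows)

    def mixture(weight, n):
        comp = rng.random(n) < weight
        vals = np.where(
            comp,
            rng.normal(low_mean, low_sd, n),
            rng.normal(high_mean, high_sd, n),
        )
        return vals

    int_rows = []
    for label, w in (("UV", low_weight), ("control", control_low_weight)):
        for v in mixture(w, n_nuclei):
            int_rows.append({"sample": label, "intensity": v})
    intensity_df = pd.DataFrame(int_rows)

    if ct_path is not None:
        ct_df.to_csv(ct_path, sep="\t", index=False)
    if intensity_path is not None:
        intensity_df.to_csv(intensity_path, sep="\t", index=False)
    return ct_df, intensity_df
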