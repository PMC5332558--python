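# Methods

## The analysis

`polwave` quantifies how fast RNA polymerase II elongates through genes,
from nascent-transcription (GRO-seq) coverage, and how transcripts switch
between alternative last exons (ALE), from exon-level RNA-seq counts.

The elongation readout relies on DRB synchronization: with elongation
chemically blocked, engaged polymerases accumulate in the
promoter-proximal ~600 bp; on release, they advance into gene bodies as a
coherent wave. At each time point the furthest downstream extent of
nascent signal — the wave-front — marks how far the cohort of polymerases
has traveled, and front displacement over time is the elongation rate.

## Coverage model

Aligned reads (BED6; 0-based half-open coordinates throughout) are
extended 250 bp from their 5′ start in the 3′ direction, piled up
per strand, and scaled by `target_depth / total_reads` with
`target_depth` = 20 million. Genes enter the analysis as the single
longest transcript per gene, kept only if ≥ 30 kb (shorter genes are
fully traversed before the first time point and carry no front
information). Per-gene windows span −2 kb..+120 kb around the TSS
(122,001 bp), re-oriented so increasing offset is sense-direction travel.
Meta-gene profiles are per-bp 5% trimmed means across windows
(`floor(n·trim)` genes dropped per tail); single-gene displays use
log2(1+depth), 500 bp bin means, and a smoothing spline whose penalty is
chosen by generalized cross-validation (fixed-penalty override available;
fewer than five bins returns the raw means).

Coverage is strand-specific: reads only count toward their own strand's
track and each gene reads its sense strand. GRO-seq is strand-resolved
and gene-body signal is overwhelmingly sense, so this is the natural
convention; pooling strands would let convergent neighbors bleed into
windows.

## Per-gene wave-front calling

Scanning a window downstream from the TSS, bases with normalized depth
≥ 3 reads/bp extend a coverage island. After at least one island, the
first run of 5,000 consecutive sub-threshold bases marks a halt, and the
front is the last above-threshold base before that run ("transition
point" — under this reading, island end and gap start coincide). The
5 kb gap requirement keeps background flecks and independent downstream
transcription units from truncating or extending calls. Bases inside
annotated internal exons (up to a configurable 5 kb in size) are masked
as transparent: mature-mRNA contamination produces sharp exonic spikes
that must not seed islands, and equally must not be counted as gap —
they carry no information about nascent elongation either way. A window
whose island reaches +120 kb without a qualifying gap still yields a
front (at the last covered base) but is flagged, and the
beyond-the-termination-site filter removes such calls downstream.

Cohort filters: fronts must be called in every sample; fronts must
strictly increase over time within each condition (configurable to
non-strict); no front may lie past the TTS. Instead of manual curation
of antisense/convergent interference, genes whose analysis window
overlaps any other annotated gene on either strand are excluded — an
automated, reproducible surrogate. The recovery-experiment mode adds:
expression (RPKM ≥ 0.3 over TSS..+250 bp), sustained gene-body signal
(RPKM ≥ 0.3 over +30 kb..TTS+1 kb — the source analysis names no number
for "sustained", so the same expression threshold is reused), and a
required reduction of every UV front below the untreated front.

Rates: pairwise, (Δfront)/Δt in kb/min between consecutive time points
of the per-sample median fronts; or the ordinary-least-squares slope of
median front against time ("best-fit" mode, used for the slow 2–12 hr
recovery series).

## Meta-profile (mathematical) wave-fronts

The untreated meta-profile is subtracted from each treated profile
(treated − untreated: UV excess near the promoter is positive, the
downstream deficit negative). The signed difference is mean-binned to a
100 bp grid and smoothed with loess (degree-1 local linear fits,
robustifying iterations as implemented in statsmodels lowess). The
initial front estimate is the first downward zero crossing of the fitted
line at offsets > +1 kb (skipping the promoter peak's own sign flips),
linearly interpolated between grid points; the refined estimate is the
first grid offset after it where |d(fit)/dx| (central differences on the
grid) falls to half its value at the crossing. If the derivative never
halves — e.g. an exactly linear decline — the initial estimate is
returned, flagged.

The loess span defaults to 0.05 of the window (~6 kb). The span must
stay well below the smallest front of interest: early-recovery fronts
sit ~5 kb into genes, and a much wider span smooths the positive lobe
away entirely, leaving no crossing. Both the span and the convention
(absolute derivative values in the half-derivative rule) are
configurable. Estimates are invariant to jointly rescaling both
profiles, and refinement never moves upstream of the initial estimate.

## Splicing quantification

Per replicate and event, PSI is the length-normalized inclusion
fraction `(inc/l_inc) / (inc/l_inc + exc/l_exc)`. Evidence for a ΔPSI of
the observed sign comes from a conjugate two-proportion model: uniform
Beta(1,1) priors on each condition's inclusion-read proportion give
Beta(inc+1, exc+1) posteriors, and the Bayes factor is the posterior
odds P(sign | data)/(1 − P), computed by trapezoidal integration of
pdf·cdf on a 4,001-point grid (the prior odds are 1 by symmetry). This
is deliberately simpler than a full read-generative isoform model: it
has the same decision surface (thresholds on reads, ΔPSI sign, BF) but
assigns whole reads to isoform-distinguishing regions. The BF is capped
at 1e12 where the posterior sign probability reaches 1.0 at float
precision.

Splicing indices (effect sizes on the raw counts):
single-region events (SE, RI): `log2((Exon_T/Gene_T)/(Exon_C/Gene_C))`;
switch events (AFE/ALE, and A5SS/A3SS restricted to variant-unique
reads): `log2((Exon2_T/Exon2_C)/(Exon1_T/Exon1_C))`, antisymmetric under
exon relabeling.

An event survives when, in every replicate: inclusion and exclusion
reads > 10; ΔPSI nonzero with a consistent sign; BF > 10; and
|log2 SI| ≥ 0.25 with a consistent sign. Relaxing any threshold can only
grow the surviving set. ALE events classify "short" when the
TSS-proximal terminal exon's relative usage rises under treatment. The
relative isoform-length change of a switch is (b − a)/b for long/short
pre-mRNA lengths b and a. GRO-seq terminal-exon shifts are summarized as
the difference of the two exons' log2 fold changes (the log of the
fold-change ratio) — a literal quotient of signed log values would be
ill-defined near zero.

## Assay statistics

qPCR fold changes use the ΔΔCT (Livak) method, 2^(−ΔΔCT); replicate
fold changes are averaged on the linear scale with SEM (geometric
averaging available by log-transforming upstream). Fractionation
enrichment is 2^(−(CT_fraction − CT_reference_fraction)) with no
reference gene, the two fractions being equal inputs of one sample. The
EU (5-ethynyl-uridine) recovery statistic is the fraction of nuclei
below a low-transcription intensity threshold over the fraction above a
high threshold, normalized to the same quantity in the control
(control = 1). Thresholds are explicit inputs — in practice they are set
per experiment from the intensity histogram; `suggest_thresholds` points
at KDE valleys but is never applied silently. The ratio is invariant
under any monotone rescaling applied jointly to intensities and
thresholds.

## Synthetic data: what it emulates, what it does not

The generator produces the study's data *structure* with known truth:

- **Annotation** — genes laid head-to-tail on one contig, 130 kb apart
  (wider than the window, so the overlap filter is exercised only when
  intruders are added deliberately), random strand, a fixed exon
  skeleton (300 bp first exon, 150 bp internal exons every 10 kb, 1 kb
  last exon), and an optional short ALE isoform sharing 5′ exons and
  ending in a unique terminal exon at ~30% of gene length.
- **GRO-seq** — per-bp expected read-start rates: promoter peak
  (20 starts/bp over 600 bp, the DRB-confined region), a step plateau
  (5 starts/bp) from the TSS to the front, uniform background, optional
  exonic contamination. The front is the time-integral of the configured
  speed (scalar or per-interval, kb/min), capped at the TTS; an infinite
  speed marks steady-state (untreated) samples. Noise is Poisson per bp,
  or "none" for the rounded expectation. Reads are 1 bp 5′ starts; the
  250 bp extension is applied by the consumer, keeping the
  generator/consumer contract clean.
- **ALE counts** — Poisson counts for proximal/distal terminal exons and
  shared gene body, with per-condition true ψ, per-replicate library
  size 10⁴, two biological replicates, effective lengths 1/1/5 kb.
- **Assay tables** — CT tables encoding a known fold change, and
  per-nucleus intensities from a two-component Gaussian mixture with a
  configurable low-transcription weight.

Default condition values mirror the study design where it states them
(10/25/40 min DRB-release time points; 2–12 hr recovery at ~0.04 kb/min;
two replicates; read counts and thresholds as above). The step plateau
is the simplest geometry with an unambiguous front; real profiles decay
with distance, carry mappability gaps, and have heterogeneous per-gene
rates — so passing tests demonstrate that the estimators recover truth
under the stated sampling noise, not that they are robust to every
artifact of real GRO-seq. No sequencing-error or alignment simulation is
attempted.

## Problem sizes and numerical choices

Stochastic checks run at 50 genes × 6 samples (DRB-release rate
recovery), 20 genes × 10 samples (slow recovery), 200 events × 2
replicates (splicing), 10⁴ nuclei (EU mixture), and 1,000 random 20 kb
windows (caller/oracle agreement) — sizes at which every Monte-Carlo
tolerance in the tests is several standard errors wide. Oracle-agreement
windows use a 2 kb halt gap so that gap/island interactions actually
occur inside 20 kb. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical config + seed reproduces
every output file byte for byte. Ties in longest-transcript selection
break on the lexicographically smallest transcript id. Median fronts use
the standard even-count convention (mean of the central pair).

## Known limitations

- The wave-front caller assumes sense-strand, single-gene windows;
  overlapping transcription is excluded, not modeled.
- The Bayes factor is a stand-in with binomial read assignment; its
  absolute scale is not comparable to a full isoform-generative model,
  only its ranking/thresholding behavior is.
- The loess route estimates one cohort front per sample; it cannot
  resolve per-gene rate heterogeneity.
- RPKM from depth (`rpkm_from_window`) is exact only for reads fully
  inside the region; the alignment-based `rpkm` is exact by
  construction.
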