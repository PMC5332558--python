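"""Alternative-isoform quantification: PSI, Bayes factors, splicing indices.

Events come in as exon-level count tables (two conditions, two biological
replicates). Per replicate we compute:

* PSI — the length-normalized fraction of transcripts supporting the
  inclusion / proximal isoform,
* a Bayes factor for the change in PSI having its observed sign, from a
  conjugate two-proportion model (independent uniform priors on the two
  read proportions; posterior odds computed by numeric integration of
  Beta posteriors),
* the log2 splicing index (SI): for single-region events (skipped exon,
  retained intron) the exon/gene read-fraction ratio between conditions;
  for switch events (AFE/ALE, and A5SS/A3SS restricted to reads unique
  to each variant) the ratio of the two exons' fold changes.

The final event list keeps events that pass, in *both* replicates:
inclusion and exclusion reads > 10, a consistently signed nonzero ΔPSI,
Bayes factor > 10, and |log2 SI| ≥ 0.25 with the same sign.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

BF_CAP = 1e12  # posterior mass of 1.0 at float precision maps here

DEFAULT_MIN_READS = 10
DEFAULT_MIN_BF = 10.0
DEFAULT_MIN_SI = 0.25


class UndefinedStatistic(ValueError):
    """A denominator needed by a closed-form statistic is zero."""


# ---------------------------------------------------------------------------
# PSI and the Bayes-factor stand-in
# ---------------------------------------------------------------------------

def psi_point(inclusion: float, exclusion: float, len_inc: float = 1.0,
              len_exc: float = 1.0) -> float:
    """Length-normalized inclusion fraction.

    PSI = (inc/len_inc) / (inc/len_inc + exc/len_exc); NaN when both
    counts are zero.
    """
    a = inclusion / len_inc
    b = exclusion / len_exc
    if a + b == 0:
        return float("nan")
    return a / (a + b)


def estimate_psi(
    inc_treated: int,
    exc_treated: int,
    inc_control: int,
    exc_control: int,
    len_inc: float = 1.0,
    len_exc: float = 1.0,
    grid: int = 4001,
) -> Dict[str, float]:
    """PSI per condition, ΔPSI (treated − control), and the Bayes factor.

    The Bayes factor compares "ΔPSI has the observed sign" against the
    opposite sign. With uniform priors on each condition's inclusion-read
    proportion θ (Beta(1,1)), the posterior for θ is
    Beta(inc+1, exc+1) and the prior probability of either sign is 1/2,
    so BF = P(sign | data) / (1 − P(sign | data)). The sign of the read
    proportion difference equals the sign of ΔPSI because the
    length-normalization map θ→ψ is strictly monotone and shared between
    conditions. P is computed by trapezoidal integration of
    pdf_treated × cdf_control on a θ grid.
    """
    for c in (inc_treated, exc_treated, inc_control, exc_control):
        if c < 0:
            raise ValueError("counts must be non-negative")
    psi_t = psi_point(inc_treated, exc_treated, len_inc, len_exc)
    psi_c = psi_point(inc_control, exc_control, len_inc, len_exc)
    if math.isnan(psi_t) or math.isnan(psi_c):
        return {
            "psi_treated": psi_t,
            "psi_control": psi_c,
            "delta_psi": float("nan"),
            "bayes_factor": float("nan"),
        }
    dpsi = psi_t - psi_c

    theta = np.linspace(0.0, 1.0, grid)
    post_t = stats.beta(inc_treated + 1, exc_treated + 1)
    post_c = stats.beta(inc_control + 1, exc_control + 1)
    # P(theta_t > theta_c | data)
    p_greater = float(np.trapezoid(post_t.pdf(theta) * post_c.cdf(theta), theta))
    p_greater = min(max(p_greater, 0.0), 1.0)
    p_sign = p_greater if dpsi >= 0 else 1.0 - p_greater
    if p_sign >= 1.0:
        bf = BF_CAP
    elif p_sign <= 0.0:
        bf = 0.0
    else:
        bf = min(p_sign / (1.0 - p_sign), BF_CAP)
    return {
        "psi_treated": psi_t,
        "psi_control": psi_c,
        "delta_psi": dpsi,
        "bayes_factor": bf,
    }


# ---------------------------------------------------------------------------
# Splicing-index formulas
# ---------------------------------------------------------------------------

def si_single(exon_treated: float, gene_treated: float, exon_control: float,
              gene_control: float) -> float:
    """log2((Exon_T/Gene_T)/(Exon_C/Gene_C)) for single-region events
    (skipped exon, retained intron)."""
    if min(gene_treated, gene_control, exon_control) <= 0:
        raise UndefinedStatistic("zero denominator in si_single")
    if exon_treated <= 0:
        raise UndefinedStatistic("zero exon count in si_single")
    return math.log2(
        (exon_treated / gene_treated) / (exon_control / gene_control)
    )


def si_switch(exon1_treated: float, exon1_control: float, exon2_treated: float,
              exon2_control: float) -> float:
    """log2((Exon2_T/Exon2_C)/(Exon1_T/Exon1_C)) for switch events
    (AFE/ALE; A5SS/A3SS using only variant-unique reads). Positive when
    exon2 gains relative to exon1 under treatment."""
    if min(exon1_control, exon2_control, exon1_treated, exon2_treated) <= 0:
        raise UndefinedStatistic("zero count in si_switch")
    return math.log2(
        (exon2_treated / exon2_control) / (exon1_treated / exon1_control)
    )


def relative_length_change(a: float, b: float) -> float:
    """Relative shortening (b − a)/b when switching from the long
    (pre-mRNA length b) to the short (length a) isoform."""
    if b <= 0:
        raise ValueError("long-isoform length must be positive")
    return (b - a) / b


# ---------------------------------------------------------------------------
# Event filtering and ALE classification
# ---------------------------------------------------------------------------

def evaluate_events(
    counts: pd.DataFrame,
    treated: str = "UV",
    control: str = "UN",
) -> pd.DataFrame:
    """Per-replicate statistics for a tidy ALE/AFE count table.

    Expects one row per (event_id, replicate) with columns
    ``proximal_<cond>``, ``distal_<cond>``, ``gene_<cond>``,
    ``len_proximal``, ``len_distal``. The proximal terminal exon plays
    the inclusion role in PSI. Adds psi/ΔPSI/BF and the switch SI
    (exon1 = proximal, exon2 = distal, so SI < 0 for a shift toward the
    short isoform).
    """
    rows = []
    for _, r in counts.iterrows():
        res = estimate_psi(
            int(r[f"proximal_{treated}"]),
            int(r[f"distal_{treated}"]),
            int(r[f"proximal_{control}"]),
            int(r[f"distal_{control}"]),
            len_inc=float(r.get("len_proximal", 1.0)),
            len_exc=float(r.get("len_distal", 1.0)),
        )
        try:
            si = si_switch(
                r[f"proximal_{treated}"],
                r[f"proximal_{control}"],
                r[f"distal_{treated}"],
                r[f"distal_{control}"],
            )
        except UndefinedStatistic:
            si = float("nan")
        rows.append(
            {
                "event_id": r["event_id"],
                "replicate": r["replicate"],
                "inclusion_treated": int(r[f"proximal_{treated}"]),
                "exclusion_treated": int(r[f"distal_{treated}"]),
                "inclusion_control": int(r[f"proximal_{control}"]),
                "exclusion_control": int(r[f"distal_{control}"]),
                **res,
                "log2_si": si,
            }
        )
    return pd.DataFrame(rows)


def filter_events(
    stats_df: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    min_bf: float = DEFAULT_MIN_BF,
    min_si: float = DEFAULT_MIN_SI,
) -> pd.DataFrame:
    """Replicated filtering of per-replicate event statistics.

    One output row per event with per-filter pass flags and ``passed``;
    every filter must hold in both (all) replicates:

    * ``reads``: inclusion > min_reads and exclusion > min_reads
      (inclusion/exclusion read support, checked in the treated
      condition and the control);
    * ``dpsi``: ΔPSI nonzero with the same sign across replicates;
    * ``bf``: Bayes factor > min_bf;
    * ``si``: |log2 SI| ≥ min_si with the same sign across replicates.
    """
    if stats_df.groupby("event_id")["replicate"].nunique().nunique() > 1:
        raise ValueError("events carry different replicate sets")
    out = []
    for eid, g in stats_df.groupby("event_id", sort=True):
        reads_ok = bool(
            (
                (g["inclusion_treated"] > min_reads)
                & (g["exclusion_treated"] > min_reads)
                & (g["inclusion_control"] > min_reads)
                & (g["exclusion_control"] > min_reads)
            ).all()
        )
        d = g["delta_psi"].to_numpy()
        dpsi_ok = bool(
            np.isfinite(d).all() and (np.all(d > 0) or np.all(d < 0))
        )
        bf_ok = bool((g["bayes_factor"] > min_bf).all())
        si = g["log2_si"].to_numpy()
        si_ok = bool(
            np.isfinite(si).all()
            and (np.abs(si) >= min_si).all()
            and (np.all(si > 0) or np.all(si < 0))
        )
        out.append(
            {
                "event_id": eid,
                "pass_reads": reads_ok,
                "pass_dpsi": dpsi_ok,
                "pass_bf": bf_ok,
                "pass_si": si_ok,
                "passed": reads_ok and dpsi_ok and bf_ok and si_ok,
                "mean_delta_psi": float(np.nanmean(d)),
                "mean_log2_si": float(np.nanmean(si)) if np.isfinite(si).any() else float("nan"),
            }
        )
    return pd.DataFrame(out)


def classify_ale(
    proximal_treated: float,
    proximal_control: float,
    distal_treated: float,
    distal_control: float,
) -> Optional[str]:
    """Direction of an ALE switch: "short" when the TSS-proximal terminal
    exon's relative usage rises under treatment, "long" when it falls,
    None when unchanged (no-call)."""
    tot_t = proximal_treated + distal_treated
    tot_c = proximal_control + distal_control
    if tot_t <= 0 or tot_c <= 0:
        raise ValueError("cannot classify an event with no reads in a condition")
    rel_t = proximal_treated / tot_t
    rel_c = proximal_control / tot_c
    if rel_t > rel_c:
        return "short"
    if rel_t < rel_c:
        return "long"
    return None


def terminal_exon_ratio(
    proximal_rpkm_treated: float,
    proximal_rpkm_control: float,
    distal_rpkm_treated: float,
    distal_rpkm_control: float,
) -> Tuple[float, float, float]:
    """GRO-seq terminal-exon fold changes for an ALE pair.

    Returns (log2 FC proximal, log2 FC distal, statistic) with
    statistic = proximal log2FC − distal log2FC, i.e. the log2 of the
    fold-change ratio; positive when nascent synthesis shifts toward the
    short isoform's terminal exon.
    """
    if proximal_rpkm_control <= 0 or distal_rpkm_control <= 0:
        raise UndefinedStatistic("zero untreated RPKM")
    if proximal_rpkm_treated <= 0 or distal_rpkm_treated <= 0:
        raise UndefinedStatistic("zero treated RPKM")
    l2p = math.log2(proximal_rpkm_treated / proximal_rpkm_control)
    l2d = math.log2(distal_rpkm_treated / distal_rpkm_control)
    return l2p, l2d, l2p - l2d
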