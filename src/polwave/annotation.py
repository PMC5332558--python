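"""Transcript models and annotation I/O.

Coordinates are 0-based, half-open throughout the package (BED-native).
GTF is converted to/from 1-based closed intervals on write/read.

A :class:`TranscriptModel` carries the strand-oriented geometry every
downstream stage needs: the transcription start site (TSS), the
transcription termination site (TTS), and exon intervals both in genomic
coordinates and as offsets downstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript of one gene, with exon structure.

    Parameters
    ----------
    gene_id, transcript_id : str
        Identifiers; several transcripts may share a gene_id.
    contig : str
        Reference sequence name.
    strand : str
        ``"+"`` or ``"-"``.
    start, end : int
        Genomic span, 0-based half-open; ``start < end``.
    exons : tuple of (int, int)
        Genomic exon intervals, 0-based half-open, sorted by start.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Genomic position of the transcription termination site (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    def offset_to_genomic(self, offset: int) -> int:
        """Map an offset downstream of the TSS (sense direction) to a genomic position."""
        return self.tss + offset if self.strand == "+" else self.tss - offset

    def exon_offsets(self) -> list:
        """Exon intervals as half-open [lo, hi) offsets downstream of the TSS,
        sorted in transcript (5'→3') order."""
        out = []
        for s, e in self.exons:
            if self.strand == "+":
                out.append((s - self.tss, e - self.tss))
            else:
                out.append((self.tss - e + 1, self.tss - s + 1))
        return sorted(out)

    def internal_exon_offsets(self) -> list:
        """Offsets of exons other than the first and last (mature-mRNA
        contamination there creates false coverage islands)."""
        offs = self.exon_offsets()
        return offs[1:-1] if len(offs) > 2 else []


def longest_per_gene(transcripts: Iterable[TranscriptModel]) -> list:
    """Keep the single longest transcript of each gene.

    Ties break on the lexicographically smallest transcript id so the
    selection is deterministic across runs and platforms.
    """
    best: dict = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if cur is None or (t.length, _neg_id(t)) > (cur.length, _neg_id(cur)):
            best[t.gene_id] = t
    return [best[g] for g in sorted(best)]


def _neg_id(t: TranscriptModel):
    # larger sort key == preferred; invert id ordering so smaller id wins ties
    return tuple(-ord(c) for c in t.transcript_id)


# ---------------------------------------------------------------------------
# GTF / BED12 serialization
# ---------------------------------------------------------------------------

def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcript + exon records as GTF (1-based, closed intervals)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.contig}\tpolwave\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\tpolwave\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list:
    """Read transcripts from a GTF carrying ``transcript`` and ``exon``
    features with gene_id / transcript_id attributes (parsed via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out = []
    for tr in db.features_of_type("transcript"):
        exons = tuple(
            sorted(
                (e.start - 1, e.end)
                for e in db.children(tr, featuretype="exon")
            )
        )
        out.append(
            TranscriptModel(
                gene_id=tr.attributes["gene_id"][0],
                transcript_id=tr.attributes["transcript_id"][0],
                contig=tr.seqid,
                strand=tr.strand,
                start=tr.start - 1,
                end=tr.end,
                exons=exons,
            )
        )
    out.sort(key=lambda t: (t.contig, t.start, t.transcript_id))
    return out


def write_bed12(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcripts in BED12 (0-based, half-open; blocks = exons)."""
    with open(path, "w") as fh:
        for t in transcripts:
            ex = sorted(t.exons) or [(t.start, t.end)]
            sizes = ",".join(str(e - s) for s, e in ex) + ","
            starts = ",".join(str(s - t.start) for s, _ in ex) + ","
            fh.write(
                "\t".join(
                    [
                        t.contig,
                        str(t.start),
                        str(t.end),
                        t.transcript_id,
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(len(ex)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
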