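"""Reading-frame analysis of binding sites inside coding regions.

A 22-nt site inside a CDS can be read in three codon phasings. Frames are
indexed 0/1/2 relative to the site's FIRST nucleotide: frame f places codon
starts at site positions f+1, f+4, ... Edge codons are completed with real
transcript nucleotides (never padding), because the residues the site
encodes can depend on the flanking bases — e.g. a tryptophan whose codon
starts one base upstream of the site. Exactly one frame coincides with the
transcript's own CDS phasing (the annotated frame); a stop codon in a frame
is reported, never truncated.
"""

from __future__ import annotations

import dataclasses
import logging

from .scanner import SiteHit
from .seqcore import REGION_CDS, TranscriptRecord, translate

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class FrameTranslation:
    frame: int
    peptide: str
    has_stop: bool
    nt_start: int  # 1-based transcript coordinate of the first translated base
    nt_end: int


@dataclasses.dataclass(frozen=True)
class FrameReport:
    """Site translations in all three phasings, with the CDS frame marked."""

    transcript_id: str
    gene: str
    site_start: int
    site_end: int
    annotated_frame: int
    frames: tuple[FrameTranslation, FrameTranslation, FrameTranslation]

    @property
    def annotated(self) -> FrameTranslation:
        return self.frames[self.annotated_frame]


@dataclasses.dataclass(frozen=True)
class PeptideContext:
    """Site-encoded residues with flanking CDS context (annotated frame only)."""

    upstream: str
    core: str
    downstream: str

    @property
    def context(self) -> str:
        return self.upstream + self.core + self.downstream


def _require_cds(hit: SiteHit) -> None:
    if hit.region != REGION_CDS:
        raise ValueError(f"site not in CDS (hit at {hit.start} is in {hit.region})")


def annotated_frame_of(hit: SiteHit, transcript: TranscriptRecord) -> int:
    """Frame index (relative to the site start) matching the CDS phasing."""
    return (transcript.cds_start - hit.start) % 3


def frame_report(hit: SiteHit, transcript: TranscriptRecord) -> FrameReport:
    """Translate the site in all three frames, completing edge codons.

    For frame f, (3-f)%3 upstream and however many downstream transcript
    nucleotides are needed to reach codon boundaries are included; at the
    transcript ends partial codons are dropped instead.
    """
    _require_cds(hit)
    site_len = hit.end - hit.start + 1
    frames = []
    for f in range(3):
        up_pad = (3 - f) % 3
        down_pad = (3 - (site_len + up_pad) % 3) % 3
        nt_start = hit.start - up_pad
        if nt_start < 1:
            nt_start += 3  # drop the incomplete leading codon
        nt_end = min(len(transcript), hit.end + down_pad)
        peptide = translate(transcript.subseq(nt_start, nt_end))
        frames.append(
            FrameTranslation(
                frame=f,
                peptide=peptide,
                has_stop="*" in peptide,
                nt_start=nt_start,
                nt_end=nt_end,
            )
        )
    annotated = annotated_frame_of(hit, transcript)
    if frames[annotated].has_stop:
        logger.info(
            "site at %d in %s overlaps a stop codon in the annotated frame",
            hit.start,
            transcript.transcript_id,
        )
    return FrameReport(
        transcript_id=hit.transcript_id,
        gene=hit.gene,
        site_start=hit.start,
        site_end=hit.end,
        annotated_frame=annotated,
        frames=tuple(frames),
    )


def peptide_context(
    hit: SiteHit, transcript: TranscriptRecord, flank_aa: int = 7
) -> PeptideContext:
    """Residues encoded by codons overlapping the site, with CDS flanks.

    The core covers every CDS codon that overlaps the site; upstream and
    downstream flanks are up to ``flank_aa`` residues each, truncated (not
    padded) at the CDS ends. All residues come from translating the CDS in
    its own frame, so upstream+core+downstream is a contiguous slice of the
    protein.
    """
    _require_cds(hit)
    if flank_aa < 0:
        raise ValueError("flank_aa must be >= 0")
    protein = translate(transcript.cds_sequence)
    c0 = (hit.start - transcript.cds_start) // 3
    c1 = min((hit.end - transcript.cds_start) // 3, len(protein) - 1)
    return PeptideContext(
        upstream=protein[max(0, c0 - flank_aa) : c0],
        core=protein[c0 : c1 + 1],
        downstream=protein[c1 + 1 : c1 + 1 + flank_aa],
    )


def frame_report_rows(report: FrameReport, context: PeptideContext) -> list[dict]:
    """Tidy rows for the peptide TSV (one row per frame)."""
    rows = []
    for ft in report.frames:
        annotated = ft.frame == report.annotated_frame
        rows.append(
            {
                "transcript_id": report.transcript_id,
                "gene": report.gene,
                "site_start": report.site_start,
                "frame": ft.frame,
                "annotated": annotated,
                "upstream": context.upstream if annotated else "",
                "core": context.core if annotated else ft.peptide,
                "downstream": context.downstream if annotated else "",
                "has_stop": ft.has_stop,
            }
        )
    return rows
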