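"""Sliding-window site scanning, region annotation and target summaries.

Every window of miRNA length on the transcript is scored by the
hydrogen-bond energy model; windows whose dG/dGm ratio reaches the
threshold (default 100%, i.e. complete complementarity) are reported as
hits. At the default threshold with the default scheme the scan is exactly
equivalent to exact substring search for the miRNA's reverse complement.
Overlapping hits are all reported — no suppression rule is applied.

Hit coordinates are 1-based inclusive on the mRNA. Each hit is assigned to
the region (5UTR/CDS/3UTR) containing its START position; a hit whose end
falls in a different region carries boundary_flag=True.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .energy import DEFAULT_SCHEME, DuplexScore, EnergyScheme, bond_profile, encode, max_hydrogen_bonds
from .seqcore import MatureMiRNA, TranscriptRecord, normalize

logger = logging.getLogger(__name__)

_RATIO_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class SiteHit:
    """One scored, region-annotated miRNA binding-site occurrence."""

    transcript_id: str
    gene: str
    species: str
    start: int  # 1-based inclusive
    end: int
    site_seq: str
    score: DuplexScore
    region: str
    boundary_flag: bool


@dataclasses.dataclass(frozen=True)
class TargetSummary:
    """Cohort-level tallies of hits from one miRNA over a transcript set."""

    total_hits: int
    per_gene: dict[str, int]
    per_region: dict[str, int]
    multiplicity: dict[int, list[str]]


def window_bond_counts(
    mirna: MatureMiRNA, seq: str, scheme: EnergyScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Bond count of every miRNA-length window of ``seq`` (normalized RNA).

    Returns an empty array when the sequence is shorter than the miRNA.
    """
    L = mirna.length
    idx = encode(seq)
    n_win = len(seq) - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    prof = bond_profile(mirna, scheme)
    scores = np.zeros(n_win, dtype=np.int64)
    for j in range(L):
        scores += prof[j, idx[j : j + n_win]]
    return scores


def annotate_region(start: int, end: int, transcript: TranscriptRecord) -> tuple[str, bool]:
    """Region of the hit's start position, plus a junction-spanning flag."""
    region = transcript.region_of(start)
    return region, transcript.region_of(end) != region


def scan_transcript(
    mirna: MatureMiRNA,
    transcript: TranscriptRecord,
    scheme: EnergyScheme = DEFAULT_SCHEME,
    threshold_percent: float = 100.0,
) -> list[SiteHit]:
    """All windows whose dG/dGm ratio reaches the threshold, ordered by start."""
    if not 0 < threshold_percent <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold_percent}")
    if len(transcript) < mirna.length:
        logger.warning(
            "transcript %s (%d nt) shorter than miRNA (%d nt); no scan",
            transcript.transcript_id,
            len(transcript),
            mirna.length,
        )
        return []
    bonds = window_bond_counts(mirna, transcript.sequence, scheme)
    max_bonds = max_hydrogen_bonds(mirna, scheme)
    ratios = 100.0 * bonds / max_bonds
    hits = []
    for w in np.nonzero(ratios >= threshold_percent - _RATIO_EPS)[0]:
        start = int(w) + 1
        end = start + mirna.length - 1
        region, boundary = annotate_region(start, end, transcript)
        score = DuplexScore(
            bonds=int(bonds[w]),
            max_bonds=max_bonds,
            dg=-scheme.e_bond * int(bonds[w]),
            dg_max=-scheme.e_bond * max_bonds,
            ratio=float(ratios[w]),
        )
        hits.append(
            SiteHit(
                transcript_id=transcript.transcript_id,
                gene=transcript.gene,
                species=transcript.species,
                start=start,
                end=end,
                site_seq=transcript.subseq(start, end),
                score=score,
                region=region,
                boundary_flag=boundary,
            )
        )
    return hits


def scan_transcripts(
    mirna: MatureMiRNA,
    transcripts: Iterable[TranscriptRecord],
    scheme: EnergyScheme = DEFAULT_SCHEME,
    threshold_percent: float = 100.0,
) -> list[SiteHit]:
    hits: list[SiteHit] = []
    for t in transcripts:
        hits.extend(scan_transcript(mirna, t, scheme, threshold_percent))
    return hits


def scan_fragment(
    mirna: MatureMiRNA,
    fragment: str,
    scheme: EnergyScheme = DEFAULT_SCHEME,
    threshold_percent: float = 100.0,
) -> list[tuple[int, DuplexScore]]:
    """Scan a bare sequence fragment; returns (1-based start, score) pairs.

    Convenience for fragment panels that carry no CDS annotation.
    """
    frag = normalize(fragment, "rna")
    bonds = window_bond_counts(mirna, frag, scheme)
    max_bonds = max_hydrogen_bonds(mirna, scheme)
    out = []
    for w in np.nonzero(100.0 * bonds / max_bonds >= threshold_percent - _RATIO_EPS)[0]:
        b = int(bonds[w])
        out.append(
            (
                int(w) + 1,
                DuplexScore(
                    bonds=b,
                    max_bonds=max_bonds,
                    dg=-scheme.e_bond * b,
                    dg_max=-scheme.e_bond * max_bonds,
                    ratio=100.0 * b / max_bonds,
                ),
            )
        )
    return out


def summarize_targets(hits: Sequence[SiteHit]) -> TargetSummary:
    """Deterministic per-gene, per-region and multiplicity tallies."""
    per_gene: dict[str, int] = {}
    per_region = {"5UTR": 0, "CDS": 0, "3UTR": 0}
    for h in hits:
        per_gene[h.gene] = per_gene.get(h.gene, 0) + 1
        per_region[h.region] += 1
    multiplicity: dict[int, list[str]] = {}
    for gene in sorted(per_gene):
        multiplicity.setdefault(per_gene[gene], []).append(gene)
    return TargetSummary(
        total_hits=len(hits),
        per_gene=dict(sorted(per_gene.items())),
        per_region=per_region,
        multiplicity=dict(sorted(multiplicity.items())),
    )


def hits_to_frame(hits: Sequence[SiteHit]) -> pd.DataFrame:
    """Hit table with 2-decimal energies; coordinates 1-based inclusive."""
    rows = [
        {
            "transcript_id": h.transcript_id,
            "gene": h.gene,
            "species": h.species,
            "start": h.start,
            "end": h.end,
            "region": h.region,
            "boundary_flag": h.boundary_flag,
            "site_seq": h.site_seq,
            "dg_kj_mol": round(h.score.dg, 2),
            "ratio_percent": round(h.score.ratio, 2),
        }
        for h in hits
    ]
    columns = [
        "transcript_id",
        "gene",
        "species",
        "start",
        "end",
        "region",
        "boundary_flag",
        "site_seq",
        "dg_kj_mol",
        "ratio_percent",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_hits_tsv(path: str | Path, hits: Sequence[SiteHit]) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_hits_bed(path: str | Path, hits: Sequence[SiteHit]) -> None:
    """BED6 export. Internal 1-based inclusive coordinates become 0-based
    half-open; the BED score column is round(10 * ratio_percent), capped at
    the format's 1000."""
    with open(path, "w") as fh:
        fh.write("# coordinates converted from 1-based inclusive to BED 0-based half-open\n")
        for h in hits:
            score = min(1000, int(round(10 * h.score.ratio)))
            fh.write(
                f"{h.transcript_id}\t{h.start - 1}\t{h.end}\t{h.gene}\t{score}\t+\n"
            )


def summary_to_frames(summary: TargetSummary) -> dict[str, pd.DataFrame]:
    """Render a TargetSummary as tidy frames (genes sorted lexicographically)."""
    gene_df = pd.DataFrame(
        [{"gene": g, "n_sites": n} for g, n in summary.per_gene.items()],
        columns=["gene", "n_sites"],
    )
    region_df = pd.DataFrame(
        [{"region": r, "n_sites": n} for r, n in summary.per_region.items()],
        columns=["region", "n_sites"],
    )
    mult_df = pd.DataFrame(
        [
            {"n_sites": k, "n_genes": len(v), "genes": ",".join(v)}
            for k, v in summary.multiplicity.items()
        ],
        columns=["n_sites", "n_genes", "genes"],
    )
    return {"per_gene": gene_df, "per_region": region_df, "multiplicity": mult_df}
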