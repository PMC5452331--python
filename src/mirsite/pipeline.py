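"""End-to-end orchestration: scan -> annotate -> summarize -> ORF -> conservation.

A RunConfig (flags or YAML) fully determines a run; rerunning with the same
config and inputs reproduces the output TSVs byte for byte. A run log
records the package version, a hash of the canonical config, and the item
counts at each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .conservation import (
    anchor_align,
    frequency_matrix,
    grouped_frequency_matrices,
    read_family_table,
    substitution_profile,
    write_logo_matrix,
    write_variation_tsv,
)
from .energy import DEFAULT_SCHEME, EnergyScheme
from .orfpeptides import frame_report, frame_report_rows, peptide_context
from .scanner import (
    scan_transcripts,
    summarize_targets,
    summary_to_frames,
    write_hits_bed,
    write_hits_tsv,
)
from .seqcore import MatureMiRNA, read_fasta, read_transcript_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    mirna_fasta: str
    transcripts_fasta: str
    annotations_tsv: str
    out_dir: str
    families_tsv: str | None = None
    threshold: float = 100.0
    anchor_threshold: float = 80.0
    scheme: dict = dataclasses.field(default_factory=dict)
    flank_aa: int = 7
    n_groups: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for key in ("mirna_fasta", "transcripts_fasta", "annotations_tsv"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: no such file {p}")
        if self.families_tsv is not None and not Path(self.families_tsv).exists():
            raise FileNotFoundError(f"families_tsv: no such file {self.families_tsv}")
        if not 0 < self.threshold <= 100:
            raise ValueError(f"threshold must be in (0, 100], got {self.threshold}")

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("load")
def _load(config: RunConfig):
    mirna_records = read_fasta(config.mirna_fasta)
    mid, mseq = mirna_records[0]
    mirna = MatureMiRNA(id=mid, sequence=mseq)
    transcripts = read_transcript_table(config.transcripts_fasta, config.annotations_tsv)
    scheme = EnergyScheme.from_dict(config.scheme) if config.scheme else DEFAULT_SCHEME
    return mirna, transcripts, scheme


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage; returns the paths of the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    paths: dict[str, Path] = {}

    mirna, transcripts, scheme = _load(config)
    counts["transcripts"] = len(transcripts)

    @_stage("scan")
    def do_scan():
        hits = scan_transcripts(mirna, transcripts, scheme, config.threshold)
        write_hits_tsv(out / "hits.tsv", hits)
        write_hits_bed(out / "hits.bed", hits)
        return hits

    hits = do_scan()
    paths["hits"] = out / "hits.tsv"
    paths["bed"] = out / "hits.bed"
    counts["hits"] = len(hits)

    @_stage("summarize")
    def do_summary():
        summary = summarize_targets(hits)
        for name, frame in summary_to_frames(summary).items():
            p = out / f"summary_{name}.tsv"
            frame.to_csv(p, sep="\t", index=False)
            paths[f"summary_{name}"] = p
        return summary

    do_summary()

    @_stage("orf")
    def do_orf():
        import pandas as pd

        by_id = {t.transcript_id: t for t in transcripts}
        rows = []
        for h in hits:
            if h.region != "CDS":
                continue
            t = by_id[h.transcript_id]
            rows.extend(
                frame_report_rows(frame_report(h, t), peptide_context(h, t, config.flank_aa))
            )
        p = out / "peptides.tsv"
        cols = ["transcript_id", "gene", "site_start", "frame", "annotated",
                "upstream", "core", "downstream", "has_stop"]
        pd.DataFrame(rows, columns=cols).to_csv(p, sep="\t", index=False)
        paths["peptides"] = p
        return rows

    counts["cds_peptide_rows"] = len(do_orf())

    if config.families_tsv is not None:

        @_stage("conservation")
        def do_conservation():
            import pandas as pd

            families = read_family_table(config.families_tsv)
            aligned = {
                g: anchor_align(f, mirna, scheme, config.anchor_threshold)
                for g, f in sorted(families.items())
            }
            pooled = frequency_matrix(list(aligned.values()))
            write_variation_tsv(out / "variation.tsv", pooled)
            write_logo_matrix(out / "logo_matrix.tsv", pooled)
            paths["variation"] = out / "variation.tsv"
            paths["logo_matrix"] = out / "logo_matrix.tsv"
            prof_rows = []
            for g, af in aligned.items():
                if not af.fragments:
                    continue
                ref = af.fragments[0].species
                prof = substitution_profile(af, ref)
                for sp, diffs in prof.per_member.items():
                    for col, ref_b, alt_b in diffs:
                        prof_rows.append(
                            {"gene": g, "reference": ref, "species": sp,
                             "column": col, "in_site": 1 <= col <= af.site_len,
                             "ref_base": ref_b, "alt_base": alt_b}
                        )
            pcols = ["gene", "reference", "species", "column", "in_site", "ref_base", "alt_base"]
            pd.DataFrame(prof_rows, columns=pcols).to_csv(
                out / "substitutions.tsv", sep="\t", index=False
            )
            paths["substitutions"] = out / "substitutions.tsv"
            for i, (genes, mat) in enumerate(
                grouped_frequency_matrices(aligned, config.n_groups), start=1
            ):
                p = out / f"variation_group{i}.tsv"
                write_variation_tsv(p, mat)
                paths[f"variation_group{i}"] = p
            return len(aligned)

        counts["families"] = do_conservation()

    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "counts": counts,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    paths["run_log"] = out / "run_log.json"
    logger.info("pipeline complete: %s", counts)
    return paths
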