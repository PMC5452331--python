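"""Window scanning, region annotation and cohort summaries."""

import numpy as np
import pytest

from mirsite.datasets import PERFECT_SITE_RNA, binding_site_fragments
from mirsite.scanner import (
    annotate_region,
    hits_to_frame,
    scan_fragment,
    scan_transcript,
    summarize_targets,
    write_hits_bed,
    write_hits_tsv,
)
from mirsite.seqcore import TranscriptRecord, normalize

from conftest import build_transcript


def naive_exact_search(text: str, pattern: str) -> list[int]:
    """Brute-force exact substring search; 1-based starts."""
    return [i + 1 for i in range(len(text) - len(pattern) + 1) if text[i : i + len(pattern)] == pattern]


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestScanTranscript:
    def test_fragment_with_planted_site(self, mirna):
        # 5'UTR ortholog fragment: 7-nt flanks around the site
        frag = "CUGGCCA" + PERFECT_SITE_RNA + "ACUUUGG"
        t = TranscriptRecord("t", "USP29", "Hsa", frag + "A" * 60, cds_start=37, cds_end=96)
        hits = scan_transcript(mirna, t)
        assert len(hits) == 1
        assert hits[0].start == 8
        assert hits[0].site_seq == PERFECT_SITE_RNA
        assert hits[0].region == "5UTR"
        assert hits[0].score.ratio == 100.0

    def test_no_hits_in_random_sequence(self, mirna):
        rng = np.random.default_rng(7)
        seq = random_rna(rng, 500)
        while PERFECT_SITE_RNA in seq:
            seq = random_rna(rng, 500)
        t = TranscriptRecord("t", "g", "Hsa", seq, cds_start=101, cds_end=400)
        assert scan_transcript(mirna, t) == []

    def test_equivalence_with_naive_search_on_random_and_planted(self, mirna):
        rng = np.random.default_rng(42)
        for trial in range(50):
            seq = list(random_rna(rng, 300))
            if trial % 2:
                p = int(rng.integers(0, 300 - 22))
                seq[p : p + 22] = PERFECT_SITE_RNA
            seq = "".join(seq)
            t = TranscriptRecord("t", "g", "Hsa", seq, cds_start=1, cds_end=300)
            got = [h.start for h in scan_transcript(mirna, t)]
            assert got == naive_exact_search(seq, PERFECT_SITE_RNA)

    def test_threshold_monotonicity(self, mirna):
        rng = np.random.default_rng(3)
        seq = random_rna(rng, 200)
        t = TranscriptRecord("t", "g", "Hsa", seq, cds_start=1, cds_end=198)
        prev: set[int] = set()
        for thr in (100, 95, 80, 60, 40, 20):
            starts = {h.start for h in scan_transcript(mirna, t, threshold_percent=thr)}
            assert prev <= starts  # lowering the threshold never removes a hit
            prev = starts

    def test_short_transcript_warns_and_returns_empty(self, mirna, caplog):
        t = TranscriptRecord("tiny", "g", "Hsa", "ACGUACGUACGU", cds_start=1, cds_end=12)
        with caplog.at_level("WARNING"):
            assert scan_transcript(mirna, t) == []
        assert "tiny" in caplog.text

    def test_bad_threshold(self, mirna):
        t = TranscriptRecord("t", "g", "Hsa", "A" * 60, cds_start=1, cds_end=60)
        for thr in (0, -5, 120):
            with pytest.raises(ValueError):
                scan_transcript(mirna, t, threshold_percent=thr)


class TestFragmentPanels:
    """Every published fragment row anchors exactly one site at the bold offset."""

    @pytest.mark.parametrize("row", binding_site_fragments(), ids=lambda r: f"{r.group}-{r.species}-{r.gene}-{r.position}")
    def test_row_scans_at_printed_offset(self, mirna, row):
        exact = row.site_seq == PERFECT_SITE_RNA
        at_full = scan_fragment(mirna, row.fragment, threshold_percent=100)
        at_anchor = scan_fragment(mirna, row.fragment, threshold_percent=80)
        assert len(at_anchor) == 1
        assert at_anchor[0][0] == row.site_offset + 1
        if exact:
            assert len(at_full) == 1 and at_full[0][0] == row.site_offset + 1
        else:
            assert at_full == []

    def test_panel_shape(self):
        rows = binding_site_fragments()
        assert len(rows) == 54
        exact = sum(r.site_seq == PERFECT_SITE_RNA for r in rows)
        assert exact == 38


class TestAnnotateRegion:
    @pytest.fixture()
    def transcript(self):
        return TranscriptRecord("t", "g", "Hsa", "A" * 200, cds_start=61, cds_end=150)

    def test_leader_site(self, transcript):
        assert annotate_region(2, 23, transcript) == ("5UTR", False)

    def test_cds_interior(self, transcript):
        assert annotate_region(70, 91, transcript) == ("CDS", False)

    def test_boundary_spanning_assigned_by_start(self, transcript):
        region, boundary = annotate_region(141, 162, transcript)
        assert region == "CDS" and boundary is True
        region, boundary = annotate_region(50, 71, transcript)
        assert region == "5UTR" and boundary is True


class TestSummaries:
    def _hit(self, mirna, gene, start, transcript):
        (h,) = [h for h in scan_transcript(mirna, transcript) if h.start == start]
        assert h.gene == gene
        return h

    def test_counts_and_multiplicity(self, mirna):
        hits = []
        rng = np.random.default_rng(11)
        for gene, n_sites in (("g1", 1), ("g2", 2), ("g3", 3)):
            utr3 = list(random_rna(rng, 300))
            for k in range(n_sites):
                utr3[k * 40 : k * 40 + 22] = PERFECT_SITE_RNA
            t = build_transcript(random_rna(rng, 30), random_rna(rng, 60), "".join(utr3),
                                 transcript_id=gene, gene=gene)
            hits.extend(scan_transcript(mirna, t))
        summary = summarize_targets(hits)
        assert summary.total_hits == 6
        assert summary.per_gene == {"g1": 1, "g2": 2, "g3": 3}
        assert summary.multiplicity == {1: ["g1"], 2: ["g2"], 3: ["g3"]}
        assert sum(summary.per_region.values()) == summary.total_hits

    def test_empty_summary(self):
        summary = summarize_targets([])
        assert summary.total_hits == 0
        assert summary.per_gene == {}
        assert summary.per_region == {"5UTR": 0, "CDS": 0, "3UTR": 0}
        assert summary.multiplicity == {}


def test_hit_tsv_and_bed_export(tmp_path, mirna):
    frag = "CUGGCCA" + PERFECT_SITE_RNA + "ACUUUGG"
    t = TranscriptRecord("tx1", "USP29", "Hsa", frag + "A" * 60, cds_start=37, cds_end=96)
    hits = scan_transcript(mirna, t)
    tsv, bed = tmp_path / "hits.tsv", tmp_path / "hits.bed"
    write_hits_tsv(tsv, hits)
    write_hits_bed(bed, hits)
    frame = hits_to_frame(hits)
    assert list(frame.columns) == [
        "transcript_id", "gene", "species", "start", "end", "region",
        "boundary_flag", "site_seq", "dg_kj_mol", "ratio_percent",
    ]
    assert frame.loc[0, "dg_kj_mol"] == -121.0
    lines = [l for l in bed.read_text().splitlines() if not l.startswith("#")]
    chrom, start0, end, name, score, strand = lines[0].split("\t")
    # 1-based inclusive [8, 29] -> 0-based half-open [7, 29)
    assert (chrom, int(start0), int(end), name, strand) == ("tx1", 7, 29, "USP29", "+")
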