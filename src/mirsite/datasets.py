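"""Bundled reference inputs: the query miRNA and published ortholog fragment panels.

The query is the mature human miR-619-5p sequence as deposited in miRBase.
The fragment panels are the published per-species mRNA fragments around its
binding sites in ortholog families: a 5'UTR panel (CCDC114, DHRS9, RGS3,
USP29; RNA, 7-nt flanks), a 3'UTR panel (ADAM17, ALDH3A2, ARL11; DNA,
10-nt upstream flank) and a two-site 3'UTR panel (ERBB3, FBLIM1, FKBP14;
DNA, 10-nt upstream flank). ``site_offset`` is the 0-based offset of the
annotated site within each fragment; ``position`` is the reported site
position on the full mRNA (informational only — fragments, not full mRNAs,
are bundled).
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .conservation import FamilyMember, OrthologFamily
from .seqcore import MatureMiRNA, normalize

#: Mature human miR-619-5p, 5'->3' (miRBase).
MIR619_5P_SEQUENCE = "GCUGGGAUUACAGGCAUGAGCC"

#: The complete complementary binding site, RNA and DNA spellings.
PERFECT_SITE_RNA = "GGCUCAUGCCUGUAAUCCCAGC"
PERFECT_SITE_DNA = "GGCTCATGCCTGTAATCCCAGC"

GROUP_UTR5 = "utr5"
GROUP_UTR3 = "utr3"
GROUP_UTR3_TWO_SITE = "utr3_two_site"


def mir619_5p() -> MatureMiRNA:
    return MatureMiRNA(id="hsa-miR-619-5p", sequence=MIR619_5P_SEQUENCE)


@dataclasses.dataclass(frozen=True)
class FragmentRow:
    group: str
    species: str
    gene: str
    position: int  # reported site position on the full mRNA, 1-based
    fragment: str  # as published (RNA for the 5'UTR panel, DNA otherwise)
    site_offset: int  # 0-based offset of the annotated site within fragment

    @property
    def site_seq(self) -> str:
        """The annotated 22-nt site, RNA spelling."""
        return normalize(self.fragment, "rna")[self.site_offset : self.site_offset + 22]


_S = PERFECT_SITE_RNA
_D = PERFECT_SITE_DNA

# (species, gene, position, upstream, site, downstream)
_UTR5_ROWS = [
    ("Hsa", "CCDC114", 261, "GCAUGCU", _S, "ACUUUGG"),
    ("Hsa", "DHRS9", 1281, "GCGCGGU", _S, "ACUUUGG"),
    ("Hsa", "RGS3", 205, "GCGCAGU", _S, "ACUUUGG"),
    ("Ptr", "RGS3", 1, "GCGCAGU", _S, "ACUUUGG"),
    ("Nle", "RGS3", 205, "GCACGGU", _S, "ACUUUGG"),
    ("Hsa", "USP29", 2, "CUGGCCA", _S, "ACUUUGG"),
    ("Pab", "USP29", 52, "CUGGCCA", _S, "ACUUUGG"),
    ("Nle", "USP29", 52, "CUGGCCA", _S, "ACUUUGG"),
    ("Mle", "USP29", 47, "CUGGCCA", _S, "ACUUUGG"),
    ("Can", "USP29", 98, "CUGGCCA", _S, "AUUUUGG"),
    ("Ggo", "USP29", 100, "CUGGCCA", "GGCUCAUGCCUGUAAUUCCAGC", "ACUUUGG"),
    ("Rro", "USP29", 52, "CUGGCCA", "GGCUCAUGCCUGUAAUCGCAGC", "ACUUUGG"),
]

_UTR3_ROWS = [
    ("Hsa", "ADAM17", 3466, "TGGGAGTGGT", _D, "ACTTGGAGAGG"),
    ("Cat", "ADAM17", 3485, "GGGGCGCAGT", _D, "ACTTTGGGAGG"),
    ("Mmul", "ADAM17", 3491, "GGGGCGCGGT", _D, "ACTTTGGGAGG"),
    ("Mne", "ADAM17", 3438, "GGGGCGCGGT", _D, "ACTTTGGGAGG"),
    ("Ptr", "ADAM17", 3449, "TGGGAGTGGT", _D, "ACTTGGAGAGG"),
    ("Rro", "ADAM17", 3425, "GGGGCGCGGT", _D, "ACTTTGGGAGG"),
    ("Hsa", "ALDH3A2", 2617, "CGGGCGTGGT", _D, "ACTTTGGGAGG"),
    ("Cja", "ALDH3A2", 3444, "CGGGCGTGGT", _D, "ACTTTAGGAGG"),
    ("Ggo", "ALDH3A2", 2712, "CGGGCGTGGT", _D, "ACTTTGGGAGG"),
    ("Mmul", "ALDH3A2", 2509, "CGGACATGGT", _D, "ACTTTGGGAGG"),
    ("Mne", "ALDH3A2", 2504, "CGGACATGGT", _D, "ACTTTGGGAGG"),
    ("Nle", "ALDH3A2", 2714, "TGGTCATGGT", _D, "ACTTTGGGAGG"),
    ("Pab", "ALDH3A2", 2297, "TGGGCATGGT", _D, "ACTTTGGGAGG"),
    ("Ppa", "ALDH3A2", 2715, "CGGGCATGGT", "GGCTCATGTCTGTAATCCCAGC", "ACTTTGGGAGG"),
    ("Ptr", "ALDH3A2", 2711, "CGGGCATGGT", "GGCTCATGTCTGTAATCCCAGC", "ACTTTGGGAGG"),
    ("Rro", "ALDH3A2", 2727, "CGGACGTGGT", _D, "ACTTTGGGAGG"),
    ("Hsa", "ARL11", 1033, "TTGGCCCGGT", _D, "ACTGTGGGAGA"),
    ("Cat", "ARL11", 1642, "CAGATGCAGT", _D, "ACTTTGGGTGG"),
    ("Mfa", "ARL11", 1698, "CAGATGCAGT", _D, "ACTTTGGGTGG"),
    ("Mmul", "ARL11", 1747, "CAGATGCAGT", _D, "ACTTTGGGTGG"),
    ("Mne", "ARL11", 1024, "TTGGCACGGT", _D, "ACTTTGGGAGA"),
    ("Mne", "ARL11", 1471, "CAGATGCAGT", _D, "ACTTTGGGTGG"),
    ("Ptr", "ARL11", 1353, "CGGGCATGGT", "GGCTCATGTCTGTAATCCCAGC", "ACTTTGGGAGG"),
    ("Rro", "ARL11", 1254, "CAGGTGCAGT", _D, "ACTTTGGGCGG"),
]

_UTR3_TWO_SITE_ROWS = [
    ("Hsa", "ERBB3", 4950, "CGGGCATGGT", "GGCTCATGCCTGTAATCTCAGC", "ACTTTGGGAG"),
    ("Hsa", "ERBB3", 5104, "TGGGTGCAGT", _D, "CAGCACTTTG"),
    ("Csa", "ERBB3", 4989, "CGGGCATGGT", "GGCTCATGCCTGTAATCCTAGC", "ACTTTGGGAG"),
    ("Csa", "ERBB3", 5149, "TGGGCGCTGT", "GGCTCATGCCTGCAATCCCAGC", "ACTTTGGGAG"),
    ("Mfa", "ERBB3", 5114, "TGGGCATGGT", _D, "ACTTTGGGAG"),
    ("Mfa", "ERBB3", 5269, "TGGGCGCTGT", "GGCTCATGCCTGCAATCCCAGC", "CCTTTGGGAG"),
    ("Mmu", "ERBB3", 5114, "TGGGCATGGT", _D, "ACTTTGGGAG"),
    ("Mmu", "ERBB3", 5269, "TGGGCGCTGT", "GGCTCATGCCTGCAATCCCAGC", "CCTTTGGGAG"),
    ("Mne", "ERBB3", 5112, "CGGGCATGGT", _D, "ACTTTGGGAG"),
    ("Mne", "ERBB3", 5267, "TGGGCGCTGT", "GGCTCATGCCTGCAATCCCAGC", "CCTTTGGGAG"),
    ("Pan", "ERBB3", 5106, "CGGGCATGGT", _D, "ACTTTGGGAG"),
    ("Pan", "ERBB3", 5274, "TGGGCGCTGT", "GGCTCATGCCTGCAGTCCCAGC", "ACTTTGGGAG"),
    ("Ptr", "ERBB3", 5105, "CGGGCATGGT", "GGCTCATGCCTGTAATCTCAGC", "ACTTTGGGAG"),
    ("Ptr", "ERBB3", 5243, "TGGGTGCAGT", _D, "CAGCACTTTG"),
    ("Mne", "FBLIM1", 1938, "TGGGCGTGGT", "GGCTCATGCCTGTAATCCCTGC", "ACTTTGGGAG"),
    ("Mne", "FBLIM1", 5267, "TGGGCGCTGT", "GGCTCATGCCTGCAATCCCAGC", "CCTTTGGGAG"),
    ("Pab", "FKBP14", 1514, "CAGGCACGGT", "GGCTCACGCCTGTAATCCCAGC", "ACTTCGGGAG"),
    ("Pab", "FKBP14", 2128, "TGGGTGTGGT", _D, "ACTTTGGGGG"),
]


def _build_rows() -> list[FragmentRow]:
    rows = []
    for group, raw in (
        (GROUP_UTR5, _UTR5_ROWS),
        (GROUP_UTR3, _UTR3_ROWS),
        (GROUP_UTR3_TWO_SITE, _UTR3_TWO_SITE_ROWS),
    ):
        for species, gene, pos, up, site, down in raw:
            rows.append(
                FragmentRow(
                    group=group,
                    species=species,
                    gene=gene,
                    position=pos,
                    fragment=up + site + down,
                    site_offset=len(up),
                )
            )
    return rows


FRAGMENT_ROWS: tuple[FragmentRow, ...] = tuple(_build_rows())


def binding_site_fragments(group: str | None = None) -> list[FragmentRow]:
    """All bundled fragment rows, optionally restricted to one panel."""
    if group is None:
        return list(FRAGMENT_ROWS)
    valid = {GROUP_UTR5, GROUP_UTR3, GROUP_UTR3_TWO_SITE}
    if group not in valid:
        raise ValueError(f"unknown panel {group!r}; choose from {sorted(valid)}")
    return [r for r in FRAGMENT_ROWS if r.group == group]


def fragments_frame() -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in FRAGMENT_ROWS])


def fragment_families(group: str | None = None) -> dict[str, OrthologFamily]:
    """Bundle fragment rows into per-gene ortholog families.

    Genes with two distinct sites (the two-site panel) contribute one member
    per fragment; species labels may therefore repeat within a family.
    """
    rows = binding_site_fragments(group)
    by_gene: dict[str, list[FamilyMember]] = {}
    for r in rows:
        by_gene.setdefault(r.gene, []).append(
            FamilyMember(
                species=r.species,
                fragment=r.fragment,
                declared_offset=r.site_offset + 1,
            )
        )
    return {
        g: OrthologFamily(gene=g, members=tuple(ms))
        for g, ms in by_gene.items()
        if len(ms) >= 2
    }
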