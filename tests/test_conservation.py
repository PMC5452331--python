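"""Anchor alignment, substitution profiles and position-frequency matrices."""

import numpy as np
import pytest

from mirsite.conservation import (
    AlignedFamily,
    FamilyMember,
    OrthologFamily,
    anchor_align,
    frequency_matrix,
    group_genes,
    grouped_frequency_matrices,
    read_family_table,
    substitution_profile,
    write_logo_matrix,
    write_variation_tsv,
)
from mirsite.datasets import (
    GROUP_UTR3,
    GROUP_UTR5,
    PERFECT_SITE_DNA,
    PERFECT_SITE_RNA,
    fragment_families,
)
from mirsite.synthetic import make_family


@pytest.fixture(scope="module")
def usp29(mirna):
    fam = fragment_families(GROUP_UTR5)["USP29"]
    return anchor_align(fam, mirna)


class TestAnchorAlign:
    def test_published_5utr_panel_anchors_all_rows(self, mirna):
        for gene, family in fragment_families(GROUP_UTR5).items():
            aligned = anchor_align(family, mirna)
            assert not aligned.excluded
            for frag in aligned.fragments:
                assert frag.site_start == 7  # printed 7-nt upstream flank
                assert frag.ratio >= 80.0

    def test_single_substitution_variant_still_anchors(self, mirna, usp29):
        ggo = next(f for f in usp29.fragments if f.species == "Ggo")
        assert ggo.ratio == pytest.approx(100 * 55 / 57, abs=0.01)

    def test_random_fragment_excluded(self, mirna):
        rng = np.random.default_rng(5)
        junk = "".join(rng.choice(list("ACGU"), size=40))
        fam = OrthologFamily(
            "X",
            (
                FamilyMember("Hsa", "AAAAA" + PERFECT_SITE_RNA + "CCCCC"),
                FamilyMember("Zzz", junk),
            ),
        )
        aligned = anchor_align(fam, mirna)
        assert [f.species for f in aligned.fragments] == ["Hsa"]
        assert aligned.excluded[0][0] == "Zzz"

    def test_two_identical_fragments_zero_substitutions(self, mirna):
        frag = "GCAUGCU" + PERFECT_SITE_RNA + "ACUUUGG"
        fam = OrthologFamily("Y", (FamilyMember("Hsa", frag), FamilyMember("Ptr", frag)))
        prof = substitution_profile(anchor_align(fam, mirna), "Hsa")
        assert prof.n_in_site == 0 and prof.n_flank == 0


class TestSubstitutionProfile:
    def test_usp29_family_variants(self, usp29):
        prof = substitution_profile(usp29, "Hsa")
        # in-site changes only in Ggo (site position 17) and Rro (18)
        assert prof.in_site == {17: 1, 18: 1}
        assert [c for c, _, _ in prof.per_member["Ggo"]] == [17]
        assert [c for c, _, _ in prof.per_member["Rro"]] == [18]
        # Can differs only in the downstream flank (second flank column)
        can = prof.per_member["Can"]
        assert len(can) == 1 and can[0][0] == 24  # site_len 22 + 2
        assert prof.per_member.get("Pab", []) == []
        assert prof.per_member.get("Mle", []) == []

    def test_symmetry_between_two_members(self, mirna):
        fam = OrthologFamily(
            "USP29",
            (
                FamilyMember("Hsa", "CUGGCCA" + PERFECT_SITE_RNA + "ACUUUGG"),
                FamilyMember("Ggo", "CUGGCCA" + "GGCUCAUGCCUGUAAUUCCAGC" + "ACUUUGG"),
            ),
        )
        aligned = anchor_align(fam, mirna)
        p1 = substitution_profile(aligned, "Hsa")
        p2 = substitution_profile(aligned, "Ggo")
        assert set(p1.in_site) == set(p2.in_site) == {17}

    def test_missing_reference(self, usp29):
        with pytest.raises(ValueError, match="reference"):
            substitution_profile(usp29, "Xxx")


class TestFrequencyMatrix:
    def test_pooled_3utr_panel_site_consensus_is_perfect_site(self, mirna):
        aligned = [anchor_align(f, mirna) for f in fragment_families(GROUP_UTR3).values()]
        matrix = frequency_matrix(aligned)
        assert matrix.site_consensus(dna=True) == PERFECT_SITE_DNA
        assert matrix.site_consensus() == PERFECT_SITE_RNA

    def test_column_sums_equal_coverage(self, mirna):
        aligned = [anchor_align(f, mirna) for f in fragment_families(GROUP_UTR3).values()]
        matrix = frequency_matrix(aligned)
        n_members = sum(len(a.fragments) for a in aligned)
        # every member covers every site column
        assert (matrix.counts.loc[1:22].sum(axis=1) == n_members).all()
        freqs = matrix.frequencies.loc[1:22].sum(axis=1)
        assert np.allclose(freqs, 1.0)

    def test_single_member_frequencies(self, mirna):
        fam = OrthologFamily(
            "Z",
            (
                FamilyMember("Hsa", "AA" + PERFECT_SITE_RNA + "GG"),
                FamilyMember("Ptr", "AA" + PERFECT_SITE_RNA + "GG"),
            ),
        )
        matrix = frequency_matrix([anchor_align(fam, mirna)])
        assert matrix.consensus([-2, -1]) == "AA"
        assert (matrix.frequencies.loc[1:22].max(axis=1) == 1.0).all()

    def test_even_split_gives_iupac_code(self, mirna):
        fam = OrthologFamily(
            "Z",
            (
                FamilyMember("Hsa", "A" + PERFECT_SITE_RNA),
                FamilyMember("Ptr", "G" + PERFECT_SITE_RNA),
            ),
        )
        matrix = frequency_matrix([anchor_align(fam, mirna)])
        assert matrix.consensus([-1]) == "R"  # A/G tie


def test_group_genes_quartiles():
    genes = [f"G{i:02d}" for i in range(10)]
    groups = group_genes(genes, 4)
    assert [len(g) for g in groups] == [3, 3, 2, 2]
    assert sum(groups, []) == sorted(genes)


def test_grouped_frequency_matrices(mirna):
    aligned = {g: anchor_align(f, mirna) for g, f in fragment_families(GROUP_UTR3).items()}
    groups = grouped_frequency_matrices(aligned, n_groups=2)
    assert len(groups) == 2
    for genes, matrix in groups:
        assert matrix.site_consensus(dna=True) == PERFECT_SITE_DNA


def test_family_table_round_trip(tmp_path, mirna):
    family, _ = make_family("FAM1", 5, f_flank=0.1, s_site=0.0, seed=3)
    path = tmp_path / "families.tsv"
    rows = ["gene\tspecies\tfragment\tposition"]
    rows += [f"{family.gene}\t{m.species}\t{m.fragment}\t{m.declared_offset}" for m in family.members]
    path.write_text("\n".join(rows) + "\n")
    families = read_family_table(path)
    assert set(families) == {"FAM1"}
    assert [m.species for m in families["FAM1"].members] == [m.species for m in family.members]
    aligned = anchor_align(families["FAM1"], mirna)
    assert all(f.site_start == 10 for f in aligned.fragments)


def test_variation_outputs(tmp_path, mirna):
    aligned = [anchor_align(f, mirna) for f in fragment_families(GROUP_UTR5).values()]
    matrix = frequency_matrix(aligned)
    write_variation_tsv(tmp_path / "var.tsv", matrix)
    write_logo_matrix(tmp_path / "logo.tsv", matrix)
    import pandas as pd

    var = pd.read_csv(tmp_path / "var.tsv", sep="\t")
    assert list(var.columns) == ["column", "in_site", "A", "C", "G", "U", "consensus"]
    assert var[var.in_site].shape[0] == 22
    logo = pd.read_csv(tmp_path / "logo.tsv", sep="\t", index_col="position")
    assert np.allclose(logo.loc[1:22].sum(axis=1), 1.0, atol=1e-3)


def test_family_needs_two_members():
    with pytest.raises(ValueError, match=">= 2"):
        OrthologFamily("solo", (FamilyMember("Hsa", "ACGU" * 10),))
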