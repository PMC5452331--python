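"""Ortholog site conservation: anchor alignment, substitution profiles and
position-frequency matrices.

Fragments from orthologous transcripts are aligned by anchoring each
member's best-scoring window of the miRNA site at a common set of columns:
site columns run 1..L (L = miRNA length), upstream flank columns are
negative (-1 adjacent to the site), and downstream flank columns continue
at L+1, L+2, ... No gapped alignment is attempted — published fragment
panels for this site family are gap-free, and the anchor plus fixed flank
columns suffices.

A member whose best window scores below the anchor threshold (default 80%
dG/dGm — comfortably above the ~30% expected for a random 22-mer, below
the ~95% of the printed one- and two-substitution ortholog variants) is
excluded with a logged reason.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .energy import DEFAULT_SCHEME, EnergyScheme, max_hydrogen_bonds
from .scanner import window_bond_counts
from .seqcore import MatureMiRNA, normalize

logger = logging.getLogger(__name__)

RNA_LETTERS = ("A", "C", "G", "U")

# IUPAC ambiguity codes over the RNA alphabet, for consensus ties.
_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("U"): "U",
    frozenset("AG"): "R",
    frozenset("CU"): "Y",
    frozenset("CG"): "S",
    frozenset("AU"): "W",
    frozenset("GU"): "K",
    frozenset("AC"): "M",
    frozenset("CGU"): "B",
    frozenset("AGU"): "D",
    frozenset("ACU"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGU"): "N",
}


@dataclasses.dataclass(frozen=True)
class FamilyMember:
    species: str
    fragment: str  # normalized RNA
    declared_offset: int | None = None  # 1-based site start within fragment, if known

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment", normalize(self.fragment, "rna"))


@dataclasses.dataclass(frozen=True)
class OrthologFamily:
    """Per-species fragments around a site in one gene's orthologs."""

    gene: str
    members: tuple[FamilyMember, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) < 2:
            raise ValueError(f"family {self.gene!r} needs >= 2 members")


@dataclasses.dataclass(frozen=True)
class AlignedFragment:
    species: str
    fragment: str
    site_start: int  # 0-based index of the anchored site within the fragment
    ratio: float

    def columns(self, site_len: int) -> dict[int, str]:
        """Map alignment column -> base for this member."""
        out = {}
        for j, base in enumerate(self.fragment):
            rel = j - self.site_start
            col = rel if rel < 0 else rel + 1
            out[col] = base
        return out


@dataclasses.dataclass(frozen=True)
class AlignedFamily:
    gene: str
    site_len: int
    fragments: tuple[AlignedFragment, ...]
    excluded: tuple[tuple[str, float], ...] = ()


@dataclasses.dataclass(frozen=True)
class SubstitutionProfile:
    """Per-column mismatch counts against a reference member."""

    reference: str
    in_site: dict[int, int]
    flank: dict[int, int]
    per_member: dict[str, list[tuple[int, str, str]]]  # species -> (col, ref, alt)

    @property
    def n_in_site(self) -> int:
        return sum(self.in_site.values())

    @property
    def n_flank(self) -> int:
        return sum(self.flank.values())


@dataclasses.dataclass(frozen=True)
class VariationMatrix:
    """Per-column nucleotide occurrence counts over pooled aligned fragments."""

    counts: pd.DataFrame  # index: columns; columns: A,C,G,U
    site_len: int

    @property
    def in_site_mask(self) -> pd.Series:
        idx = self.counts.index
        return pd.Series((idx >= 1) & (idx <= self.site_len), index=idx)

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0)

    def consensus(self, columns: Iterable[int] | None = None, dna: bool = False) -> str:
        """Per-column majority base; exact ties become IUPAC ambiguity codes."""
        cols = list(columns) if columns is not None else list(self.counts.index)
        letters = []
        for col in cols:
            row = self.counts.loc[col]
            top = row.max()
            if top == 0:
                letters.append("N")
                continue
            winners = frozenset(b for b in RNA_LETTERS if row[b] == top)
            letters.append(_IUPAC[winners])
        out = "".join(letters)
        return out.replace("U", "T") if dna else out

    def site_consensus(self, dna: bool = False) -> str:
        return self.consensus(range(1, self.site_len + 1), dna=dna)


def anchor_align(
    family: OrthologFamily,
    mirna: MatureMiRNA,
    scheme: EnergyScheme = DEFAULT_SCHEME,
    anchor_threshold: float = 80.0,
) -> AlignedFamily:
    """Anchor each member's best-scoring window at site columns 1..L.

    Ties go to the leftmost window; members whose best ratio falls below
    the anchor threshold are excluded (logged), never silently dropped.
    """
    max_bonds = max_hydrogen_bonds(mirna, scheme)
    kept, excluded = [], []
    for m in family.members:
        if len(m.fragment) < mirna.length:
            logger.warning("family %s member %s: fragment shorter than miRNA; excluded",
                           family.gene, m.species)
            excluded.append((m.species, 0.0))
            continue
        bonds = window_bond_counts(mirna, m.fragment, scheme)
        best = int(np.argmax(bonds))  # argmax is leftmost on ties
        ratio = 100.0 * bonds[best] / max_bonds
        if ratio < anchor_threshold:
            logger.warning(
                "family %s member %s: best window ratio %.1f%% below anchor "
                "threshold %.1f%%; excluded",
                family.gene, m.species, ratio, anchor_threshold,
            )
            excluded.append((m.species, float(ratio)))
            continue
        kept.append(AlignedFragment(m.species, m.fragment, best, float(ratio)))
    return AlignedFamily(
        gene=family.gene,
        site_len=mirna.length,
        fragments=tuple(kept),
        excluded=tuple(excluded),
    )


def substitution_profile(aligned: AlignedFamily, reference_species: str) -> SubstitutionProfile:
    """Per-column mismatches of every non-reference member vs the reference.

    Only columns covered by both the reference and the member are compared,
    so flank-length differences do not count as substitutions.
    """
    ref = next((f for f in aligned.fragments if f.species == reference_species), None)
    if ref is None:
        raise ValueError(f"reference species {reference_species!r} not in aligned family")
    ref_cols = ref.columns(aligned.site_len)
    in_site: dict[int, int] = {}
    flank: dict[int, int] = {}
    per_member: dict[str, list[tuple[int, str, str]]] = {}
    for frag in aligned.fragments:
        if frag is ref:
            continue
        diffs = []
        for col, base in frag.columns(aligned.site_len).items():
            if col not in ref_cols or base == ref_cols[col]:
                continue
            diffs.append((col, ref_cols[col], base))
            if 1 <= col <= aligned.site_len:
                in_site[col] = in_site.get(col, 0) + 1
            else:
                flank[col] = flank.get(col, 0) + 1
        per_member.setdefault(frag.species, []).extend(diffs)
    return SubstitutionProfile(
        reference=reference_species,
        in_site=dict(sorted(in_site.items())),
        flank=dict(sorted(flank.items())),
        per_member=per_member,
    )


def frequency_matrix(aligned_sets: Sequence[AlignedFamily]) -> VariationMatrix:
    """Pool aligned fragments into per-column nucleotide counts.

    Column count sums equal the number of members with coverage at that
    column; N bases are not counted toward any letter.
    """
    if not aligned_sets:
        raise ValueError("frequency_matrix needs at least one aligned family")
    site_len = aligned_sets[0].site_len
    tallies: dict[int, dict[str, int]] = {}
    for fam in aligned_sets:
        if fam.site_len != site_len:
            raise ValueError("aligned families have inconsistent site lengths")
        for frag in fam.fragments:
            for col, base in frag.columns(site_len).items():
                if base not in RNA_LETTERS:
                    continue
                row = tallies.setdefault(col, {b: 0 for b in RNA_LETTERS})
                row[base] += 1
    counts = pd.DataFrame.from_dict(tallies, orient="index").sort_index()
    counts = counts.reindex(columns=list(RNA_LETTERS), fill_value=0).astype(int)
    return VariationMatrix(counts=counts, site_len=site_len)


def group_genes(genes: Iterable[str], n_groups: int = 4) -> list[list[str]]:
    """Lexicographically sorted genes split into near-equal contiguous groups."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    ordered = sorted(set(genes))
    return [list(chunk) for chunk in np.array_split(ordered, n_groups)]


def grouped_frequency_matrices(
    aligned_by_gene: dict[str, AlignedFamily], n_groups: int = 4
) -> list[tuple[list[str], VariationMatrix]]:
    """Group-wise position-frequency matrices over gene families.

    Genes are sorted lexicographically and split into ``n_groups`` near-equal
    groups (the grouping convention for the cohort-wide conservation
    display); each group's families are pooled into one matrix. Empty groups
    are skipped.
    """
    out = []
    for group in group_genes(aligned_by_gene, n_groups):
        fams = [aligned_by_gene[g] for g in group]
        if fams:
            out.append((group, frequency_matrix(fams)))
    return out


def read_family_table(path: str | Path) -> dict[str, OrthologFamily]:
    """Family input TSV: columns gene, species, fragment[, position]."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "species", "fragment"}
    if missing := required - set(table.columns):
        raise ValueError(f"family table {path} lacks columns {sorted(missing)}")
    families: dict[str, list[FamilyMember]] = {}
    for row in table.itertuples(index=False):
        offset = None
        if "position" in table.columns and pd.notna(getattr(row, "position", None)):
            offset = int(row.position)
        families.setdefault(row.gene, []).append(
            FamilyMember(species=row.species, fragment=row.fragment, declared_offset=offset)
        )
    return {g: OrthologFamily(gene=g, members=tuple(ms)) for g, ms in families.items()}


def write_variation_tsv(path: str | Path, matrix: VariationMatrix) -> None:
    """Variation TSV: column, in_site, A/C/G/U counts, consensus letter."""
    freq = matrix.counts
    consensus = matrix.consensus()
    rows = []
    for i, col in enumerate(freq.index):
        rows.append(
            {
                "column": col,
                "in_site": bool(1 <= col <= matrix.site_len),
                "A": freq.loc[col, "A"],
                "C": freq.loc[col, "C"],
                "G": freq.loc[col, "G"],
                "U": freq.loc[col, "U"],
                "consensus": consensus[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_logo_matrix(path: str | Path, matrix: VariationMatrix) -> None:
    """Logo-ready matrix: one row per column, A/C/G/U frequencies summing to 1."""
    matrix.frequencies.rename_axis("position").to_csv(path, sep="\t", float_format="%.4f")
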