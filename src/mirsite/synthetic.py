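"""Synthetic transcripts, cohorts and ortholog families with known ground truth.

Backgrounds are i.i.d. uniform over {A,C,G,U}; planted sites are written at
exact, recorded positions. Any accidental background occurrence of the
perfect site is re-randomized away, so the plant manifest is the complete
truth about complete-complementarity hits — a deliberate departure from
pure i.i.d. sampling that makes manifests exact oracles for the scanner.

Everything is driven by a seedable PRNG; the same seed reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .conservation import FamilyMember, OrthologFamily
from .seqcore import RNA_BASES, MatureMiRNA, TranscriptRecord, write_fasta, write_transcript_table
from .datasets import mir619_5p

_BASES = np.array(list("ACGU"))

#: Species codes used for simulated ortholog families (primates + other
#: mammals typical of published ortholog panels).
DEFAULT_SPECIES = (
    "Hsa", "Ptr", "Ppa", "Ggo", "Pab", "Nle", "Mmu", "Mfa", "Mne", "Mle",
    "Can", "Rro", "Csa", "Cja", "Pan", "Eca", "Oar", "Bmu", "Cdr", "Cfe",
)


@dataclasses.dataclass(frozen=True)
class Plant:
    """One site to embed: 1-based transcript position, optional substitutions.

    ``substitutions`` maps 1-based positions WITHIN the site to replacement
    RNA bases; empty means an exact (complete-complementarity) plant.
    """

    position: int
    substitutions: dict[int, str] = dataclasses.field(default_factory=dict)

    @property
    def is_exact(self) -> bool:
        return not self.substitutions


@dataclasses.dataclass(frozen=True)
class PlantRecord:
    transcript_id: str
    position: int
    region: str
    variant: str  # "exact" or "sub@p1,p2,..."
    is_exact: bool


@dataclasses.dataclass
class PlantManifest:
    """Ground truth for a synthetic dataset: what was planted where."""

    seed: int
    plants: list[PlantRecord] = dataclasses.field(default_factory=list)
    family_params: dict = dataclasses.field(default_factory=dict)

    def exact_positions(self, transcript_id: str) -> list[int]:
        return sorted(
            p.position
            for p in self.plants
            if p.transcript_id == transcript_id and p.is_exact
        )

    def region_tallies(self) -> dict[str, int]:
        out = {"5UTR": 0, "CDS": 0, "3UTR": 0}
        for p in self.plants:
            if p.is_exact:
                out[p.region] += 1
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "plants": [dataclasses.asdict(p) for p in self.plants],
            "family_params": self.family_params,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _scrub_accidental_sites(
    seq: list[str],
    site: str,
    protected: set[int],
    allowed_starts: set[int],
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> None:
    """Re-randomize background bases until the perfect site occurs only at
    the planted starts. ``protected`` holds 0-based indices inside plant
    footprints that must not be touched."""
    L = len(site)
    text = "".join(seq)
    for _ in range(max_rounds):
        accidental = []
        start = text.find(site)
        while start != -1:
            if start not in allowed_starts:
                accidental.append(start)
            start = text.find(site, start + 1)
        if not accidental:
            return
        for occ in accidental:
            free = [i for i in range(occ, occ + L) if i not in protected]
            if not free:
                raise RuntimeError("accidental site fully covered by plants; cannot scrub")
            i = int(rng.choice(free))
            old = seq[i]
            choices = [b for b in "ACGU" if b != old]
            seq[i] = str(rng.choice(choices))
        text = "".join(seq)
    raise RuntimeError("failed to scrub accidental sites")


def make_transcript(
    utr5_len: int,
    cds_len: int,
    utr3_len: int,
    plants: list[Plant],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mirna: MatureMiRNA | None = None,
    transcript_id: str = "SYN1",
    gene: str = "SYNGENE",
    species: str = "Hsa",
) -> tuple[TranscriptRecord, PlantManifest]:
    """A uniform-background transcript with sites planted at exact positions.

    Plants must fit wholly inside a single region and must not overlap one
    another. The returned manifest is the complete truth about exact-site
    occurrences (accidental occurrences are scrubbed).
    """
    if cds_len % 3 != 0:
        raise ValueError(f"cds_len {cds_len} not divisible by 3")
    if cds_len < 3:
        raise ValueError("cds_len must be >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    mirna = mirna or mir619_5p()
    site = mirna.perfect_site()
    L = mirna.length
    total = utr5_len + cds_len + utr3_len
    cds_start, cds_end = utr5_len + 1, utr5_len + cds_len

    def region_of(pos: int) -> str:
        if pos < cds_start:
            return "5UTR"
        return "CDS" if pos <= cds_end else "3UTR"

    # validate plants: in bounds, inside one region, non-overlapping
    spans = []
    for p in sorted(plants, key=lambda p: p.position):
        if not 1 <= p.position <= total - L + 1:
            raise ValueError(f"plant at {p.position} outside transcript of length {total}")
        if region_of(p.position) != region_of(p.position + L - 1):
            raise ValueError(f"plant at {p.position} crosses a region boundary")
        for sp, _ in spans:
            if p.position < sp + L and sp < p.position + L:
                raise ValueError(f"overlapping plants at {sp} and {p.position}")
        for k, b in p.substitutions.items():
            if not 1 <= k <= L:
                raise ValueError(f"substitution position {k} outside site 1..{L}")
            if b not in RNA_BASES:
                raise ValueError(f"substitution base {b!r} not an RNA base")
        spans.append((p.position, p))

    seq = list(_random_seq(rng, total))
    protected: set[int] = set()
    allowed_starts: set[int] = set()
    for pos, p in spans:
        planted = list(site)
        for k, b in p.substitutions.items():
            planted[k - 1] = b
        seq[pos - 1 : pos - 1 + L] = planted
        protected.update(range(pos - 1, pos - 1 + L))
        if p.is_exact:
            allowed_starts.add(pos - 1)
    _scrub_accidental_sites(seq, site, protected, allowed_starts, rng)

    record = TranscriptRecord(
        transcript_id=transcript_id,
        gene=gene,
        species=species,
        sequence="".join(seq),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    manifest = PlantManifest(seed=-1 if seed is None else seed)
    for pos, p in spans:
        variant = "exact" if p.is_exact else "sub@" + ",".join(map(str, sorted(p.substitutions)))
        manifest.plants.append(
            PlantRecord(
                transcript_id=transcript_id,
                position=pos,
                region=region_of(pos),
                variant=variant,
                is_exact=p.is_exact,
            )
        )
    return record, manifest


def _positions_in_region(
    rng: np.random.Generator, lo: int, hi: int, n: int, L: int, taken: list[int]
) -> list[int]:
    """n non-overlapping 1-based plant positions with sites inside [lo, hi]."""
    out = []
    for _ in range(10_000):
        if len(out) == n:
            break
        cand = int(rng.integers(lo, hi - L + 2))
        if all(abs(cand - t) >= L for t in taken + out):
            out.append(cand)
    if len(out) < n:
        raise RuntimeError(f"could not place {n} sites in region [{lo},{hi}]")
    return out


def make_cohort(
    multiplicity: dict[int, int],
    seed: int,
    utr5_len: int = 150,
    cds_len: int = 300,
    utr3_len: int = 600,
    region_weights: dict[str, float] | None = None,
    mirna: MatureMiRNA | None = None,
) -> tuple[list[TranscriptRecord], PlantManifest]:
    """A cohort of one-transcript genes with planted site multiplicities.

    ``multiplicity`` maps sites-per-gene -> number of genes (e.g. {4: 27,
    5: 7}). Site regions are drawn from ``region_weights`` (default: all
    3'UTR, the dominant localization for this site family).
    """
    rng = np.random.default_rng(seed)
    mirna = mirna or mir619_5p()
    L = mirna.length
    weights = region_weights or {"3UTR": 1.0}
    regions = sorted(weights)
    probs = np.array([weights[r] for r in regions], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("region weights must sum to > 0")
    probs /= probs.sum()
    bounds = {
        "5UTR": (1, utr5_len),
        "CDS": (utr5_len + 1, utr5_len + cds_len),
        "3UTR": (utr5_len + cds_len + 1, utr5_len + cds_len + utr3_len),
    }
    for r in regions:
        lo, hi = bounds[r]
        if hi - lo + 1 < L:
            raise ValueError(f"region {r} too short ({hi - lo + 1} nt) for a {L}-nt site")

    transcripts: list[TranscriptRecord] = []
    manifest = PlantManifest(seed=seed)
    gene_idx = 0
    for n_sites in sorted(multiplicity):
        for _ in range(multiplicity[n_sites]):
            gene_idx += 1
            gene = f"SYN{gene_idx:04d}"
            chosen = rng.choice(len(regions), size=n_sites, p=probs)
            taken: list[int] = []
            plants = []
            for ri in chosen:
                lo, hi = bounds[regions[int(ri)]]
                pos = _positions_in_region(rng, lo, hi, 1, L, taken)[0]
                taken.append(pos)
                plants.append(Plant(position=pos))
            rec, man = make_transcript(
                utr5_len,
                cds_len,
                utr3_len,
                plants,
                rng=rng,
                mirna=mirna,
                transcript_id=gene,
                gene=gene,
            )
            transcripts.append(rec)
            manifest.plants.extend(man.plants)
    return transcripts, manifest


def write_cohort(
    out_dir: str | Path, transcripts: list[TranscriptRecord], manifest: PlantManifest
) -> dict[str, Path]:
    """Write the FASTA/annotation-TSV/manifest-JSON triple the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "cohort.fasta",
        "annotations": out / "cohort.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(paths["fasta"], [(t.transcript_id, t.sequence) for t in transcripts])
    write_transcript_table(paths["annotations"], transcripts)
    manifest.to_json(paths["manifest"])
    return paths


def make_family(
    gene: str,
    n_species: int,
    f_flank: float,
    s_site: float,
    seed: int,
    flank_len: int = 10,
    mirna: MatureMiRNA | None = None,
) -> tuple[OrthologFamily, PlantManifest]:
    """A simulated ortholog family around one site.

    The reference member (first species) carries the exact site with random
    flanks; every other member is the reference mutated position-by-position
    i.i.d. — rate ``s_site`` inside the 22-nt site, ``f_flank`` in the
    flanks — emulating the slower in-site substitution of a conserved
    binding site. Requires 0 <= s_site <= f_flank <= 0.5.
    """
    if not 0 <= s_site <= f_flank <= 0.5:
        raise ValueError("need 0 <= s_site <= f_flank <= 0.5")
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    mirna = mirna or mir619_5p()
    site = mirna.perfect_site()
    L = mirna.length
    species = [DEFAULT_SPECIES[i % len(DEFAULT_SPECIES)] + ("" if i < len(DEFAULT_SPECIES) else str(i)) for i in range(n_species)]
    up = "".join(_random_seq(rng, flank_len))
    down = "".join(_random_seq(rng, flank_len))
    reference = up + site + down
    total = len(reference)
    in_site = np.zeros(total, dtype=bool)
    in_site[flank_len : flank_len + L] = True
    rates = np.where(in_site, s_site, f_flank)

    members = [FamilyMember(species=species[0], fragment=reference, declared_offset=flank_len + 1)]
    sub_log = {}
    for sp in species[1:]:
        mutate = rng.random(total) < rates
        frag = list(reference)
        cols = []
        for i in np.nonzero(mutate)[0]:
            frag[i] = str(rng.choice([b for b in "ACGU" if b != reference[i]]))
            cols.append(int(i))
        members.append(FamilyMember(species=sp, fragment="".join(frag), declared_offset=flank_len + 1))
        sub_log[sp] = cols
    family = OrthologFamily(gene=gene, members=tuple(members))
    manifest = PlantManifest(
        seed=seed,
        family_params={
            "gene": gene,
            "f_flank": f_flank,
            "s_site": s_site,
            "flank_len": flank_len,
            "species": species,
            "substituted_indices": sub_log,  # 0-based indices into the fragment
        },
    )
    return family, manifest
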