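# Methods

## Scope and coordinate conventions

`mirsite` scans mRNAs for binding sites of a single mature miRNA, scores
each candidate by a hydrogen-bond hybridization energy, localizes hits to
5′UTR/CDS/3′UTR, translates CDS-overlapping sites in all reading frames,
and profiles site conservation across ortholog fragment panels. All
coordinates are 1-based, inclusive, on the mRNA read 5′→3′; BED export
converts to 0-based half-open and says so in its header. The canonical
internal alphabet is RNA; DNA input is converted on read (the duplex is an
RNA-level object), and any letter outside {A,C,G,U,T} collapses to the
single ambiguity class N.

## Duplex energy model

A site is a contiguous window of miRNA length L (22 for the bundled
query); pairing is antiparallel with no gaps or bulges. Each pair
contributes a hydrogen-bond count: G:C = 3, A:U = 2, G:U wobble = 1,
A:C = 0, all else 0; N never pairs. ΔG = −e_bond · Σ bonds, with
e_bond = 121/57 ≈ 2.1228 kJ/mole per bond, chosen so the perfect duplex of
the bundled miR-619-5p query (13 G:C + 9 A:U = 57 bonds) scores
−121 kJ/mole, the reference energy for this site family. The acceptance
statistic ΔG/ΔGm (percent of the perfect-complement energy) cancels
e_bond, so the headline 100% criterion is parameterization-independent;
the per-pair weights and e_bond are nevertheless configurable (YAML) for
reuse, subject to gu ≤ 2 so that no substitution of a perfect site can
keep the ratio at 100%. Whether noncanonical A:C pairs should carry weight
is genuinely open in this model family; the default is 0, which is
irrelevant at the 100% threshold because any weight below the
corresponding Watson–Crick weight keeps the perfect site strictly optimal.

Nearest-neighbour (stacking) thermodynamics and secondary-structure
energetics are deliberately out of scope: the criterion implemented is
whole-duplex complementarity, not folding stability.

## Scanning and localization

Every window is scored (vectorized as a 22×5 bond-profile lookup summed
over window offsets) and windows with ratio ≥ threshold are reported,
ordered by start; overlapping hits are all kept, since no suppression rule
is defined for this criterion and at 100% a non-self-complementary 22-mer
cannot overlap itself. The default threshold is 100%. At that default the
scan is provably identical to exact substring search for the miRNA's
reverse complement, and the test suite enforces this equivalence against a
naive search oracle. A hit is assigned to the region containing its START
position; junction-spanning hits are flagged (`boundary_flag`) rather than
split, a deterministic convention chosen because single-region assignment
is ambiguous for spanning hits. Transcripts shorter than the miRNA yield
an empty hit list with a logged warning.

## Reading-frame peptides

Frames are indexed 0/1/2 relative to the site's first nucleotide (codon
starts at site positions f+1, f+4, …). Edge codons are completed with real
transcript nucleotides — never padding — because site-encoded residues can
depend on flanking bases (the canonical example: a W whose codon begins
one base upstream of the site). The frame matching the transcript's CDS
phasing, `(cds_start − site_start) mod 3` mapped to the site-relative
index, is marked annotated. Stop codons are emitted as `*` and translation
continues: the presence of a stop in a frame is the reported feature.
`peptide_context` returns the annotated-frame residues of every codon
overlapping the site (core) with up to 7 flanking residues each side
(matching the published display width), truncated at CDS ends. Published
panels are typographically inconsistent about whether an edge partial
codon belongs to the bold core; the symmetric all-overlapping-codons rule
is used here, and the concatenated upstream+core+downstream string equals
the published 21-residue context exactly. Only the standard genetic code
is supported; codons containing N translate to X.

## Conservation

Ortholog fragments for a gene are aligned by anchoring each member's
best-scoring window at site columns 1..22 (leftmost on ties); upstream
flank columns are negative, downstream columns continue at 23+. Members
whose best ratio falls below the anchor threshold are excluded with a
logged reason. The default anchor threshold of 80% sits between the ~30%
bond fraction expected of a random 22-mer under this scheme and the
≥94.7% of the published one- and two-substitution ortholog variants, so it
rejects junk without losing real variants. No gapped alignment is
performed; the published fragment panels are gap-free and the anchor
suffices.

Substitution profiles count per-column mismatches of each member against a
chosen reference, split in-site versus flank, over columns covered by
both. Frequency matrices pool aligned fragments into per-column A/C/G/U
counts (N uncounted); consensus is the per-column majority with exact ties
rendered as IUPAC ambiguity codes. For cohort-wide displays, genes are
sorted lexicographically and split into a configurable number of
near-equal groups (default 4) — an explicit convention for grouping, one
matrix per group.

## Synthetic data generator

The generator emulates the study inputs: mRNAs with 5′UTR/CDS/3′UTR
structure carrying planted exact or substituted sites, cohorts with
specified per-gene site multiplicities and region weights, and ortholog
families in which the in-site substitution rate s is lower than the flank
rate f (members mutated i.i.d. per position from an exact-site reference;
0 ≤ s ≤ f ≤ 0.5). Backgrounds are i.i.d. uniform over {A,C,G,U} — no
codon-usage, dinucleotide or phylogenetic correlation structure — and any
accidental background occurrence of the perfect site is re-randomized
away, a deliberate departure from pure i.i.d. sampling that makes the
plant manifest the complete truth for complete-complementarity scans.
Consequently, passing tests demonstrate correctness of scanning, tallying
and rate recovery on known ground truth; they do not demonstrate
performance on real transcript composition, splice variants, or
phylogenetically correlated substitution patterns.

Default cohort dimensions (150 nt leader, 300 nt CDS, 600 nt trailer,
sites defaulting to the 3′UTR) reflect the shape of the reference site
family, where the large majority of sites lie in 3′UTRs; family defaults
(10-nt flanks, f = 0.1, s = 0.01, 20 species) mirror the published panel
widths and the strong in-site conservation they display. Test and
validation runs use reduced transcript sizes (tens to a few hundred nt)
chosen as the smallest scales at which every region can still carry a
22-nt site; all generators take explicit seeds and reproduce outputs
byte-for-byte.

## Numerical and degenerate-input choices

Ratios are compared against thresholds with a 1e-9 tolerance to absorb
float division; bond counts themselves are exact integers. Empty leader or
trailer regions are represented as empty intervals and handled throughout.
A complete CDS must have length divisible by 3; records can be marked
incomplete to skip that check. Fewer than three translatable nucleotides
yield an empty peptide rather than an error. The energy ratio of an all-N
window is 0, never a hit at any positive threshold.

## Bundled reference inputs

The package bundles the mature miR-619-5p query and the published
per-species fragment panels around its sites (a 5′UTR panel with 7-nt
flanks and two 3′UTR panels with 10-nt upstream flanks, 54 fragments in
total, spanning USP29, RGS3, ADAM17, ALDH3A2, ARL11, ERBB3, FBLIM1 and
FKBP14 orthologs among others). These drive the fixture tests: every
fragment anchors exactly once at its printed offset; complete-
complementarity rows hit at 100% and substituted rows only at the anchor
threshold; and the pooled 3′UTR panel's in-site consensus equals the
perfect site.

## Known limitations

Genome-wide target counts for the reference miRNA (hundreds of genes,
hundreds of sites) require the full transcriptome download and are not
recomputable from bundled data; the pipeline's correctness at that scale
is instead established by exhaustive manifest-equality and oracle-
equivalence properties on seeded simulations. Reported full-mRNA site
positions for fragment panels are carried as metadata only — positions are
verified within fragments, not against full mRNAs. No statistical test of
conservation significance is computed, and no phylogenetic substitution
model is fitted.
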