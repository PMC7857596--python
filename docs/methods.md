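# Methods

`mesfinder` re-implements, as a tested pipeline over synthetic data, the
comparative-genomics procedure used to discover and classify families of
folate-independent ("core") methionine synthases: MetE-homologous catalytic
domains that transfer a methyl group to homocysteine without the N-terminal
folate-binding domain of MetE.  This note records the models, the parameters
that matter, what the synthetic data do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Homology scoring

Every family threshold is a bit score computed from a Smith-Waterman local
alignment with affine gaps (BLOSUM62; gap open 11, gap extend 1, so a gap of
length n costs 11 + n) converted to bits with the Karlin-Altschul
transformation `bits = (lambda * raw - ln K) / ln 2` using the standard
gapped BLASTp constants lambda = 0.267 nats per score unit and K = 0.041.
This makes the scale *comparable to* — but not identical with — phmmer or
BLASTp bits, which is why every calling threshold is configuration rather
than a constant, and why `references.calibrate_thresholds` exists: it
rescales thresholds so that a given true/decoy set separates.

Conventions, fixed once:

* percent identity = identities / aligned columns *including* gap columns
  (BLAST `pident`), reported rounded to integer percent with the unrounded
  value retained internally;
* `X` scores 0 against every residue;
* alignment tie-breaks are deterministic: among equally scoring end cells the
  smallest subject and then query coordinate wins, and the traceback prefers
  a diagonal step, then a gap in the subject, then a gap in the query.

E-value statistics are deliberately out of scope; where a published
procedure used an E-value fallback (`E < 0.001`), the package uses a
configurable bit floor instead (MetH: 50 bits plus an 80%-of-query coverage
requirement).

## Profile models

Domain calls (MetE N-terminal folate-binding domain, catalytic domain,
DUF1852/MesX, MetF) use position-specific scoring models: per-column log-odds
`log2(((count_r + pc * bg_r) / (n + pc)) / bg_r)` with uniform background
1/20 and pseudocount 1, columns with more than half gaps dropped.  A sequence
is scored by its best ungapped placement (maximum-sum contiguous run per
diagonal); gapped profile alignment is not implemented — family members in
this package's data are substitution-only, so ungapped window scoring is
exact for them, and the locality property (flanking residues never change
the score) is what the split-MetE component logic relies on.

**Trusted cutoffs are leave-one-out, not held-in.**  With mini-profiles
built from 14 training rows, a training member scored against a profile it
helped build is inflated by its own counts (several hundred bits at these
lengths); `min(held-in scores)` would then reject genuine fresh members.
Each cutoff is therefore the minimum over training rows of the row's score
against the profile built from the *other* rows.  Cutoffs still derive from
training data alone at build time.

## Family classification

A protein is scored against every family reference and is eligible for each
family whose bit threshold, length policy, and coverage policy it meets.
Among eligible families, the one with the highest percent identity to its
query wins.  This disambiguation step is load-bearing: all MetE-homologous
families cross-hit each other at the permissive MesC threshold (38 bits),
and full-length MetE proteins hit every core-synthase seed.  MetE itself
additionally requires at least 600 residues (true MetE proteins are
two-domain, ~700+ aa; core synthases are at most ~386 aa), which is what
prevents a split-MetE catalytic subunit from being called MetE.

Core-family calls (MesA/MesB/MesC/MesD) enforce a zinc-site policy: the four
zinc-ligand positions of the family seed are mapped onto the candidate
through the pairwise alignment and classified per site:

| position (MetE numbering) | conserved | compatible | notes |
|---|---|---|---|
| 641 | H | — | histidine required |
| 643 | C | H, Y | both are rare but attested zinc ligands |
| 665 | E | D | aspartate is the MesB-characteristic state |
| 726 | C | N | asparagine possibly compatible |

Any other residue, or an unalignable position, is incompatible; the overall
verdict is *intact* (all conserved), *broken* (any incompatible/unaligned),
else *compatible*.  A hit above threshold with a broken verdict becomes a
non-enzymatic family-like record and is excluded from synthase counts.  The
compatibility table encodes exactly the substitutions with literature
support and nothing more; it is configuration.  Substrate-binding positions
(433, 484, 599; Gln-for-Glu484 counts as compatible) are reported but never
demote a call — in particular, an unalignable position 484 does not break a
MesB verdict, since that region is genuinely variable in MesB.

Split MetE (the two MetE domains as separate proteins) is a genome-level
call: the catalytic component needs >= 200 bits against the catalytic
reference and at most 400 residues (best-scoring candidate per genome; ties
broken by lexicographic protein id), the folate-binding component must match
the N-domain profile at its cutoff, be at most 400 residues, and — when it
also matches the catalytic-domain profile — score strictly higher on the
N-domain model.  The two components are *not* required to be adjacent for
presence; adjacency is evaluated and reported separately.

MesD has two calling presets (`uniprot`: 560 bits, ~72% identity;
`microbesonline`: 390 bits, ~55% identity); which to use is the caller's
choice and the stricter preset is the default.  MetF calling is
reference-based: a hit must cover at least 80% of the MetF query to be
called MetF, otherwise it is at best a partial-domain homolog and not
counted (the known distant homolog that aligns to only the C-terminal part
of the domain probably has another function).

## Genome context

"Adjacent" means consecutive genes (no gene in between) on the same contig
and strand with intergenic gap <= 300 bp — the standard operon heuristic;
the gap is configurable because no published value exists for it.
Co-occurrence is a plain conditional fraction with numerator and denominator
reported alongside (a denominator of zero is "undefined", not an error).
Sole-synthase detection treats MesD/MesX as a functional unit by default
(MesD without MesX does not count as a synthase); a switch disables this.
Genomes with *no* synthase are reported as their own category, since such
genomes are exactly where new families get discovered.

## Alignment, trimming, trees

The multiple aligner is progressive: a UPGMA guide tree from 3-mer set
distances, then profile-profile global alignment (affine gaps, same scoring
scheme) up the tree.  It is deliberately not MUSCLE; determinism is
guaranteed by lexicographic-id tie-breaks, so input order never changes the
result.  The trimmer honors exactly two rules — drop columns with more than
half gaps, keep only runs of surviving columns at least 2 long — and records
column provenance; no conservation-based criteria are applied.

Distances on trimmed alignments are mismatch fractions p over mutually
ungapped columns with the Kimura-style correction `d = -ln(1 - p - p^2/5)`;
p is clamped at 0.85 (just below the correction's singularity at ~0.854)
with the affected pairs flagged.  Trees are Saitou-Nei neighbor joining with
deterministic tie-breaks (smallest joined pair by taxon id), negative branch
lengths clamped to zero with the deficit moved to the sister branch, and a
final three-taxon star resolution.  On additive matrices the tree reproduces
every pairwise path length to machine precision; on real data the stage
claims topology-level grouping only (e.g. separating enzymatic MesB from the
zinc-broken sister clade), not maximum-likelihood branch lengths.

## Gene fitness

Strain fitness is `log2(((n_after + 1) / N_after) / ((n_before + 1) / N_before))`
(pseudocount 1 configurable); gene fitness is the inverse-variance weighted
mean `w_s = 1 / (1/(1+n_before) + 1/(1+n_after))` over strains whose
insertion lies in the central 10-90% of the gene; per-sample values are
centered on the median.  The median was chosen over a mode estimate because
it is deterministic and matches "most genes are neutral" when that is true
of the data — which it is in the simulated experiments (a handful of
methionine-biosynthesis genes against ~190 neutral genes).  Exact numeric
agreement with any published fitness-browser pipeline is not claimed; the
recovery test (below) is the accuracy contract.

## Synthetic data: what it emulates, what it does not

No real protein sequences ship with the package.  The reference set is a
deterministic synthetic construction: a 753-residue MetE-like scaffold with
the canonical functional residues at their E. coli MetE positions (zinc
H641/C643/E665/C726, substrate S433/E484/D599), family seeds derived from
the scaffold's catalytic domain through family-specific homology blocks so
that the scaffold positions map, through actual alignment, onto each seed
exactly where they sit in the corresponding real family (MesA-like
216/218/240/301 and 8/59/174; MesB-like 214/216/235/311 and 15/69/177;
MesC-like 204/206/225/314 and 11/59/166), with family-characteristic site
residues (MesB: Asp for Glu665; MesC: His for Cys643; MesA/MesC: Gln for
Glu484).  Block conservation (0.52) was chosen at construction time so the
four seeds are mutually under 30% alignment identity — genuinely distinct
families — while the site neighborhoods stay alignable.  MetH, MesX,
AcsB/C/D, and MetF seeds are unrelated random sequences.

Generated family members diverge from their seed by substitutions only,
drawn proportional to BLOSUM62-positive exchange scores, with functional
sites pinned (intact) or replaced by one of the attested broken patterns
FSHG/YCDQ/YREQ.  Member identity ranges encode the family definitions:
MesA/MesB/MesC/MetE members at 40-90% identity to seed, MesD at 75-95%
(that family is defined by a ~72%-identity threshold), profile-called
families at 70-95%.  Decoys are composition-matched shuffles of the seeds.
The default panel is 50 genomes across fixed archetypes (MesA methanogens
with/without Wood-Ljungdahl genes, MesB operon genomes, zinc-broken
MesB-like genomes, MesC archaea, MesD/MesX aerobes with/without MetH/MetE,
split-MetE genomes, MetE/MetH genomes, and synthase-free genomes), each with
10 shuffled decoys.

What this means for interpretation: passing tests show the *pipeline logic*
is correct under alignable, substitution-only evolution with honest decoys.
They do not show robustness to indels, domain fusions, compositional bias,
contamination, or fragmented assemblies — all present in real proteomes and
all out of scope here.  BarSeq counts are Poisson draws from exact
relative-abundance dynamics (`abundance_after ∝ abundance_before * 2^f`);
real experiments add PCR/bottleneck overdispersion the generator omits.

## Problem sizes and determinism

The default study sizes are 50 genomes (~650 proteins) for the screen and
1,000 strains (200 genes x 5) at depth 5x10^5 for fitness recovery; both run
in well under a minute of CPU apiece.  All randomness in an analysis flows
from a single integer seed; the packaged reference construction uses its own
frozen internal seed, so references are identical across runs and machines.

## Known limitations

* Profile scoring is ungapped; real insertions in a domain would fragment
  the window score.
* The bit scale differs from phmmer's, so the default thresholds, although
  set to the published values, have a different effective identity meaning;
  recalibration is provided but not automatic.
* The trimmer implements only the two stated rules, not the full Gblocks
  criterion set, and cannot claim column-identical output to it.
* Taxonomy-aware curation (removing contaminant homologs by lineage) is
  represented only as an id-blacklist option; no taxonomy is modeled.
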