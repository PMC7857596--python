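"""Family assignment and split-MetE detection.

A protein is scored against every family reference; among the families whose
bit threshold (and length/coverage policy) it meets, it is assigned the one
to whose query it is most identical.  This disambiguation step matters
because all MetE-homologous families cross-hit each other at permissive
thresholds — a MesA protein will typically also exceed the (very low) MesC
threshold, and full-length MetE proteins hit every core-synthase seed.

Family calls can additionally require an intact-or-compatible zinc site: a
hit above threshold whose zinc ligands are broken is recorded as a
non-enzymatic family-like homolog and excluded from synthase counts, the way
zinc-site-degenerate relatives of a core synthase must be excluded from a
functional repertoire.

Split MetE (the two MetE domains as separate proteins) is detected
per genome: a catalytic component needs >= 200 bits against the catalytic
reference and at most 400 residues, keeping only the best-scoring candidate
per genome; a folate-binding component must match the N-domain profile at
its cutoff, be at most 400 residues, and — if it also matches the catalytic
domain profile — score strictly higher on the N-domain model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .formats import GeneFeature, ProteinRecord
from .pairwise import (
    DEFAULT_SCHEME,
    AlignmentResult,
    ScoringScheme,
    align_local,
    percent_identity,
)
from .profile import ProfileModel, score_profile
from .sites import (
    DEFAULT_ZINC_RULES,
    ReferenceSites,
    SiteVerdict,
    classify_zinc_site,
    map_reference_sites,
)


@dataclass(frozen=True)
class FamilyReference:
    """One family's query (sequence or profile) plus its calling policy."""

    name: str
    threshold: float
    query: ProteinRecord | None = None
    profile: ProfileModel | None = None
    max_length: int | None = None
    min_length: int | None = None
    min_coverage: float | None = None  # fraction of the query that must align
    enforce_zinc: bool = False
    zinc_positions: tuple[int, ...] | None = None  # on the query sequence
    synthase: bool = True  # counts toward the methionine-synthase repertoire

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"{self.name}: threshold must be positive")
        if (self.query is None) == (self.profile is None):
            raise ValueError(f"{self.name}: exactly one of query/profile required")


@dataclass
class FamilyCall:
    protein_id: str
    genome_id: str
    family: str | None
    bit_score: float
    identity: float
    non_enzymatic: bool = False
    family_like: str | None = None  # family of a non-enzymatic homolog
    disambiguated: bool = False
    length_violation: bool = False
    zinc_verdict: SiteVerdict | None = None


@dataclass
class SplitMetECall:
    genome_id: str
    catalytic_id: str | None = None
    catalytic_bits: float = 0.0
    folate_id: str | None = None
    folate_bits: float = 0.0
    adjacent: bool = False

    @property
    def present(self) -> bool:
        return self.catalytic_id is not None and self.folate_id is not None


def _score_against(
    protein: ProteinRecord, ref: FamilyReference, scheme: ScoringScheme
) -> tuple[float, float, AlignmentResult | None]:
    """(bits, identity%, alignment) of a protein against one reference."""
    if ref.profile is not None:
        return score_profile(ref.profile, protein), 0.0, None
    aln = align_local(ref.query, protein, scheme)
    if aln.is_empty:
        return aln.bit_score, 0.0, aln
    return aln.bit_score, percent_identity(aln, rounded=False), aln


def assign_family(
    protein: ProteinRecord,
    references: list[FamilyReference],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    zinc_rules=None,
) -> FamilyCall:
    """Assign a protein to the best-matching family, or to none.

    Eligibility per family: bit score >= threshold, plus any length and
    query-coverage requirements.  Among eligible families the one with the
    highest identity to its query wins (``disambiguated`` is set when more
    than one was eligible).  If the winner enforces the zinc-site policy and
    the mapped zinc ligands are broken, the call becomes a non-enzymatic
    family-like record instead of a synthase call.
    """
    if not references:
        raise ValueError("no family references supplied")
    zinc_rules = DEFAULT_ZINC_RULES if zinc_rules is None else zinc_rules
    eligible: list[tuple[float, float, FamilyReference]] = []
    best_any = (0.0, 0.0)  # (bits, identity) of best hit even if ineligible
    length_violation = False
    for ref in references:
        bits, ident, aln = _score_against(protein, ref, scheme)
        if bits > best_any[0]:
            best_any = (bits, ident)
        if bits < ref.threshold:
            continue
        if ref.max_length is not None and protein.length > ref.max_length:
            length_violation = True
            continue
        if ref.min_length is not None and protein.length < ref.min_length:
            length_violation = True
            continue
        if ref.min_coverage is not None and aln is not None:
            if aln.query_coverage(ref.query.length) < ref.min_coverage:
                continue
        eligible.append((ident, bits, ref))
    if not eligible:
        return FamilyCall(
            protein_id=protein.protein_id,
            genome_id=protein.genome_id,
            family=None,
            bit_score=best_any[0],
            identity=best_any[1],
            length_violation=length_violation,
        )
    eligible.sort(key=lambda t: (-t[0], -t[1], t[2].name))
    ident, bits, winner = eligible[0]
    call = FamilyCall(
        protein_id=protein.protein_id,
        genome_id=protein.genome_id,
        family=winner.name,
        bit_score=bits,
        identity=ident,
        disambiguated=len(eligible) > 1,
        length_violation=length_violation,
    )
    if winner.enforce_zinc and winner.zinc_positions is not None:
        sites = ReferenceSites(
            reference_id=winner.query.protein_id,
            zinc_positions=winner.zinc_positions,
            substrate_positions=(),
        )
        smap = map_reference_sites(winner.query, sites, protein, scheme)
        observed = {
            rule_pos: smap.observed[seed_pos]
            for rule_pos, seed_pos in zip(sorted(zinc_rules), winner.zinc_positions)
        }
        verdict = classify_zinc_site(observed, zinc_rules)
        call.zinc_verdict = verdict
        if verdict.overall == "broken":
            call.non_enzymatic = True
            call.family_like = winner.name
            call.family = None
    return call


def catalytic_candidate_ok(
    bits: float, length: int, threshold: float = 200.0, max_length: int = 400
) -> bool:
    """Catalytic-component rule: enough bits, short enough protein."""
    return bits >= threshold and length <= max_length


def folate_candidate_ok(
    n_bits: float,
    c_bits: float,
    length: int,
    n_cutoff: float,
    c_cutoff: float,
    max_length: int = 400,
) -> bool:
    """Folate-binding-component rule: N-domain model hit, short enough, and
    when the catalytic model also hits, the N-domain score must be strictly
    higher (rejects ambiguous two-domain matchers)."""
    if length > max_length or n_bits < n_cutoff:
        return False
    if c_bits >= c_cutoff and not (n_bits > c_bits):
        return False
    return True


def detect_split_mete(
    proteins: list[ProteinRecord],
    catalytic_reference: ProteinRecord,
    n_domain_profile: ProfileModel,
    c_domain_profile: ProfileModel,
    features: list[GeneFeature] | None = None,
    catalytic_threshold: float = 200.0,
    max_length: int = 400,
    max_intergenic_bp: int = 300,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> SplitMetECall:
    """Detect the two components of a split MetE in one genome's proteome."""
    if not proteins:
        return SplitMetECall(genome_id="")
    genome_id = proteins[0].genome_id
    call = SplitMetECall(genome_id=genome_id)

    catalytic: list[tuple[float, str]] = []
    for p in proteins:
        aln = align_local(catalytic_reference, p, scheme)
        if catalytic_candidate_ok(aln.bit_score, p.length, catalytic_threshold, max_length):
            catalytic.append((aln.bit_score, p.protein_id))
    if catalytic:
        # highest score wins; ties broken by lexicographic protein id
        catalytic.sort(key=lambda t: (-t[0], t[1]))
        call.catalytic_bits, call.catalytic_id = catalytic[0]

    folate: list[tuple[float, str]] = []
    for p in proteins:
        if p.length > max_length:
            continue  # cheap pre-check before scoring two profiles
        n_bits = score_profile(n_domain_profile, p)
        c_bits = score_profile(c_domain_profile, p)
        if folate_candidate_ok(
            n_bits, c_bits, p.length,
            n_domain_profile.trusted_cutoff, c_domain_profile.trusted_cutoff,
            max_length,
        ):
            folate.append((n_bits, p.protein_id))
    if folate:
        folate.sort(key=lambda t: (-t[0], t[1]))
        call.folate_bits, call.folate_id = folate[0]

    if call.present and features is not None:
        call.adjacent = _are_adjacent(
            features, call.catalytic_id, call.folate_id, max_intergenic_bp
        )
    return call


def _are_adjacent(
    features: list[GeneFeature], id_a: str, id_b: str, max_intergenic_bp: int
) -> bool:
    by_id = {f.gene_id: f for f in features}
    fa, fb = by_id.get(id_a), by_id.get(id_b)
    if fa is None or fb is None or fa.contig != fb.contig or fa.genome_id != fb.genome_id:
        return False
    contig = sorted(
        (f for f in features if f.genome_id == fa.genome_id and f.contig == fa.contig),
        key=lambda f: f.start,
    )
    idx = {f.gene_id: k for k, f in enumerate(contig)}
    if abs(idx[id_a] - idx[id_b]) != 1:
        return False
    left, right = sorted((fa, fb), key=lambda f: f.start)
    return right.start - left.end - 1 <= max_intergenic_bp


def call_metH(
    protein: ProteinRecord,
    reference: ProteinRecord,
    profile: ProfileModel | None = None,
    bit_floor: float = 50.0,
    min_coverage: float = 0.8,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> bool:
    """MetH call: profile cutoff met, or a pairwise hit covering >= 80% of
    the reference query at or above the bit floor."""
    if profile is not None and score_profile(profile, protein) >= profile.trusted_cutoff:
        return True
    aln = align_local(reference, protein, scheme)
    return (
        aln.bit_score >= bit_floor
        and aln.query_coverage(reference.length) >= min_coverage
    )


def calls_to_frame(calls: list[FamilyCall]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": c.genome_id,
            "protein_id": c.protein_id,
            "family": c.family or "",
            "bits": round(c.bit_score, 2),
            "identity": round(c.identity, 1),
            "non_enzymatic": c.non_enzymatic,
            "family_like": c.family_like or "",
            "disambiguated": c.disambiguated,
            "length_violation": c.length_violation,
            "zinc_verdict": c.zinc_verdict.overall if c.zinc_verdict else "",
        }
        for c in calls
    ]
    return pd.DataFrame(rows)


def split_calls_to_frame(calls: list[SplitMetECall]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": c.genome_id,
            "present": c.present,
            "catalytic_id": c.catalytic_id or "",
            "catalytic_bits": round(c.catalytic_bits, 2),
            "folate_id": c.folate_id or "",
            "folate_bits": round(c.folate_bits, 2),
            "adjacent": c.adjacent,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
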