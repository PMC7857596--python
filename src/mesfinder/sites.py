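"""Catalytic-residue mapping, zinc-site compatibility, and logo information.

MetE-family methionine synthases activate homocysteine through a zinc
thiolate.  In E. coli MetE numbering the zinc is coordinated by His641,
Cys643, Glu665, and Cys726, and the substrate amino/carboxyl groups are bound
by Ser433, Glu484, and Asp599.  Core methionine synthases keep these residues
(or biochemically defensible substitutes) even at < 30% overall identity, so
mapping them through an alignment and checking compatibility is the main
evidence that a distant homolog is still an enzyme.

The compatibility table encodes exactly the substitutions with literature
support and nothing else:

* position 641: His required;
* position 643: Cys conserved, His or Tyr possibly compatible (both are rare
  but attested zinc ligands);
* position 665: Glu conserved, Asp compatible, Gly incompatible;
* position 726: Cys conserved, Asn possibly compatible.

Any other residue — or an unalignable position — is treated as incompatible
and the overall verdict becomes "broken".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter

from .formats import ProteinRecord
from .pairwise import DEFAULT_SCHEME, AlignmentResult, ScoringScheme, align_local

ZINC_POSITIONS = (641, 643, 665, 726)
SUBSTRATE_POSITIONS = (433, 484, 599)

#: per reference position: (conserved residues, compatible residues)
DEFAULT_ZINC_RULES: dict[int, tuple[frozenset[str], frozenset[str]]] = {
    641: (frozenset("H"), frozenset()),
    643: (frozenset("C"), frozenset("HY")),
    665: (frozenset("E"), frozenset("D")),
    726: (frozenset("C"), frozenset("N")),
}

#: substrate sites report conservation only; Gln for Glu484 keeps the
#: hydrogen bond to the homocysteine amino group and counts as compatible
DEFAULT_SUBSTRATE_RULES: dict[int, tuple[frozenset[str], frozenset[str]]] = {
    433: (frozenset("S"), frozenset("T")),
    484: (frozenset("E"), frozenset("Q")),
    599: (frozenset("D"), frozenset("E")),
}


@dataclass(frozen=True)
class ReferenceSites:
    """Functional positions on a reference protein (1-based)."""

    reference_id: str
    zinc_positions: tuple[int, ...] = ZINC_POSITIONS
    substrate_positions: tuple[int, ...] = SUBSTRATE_POSITIONS

    def __post_init__(self) -> None:
        for group in (self.zinc_positions, self.substrate_positions):
            if list(group) != sorted(set(group)):
                raise ValueError("site positions must be strictly increasing")

    @property
    def all_positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.zinc_positions + self.substrate_positions))


@dataclass
class SiteMap:
    """Where each reference site lands on a candidate (None = unaligned)."""

    candidate_id: str
    mapping: dict[int, int | None]
    observed: dict[int, str | None]


@dataclass(frozen=True)
class SiteVerdict:
    per_site: dict[int, str]  # conserved | compatible | incompatible | unaligned
    overall: str  # intact | compatible | broken


def map_reference_sites(
    reference: ProteinRecord,
    sites: ReferenceSites,
    candidate: ProteinRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    alignment: AlignmentResult | None = None,
) -> SiteMap:
    """Map reference site positions onto a candidate through a local alignment.

    A precomputed reference-vs-candidate alignment may be supplied (e.g. one
    taken from a family MSA); by default a fresh pairwise alignment is used.
    """
    for p in sites.all_positions:
        if p > reference.length:
            raise ValueError(
                f"site position {p} beyond reference length {reference.length}"
            )
    if alignment is None:
        alignment = align_local(reference, candidate, scheme)
    ref_to_cand: dict[int, int] = {
        q: s for q, s in alignment.column_map if q is not None and s is not None
    }
    mapping: dict[int, int | None] = {}
    observed: dict[int, str | None] = {}
    for p in sites.all_positions:
        cpos = ref_to_cand.get(p)
        mapping[p] = cpos
        observed[p] = candidate.sequence[cpos - 1] if cpos is not None else None
    return SiteMap(candidate_id=candidate.protein_id, mapping=mapping, observed=observed)


def classify_zinc_site(
    observed: dict[int, str | None],
    rules: dict[int, tuple[frozenset[str], frozenset[str]]] | None = None,
) -> SiteVerdict:
    """Classify the four zinc-ligand positions.

    ``observed`` maps reference position -> candidate residue, with None for
    an unalignable position.  Overall verdict: intact iff all conserved;
    broken iff any site incompatible or unaligned; otherwise compatible.
    """
    rules = DEFAULT_ZINC_RULES if rules is None else rules
    per_site: dict[int, str] = {}
    for pos, (conserved, compatible) in rules.items():
        res = observed.get(pos)
        if res is None:
            per_site[pos] = "unaligned"
        elif res in conserved:
            per_site[pos] = "conserved"
        elif res in compatible:
            per_site[pos] = "compatible"
        else:
            per_site[pos] = "incompatible"
    if all(v == "conserved" for v in per_site.values()):
        overall = "intact"
    elif any(v in ("incompatible", "unaligned") for v in per_site.values()):
        overall = "broken"
    else:
        overall = "compatible"
    return SiteVerdict(per_site=per_site, overall=overall)


def classify_substrate_site(
    observed: dict[int, str | None],
    rules: dict[int, tuple[frozenset[str], frozenset[str]]] | None = None,
) -> dict[int, str]:
    """Conservation report for the substrate-binding positions.

    Substrate sites never demote a family call on their own; in particular an
    unalignable position 484 (a genuinely variable region in some families)
    is reported but not penalized.
    """
    rules = DEFAULT_SUBSTRATE_RULES if rules is None else rules
    report: dict[int, str] = {}
    for pos, (conserved, compatible) in rules.items():
        res = observed.get(pos)
        if res is None:
            report[pos] = "unaligned"
        elif res in conserved:
            report[pos] = "conserved"
        elif res in compatible:
            report[pos] = "compatible"
        else:
            report[pos] = "divergent"
    return report


def column_information(column: str) -> float:
    """Information content of an alignment column in bits.

    IC = log2(20) - H with H the Shannon entropy of the observed (non-gap)
    residue frequencies; no small-sample correction.
    """
    residues = [c for c in column if c != "-"]
    if not residues:
        raise ValueError("all-gap column has no information content")
    counts = Counter(residues)
    n = len(residues)
    entropy = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return math.log2(20) - entropy


def logo_data(msa_rows: list[str]) -> list[dict[str, float]]:
    """Per-column letter heights (frequency * column information), gaps
    excluded — the numbers behind a sequence logo."""
    out: list[dict[str, float]] = []
    for j in range(len(msa_rows[0])):
        col = "".join(r[j] for r in msa_rows)
        residues = [c for c in col if c != "-"]
        if not residues:
            out.append({})
            continue
        ic = column_information(col)
        n = len(residues)
        out.append({r: ic * c / n for r, c in Counter(residues).items()})
    return out
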