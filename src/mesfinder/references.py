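"""Packaged synthetic reference sequences, profiles, and calling policies.

Real reference accessions for the core-synthase families are not bundled
with this package; instead the reference set is a deterministic synthetic
construction that reproduces the *architecture* of the real proteins:

* a full-length MetE-like scaffold (753 aa) with the canonical functional
  residues at E. coli MetE numbering — zinc ligands H641, C643, E665, C726
  and substrate binders S433, E484, D599;
* one seed per core family (MesA/MesB/MesC/MesD-like), built from the
  scaffold's catalytic domain through family-specific homology blocks so
  that the scaffold's functional positions map onto each seed exactly where
  they sit in the real families (MesA-like: zinc at 216,218,240,301 and
  substrate at 8,59,174; MesB-like: 214,216,235,311 and 15,69,177;
  MesC-like: 204,206,225,314 and 11,59,166), with the family-characteristic
  site residues (MesB carries Asp for Glu665; MesC carries His for Cys643;
  MesA and MesC carry Gln for Glu484);
* a split-MetE catalytic seed and a folate-binding (N-domain) seed derived
  from the scaffold's two domains;
* unrelated random seeds for MetH, MesX (DUF1852), AcsB/AcsC/AcsD, and MetF;
* small training alignments and calibrated profile models for the N-domain,
  catalytic-domain, DUF1852, and MetF families.

Every sequence is reproducible from a fixed internal seed; nothing here is a
real protein, and all identities/thresholds measured against this set are
properties of the synthetic construction.

Bit thresholds default to the published per-family calling thresholds
(MesA 174, MesB 173, MesC 38, MesD 560, split-MetE catalytic 200); because
this package's Smith-Waterman/Karlin-Altschul bit scale is comparable to but
not identical with phmmer's, every threshold is configuration, and
:func:`calibrate_thresholds` can rescale them so that a true/decoy set
separates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import FamilyReference
from .formats import ProteinRecord
from .pairwise import DEFAULT_SCHEME, ScoringScheme
from .profile import ProfileModel, build_profile, calibrate_cutoff
from .sites import ReferenceSites

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(_AA)}
_BUILD_SEED = 7_301_342  # internal; reference construction is frozen

#: E. coli MetE numbering of the functional residues on the scaffold
SCAFFOLD_ZINC = {641: "H", 643: "C", 665: "E", 726: "C"}
SCAFFOLD_SUBSTRATE = {433: "S", 484: "E", 599: "D"}

#: zinc-site patterns of non-enzymatic (Chloroflexales-like) homologs
BROKEN_ZINC_PATTERNS = ("FSHG", "YCDQ", "YREQ")


@dataclass(frozen=True)
class FamilyArchitecture:
    """How one family seed is derived from the scaffold.

    ``blocks`` are (scaffold_start, seed_start, length) homology blocks,
    1-based; ``zinc``/``substrate`` map scaffold position -> seed position;
    ``site_residues`` gives the family-characteristic residue at each seed
    site position.
    """

    name: str
    length: int
    blocks: tuple[tuple[int, int, int], ...]
    zinc: dict[int, int]
    substrate: dict[int, int]
    site_residues: dict[int, str]
    conservation: float = 0.52


ARCHITECTURES: dict[str, FamilyArchitecture] = {
    "MesA": FamilyArchitecture(
        name="MesA",
        length=340,
        blocks=((426, 1, 18), (476, 51, 20), (590, 165, 22),
                (630, 205, 24), (657, 232, 18), (716, 291, 21)),
        zinc={641: 216, 643: 218, 665: 240, 726: 301},
        substrate={433: 8, 484: 59, 599: 174},
        site_residues={216: "H", 218: "C", 240: "E", 301: "C",
                       8: "S", 59: "Q", 174: "D"},
    ),
    "MesB": FamilyArchitecture(
        name="MesB",
        length=350,
        blocks=((425, 7, 21), (475, 60, 21), (588, 166, 25),
                (630, 203, 24), (657, 227, 18), (716, 301, 21)),
        zinc={641: 214, 643: 216, 665: 235, 726: 311},
        substrate={433: 15, 484: 69, 599: 177},
        site_residues={214: "H", 216: "C", 235: "D", 311: "C",
                       15: "S", 69: "E", 177: "D"},
    ),
    "MesC": FamilyArchitecture(
        name="MesC",
        length=330,
        blocks=((427, 5, 18), (477, 52, 19), (591, 158, 20),
                (631, 194, 22), (658, 218, 17), (715, 303, 22)),
        zinc={641: 204, 643: 206, 665: 225, 726: 314},
        substrate={433: 11, 484: 59, 599: 166},
        site_residues={204: "H", 206: "H", 225: "E", 314: "C",
                       11: "S", 59: "Q", 166: "D"},
    ),
    "MesD": FamilyArchitecture(
        name="MesD",
        length=380,
        blocks=((425, 14, 20), (476, 65, 20), (590, 179, 21),
                (630, 219, 24), (657, 246, 18), (716, 310, 21)),
        zinc={641: 230, 643: 232, 665: 254, 726: 320},
        substrate={433: 22, 484: 73, 599: 188},
        site_residues={230: "H", 232: "C", 254: "E", 320: "C",
                       22: "S", 73: "E", 188: "D"},
    ),
    "SplitCat": FamilyArchitecture(
        name="SplitCat",
        length=335,
        blocks=((421, 1, 330),),
        zinc={641: 221, 643: 223, 665: 245, 726: 306},
        substrate={433: 13, 484: 64, 599: 179},
        site_residues={221: "H", 223: "C", 245: "E", 306: "C",
                       13: "S", 64: "E", 179: "D"},
        conservation=0.75,
    ),
}

#: published per-family bit thresholds (configuration, not constants)
DEFAULT_THRESHOLDS = {
    "MesA": 174.0,
    "MesB": 173.0,
    "MesC": 38.0,
    "MesD": 560.0,
    "MetE": 200.0,
    "MetH": 50.0,
    "AcsB": 100.0,
    "AcsC": 100.0,
    "AcsD": 100.0,
    "MetF": 50.0,
    "SplitCat": 200.0,
}

#: alternative MesD calling preset (lower threshold, adjacency-backed)
MESD_PRESETS = {"uniprot": 560.0, "microbesonline": 390.0}

#: identity ranges (fractions) within which generated members still belong
#: to the family as defined by its calling threshold
FAMILY_IDENTITY_RANGES = {
    "MesA": (0.40, 0.90),
    "MesB": (0.40, 0.90),
    "MesC": (0.40, 0.90),
    "MesD": (0.75, 0.95),
    "MetE": (0.40, 0.90),
    "MetH": (0.60, 0.95),
    "MesX": (0.70, 0.95),
    "AcsB": (0.50, 0.95),
    "AcsC": (0.50, 0.95),
    "AcsD": (0.50, 0.95),
    "MetF": (0.60, 0.95),
    "SplitCat": (0.60, 0.95),
    "SplitN": (0.70, 0.95),
}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, 20, size=length))


def _positive_exchange_table(scheme: ScoringScheme) -> dict[str, tuple[str, np.ndarray]]:
    """For each residue: the BLOSUM-positive substitutes and their weights."""
    table: dict[str, tuple[str, np.ndarray]] = {}
    for a in _AA:
        ia = _AA_INDEX[a]
        subs = [
            (b, float(scheme.matrix[ia, _AA_INDEX[b]]))
            for b in _AA
            if b != a and scheme.matrix[ia, _AA_INDEX[b]] > 0
        ]
        if subs:
            letters = "".join(b for b, _ in subs)
            weights = np.array([w for _, w in subs])
            table[a] = (letters, weights / weights.sum())
        else:
            letters = "".join(b for b in _AA if b != a)
            table[a] = (letters, np.full(19, 1 / 19))
    return table


_EXCHANGE = _positive_exchange_table(DEFAULT_SCHEME)


def mutate_to_identity(
    sequence: str,
    target_identity: float,
    rng: np.random.Generator,
    pinned: dict[int, str] | None = None,
) -> str:
    """Substitute residues at random non-pinned positions until the identity
    to the input equals ``target_identity`` (substitutes drawn proportional
    to BLOSUM62-positive exchange scores).  ``pinned`` maps 1-based position
    -> residue to hold fixed."""
    if not 0.25 <= target_identity <= 1.0:
        raise ValueError("target identity must be in [0.25, 1.0]")
    pinned = pinned or {}
    seq = list(sequence)
    for pos, res in pinned.items():
        seq[pos - 1] = res
    n_sub = round((1.0 - target_identity) * len(seq))
    candidates = [i for i in range(len(seq)) if (i + 1) not in pinned]
    if n_sub > len(candidates):
        raise ValueError(
            f"cannot reach identity {target_identity} while preserving "
            f"{len(pinned)} pinned sites"
        )
    chosen = rng.choice(len(candidates), size=n_sub, replace=False)
    for idx in chosen:
        i = candidates[idx]
        letters, weights = _EXCHANGE[seq[i]]
        seq[i] = letters[rng.choice(len(letters), p=weights)]
    return "".join(seq)


def _derive_family_seed(
    scaffold: str, arch: FamilyArchitecture, rng: np.random.Generator
) -> str:
    """Build a family seed: random backbone, scaffold-derived homology
    blocks at the family's conservation level, pinned site residues."""
    seq = list(_random_sequence(rng, arch.length))
    for ref_start, seed_start, length in arch.blocks:
        for k in range(length):
            ref_pos = ref_start + k  # 1-based
            seed_pos = seed_start + k
            ref_res = scaffold[ref_pos - 1]
            if rng.random() < arch.conservation:
                seq[seed_pos - 1] = ref_res
            else:
                letters, weights = _EXCHANGE[ref_res]
                seq[seed_pos - 1] = letters[rng.choice(len(letters), p=weights)]
    # anchor the immediate site neighborhoods, then pin the site residues
    site_map = {**{k: v for k, v in arch.zinc.items()},
                **{k: v for k, v in arch.substrate.items()}}
    for ref_pos, seed_pos in site_map.items():
        for off in (-2, -1, 1, 2):
            rp, sp = ref_pos + off, seed_pos + off
            if 1 <= sp <= arch.length and 1 <= rp <= len(scaffold):
                seq[sp - 1] = scaffold[rp - 1]
    for seed_pos, res in arch.site_residues.items():
        seq[seed_pos - 1] = res
    return "".join(seq)


@dataclass
class ReferenceSet:
    """Everything the classifier needs: seeds, profiles, and policies."""

    scaffold: ProteinRecord
    scaffold_sites: ReferenceSites
    seeds: dict[str, ProteinRecord]
    profiles: dict[str, ProfileModel]
    families: list[FamilyReference]
    architectures: dict[str, FamilyArchitecture] = field(
        default_factory=lambda: dict(ARCHITECTURES)
    )

    def family(self, name: str) -> FamilyReference:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)

    def with_thresholds(self, overrides: dict[str, float]) -> "ReferenceSet":
        families = []
        for f in self.families:
            if f.name in overrides:
                families.append(
                    FamilyReference(
                        name=f.name, threshold=overrides[f.name], query=f.query,
                        profile=f.profile, max_length=f.max_length,
                        min_length=f.min_length, min_coverage=f.min_coverage,
                        enforce_zinc=f.enforce_zinc,
                        zinc_positions=f.zinc_positions, synthase=f.synthase,
                    )
                )
            else:
                families.append(f)
        return ReferenceSet(
            scaffold=self.scaffold, scaffold_sites=self.scaffold_sites,
            seeds=self.seeds, profiles=self.profiles, families=families,
            architectures=self.architectures,
        )


def _training_msa(seed: str, rng: np.random.Generator, n: int = 14,
                  lo: float = 0.55, hi: float = 0.85) -> list[str]:
    """Ungapped training rows for a profile: the seed plus diverged members."""
    rows = [seed]
    for _ in range(n - 1):
        rows.append(mutate_to_identity(seed, rng.uniform(lo, hi), rng))
    return rows


def build_reference_set(
    scheme: ScoringScheme = DEFAULT_SCHEME,
    thresholds: dict[str, float] | None = None,
    mesd_preset: str = "uniprot",
) -> ReferenceSet:
    """Construct the frozen synthetic reference set.

    Deterministic: repeated calls return identical sequences and profiles.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    thresholds.setdefault("MesD", MESD_PRESETS[mesd_preset])
    rng = np.random.default_rng(_BUILD_SEED)

    scaffold_seq = list(_random_sequence(rng, 753))
    for pos, res in {**SCAFFOLD_ZINC, **SCAFFOLD_SUBSTRATE}.items():
        scaffold_seq[pos - 1] = res
    scaffold = ProteinRecord("MetE_scaffold", "".join(scaffold_seq), genome_id="ref")

    seeds: dict[str, ProteinRecord] = {"MetE": scaffold}
    for name, arch in ARCHITECTURES.items():
        seeds[name] = ProteinRecord(
            f"{name}_seed", _derive_family_seed(scaffold.sequence, arch, rng),
            genome_id="ref",
        )
    # folate-binding N-domain seed, from the scaffold's N-terminal domain
    n_dom = scaffold.sequence[20:350]
    seeds["SplitN"] = ProteinRecord(
        "SplitN_seed",
        mutate_to_identity(n_dom, 0.75, rng),
        genome_id="ref",
    )
    # families unrelated to the MetE fold
    for name, length in (("MetH", 610), ("MesX", 440), ("AcsB", 730),
                         ("AcsC", 460), ("AcsD", 320), ("MetF", 290)):
        seeds[name] = ProteinRecord(
            f"{name}_seed", _random_sequence(rng, length), genome_id="ref"
        )

    profiles: dict[str, ProfileModel] = {}
    for pname, seed_name in (
        ("met_synt_1", "SplitN"),   # folate-binding N-domain
        ("met_synt_2", "SplitCat"),  # catalytic domain
        ("duf1852", "MesX"),
        ("metf", "MetF"),
    ):
        rows = _training_msa(seeds[seed_name].sequence, rng)
        model = build_profile(rows, pseudocount=1.0, name=pname)
        # leave-one-out cutoff: a member scored against a profile it helped
        # build is inflated by its own counts, so score each training row
        # against the profile of the remaining rows instead
        loo_scores = []
        for i, row in enumerate(rows):
            others = rows[:i] + rows[i + 1 :]
            loo_scores.append(
                calibrate_cutoff(build_profile(others, pseudocount=1.0, name=pname), [row]).trusted_cutoff
            )
        profiles[pname] = ProfileModel(
            name=pname, columns=model.columns, trusted_cutoff=min(loo_scores)
        )

    families = [
        FamilyReference(
            name=name, threshold=thresholds[name], query=seeds[name],
            enforce_zinc=True,
            zinc_positions=tuple(
                ARCHITECTURES[name].zinc[p] for p in sorted(ARCHITECTURES[name].zinc)
            ),
        )
        for name in ("MesA", "MesB", "MesC", "MesD")
    ]
    families.append(
        FamilyReference(name="MetE", threshold=thresholds["MetE"],
                        query=seeds["MetE"], min_length=600)
    )
    families.append(
        FamilyReference(name="MetH", threshold=thresholds["MetH"],
                        query=seeds["MetH"], min_coverage=0.8)
    )
    for name in ("AcsB", "AcsC", "AcsD"):
        families.append(
            FamilyReference(name=name, threshold=thresholds[name],
                            query=seeds[name], synthase=False)
        )
    families.append(
        FamilyReference(name="MetF", threshold=thresholds["MetF"],
                        query=seeds["MetF"], min_coverage=0.8, synthase=False)
    )
    families.append(
        FamilyReference(name="MesX", threshold=profiles["duf1852"].trusted_cutoff,
                        profile=profiles["duf1852"], synthase=False)
    )
    # per-protein label for split-MetE catalytic subunits; genome-level
    # split-MetE presence additionally needs the folate-binding component
    families.append(
        FamilyReference(name="SplitCat", threshold=thresholds["SplitCat"],
                        query=seeds["SplitCat"], max_length=400, synthase=False)
    )

    return ReferenceSet(
        scaffold=scaffold,
        scaffold_sites=ReferenceSites(
            reference_id=scaffold.protein_id,
            zinc_positions=tuple(sorted(SCAFFOLD_ZINC)),
            substrate_positions=tuple(sorted(SCAFFOLD_SUBSTRATE)),
        ),
        seeds=seeds,
        profiles=profiles,
        families=families,
    )


def calibrate_thresholds(
    refs: ReferenceSet,
    true_members: dict[str, list[ProteinRecord]],
    decoys: list[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    margin: float = 0.5,
) -> dict[str, float]:
    """Rescale family thresholds so true members and decoys separate.

    For each family the proposed threshold is the midpoint (weighted by
    ``margin``) between the weakest true-member bit score and the strongest
    decoy bit score; families whose sets do not separate keep their current
    threshold and are reported with a NaN.
    """
    from .pairwise import align_local

    out: dict[str, float] = {}
    for fam in refs.families:
        if fam.query is None or fam.name not in true_members:
            continue
        member_bits = [
            align_local(fam.query, m, scheme).bit_score for m in true_members[fam.name]
        ]
        decoy_bits = [align_local(fam.query, d, scheme).bit_score for d in decoys]
        lo, hi = max(decoy_bits, default=0.0), min(member_bits)
        if hi <= lo:
            out[fam.name] = float("nan")
        else:
            out[fam.name] = lo + margin * (hi - lo)
    return out
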