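"""Position-specific scoring models built from family alignments.

A :class:`ProfileModel` is a light-weight stand-in for a curated profile HMM:
per-column log-odds scores over the 20 residues, with a trusted bit cutoff
recorded at build time from the training members themselves.  Domain calls in
the screen (the MetE N-terminal folate-binding domain, the catalytic domain,
DUF1852/MesX, and MetF) all go through these models.

Column scores are

    s(r) = log2( ((count_r + pc * bg_r) / (n + pc)) / bg_r )

with a uniform background bg = 1/20 and pseudocount pc (default 1).  Columns
with more than half gaps are dropped.  A sequence is scored by the best
ungapped placement of a contiguous run of profile columns along the sequence
(maximum-sum sub-run per diagonal), which keeps scoring deterministic and
local: flanking residues outside the best window never change the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formats import ALPHABET, ProteinRecord

_AA = ALPHABET[:20]  # X excluded from counts
_AA_INDEX = {c: i for i, c in enumerate(_AA)}
SCORE_FLOOR = -10.0  # guard for log2(0) when pseudocount is 0


@dataclass(frozen=True)
class ProfileModel:
    name: str
    columns: np.ndarray  # shape (length, 20), bits
    trusted_cutoff: float

    @property
    def length(self) -> int:
        return int(self.columns.shape[0])


def build_profile(
    msa: list[str],
    pseudocount: float = 1.0,
    name: str = "profile",
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a profile from aligned rows (gap character ``-``).

    The trusted cutoff is set afterwards with :func:`calibrate_cutoff`; a
    fresh profile carries a cutoff of 0.
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences to build a profile")
    ncol = len(msa[0])
    if any(len(row) != ncol for row in msa):
        raise ValueError("alignment rows differ in length")
    bg = 1.0 / 20.0
    cols: list[np.ndarray] = []
    for j in range(ncol):
        residues = [row[j] for row in msa if row[j] != "-"]
        if len(residues) < len(msa) * 0.5:
            continue  # more than half gaps
        counts = np.zeros(20)
        for ch in residues:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
        n = counts.sum()
        if n == 0:
            continue
        freq = (counts + pseudocount * bg) / (n + pseudocount)
        with np.errstate(divide="ignore"):
            score = np.log2(freq / bg)
        score[np.isneginf(score)] = SCORE_FLOOR
        cols.append(score)
    if not cols:
        raise ValueError("all columns dropped; alignment too gappy")
    return ProfileModel(name=name, columns=np.array(cols), trusted_cutoff=0.0)


def score_profile(model: ProfileModel, seq: ProteinRecord | str) -> float:
    """Best ungapped window score of the profile along the sequence, in bits."""
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    if not s:
        raise ValueError("cannot score an empty sequence")
    L, P = len(s), model.length
    codes = np.array([_AA_INDEX.get(ch, -1) for ch in s])
    # S[i, j] = score of sequence position i against profile column j;
    # X and unknown symbols score 0
    S = model.columns[:, np.where(codes < 0, 0, codes)].T.copy()
    S[codes < 0, :] = 0.0
    best = -math.inf
    # each diagonal is one ungapped placement; take its best contiguous run
    for d in range(-(L - 1), P):
        x = np.diagonal(S, offset=d)
        cs = np.cumsum(x)
        prefix = np.minimum.accumulate(np.concatenate(([0.0], cs[:-1])))
        best = max(best, float(np.max(cs - prefix)))
    return best


def calibrate_cutoff(model: ProfileModel, training: list[ProteinRecord | str]) -> ProfileModel:
    """Set the trusted cutoff to the minimum training-member score."""
    if not training:
        raise ValueError("no training sequences")
    cutoff = min(score_profile(model, t) for t in training)
    return ProfileModel(name=model.name, columns=model.columns, trusted_cutoff=cutoff)


def write_profile(model: ProfileModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# profile\t{model.name}\tcutoff\t{model.trusted_cutoff:.4f}\n")
        fh.write("column\t" + "\t".join(_AA) + "\n")
        for j in range(model.length):
            fh.write(str(j + 1) + "\t" + "\t".join(f"{v:.6f}" for v in model.columns[j]) + "\n")


def read_profile(path: str | Path) -> ProfileModel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4 or header[0] != "# profile":
            raise ValueError(f"{path}: not a profile file")
        name, cutoff = header[1], float(header[3])
        fh.readline()  # column header
        rows = [
            [float(v) for v in line.rstrip("\n").split("\t")[1:]]
            for line in fh
            if line.strip()
        ]
    return ProfileModel(name=name, columns=np.array(rows), trusted_cutoff=cutoff)
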