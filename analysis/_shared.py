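"""Shared loaders for the numbered analysis steps."""

from pathlib import Path

import pandas as pd

from mesfinder.classify import FamilyCall, SplitMetECall
from mesfinder.formats import ProteinRecord, read_fasta, read_features

RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_panel():
    features = read_features(RESULTS / "panel" / "features.tsv")
    gmap = {f.gene_id: f.genome_id for f in features}
    proteins = [
        ProteinRecord(p.protein_id, p.sequence, genome_id=gmap[p.protein_id])
        for p in read_fasta(RESULTS / "panel" / "proteomes.faa")
    ]
    return proteins, features


def load_calls() -> list[FamilyCall]:
    df = pd.read_csv(RESULTS / "calls.tsv", sep="\t", comment="#").fillna("")
    return [
        FamilyCall(
            protein_id=r.protein_id, genome_id=r.genome_id,
            family=r.family or None, bit_score=r.bits, identity=r.identity,
            non_enzymatic=bool(r.non_enzymatic), family_like=r.family_like or None,
        )
        for r in df.itertuples()
    ]


def load_splits() -> list[SplitMetECall]:
    df = pd.read_csv(RESULTS / "split_mete.tsv", sep="\t", comment="#").fillna("")
    return [
        SplitMetECall(
            genome_id=r.genome_id,
            catalytic_id=r.catalytic_id or None, catalytic_bits=r.catalytic_bits,
            folate_id=r.folate_id or None, folate_bits=r.folate_bits,
            adjacent=bool(r.adjacent),
        )
        for r in df.itertuples()
    ]
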