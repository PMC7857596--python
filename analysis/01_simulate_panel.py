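"""Generate the synthetic study panel.

Writes a 50-genome miniature proteome collection (FASTA + feature table +
truth manifest) under results/panel/.  The panel mixes genome archetypes:
MesA methanogen-like genomes with and without Wood-Ljungdahl genes, MesB
genomes with mesB-acsC-acsD operons, zinc-broken MesB-like genomes, MesC
archaea, MesD/MesX aerobes (often with MetH/MetE), split-MetE genomes,
plain MetE/MetH genomes, and genomes with no methionine synthase, each
padded with shuffled decoy proteins.
"""

from pathlib import Path

from mesfinder.references import build_reference_set
from mesfinder.synthetic_data import generate_panel, write_panel

SEED = 1
N_GENOMES = 50
OUT = Path(__file__).resolve().parents[1] / "results" / "panel"


def main() -> None:
    refs = build_reference_set()
    proteins, features, truth = generate_panel(refs, seed=SEED, n_genomes=N_GENOMES)
    write_panel(proteins, features, truth, OUT)
    n_family = sum(1 for t in truth.proteins if t.family)
    n_decoy = sum(1 for t in truth.proteins if t.family is None)
    print(f"panel: {N_GENOMES} genomes, {n_family} family members, {n_decoy} decoys")
    print(f"wrote {OUT}/proteomes.faa, features.tsv, truth.tsv")


if __name__ == "__main__":
    main()
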