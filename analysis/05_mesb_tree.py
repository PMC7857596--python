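"""Tree of MesB members and their zinc-broken relatives.

Aligns all MesB calls plus the non-enzymatic MesB-like homologs, trims the
alignment (max half gaps per column, minimum block length 2), computes
Kimura-corrected distances, and writes a neighbor-joining tree in Newick
format with a per-leaf group table.  The point of the tree is qualitative:
the zinc-broken homologs should fall together, apart from the enzymatic
MesB clade.
"""

import sys
from io import StringIO
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS, load_calls, load_panel

from mesfinder.pipeline import mesb_tree
from mesfinder.references import build_reference_set


def main() -> None:
    refs = build_reference_set()
    proteins, _ = load_panel()
    calls = load_calls()
    result = mesb_tree(proteins, calls, refs)
    if result is None:
        print("fewer than 3 MesB-like proteins in the panel; no tree")
        return
    newick, groups = result
    (RESULTS / "mesb_tree.nwk").write_text(newick + "\n")
    groups.to_csv(RESULTS / "mesb_tree_groups.tsv", sep="\t", index=False)
    n_mesb = (groups.group == "MesB").sum()
    n_broken = (groups.group == "MesB_like_nonenzymatic").sum()
    print(f"tree over {len(groups)} leaves: {n_mesb} MesB, {n_broken} zinc-broken")
    print(f"wrote {RESULTS}/mesb_tree.nwk")


if __name__ == "__main__":
    main()
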