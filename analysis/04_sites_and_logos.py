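"""Catalytic-residue verification and sequence-logo data.

Maps the zinc-coordinating and substrate-binding positions onto every
core-family call through alignment to the family seed, classifies each zinc
site as conserved/compatible/incompatible, and writes per-family logo data
(per-column information content in bits) from each family's own member
alignment.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS, load_calls, load_panel

from mesfinder.pipeline import family_logos, site_report
from mesfinder.references import build_reference_set


def main() -> None:
    refs = build_reference_set()
    proteins, _ = load_panel()
    calls = load_calls()

    report = site_report(proteins, calls, refs)
    report.to_csv(RESULTS / "sites.tsv", sep="\t", index=False)
    print(report.groupby(["family", "verdict"]).size().to_string())

    for fam, frame in family_logos(proteins, calls, refs).items():
        frame.to_csv(RESULTS / f"logo_{fam}.tsv", sep="\t", index=False)
        peak = frame.groupby("column")["height"].sum().max()
        print(f"logo_{fam}.tsv: {frame['column'].nunique()} columns, "
              f"max stack {peak:.2f} bits")


if __name__ == "__main__":
    main()
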