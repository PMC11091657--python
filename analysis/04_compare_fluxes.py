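"""Classify flux changes across the two condition shifts.

Reads the per-condition flux tables written by 03_simulate_conditions.py
(re-computing them if absent), classifies every reaction's change across the
pH shift (neutral vs acidic, 2 g/l succinate) and the succinate
supplementation shift (2 vs 4 g/l at acidic pH) with the 20% relative-change
rule, and summarises counts per pathway.  Headline observations printed at
the end: glutamate decarboxylase (GLUDC) is induced by the pH shift while
glycolysis and the pentose phosphate pathway are predominantly suppressed,
and the TCA cycle is predominantly induced by succinate supplementation.
"""

import argparse
from pathlib import Path

from gabaflux.flux_analysis import read_solution
from gabaflux.flux_comparison import (
    compare_conditions,
    summarize_by_pathway,
    write_change_table,
    write_pathway_summaries,
)
from gabaflux.synthetic_data import TOY_PATHWAYS

PAIRS = [("neutral-2gl", "acidic-2gl"), ("acidic-2gl", "acidic-4gl")]


def load_solutions(out_dir: Path) -> dict:
    solutions = {}
    for condition in {c for pair in PAIRS for c in pair}:
        table = out_dir / f"fluxes_{condition}.tsv"
        solutions[condition] = read_solution(table, out_dir / f"fluxes_{condition}.json")
    return solutions


def main(out_dir: Path, threshold: float = 0.20) -> None:
    if not (out_dir / "fluxes_neutral-2gl.tsv").exists():
        import runpy
        import sys

        sys.argv = ["03_simulate_conditions.py", "--out", str(out_dir)]
        runpy.run_path(Path(__file__).with_name("03_simulate_conditions.py"), run_name="__main__")
    solutions = load_solutions(out_dir)
    for label_a, label_b in PAIRS:
        changes = compare_conditions(solutions[label_a], solutions[label_b], threshold)
        summaries = summarize_by_pathway(changes, TOY_PATHWAYS)
        stem = f"{label_a}_vs_{label_b}"
        write_change_table(changes, out_dir / f"changes_{stem}.tsv")
        write_pathway_summaries(summaries, out_dir / f"pathways_{stem}.json")
        print(f"\n{label_a} -> {label_b} (threshold {threshold:.0%}):")
        for summary in summaries:
            print(f"  {summary.pathway}: {summary.counts}")
        by_id = {c.reaction_id: c.classification for c in changes}
        if (label_a, label_b) == PAIRS[0]:
            print(f"  headline: GLUDC (glutamate decarboxylase) is {by_id['GLUDC']}")
    print(f"\nwrote change tables and pathway summaries to {out_dir}/")


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results", type=Path)
    parser.add_argument("--threshold", default=0.20, type=float)
    args = parser.parse_args()
    main(args.out, args.threshold)
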