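"""Triage the identified N-terminal peptides of the baseline experiment.

Sorts peptides into database-annotated starts, proteolytic neo-N-termini
and putative alternative-initiation events by start position and N-terminal
modification, and writes counts, raw fractions and integer percentages to
results/triage.json.
"""

import json
from pathlib import Path

from kindeg import read_peptide_table, summarize_triage

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    peptides = read_peptide_table(ROOT / "results" / "experiment" / "peptides.tsv")
    summary = summarize_triage(peptides)
    out = ROOT / "results" / "triage.json"
    out.write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    for cat, count in summary.counts.items():
        print(f"  {cat.value}: {count} ({summary.percentages[cat]}%)")
    print(f"-> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
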