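"""Run the two-stage MR + SMR prioritization on the bundled candidate table.

Writes results/candidates.tsv with one row per gene: retention, direction
and the reason for the decision.
"""

from pathlib import Path

import pandas as pd

from excluscope import prioritize_candidates, two_stage_filter
from excluscope.io import load_candidate_metrics

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tmr, smr = load_candidate_metrics()
    cohorts = sorted({t.cohort for t in tmr})
    discovery = [t for t in tmr if t.cohort == cohorts[0]]
    replication = [t for t in tmr if t.cohort == cohorts[1]]
    supported = two_stage_filter(discovery, replication)
    candidates = prioritize_candidates(supported, smr, tmr)

    table = pd.DataFrame(
        [
            {"gene": c.gene, "retained": c.retained,
             "direction": c.direction or "", "reason": c.reason}
            for c in candidates
        ]
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "candidates.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
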