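#!/usr/bin/env python
"""Score the pipeline's output against the planted ground truth.

Reports, per namespace: adjusted Rand index between recovered groups and
planted families, whether the fastest-evolving family's group is flagged as
extreme by Tukey's HSD, and whether each family's anchor term (or one of its
descendants) ranks in its group's top-3 enrichment.  Writes
results/tables/recovery.tsv.
"""

import json
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from funcdiv.io import write_tsv
from funcdiv.ontology import NAMESPACES, parse_obo
from funcdiv.simulate import simulate_study

DATA = Path("results/data/study")
RUN = Path("results/pipeline")
SEED = 1


def main() -> None:
    study = simulate_study(seed=SEED)  # regenerates the same truth
    report = json.loads((RUN / "report.json").read_text())
    extreme_family = int(np.argmax(study.config.family_omega_means))
    rows = []
    for ns in NAMESPACES:
        short = ns.split("_")[0]
        groups = pd.read_csv(RUN / f"{ns}_groups.tsv", sep="\t", comment="#")
        label_of = dict(zip(groups["pair"], groups["group"]))
        pids = [pid for pid in study.truth if pid in label_of]
        ari = adjusted_rand_score(
            [study.truth[p] for p in pids], [label_of[p] for p in pids]
        )
        ns_report = report["namespaces"][ns]
        fam_groups = Counter(
            label_of[pid] for pid, f in study.truth.items()
            if f == extreme_family and pid in label_of
        )
        extreme_ok = fam_groups.most_common(1)[0][0] in ns_report["extreme_groups"]
        descendants = {
            fam: {
                t for t in study.graph.terms
                if study.anchors[ns][fam] in study.graph.reflexive_ancestors(t)
            }
            for fam in range(study.config.n_families)
        }
        hits = 0
        for fam in range(study.config.n_families):
            fgroups = Counter(
                label_of[pid] for pid, f in study.truth.items()
                if f == fam and pid in label_of
            )
            dominant = fgroups.most_common(1)[0][0]
            top3 = [t for t, _ in ns_report["enrichment_top3"][dominant]]
            hits += any(t in descendants[fam] for t in top3)
        rows.append(
            {
                "namespace": ns,
                "n_pairs": len(pids),
                "n_groups": ns_report["n_groups"],
                "ari": ari,
                "anova_F": ns_report["anova_F"],
                "anova_p": ns_report["anova_p"],
                "extreme_family_flagged": extreme_ok,
                "anchor_top3_hits": f"{hits}/{study.config.n_families}",
            }
        )
    frame = pd.DataFrame(rows)
    write_tsv(frame, Path("results/tables/recovery.tsv"))
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
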