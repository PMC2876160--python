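#!/usr/bin/env python
"""Check robustness of the group effect to clustering parameters.

Re-cuts the cached similarity trees at fixed heights (0.1 and 0.001 on the
Ward-cost scale) and alternative minimum group sizes, re-running the ANOVA at
each setting.  A robust functional signal keeps the group effect significant
across all settings even as the number of groups changes widely.  Writes
results/pipeline/sensitivity_scan.tsv.
"""

from pathlib import Path

from funcdiv.pipeline import PipelineConfig, sensitivity_scan

DATA = Path("results/data/study")
OUT = Path("results/pipeline")


def main() -> None:
    config = PipelineConfig(
        obo=str(DATA / "ontology.obo"),
        gaf=str(DATA / "annotations.gaf"),
        pairs=str(DATA / "pairs.tsv"),
        proteins=str(DATA / "proteins.fasta"),
        cds=str(DATA / "cds.fasta"),
        out_dir=str(OUT),
    )
    frame = sensitivity_scan(config, heights=[0.1, 0.001], min_sizes=[10, 20, 40])
    print(frame.to_string(index=False))
    sig = frame.dropna(subset=["p"])
    print(f"\ngroup effect p < 1e-3 at {(sig.p < 1e-3).sum()}/{len(sig)} settings")


if __name__ == "__main__":
    main()
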