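"""Readers and writers for the pipeline's file formats.

Inputs are the field's standard plain-text formats (OBO, GAF, FASTA, TSV);
outputs are TSV/JSON/Newick with a provenance header comment carrying the
configuration hash, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .annotations import AnnotationSet
from .ontology import OntologyGraph
from .pairs import DuplicatePair

STAGE_VERSION = "funcdiv-0.1.0"


def config_hash(config) -> str:
    try:
        from dataclasses import asdict, is_dataclass

        payload = asdict(config) if is_dataclass(config) else dict(config)
    except TypeError:
        payload = {"repr": repr(config)}
    payload.pop("out_dir", None)  # where results go does not change what they are
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def provenance_header(config) -> str:
    return f"# {STAGE_VERSION} config_hash={config_hash(config)}\n"


def write_tsv(df: pd.DataFrame, path, config=None, float_format: str = "%.10g") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(provenance_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def write_json(obj, path, config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if config is not None:
        payload["_provenance"] = {
            "version": STAGE_VERSION,
            "config_hash": config_hash(config),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# --------------------------------------------------------------------------
# study inputs
# --------------------------------------------------------------------------


def write_obo(graph: OntologyGraph, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in sorted(graph.terms):
            term = graph.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {term.name}\nnamespace: {term.namespace}\n")
            for parent, rel in sorted(graph.parents.get(tid, ())):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def write_gaf(annotations: AnnotationSet, path, db: str = "SYNTH") -> None:
    aspect = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for rec in sorted(
            annotations.records, key=lambda r: (r.gene, r.term, r.evidence)
        ):
            cols = [
                db, rec.gene, rec.gene, "", rec.term, "SYNTH:0001", rec.evidence,
                "", aspect[rec.namespace], rec.gene, "", "gene", "taxon:3702",
                "20090604", db, "", "",
            ]
            fh.write("\t".join(cols) + "\n")


def write_pairs(pairs: list[DuplicatePair], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# gene1\tgene2\tcopy_number_class\n")
        for p in sorted(pairs, key=lambda p: p.key):
            fh.write(f"{p.gene1}\t{p.gene2}\t{p.copy_number_class}\n")


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_layout(layout: pd.DataFrame, centromeres: dict[int, int], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# centromeres: " + json.dumps({str(k): v for k, v in sorted(centromeres.items())}) + "\n")
        layout.to_csv(fh, sep="\t", index=False)


def read_layout(path):
    with open(path) as fh:
        first = fh.readline()
        centromeres = {
            int(k): int(v)
            for k, v in json.loads(first.split("centromeres:", 1)[1]).items()
        }
        layout = pd.read_csv(fh, sep="\t")
    return layout, centromeres


def write_study(study, out_dir) -> None:
    """Write a synthetic study in the formats the real pipeline reads."""
    out = Path(out_dir)
    write_obo(study.graph, out / "ontology.obo")
    write_gaf(study.annotations, out / "annotations.gaf")
    write_pairs(study.pairs, out / "pairs.tsv")
    write_fasta(study.proteins, out / "proteins.fasta")
    write_fasta(study.cds, out / "cds.fasta")
    write_layout(study.layout, study.centromeres, out / "layout.tsv")
    write_json(
        {
            "family_by_pair": study.truth,
            "omega_by_pair": study.omega,
            "anchors": study.anchors,
        },
        out / "truth.json",
        config=study.config,
    )
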