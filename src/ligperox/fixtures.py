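"""One-call construction of a complete on-disk synthetic study.

Bundles the synthetic generators into the standard file set the pipeline
consumes (proteins, reference, anchors, labels, GFF3, loci, species table,
truth) plus a ready-to-run pipeline configuration.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .duplications import loci_table
from .genes import write_gff3
from .pipeline import PipelineConfig
from .synthetic import (FamilyModel, SyntheticTruth, generate_family,
                        generate_gene_structures, generate_genome_layout,
                        generate_sequences, generate_species_table, write_fasta)

DEFAULT_SCENARIO = (
    ("TD", "MnP_000"), ("TD", "LiP_000"), ("TD", "VP_000"),
    ("SD", "CIIBA_000"), ("SD", "CIIBB_000"),
    ("WGD", "CIIBC_000"),
)


def build_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_subclasses: int = 9,
    n_per_class: int = 20,
    sub_rate: float = 0.15,
    preset: str = "basidiomycete",
    scenario=DEFAULT_SCENARIO,
    n_species: int = 200,
    violation_rate: float = 0.1,
) -> dict:
    """Generate and write a full synthetic study under ``out_dir``.

    Returns the in-memory objects (model, records, structures, loci, truth,
    species table, config) keyed by name.  Seeds for the individual
    generators are derived from ``seed`` by fixed offsets.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = generate_family(n_subclasses=n_subclasses, seed=seed)
    records, truth = generate_sequences(model, n_per_class, sub_rate, seed=seed + 1)
    labels = {k: v["subclass"] for k, v in truth.sequence_labels.items()}
    structures, gtruth = generate_gene_structures(
        records, model, labels, preset=preset, seed=seed + 2)
    truth.merge(gtruth)
    records, loci, structures, ltruth = generate_genome_layout(
        records, structures, model, scenario, seed=seed + 3)
    truth.merge(ltruth)
    for dtype, gid in scenario:  # copies inherit the original's labels
        copy_id = f"{gid}_d"
        truth.sequence_labels[copy_id] = dict(truth.sequence_labels[gid])
        labels[copy_id] = labels[gid]
    species_df, struth = generate_species_table(
        n_species, violation_rate, seed=seed + 4)
    truth.merge(struth)

    write_fasta(records, out / "proteins.fa")
    write_fasta({model.reference_id: model.reference_sequence}, out / "reference.fa")
    model.anchors.to_json(out / "anchors.json")
    pd.DataFrame(
        {"sequence_id": list(labels), "subclass": list(labels.values())}
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    write_gff3(structures, out / "genes.gff3")
    loci_table(loci).to_csv(out / "loci.tsv", sep="\t", index=False)
    species_df.to_csv(out / "species.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")

    config = PipelineConfig(
        fasta=str(out / "proteins.fa"),
        reference=str(out / "reference.fa"),
        anchors=str(out / "anchors.json"),
        labels=str(out / "labels.tsv"),
        gff=str(out / "genes.gff3"),
        loci=str(out / "loci.tsv"),
        species_table=str(out / "species.tsv"),
        out_dir=str(out / "results"),
        seed=seed,
    )
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    return {
        "model": model, "records": records, "structures": structures,
        "loci": loci, "truth": truth, "labels": labels,
        "species_table": species_df, "config": config,
    }
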