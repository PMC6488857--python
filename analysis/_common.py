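"""Shared paths and dataset loading for the numbered analysis scripts.

The raw synthetic dataset (expression matrix, annotation, gene sets,
truth tables, qPCR panel) lives under ``scratch/data`` and is regenerated
on demand, so every numbered script can be run standalone and in order.
Derived tables land under ``results/``.
"""

from __future__ import annotations

import json
from pathlib import Path

from lncnet.array_io import (
    read_expression_matrix,
    read_group_map,
    read_probe_annotation,
)
from lncnet.enrichment import GeneSetCollection
from lncnet.synthetic_data import SimConfig, generate_dataset

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "data"
RESULTS_DIR = ROOT / "results"

SEED = 7  # one seed for the whole worked analysis


def simulate(seed: int = SEED) -> Path:
    """Generate the study-design dataset and write it under scratch/data."""
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=seed)
    matrix, annotation, gene_sets, truth = generate_dataset(config)
    matrix.write_tsv(DATA_DIR / "matrix.tsv", DATA_DIR / "groups.tsv")
    annotation.write_tsv(DATA_DIR / "annotation.tsv")
    gene_sets.to_gmt(DATA_DIR / "gene_sets.gmt")
    truth.write_tsv(
        DATA_DIR / "truth_de.tsv", DATA_DIR / "truth_edges.tsv", DATA_DIR / "truth_cis.tsv"
    )
    with open(DATA_DIR / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    return DATA_DIR


def load_dataset():
    """(matrix, annotation, gene_sets) from scratch/data, simulating if absent."""
    if not (DATA_DIR / "matrix.tsv").exists():
        simulate()
    groups = read_group_map(DATA_DIR / "groups.tsv")
    matrix = read_expression_matrix(DATA_DIR / "matrix.tsv", groups)
    annotation = read_probe_annotation(DATA_DIR / "annotation.tsv")
    gene_sets = GeneSetCollection.from_gmt(DATA_DIR / "gene_sets.gmt")
    return matrix, annotation, gene_sets


def results_dir() -> Path:
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    return RESULTS_DIR
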