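"""Packaged worked examples: mini ontologies, curated fixtures, printed tables.

Three hand-built curation fixtures ship with the package:

* **corngrass** — a classic pleiotropic maize mutant whose free-text
  phenotype ("narrow leaves, extreme tillering, highly reduced ears and
  tassel, grasslike growth habit, vegetative leaves in the ear") decomposes
  into five atomized phenes, one EQ statement each;
* **mac1** — the *multiple archesporial cells1* sterility anecdote: the
  asserted quality "male and female infertility" sits below "complete
  sterility" in the mini quality ontology, so closure infers a
  complete-sterility phene that was never asserted;
* **anthocyanin quartet** — four maize anthocyanin-pathway genotypes
  (*c2*, *c1*, *r1*, *b1*) whose profiles force the ranked similarity
  query c1 = 1.0, r1 = 0.6666666667, b1 = 0.5 against *c2*.

Also packaged are transcriptions of the published per-species annotation
summary table and the headline counts of the published similarity network,
used as inputs for report-parity arithmetic.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .eqdata import Dataset, read_dataset
from .ontology import Ontology, merge, parse_obo, read_bridges
from .validate import ValidationConfig


def data_path(name: str) -> Path:
    path = resources.files("phenesim").joinpath("data", name)
    return Path(str(path))


def load_mini_ontology(with_bridges: bool = False) -> Ontology:
    """Merged plant + quality + GO-slice + relation mini ontologies."""
    parts = [
        parse_obo(data_path(n))
        for n in ("plant_mini.obo", "pato_mini.obo", "go_mini.obo", "ro_mini.obo")
    ]
    bridges = read_bridges(data_path("bridges.tsv")) if with_bridges else None
    return merge(parts, bridges=bridges)


def load_anthocyanin_ontology() -> Ontology:
    return parse_obo(data_path("anthocyanin_mini.obo"))


def load_corngrass() -> Dataset:
    return read_dataset(data_path("corngrass.tsv"))


def load_mac1() -> Dataset:
    return read_dataset(data_path("mac1.tsv"))


def load_anthocyanin() -> Dataset:
    return read_dataset(data_path("anthocyanin.tsv"))


def fixtures_validation_config() -> ValidationConfig:
    """Default config with quality-type roots pointed into the mini PATO."""
    return ValidationConfig(
        structural_quality_root="PATO:0001241",
        process_quality_root="PATO:0001236",
    )


def load_species_summary() -> pd.DataFrame:
    """Published per-species annotation counts (EQs, genes, genotypes, ...)."""
    return pd.read_csv(data_path("species_summary.tsv"), sep="\t")


def load_network_counts() -> dict[str, int]:
    """Published headline counts of the all-vs-all similarity network."""
    with open(data_path("network_counts.json"), encoding="utf-8") as fh:
        return {k: int(v) for k, v in json.load(fh).items()}
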