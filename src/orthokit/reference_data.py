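"""Packaged reference count tables and the arithmetic summaries over them.

The count tables are transcribed survey inputs (curated factor counts per
family and species, three-species classification totals, and the tethering
presence matrix).  The functions here recompute the headline summaries
from those inputs rather than hard-coding the results.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .domain_classification import class_one_percent, single_species_factors


def _data_path(name: str):
    return resources.files("orthokit.data").joinpath(name)


def load_reference_counts() -> dict:
    with _data_path("reference_counts.json").open() as fh:
        return json.load(fh)


def load_tethering_counts() -> pd.DataFrame:
    """Tethering factor x species member-count matrix."""
    with _data_path("tethering_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="factor")


def core_set_size() -> int:
    """Distinct curated factors: sum of the per-family counts."""
    counts = load_reference_counts()["core_set_family_counts"]
    return sum(counts.values())


def pre_overlap_total() -> int:
    """Combined literature list size before removing inter-species overlap."""
    counts = load_reference_counts()["literature_species_counts"]
    return sum(counts.values())


def deduplicated_total() -> int:
    """Pre-overlap total minus the inter-species overlap."""
    ref = load_reference_counts()
    return pre_overlap_total() - ref["literature_overlap"]


def three_species_class_one_percent() -> int:
    """Rounded class-I percentage among the three-species orthogroup members."""
    counts = load_reference_counts()["three_species_class_counts"]
    return round(class_one_percent(counts["class_I"], counts["total"]))


def three_species_coorthologue_total() -> int:
    """Total members entering the three-species domain analysis."""
    counts = load_reference_counts()["three_species_coorthologue_counts"]
    return sum(counts.values())


def yeast_only_tethering_factors() -> list[str]:
    """Tethering factors whose members occur only in yeast."""
    return single_species_factors(load_tethering_counts(), "yeast")
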