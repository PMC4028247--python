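"""Subcellular-localization consensus voting at two certainty tiers.

High tier: experimental/literature records outvote predictors entirely —
predictor calls are only consulted when no experimental record exists.
Low tier: a small roster of automatable predictors votes, with calls of
the two 11-compartment tools for vacuole/ER/Golgi/plasma-membrane merged
into a single "endomembranes" category before counting.  "Bare majority"
is a plurality (mode); ties yield multi-compartment calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

COMPARTMENTS = (
    "extracellular",
    "nucleus",
    "golgi",
    "er",
    "mitochondrion",
    "plastid",
    "plasma_membrane",
    "peroxisome",
    "vacuole",
    "cytosol",
    "cytoskeleton",
)

#: Compartments relabeled "endomembranes" in the low-certainty tier.
ENDOMEMBRANE_MERGE = frozenset({"vacuole", "er", "golgi", "plasma_membrane"})

EXPERIMENTAL_KINDS = frozenset({"experimental_gfp", "experimental_ms", "literature"})

#: Predictor kinds in the low-certainty roster.  ``multi11`` tools are
#: subject to the endomembrane merge; ``single`` tools vote only when they
#: fire (a negative call is simply absent from the input).
LOW_TIER_KINDS = ("multi11", "three_class", "single")


@dataclass(frozen=True)
class LocalizationEvidence:
    protein_id: str
    compartment: str
    source_kind: str  # experimental_gfp | experimental_ms | literature | predictor
    source_name: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS and self.compartment != "endomembranes":
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class ConsensusCall:
    protein_id: str
    compartments: frozenset[str]
    votes_for: int
    votes_total: int
    certainty: str  # high | low

    def __post_init__(self) -> None:
        if self.votes_for > self.votes_total:
            raise ValueError("votes_for cannot exceed votes_total")

    @property
    def label(self) -> str:
        """Human-readable call, e.g. ``plastid/mitochondrion`` for a tie."""
        if not self.compartments:
            return "unknown"
        return "/".join(sorted(self.compartments))

    @property
    def support(self) -> str:
        return f"{self.votes_for} of {self.votes_total}"


def _plurality(votes: Sequence[str]) -> tuple[frozenset[str], int, int]:
    counts = Counter(votes)
    if not counts:
        return frozenset(), 0, 0
    top = max(counts.values())
    winners = frozenset(c for c, n in counts.items() if n == top)
    return winners, top, len(votes)


def consensus_high(
    evidence: Iterable[LocalizationEvidence],
    predictor_calls: Iterable[LocalizationEvidence],
    protein_id: str,
) -> ConsensusCall:
    """High-certainty consensus for one protein.

    With any experimental/literature record present, the call is the
    plurality over those records only; otherwise the plurality over
    predictor calls.  No input at all yields an "unknown" call (0 of 0).
    """
    exp = [e for e in evidence if e.protein_id == protein_id
           and e.source_kind in EXPERIMENTAL_KINDS]
    if exp:
        winners, top, total = _plurality([e.compartment for e in exp])
    else:
        preds = [e for e in predictor_calls if e.protein_id == protein_id]
        winners, top, total = _plurality([e.compartment for e in preds])
    return ConsensusCall(
        protein_id=protein_id,
        compartments=winners,
        votes_for=top,
        votes_total=total,
        certainty="high",
    )


def consensus_low(
    predictor_calls: Iterable[LocalizationEvidence],
    predictor_kinds: Mapping[str, str],
    protein_id: str,
) -> ConsensusCall:
    """Low-certainty consensus from the automatable predictor roster.

    ``predictor_kinds`` maps each tool name to ``multi11``, ``three_class``
    or ``single``.  Calls from ``multi11`` tools in the endomembrane set
    are relabeled "endomembranes" before counting.  Tools absent from the
    input contribute no vote.
    """
    votes: list[str] = []
    for call in predictor_calls:
        if call.protein_id != protein_id:
            continue
        kind = predictor_kinds.get(call.source_name)
        if kind is None:
            raise KeyError(f"predictor {call.source_name!r} not in the roster")
        compartment = call.compartment
        if kind == "multi11" and compartment in ENDOMEMBRANE_MERGE:
            compartment = "endomembranes"
        votes.append(compartment)
    winners, top, total = _plurality(votes)
    return ConsensusCall(
        protein_id=protein_id,
        compartments=winners,
        votes_for=top,
        votes_total=total,
        certainty="low",
    )


def consensus_for_all(
    evidence: Sequence[LocalizationEvidence],
    predictor_calls: Sequence[LocalizationEvidence],
    tier: str = "high",
    predictor_kinds: Mapping[str, str] | None = None,
) -> dict[str, ConsensusCall]:
    """Consensus calls for every protein mentioned in the inputs."""
    proteins = sorted(
        {e.protein_id for e in evidence} | {e.protein_id for e in predictor_calls}
    )
    calls = {}
    for pid in proteins:
        if tier == "high":
            calls[pid] = consensus_high(evidence, predictor_calls, pid)
        elif tier == "low":
            if predictor_kinds is None:
                raise ValueError("low tier requires a predictor_kinds roster")
            calls[pid] = consensus_low(predictor_calls, predictor_kinds, pid)
        else:
            raise ValueError(f"unknown tier {tier!r}")
    return calls


def cross_species_count(
    factor_groups: Mapping[str, Sequence[frozenset[tuple[str, str]]]],
    calls: Mapping[str, ConsensusCall],
    compartment: str,
    plant_species: Sequence[str],
    flag_threshold: int = 7,
) -> pd.DataFrame:
    """Per-factor "n of N" species counts for one compartment.

    ``factor_groups`` maps factor id -> list of member sets (protein,
    species) from its combined group(s).  A plant species counts when at
    least one of its members has a consensus containing ``compartment``.
    Factors at or above ``flag_threshold`` species are flagged.
    """
    n_total = len(plant_species)
    plant_set = set(plant_species)
    rows = []
    for factor in sorted(factor_groups):
        hit_species: set[str] = set()
        for members in factor_groups[factor]:
            for pid, sp in members:
                if sp not in plant_set:
                    continue
                call = calls.get(pid)
                if call is not None and compartment in call.compartments:
                    hit_species.add(sp)
        n = len(hit_species)
        rows.append(
            {
                "factor": factor,
                "count": n,
                "total": n_total,
                "support": f"{n} of {n_total}",
                "flagged": n >= flag_threshold,
            }
        )
    return pd.DataFrame(rows, columns=["factor", "count", "total", "support", "flagged"])


def read_evidence_table(path: str) -> list[LocalizationEvidence]:
    """Read an evidence TSV (protein_id, compartment, source_kind, source_name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"evidence row has {len(fields)} columns")
            out.append(LocalizationEvidence(*fields))
    return out


def write_consensus_table(calls: Mapping[str, ConsensusCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcompartments\tsupport\tcertainty\n")
        for pid in sorted(calls):
            c = calls[pid]
            fh.write(f"{pid}\t{c.label}\t{c.support}\t{c.certainty}\n")
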