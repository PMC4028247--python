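"""Bait selection and domain-architecture classification of group members.

Every orthogroup containing a curated bait gets a major bait (priority:
yeast > arabidopsis-experimental > arabidopsis-predicted, ties broken on
accession) and each member's ordered domain list is compared against the
major bait's:

* class I   — identical ordered accession lists (both empty counts);
* class II  — at least one shared accession but lists not identical;
* class III — disjoint accession sets (including exactly one side empty).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .orthogroups import OrthoGroup

FAMILIES = (
    "COP-II",
    "COP-I",
    "CCV",
    "Retromer/ESCRT",
    "RabGTPase",
    "Tethering",
    "SNARE",
)

CLASS_LABELS = ("I", "II", "III")


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered list of domain accessions for one protein."""

    protein_id: str
    domains: tuple[str, ...]

    def collapsed(self) -> "DomainArchitecture":
        """Collapse consecutive repeats of the same accession."""
        out: list[str] = []
        for d in self.domains:
            if not out or out[-1] != d:
                out.append(d)
        return DomainArchitecture(self.protein_id, tuple(out))


@dataclass(frozen=True)
class CoreFactor:
    """One curated bait factor from the literature core-set."""

    factor_id: str
    family: str
    species: str  # yeast | arabidopsis
    accession: str
    evidence: str  # experimental | predicted

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.evidence not in ("experimental", "predicted"):
            raise ValueError(f"evidence must be experimental|predicted, got {self.evidence!r}")


@dataclass(frozen=True)
class BaitAssignment:
    group_id: str
    major: str
    minors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.major in self.minors:
            raise ValueError("major bait cannot also be a minor bait")


class DomainTableError(ValueError):
    pass


def read_domain_table(path: str) -> dict[str, DomainArchitecture]:
    """Read per-protein domain hits and resolve overlaps.

    Expects a TSV with columns protein_id, accession, name, ali_start,
    ali_end, evalue (header optional).  Hits overlapping by more than 50%
    of the shorter span are resolved in favour of the lower e-value; the
    surviving hits are ordered by alignment start.
    """
    rows: dict[str, list[tuple[int, int, float, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "protein_id":
                continue
            if len(fields) != 6:
                raise DomainTableError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
                evalue = float(fields[5])
            except ValueError as exc:
                raise DomainTableError(f"{path}:{lineno}: {exc}") from exc
            rows.setdefault(fields[0], []).append((start, end, evalue, fields[1]))
    result: dict[str, DomainArchitecture] = {}
    for pid, hits in rows.items():
        result[pid] = DomainArchitecture(pid, resolve_overlaps(hits))
    return result


def resolve_overlaps(
    hits: Sequence[tuple[int, int, float, str]]
) -> tuple[str, ...]:
    """Greedy overlap resolution: best e-value first, drop hits overlapping
    an already-kept hit by >50% of the shorter span; order kept hits by
    start coordinate."""
    kept: list[tuple[int, int, float, str]] = []
    for hit in sorted(hits, key=lambda h: (h[2], h[0], h[3])):
        start, end, _, _ = hit
        span = end - start + 1
        clash = False
        for k in kept:
            overlap = min(end, k[1]) - max(start, k[0]) + 1
            shorter = min(span, k[1] - k[0] + 1)
            if overlap > 0.5 * shorter:
                clash = True
                break
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: (h[0], h[3]))
    return tuple(h[3] for h in kept)


_BAIT_PRIORITY = {
    ("yeast", "experimental"): 0,
    ("yeast", "predicted"): 0,
    ("arabidopsis", "experimental"): 1,
    ("arabidopsis", "predicted"): 2,
}


def select_bait(
    group: OrthoGroup, core: Iterable[CoreFactor]
) -> BaitAssignment | None:
    """Pick the major bait for a group; ``None`` when no core factor is a
    member (such groups are excluded from classification)."""
    ids = group.protein_ids
    candidates = sorted(
        (
            (_BAIT_PRIORITY[(f.species, f.evidence)], f.accession)
            for f in core
            if f.accession in ids
        ),
    )
    if not candidates:
        return None
    major = candidates[0][1]
    minors = tuple(acc for _, acc in candidates[1:] if acc != major)
    # dedupe while preserving priority order
    seen = {major}
    uniq = []
    for acc in minors:
        if acc not in seen:
            seen.add(acc)
            uniq.append(acc)
    return BaitAssignment(group_id=group.group_id, major=major, minors=tuple(uniq))


def classify(
    member: DomainArchitecture,
    bait: DomainArchitecture,
    collapse_repeats: bool = False,
) -> str:
    """Assign class I/II/III to a member relative to the bait architecture."""
    if collapse_repeats:
        member = member.collapsed()
        bait = bait.collapsed()
    if member.domains == bait.domains:
        return "I"
    if set(member.domains) & set(bait.domains):
        return "II"
    return "III"


def classify_groups(
    groups: Sequence[OrthoGroup],
    architectures: Mapping[str, DomainArchitecture],
    core: Sequence[CoreFactor],
    collapse_repeats: bool = False,
) -> pd.DataFrame:
    """Classify every member of every bait-bearing group.

    Returns a frame with columns group_id, protein_id, species, bait,
    class.  Proteins without a domain-table entry get an empty
    architecture.  Groups without a core-set member are skipped.
    """
    records = []
    for grp in groups:
        assignment = select_bait(grp, core)
        if assignment is None:
            continue
        bait_arch = architectures.get(
            assignment.major, DomainArchitecture(assignment.major, ())
        )
        for pid, species in sorted(grp.members):
            arch = architectures.get(pid, DomainArchitecture(pid, ()))
            records.append(
                {
                    "group_id": grp.group_id,
                    "protein_id": pid,
                    "species": species,
                    "bait": assignment.major,
                    "class": classify(arch, bait_arch, collapse_repeats),
                }
            )
    return pd.DataFrame(
        records, columns=["group_id", "protein_id", "species", "bait", "class"]
    )


def summarize_classes(
    assignments: pd.DataFrame, core: Sequence[CoreFactor] | None = None
) -> tuple[pd.DataFrame, float | None]:
    """Count assignments per (family, species, class) and give the overall
    class-I percentage (rounded to one decimal; ``None`` on empty input).

    Family resolution needs the core table to map each group's bait to its
    family; without it a single 'all' family bucket is used.
    """
    if assignments.empty:
        return (
            pd.DataFrame(columns=["family", "species", "class", "count"]),
            None,
        )
    df = assignments.copy()
    if core:
        fam_of = {f.accession: f.family for f in core}
        df["family"] = df["bait"].map(lambda b: fam_of.get(b, "all"))
    else:
        df["family"] = "all"
    table = (
        df.groupby(["family", "species", "class"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    frac = class_one_percent(int((df["class"] == "I").sum()), len(df))
    return table, frac


def class_one_percent(n_class_one: int, total: int) -> float:
    """Percentage of class-I assignments, rounded to one decimal."""
    if total == 0:
        raise ValueError("total must be positive")
    return round(100.0 * n_class_one / total, 1)


def conservation_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Flag factors private to one species or absent everywhere.

    ``counts`` is a factor x species frame of member counts (factors as the
    index).  Adds a ``status`` column: ``<species>-only`` when exactly one
    species has non-zero counts, ``absent`` when none has, ``shared``
    otherwise, plus per-species presence booleans.
    """
    presence = counts > 0
    status = []
    for factor, row in presence.iterrows():
        present = [sp for sp in counts.columns if row[sp]]
        if not present:
            status.append("absent")
        elif len(present) == 1:
            status.append(f"{present[0]}-only")
        else:
            status.append("shared")
    out = presence.copy()
    out["status"] = status
    return out


def single_species_factors(counts: pd.DataFrame, species: str) -> list[str]:
    """Factors whose members occur in ``species`` and nowhere else."""
    summary = conservation_summary(counts)
    return sorted(summary.index[summary["status"] == f"{species}-only"])


def read_core_table(path: str) -> list[CoreFactor]:
    """Read the core-set bait table (factor_id, family, species, accession,
    evidence)."""
    factors = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("factor_id"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise DomainTableError(f"core table row has {len(fields)} columns")
            factors.append(CoreFactor(*fields))
    return factors


def write_core_table(factors: Iterable[CoreFactor], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("factor_id\tfamily\tspecies\taccession\tevidence\n")
        for f in factors:
            fh.write(
                f"{f.factor_id}\t{f.family}\t{f.species}\t{f.accession}\t{f.evidence}\n"
            )
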