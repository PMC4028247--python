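"""Synthetic fixtures with planted ground truth for every pipeline stage.

Families of proteins evolve down a star phylogeny: each species inherits
every ancestral family, may duplicate it (lineage-specific co-orthologues),
substitutes residues per site, and gains/loses domains from the inherited
ordered architecture.  Localization truth and noisy predictor calls, and
expression matrices with planted tissue clusters, are generated from the
same seed, so every downstream result can be scored against truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io_qc import SequenceRecord, SimilarityHit, toy_local_similarity, write_fasta
from .localization import COMPARTMENTS, LocalizationEvidence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default low-tier predictor roster (name -> kind).
DEFAULT_LOW_TIER = {
    "multi_a": "multi11",
    "multi_b": "multi11",
    "triage_a": "three_class",
    "triage_b": "three_class",
    "mito_only": "single",
    "plastid_only": "single",
}

THREE_CLASS_SET = ("plastid", "mitochondrion", "er")
SINGLE_TARGETS = {"mito_only": "mitochondrion", "plastid_only": "plastid"}


@dataclass
class ExpressionConfig:
    n_clusters: int = 10
    genes_per_cluster: int = 50
    tissues: tuple[str, ...] = (
        "flower", "fruit", "root", "leaf", "seedling", "stem", "pollen", "ovule",
    )
    samples_per_tissue: int = 3
    profile_scale: float = 3.0
    noise_sd: float = 0.5
    cluster_profiles: np.ndarray | None = None


@dataclass
class SimulationConfig:
    seed: int
    n_species: int = 5
    n_families: int = 30
    duplication_prob: float = 0.15
    substitution_prob: float = 0.05
    sequence_length: int = 60
    domain_alphabet_size: int = 10
    domain_gain_prob: float = 0.05
    domain_loss_prob: float = 0.05
    compartment_freqs: dict[str, float] | None = None
    predictor_accuracies: dict[str, float] | None = None
    junk_per_species: int = 0
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def __post_init__(self) -> None:
        for name in ("duplication_prob", "substitution_prob",
                     "domain_gain_prob", "domain_loss_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_species < 1 or self.n_families < 1:
            raise ValueError("counts must be >= 1")

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


@dataclass
class SyntheticProteomes:
    """Generated proteomes plus complete ground truth."""

    records: dict[str, list[SequenceRecord]]  # species -> records
    architectures: dict[str, tuple[str, ...]]  # protein -> ordered domains
    domain_rows: list[tuple[str, str, str, int, int, float]]
    truth: pd.DataFrame  # protein_id, species, family, compartment
    event_log: pd.DataFrame  # per (family, species): copies generated

    @property
    def all_records(self) -> list[SequenceRecord]:
        out = []
        for sp in sorted(self.records):
            out.extend(self.records[sp])
        return out

    @property
    def species_of(self) -> dict[str, str]:
        return {rec.id: rec.species for rec in self.all_records}

    def truth_labels(self) -> pd.Series:
        """Planted orthogroup label per protein (junk excluded)."""
        t = self.truth
        return pd.Series(t["family"].values, index=t["protein_id"].values)


def _mutate(seq: str, prob: float, rng: np.random.Generator) -> str:
    if prob == 0.0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < prob)[0]
    for i in hits:
        alternatives = AMINO_ACIDS.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _evolve_architecture(
    arch: tuple[str, ...],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    alphabet: Sequence[str],
) -> tuple[str, ...]:
    out = [d for d in arch if rng.random() >= cfg.domain_loss_prob]
    if rng.random() < cfg.domain_gain_prob:
        pos = int(rng.integers(len(out) + 1))
        out.insert(pos, alphabet[int(rng.integers(len(alphabet)))])
    return tuple(out)


def simulate_proteomes(cfg: SimulationConfig) -> SyntheticProteomes:
    """Generate per-species proteomes with planted orthology and domains."""
    rng = np.random.default_rng(cfg.seed)
    domain_alphabet = [f"PF{90000 + i:05d}" for i in range(cfg.domain_alphabet_size)]
    freqs = cfg.compartment_freqs or {c: 1.0 / len(COMPARTMENTS) for c in COMPARTMENTS}
    comp_names = sorted(freqs)
    comp_p = np.array([freqs[c] for c in comp_names], dtype=float)
    comp_p = comp_p / comp_p.sum()

    ancestors = []
    for fam in range(cfg.n_families):
        seq = "".join(
            AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=cfg.sequence_length)
        )
        n_dom = int(rng.integers(1, 4))
        arch = tuple(
            domain_alphabet[int(rng.integers(len(domain_alphabet)))]
            for _ in range(n_dom)
        )
        compartment = comp_names[int(rng.choice(len(comp_names), p=comp_p))]
        ancestors.append((seq, arch, compartment))

    records: dict[str, list[SequenceRecord]] = {sp: [] for sp in cfg.species_names}
    architectures: dict[str, tuple[str, ...]] = {}
    domain_rows: list[tuple[str, str, str, int, int, float]] = []
    truth_rows = []
    events = []
    for fam, (anc_seq, anc_arch, compartment) in enumerate(ancestors):
        fam_label = f"fam{fam:03d}"
        for sp in cfg.species_names:
            n_copies = 1 + int(rng.random() < cfg.duplication_prob)
            events.append({"family": fam_label, "species": sp, "copies": n_copies})
            for copy in range(n_copies):
                pid = f"{sp}_{fam_label}_c{copy}"
                seq = _mutate(anc_seq, cfg.substitution_prob, rng)
                arch = _evolve_architecture(anc_arch, cfg, rng, domain_alphabet)
                records[sp].append(SequenceRecord(id=pid, species=sp, residues=seq))
                architectures[pid] = arch
                start = 1
                for dom in arch:
                    end = start + 19
                    evalue = float(10.0 ** -rng.uniform(5, 50))
                    domain_rows.append((pid, dom, dom.lower(), start, end, evalue))
                    start = end + 11
                truth_rows.append(
                    {
                        "protein_id": pid,
                        "species": sp,
                        "family": fam_label,
                        "compartment": compartment,
                    }
                )
    # junk sequences exercising the QC filter (not part of the truth)
    for sp in cfg.species_names:
        for j in range(cfg.junk_per_species):
            pid = f"{sp}_junk{j}"
            if j % 2 == 0:
                seq = "".join(
                    AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=5)
                )
            else:
                n = 20
                chars = [
                    AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=n)
                ]
                for pos in rng.choice(n, size=n // 2, replace=False):
                    chars[pos] = "*"
                seq = "".join(chars)
            records[sp].append(SequenceRecord(id=pid, species=sp, residues=seq))

    truth = pd.DataFrame(truth_rows, columns=["protein_id", "species", "family", "compartment"])
    event_log = pd.DataFrame(events, columns=["family", "species", "copies"])
    return SyntheticProteomes(
        records=records,
        architectures=architectures,
        domain_rows=domain_rows,
        truth=truth,
        event_log=event_log,
    )


def simulate_similarity(
    proteomes: SyntheticProteomes, cutoff: float = 1e-5
) -> list[SimilarityHit]:
    """All-vs-all toy alignment; both directions of every passing pair."""
    records = proteomes.all_records
    hits: list[SimilarityHit] = []
    for a, b in combinations(records, 2):
        hit = toy_local_similarity(a, b)
        if hit.evalue > cutoff:
            continue
        hits.append(hit)
        hits.append(
            SimilarityHit(
                query=hit.subject,
                subject=hit.query,
                identity=hit.identity,
                aln_length=hit.aln_length,
                mismatch=hit.mismatch,
                gapopen=hit.gapopen,
                qstart=hit.sstart,
                qend=hit.send,
                sstart=hit.qstart,
                send=hit.qend,
                evalue=hit.evalue,
                bitscore=hit.bitscore,
            )
        )
    return hits


def simulate_predictor_calls(
    truth: pd.DataFrame,
    accuracies: Mapping[str, float],
    seed: int,
    experimental_fraction: float = 0.0,
) -> tuple[list[LocalizationEvidence], list[LocalizationEvidence]]:
    """Noisy per-tool localization calls plus optional experimental records.

    Each predictor emits the true compartment with its accuracy, otherwise
    a uniformly chosen wrong compartment.  A fraction of proteins
    additionally receives a (always correct) experimental record.
    Returns (experimental evidence, predictor calls).
    """
    rng = np.random.default_rng(seed)
    evidence: list[LocalizationEvidence] = []
    calls: list[LocalizationEvidence] = []
    tools = sorted(accuracies)
    for row in truth.itertuples():
        true_comp = row.compartment
        for tool in tools:
            acc = accuracies[tool]
            if rng.random() < acc:
                comp = true_comp
            else:
                wrong = [c for c in COMPARTMENTS if c != true_comp]
                comp = wrong[int(rng.integers(len(wrong)))]
            kind = DEFAULT_LOW_TIER.get(tool)
            if kind == "single":
                # specialist tools only report their own compartment
                if comp != SINGLE_TARGETS[tool]:
                    continue
            elif kind == "three_class" and comp not in THREE_CLASS_SET:
                continue
            calls.append(
                LocalizationEvidence(
                    protein_id=row.protein_id,
                    compartment=comp,
                    source_kind="predictor",
                    source_name=tool,
                )
            )
        if rng.random() < experimental_fraction:
            evidence.append(
                LocalizationEvidence(
                    protein_id=row.protein_id,
                    compartment=true_comp,
                    source_kind="experimental_ms",
                    source_name="synthetic_ms",
                )
            )
    return evidence, calls


def simulate_expression(
    cfg: ExpressionConfig, seed: int
) -> tuple[pd.DataFrame, dict[str, str], pd.Series]:
    """Expression matrix with planted tissue-specific clusters.

    Returns (genes x samples matrix, sample -> tissue map, gene -> planted
    cluster labels).  Gene values are the cluster's per-tissue mean profile
    plus independent Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    n_tissues = len(cfg.tissues)
    if cfg.cluster_profiles is not None:
        profiles = np.asarray(cfg.cluster_profiles, dtype=float)
        if profiles.shape != (cfg.n_clusters, n_tissues):
            raise ValueError("cluster_profiles shape must be (n_clusters, n_tissues)")
    else:
        profiles = 8.0 + cfg.profile_scale * rng.standard_normal(
            (cfg.n_clusters, n_tissues)
        )
    samples = [
        f"{tissue}_s{i + 1}"
        for tissue in cfg.tissues
        for i in range(cfg.samples_per_tissue)
    ]
    tissue_map = {s: s.rsplit("_s", 1)[0] for s in samples}
    genes = []
    labels = []
    values = np.empty((cfg.n_clusters * cfg.genes_per_cluster, len(samples)))
    row = 0
    for cluster in range(cfg.n_clusters):
        for g in range(cfg.genes_per_cluster):
            gene = f"gene_{cluster:02d}_{g:03d}"
            genes.append(gene)
            labels.append(cluster)
            base = np.repeat(profiles[cluster], cfg.samples_per_tissue)
            noise = cfg.noise_sd * rng.standard_normal(len(samples))
            values[row] = base + noise
            row += 1
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    matrix.index.name = "gene"
    return matrix, tissue_map, pd.Series(labels, index=genes, name="cluster")


# -- file emitters -----------------------------------------------------------

def write_proteomes(proteomes: SyntheticProteomes, outdir: str) -> dict[str, str]:
    """Write FASTA per species, the domain table and the truth tables.

    Returns a manifest of logical name -> path.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, str] = {}
    for sp in sorted(proteomes.records):
        path = os.path.join(outdir, f"{sp}.fasta")
        write_fasta(proteomes.records[sp], path)
        manifest[f"fasta:{sp}"] = path
    dom_path = os.path.join(outdir, "domains.tsv")
    with open(dom_path, "w") as fh:
        fh.write("protein_id\taccession\tname\tali_start\tali_end\tevalue\n")
        for row in proteomes.domain_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    manifest["domains"] = dom_path
    truth_path = os.path.join(outdir, "truth_proteins.tsv")
    proteomes.truth.to_csv(truth_path, sep="\t", index=False)
    manifest["truth"] = truth_path
    return manifest


def write_expression(
    matrix: pd.DataFrame,
    tissue_map: Mapping[str, str],
    labels: pd.Series,
    outdir: str,
) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    expr_path = os.path.join(outdir, "expression.tsv")
    matrix.to_csv(expr_path, sep="\t", index_label="gene")
    map_path = os.path.join(outdir, "sample_map.tsv")
    with open(map_path, "w") as fh:
        fh.write("sample\ttissue\n")
        for sample in matrix.columns:
            fh.write(f"{sample}\t{tissue_map[sample]}\n")
    labels_path = os.path.join(outdir, "truth_expression_clusters.tsv")
    labels.rename("cluster").to_csv(labels_path, sep="\t", index_label="gene")
    return {"expression": expr_path, "sample_map": map_path, "truth_clusters": labels_path}
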