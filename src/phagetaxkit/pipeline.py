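"""End-to-end workflow: curation -> nucleotide similarity -> genus/species
partitions -> proteome similarity -> subcluster proposals -> tree with
bootstrap supports -> monophyly -> before/after concordance.

Every intermediate artifact is written to the output directory and the
machine-readable report echoes the full run configuration, so a run can
be reproduced exactly from its own report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from os import PathLike
from pathlib import Path

from . import concordance as conc
from . import io as pio
from . import nt_similarity as nts
from . import phylogeny as phylo
from . import prot_similarity as prot
from . import taxon_partition as taxp
from .curation import apply_exclusion_criteria
from .records import GenomeRecord, TaxonPartition, Thresholds

__all__ = ["WorkflowConfig", "WorkflowReport", "run_workflow"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorkflowConfig:
    """All knobs of one workflow run (echoed into the report)."""

    thresholds: Thresholds = Thresholds()
    alignment: nts.AlignmentParams = nts.AlignmentParams()
    fragmentation: prot.FragmentationParams = prot.FragmentationParams()
    linkage: str = "complete"
    bootstrap_replicates: int = 100
    seed: int = 1

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "WorkflowConfig":
        return cls(
            thresholds=Thresholds(**obj["thresholds"]),
            alignment=nts.AlignmentParams(**obj["alignment"]),
            fragmentation=prot.FragmentationParams(**obj["fragmentation"]),
            linkage=obj["linkage"],
            bootstrap_replicates=obj["bootstrap_replicates"],
            seed=obj["seed"],
        )


@dataclass
class WorkflowReport:
    """Bundle of results and relative paths of the written artifacts."""

    config: dict
    curation: dict
    files: dict
    genus_partition: dict
    species_partition: dict
    borderline: list
    genus_proposal: list
    subcluster_proposal: dict
    monophyly: dict
    concordance: dict

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except WorkflowError:
                raise
            except Exception as exc:
                raise WorkflowError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_workflow(
    fasta_path: str | PathLike,
    metadata_path: str | PathLike,
    out_dir: str | PathLike,
    config: WorkflowConfig = WorkflowConfig(),
) -> WorkflowReport:
    """Run the full classification workflow and write its report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = pio.read_fasta(fasta_path)
    table = pio.read_cluster_table(metadata_path)

    missing = [g.id for g in genomes if g.id not in table]
    if missing:
        raise WorkflowError(
            f"stage 'curation' failed: metadata missing FASTA id(s) {missing}"
        )

    curation = apply_exclusion_criteria(table.subset(g.id for g in genomes))
    retained = curation.retained_table
    genomes = [g for g in genomes if g.id in retained]
    if len(genomes) < 4:
        raise WorkflowError(
            f"stage 'curation' failed: only {len(genomes)} genomes retained (need >= 4)"
        )

    th = config.thresholds
    nt_matrix = _nt_stage(genomes, config)
    pio.write_matrix(nt_matrix, out / "nt_matrix.tsv")

    genus_part = taxp.threshold_partition(nt_matrix, th.genus_nt, config.linkage, "genus")
    species_part = taxp.threshold_partition(
        nt_matrix, th.species_nt, config.linkage, "species"
    )
    borderline = taxp.borderline_pairs(nt_matrix, th.genus_nt, th.borderline_band)
    for a, b, v in borderline:
        logger.info("borderline pair below genus threshold: %s vs %s at %.2f", a, b, v)

    genus_proposal = taxp.propose_genera(genus_part, retained)
    named_genus = TaxonPartition(
        rank="genus",
        assignment={
            gid: genus_proposal.name_of(label)
            for gid, label in genus_part.assignment.items()
        },
    )

    prot_table, prot_matrix, prot_sym = _prot_stage(genomes, config)
    pio.write_matrix(prot_matrix, out / "prot_matrix.tsv")
    pio.write_matrix(prot_sym, out / "prot_matrix_sym.tsv")

    sub_proposal = taxp.propose_subclusters(genus_part, retained)
    edits = conc.edits_from_proposal(retained, sub_proposal.partition())

    tree = _tree_stage(genomes, prot_table, config)
    pio.write_newick(tree, out / "tree.nwk")
    monophyly = phylo.monophyly_report(tree, named_genus)

    genus_old = TaxonPartition(
        rank="genus", assignment={r.phage_id: r.genus or "" for r in retained}
    )
    if any(not v for v in genus_old.assignment.values()):
        raise WorkflowError(
            "stage 'concordance' failed: some retained genomes lack a genus label"
        )
    pair = conc.before_after_report(retained, edits, genus_old, named_genus)

    report = WorkflowReport(
        config=config.to_json(),
        curation={
            "removed_groupings": curation.removed_groupings,
            "removed_genomes": curation.removed_genomes,
            "n_retained": curation.n_retained,
            "retained_cluster_sizes": curation.retained_cluster_sizes,
        },
        files={
            "nt_matrix": "nt_matrix.tsv",
            "prot_matrix": "prot_matrix.tsv",
            "prot_matrix_sym": "prot_matrix_sym.tsv",
            "tree": "tree.nwk",
            "report": "report.json",
        },
        genus_partition=named_genus.assignment,
        species_partition=species_part.assignment,
        borderline=[list(t) for t in borderline],
        genus_proposal=genus_proposal.entries,
        subcluster_proposal={
            "assignment": sub_proposal.assignment,
            "created": sub_proposal.created,
            "retained": sub_proposal.retained,
            "removed": sub_proposal.removed,
            "edits": [e.to_json() for e in edits],
        },
        monophyly={
            "per_genus": monophyly.monophyletic,
            "support": monophyly.support,
            "fully_supported": monophyly.fully_supported,
        },
        concordance={
            "before": pair.before.statistic,
            "before_strict": pair.before.strict_statistic,
            "after": pair.after.statistic,
            "after_strict": pair.after.strict_statistic,
            "delta": pair.delta,
            "audit": pair.audit,
        },
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


@_stage("nucleotide similarity")
def _nt_stage(genomes: list[GenomeRecord], config: WorkflowConfig):
    return nts.similarity_matrix(genomes, config.alignment)


@_stage("proteome similarity")
def _prot_stage(genomes: list[GenomeRecord], config: WorkflowConfig):
    table = prot.fragment_score_table(genomes, config.fragmentation)
    matrix = table.matrix()
    return table, matrix, prot.symmetrize(matrix)


@_stage("phylogeny")
def _tree_stage(genomes, prot_table, config: WorkflowConfig):
    if len(genomes) >= 4 and config.bootstrap_replicates >= 1:
        return phylo.bootstrap_support(
            genomes,
            config.fragmentation,
            replicates=config.bootstrap_replicates,
            seed=config.seed,
            table=prot_table,
        )
    return phylo.nj_tree(
        phylo.distance_from_similarity(prot.symmetrize(prot_table.matrix()))
    )
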