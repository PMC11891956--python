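"""End-to-end pipeline driver: validated run configuration, staged
execution, report files and a checksummed manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import Partition, objective_cluster, threshold_profile
from .completeness import coverage_stats, randomization_test
from .congruence import resolve_conflicts
from .distance import DEFAULT_MIN_OVERLAP, distance_matrix
from .io import (
    join_metadata,
    qc_stop_codons,
    read_barcode_fasta,
    read_morphospecies,
)
from .stability import (
    DEFAULT_STABILITY_GRID,
    MainHaplotypeRule,
    classify_stability,
    examination_plan,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    fasta: str
    out_dir: str
    metadata: str | None = None
    morphospecies: str | None = None
    thresholds: tuple[float, ...] = (0.02, 0.03, 0.04, 0.05)
    base_threshold: float = 0.03
    stability_grid: tuple[float, ...] = DEFAULT_STABILITY_GRID
    min_overlap: int = DEFAULT_MIN_OVERLAP
    main_haplotype_min_count: int = 2
    coverage_threshold: float = 0.05
    n_randomizations: int = 100
    seed: int = 0
    expected_length: int | None = None
    qc: bool = True

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise FileNotFoundError(self.fasta)
        for p in (self.metadata, self.morphospecies):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.base_threshold not in self.thresholds:
            raise ValueError("base_threshold must be one of thresholds")
        if max(self.stability_grid) != self.base_threshold:
            raise ValueError("stability grid must end at the base threshold")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_partition(part: Partition, path: Path) -> None:
    pd.DataFrame(
        {"specimen_id": list(part.assignment), "motu_id": list(part.assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run clustering, stability, congruence and coverage; write reports.

    Stages lacking their inputs (no morphospecies table, fewer than two
    batches) are skipped with a logged notice. Returns the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    records = read_barcode_fasta(config.fasta, config.expected_length)
    if config.metadata:
        records = join_metadata(records, config.metadata)
    if config.qc:
        records, failed = qc_stop_codons(records)
        if failed:
            logger.warning(
                "stop-codon QC removed %d sequence(s): %s",
                len(failed),
                [r.specimen_id for r, _ in failed],
            )
        if not records:
            raise ValueError("no sequences left after stop-codon QC")

    matrix = distance_matrix(records, min_overlap=config.min_overlap)

    all_thresholds = sorted(
        set(config.thresholds) | set(config.stability_grid) | {config.coverage_threshold}
    )
    partitions = {t: objective_cluster(matrix, t) for t in all_thresholds}
    for t in config.thresholds:
        p = out / f"partition_{t * 100:g}pct.tsv"
        _write_partition(partitions[t], p)
        written.append(p)
    profile = threshold_profile(matrix, list(config.thresholds))
    p = out / "threshold_profile.tsv"
    pd.DataFrame(
        profile.rows, columns=["threshold", "n_motus", "n_singletons", "n_doubletons"]
    ).to_csv(p, sep="\t", index=False)
    written.append(p)

    grid_parts = [partitions[t] for t in config.stability_grid]
    classes = classify_stability(grid_parts, config.base_threshold, matrix)
    p = out / "stability.tsv"
    pd.DataFrame(
        [
            {
                "motu_id": c.motu_id,
                "class": c.motu_class,
                "n_specimens": len(c.members),
                "n_haplotypes": c.n_haplotypes,
                "max_intra_dist": round(c.max_intra_distance, 6),
                "composition_stable": c.composition_stable,
                "stability_index": round(c.stability_index, 4),
            }
            for c in classes
        ]
    ).to_csv(p, sep="\t", index=False)
    written.append(p)

    rule = MainHaplotypeRule(min_count=config.main_haplotype_min_count)
    plan = examination_plan(classes, matrix, rule)
    p = out / "examination_plan.tsv"
    pd.DataFrame(
        [
            {"motu_id": motu, "specimen_id": sid, "reason": reason}
            for motu, items in plan.entries.items()
            for sid, reason in items
        ]
    ).to_csv(p, sep="\t", index=False)
    written.append(p)

    congruence_summary = None
    if config.morphospecies:
        morph = read_morphospecies(
            config.morphospecies, known_ids={r.specimen_id for r in records}
        )
        report = resolve_conflicts(
            list(partitions.values()), morph, partitions[config.base_threshold]
        )
        p = out / "congruence.tsv"
        pd.DataFrame(
            [
                {"morphospecies": lab, "status": status}
                for lab, status in sorted(report.statuses.status.items())
            ]
        ).to_csv(p, sep="\t", index=False)
        written.append(p)
        congruence_summary = {
            "n_motu": report.match.n_a,
            "n_morph": report.match.n_b,
            "n_congruent": report.match.n_congruent,
            "match_ratio": report.match.ratio,
            "n_species_accepted": report.n_species,
            "resolution_log": [
                {
                    "action": e.action,
                    "morphospecies": list(e.morphospecies),
                    "motus": list(e.motus),
                    "threshold": e.threshold,
                }
                for e in report.log
            ],
        }
        p = out / "congruence_summary.json"
        p.write_text(json.dumps(congruence_summary, indent=2))
        written.append(p)
    else:
        logger.info("no morphospecies table: congruence stage skipped")

    coverage_summary = None
    batch_of = {r.specimen_id: r.batch for r in records}
    batches = sorted(set(batch_of.values()))
    if len(batches) == 2:
        b1, b2 = batches
        cov = coverage_stats(
            partitions[config.coverage_threshold], batch_of, batch1=b1, batch2=b2
        )
        n1 = sum(1 for b in batch_of.values() if b == b1)
        rand = randomization_test(
            partitions[config.coverage_threshold],
            sizes=(n1, len(batch_of) - n1),
            n_reps=config.n_randomizations,
            seed=config.seed,
        )
        coverage_summary = {
            "threshold": config.coverage_threshold,
            "n_motus_combined": cov.n_motus_combined,
            "n_motus_occupied_by_batch2": cov.n_motus_occupied_by_batch2,
            "n_shared": cov.n_shared,
            "n_new": cov.n_new,
            "new_motu_specimen_count": cov.new_motu_specimen_count,
            "motu_coverage_pct": cov.motu_coverage_pct,
            "specimen_coverage_pct": cov.specimen_coverage_pct,
            "randomization": {
                "n_reps": rand.n_reps,
                "motu_coverage_mean": rand.motu_coverage_mean,
                "motu_coverage_sd": rand.motu_coverage_sd,
                "specimen_coverage_mean": rand.specimen_coverage_mean,
                "specimen_coverage_sd": rand.specimen_coverage_sd,
            },
        }
        p = out / "coverage_summary.json"
        p.write_text(json.dumps(coverage_summary, indent=2))
        written.append(p)
        p = out / "randomization.tsv"
        pd.DataFrame(
            {
                "rep": range(1, rand.n_reps + 1),
                "motu_coverage": rand.motu_coverage,
                "specimen_coverage": rand.specimen_coverage,
            }
        ).to_csv(p, sep="\t", index=False)
        written.append(p)
    else:
        logger.info(
            "found %d batch label(s) %s: coverage stage skipped", len(batches), batches
        )

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_specimens": len(records),
        "stages": {
            "clustering": True,
            "stability": True,
            "congruence": congruence_summary is not None,
            "coverage": coverage_summary is not None,
        },
        "outputs": {str(p.name): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
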