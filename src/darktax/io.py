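"""Readers/writers for barcode FASTA, specimen metadata, morphospecies
tables and externally produced MOTU partitions, plus the stop-codon
quality filter applied before distance computation.

All tabular formats are tab-delimited UTF-8 with a header row:

* metadata:       specimen_id, batch, site, habitat
* morphospecies:  specimen_id, morphospecies
* partition:      specimen_id, motu_id
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .records import UNASSIGNED_BATCH, SpecimenRecord, check_common_length, check_unique_ids

logger = logging.getLogger(__name__)

#: Default genetic code for COI: invertebrate mitochondrial (NCBI table 5).
DEFAULT_GENETIC_CODE = 5

ANY_FRAME = "any"


def read_barcode_fasta(
    path: str | Path, expected_length: int | None = None
) -> list[SpecimenRecord]:
    """Read minibarcode sequences from FASTA into specimen records.

    Sequences are uppercased and validated to a single common length
    (``expected_length`` if given, else the modal length). Metadata is
    joined separately via :func:`join_metadata`; the FASTA id token is
    the specimen id and the rest of the header is ignored.
    """
    records = [
        SpecimenRecord(specimen_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    check_unique_ids(records)
    check_common_length(records, expected_length)
    return records


def write_barcode_fasta(records: list[SpecimenRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.specimen_id}\n{rec.sequence}\n")


def join_metadata(
    records: list[SpecimenRecord], table: str | Path
) -> list[SpecimenRecord]:
    """Attach batch/site/habitat from a metadata TSV keyed by specimen_id.

    Records absent from the table keep batch "unassigned" (warning
    logged); table rows naming unknown specimens are ignored with a
    warning.
    """
    df = pd.read_csv(table, sep="\t", dtype=str).fillna("")
    required = {"specimen_id", "batch"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"metadata table {table} must have columns specimen_id, batch "
            f"(got {list(df.columns)})"
        )
    for col in ("site", "habitat"):
        if col not in df.columns:
            df[col] = ""
    if df["specimen_id"].duplicated().any():
        dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen_id rows in metadata: {dups}")
    meta = df.set_index("specimen_id")
    known = {r.specimen_id for r in records}
    for sid in meta.index:
        if sid not in known:
            logger.warning("metadata row for unknown specimen %r ignored", sid)
    out = []
    for rec in records:
        if rec.specimen_id in meta.index:
            row = meta.loc[rec.specimen_id]
            out.append(
                rec.with_metadata(
                    batch=row["batch"] or UNASSIGNED_BATCH,
                    site=row["site"],
                    habitat=row["habitat"],
                )
            )
        else:
            logger.warning(
                "specimen %r missing from metadata table; batch set to %r",
                rec.specimen_id,
                UNASSIGNED_BATCH,
            )
            out.append(rec)
    return out


def write_metadata(records: list[SpecimenRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "batch": [r.batch for r in records],
            "site": [r.site for r in records],
            "habitat": [r.habitat for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_morphospecies(path: str | Path, known_ids: set[str] | None = None) -> dict[str, str]:
    """Read specimen_id -> morphospecies label for examined specimens."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"specimen_id", "morphospecies"}.issubset(df.columns):
        raise ValueError(
            f"morphospecies table {path} must have columns specimen_id, morphospecies"
        )
    if df["specimen_id"].duplicated().any():
        dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"specimen(s) listed more than once: {dups}")
    if (df["morphospecies"] == "").any():
        bad = df.loc[df["morphospecies"] == "", "specimen_id"].tolist()
        raise ValueError(f"empty morphospecies label for: {bad}")
    table = dict(zip(df["specimen_id"], df["morphospecies"]))
    if known_ids is not None:
        unknown = sorted(set(table) - known_ids)
        if unknown:
            raise ValueError(f"morphospecies table names unknown specimens: {unknown}")
    return table


def write_morphospecies(table: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"specimen_id": list(table), "morphospecies": list(table.values())}
    ).to_csv(path, sep="\t", index=False)


def _stop_codons(genetic_code: int | str) -> frozenset[str]:
    try:
        tab = CodonTable.unambiguous_dna_by_id[int(genetic_code)]
    except (KeyError, ValueError):
        try:
            tab = CodonTable.unambiguous_dna_by_name[str(genetic_code)]
        except KeyError:
            raise ValueError(f"unknown genetic code: {genetic_code!r}") from None
    return frozenset(tab.stop_codons)


def frames_with_stops(
    sequence: str, genetic_code: int | str = DEFAULT_GENETIC_CODE
) -> list[int]:
    """Return the reading frames (0/1/2) whose translation hits a stop.

    Codons containing gaps or ambiguity codes never count as stops
    (pairwise-deletion spirit: missing data is not evidence of a
    pseudogene).
    """
    stops = _stop_codons(genetic_code)
    hit = []
    for frame in (0, 1, 2):
        for i in range(frame, len(sequence) - 2, 3):
            if sequence[i : i + 3] in stops:
                hit.append(frame)
                break
    return hit


def qc_stop_codons(
    records: list[SpecimenRecord],
    genetic_code: int | str = DEFAULT_GENETIC_CODE,
    frame_policy: int | str = ANY_FRAME,
) -> tuple[list[SpecimenRecord], list[tuple[SpecimenRecord, list[int]]]]:
    """Screen barcodes for internal stop codons (NUMT/pseudogene filter).

    Under ``frame_policy="any"`` a record passes if at least one of the
    three forward frames is stop-free; under a fixed frame (0/1/2) only
    that frame is checked. The fail list pairs each rejected record
    with its stop-bearing frame(s).
    """
    _stop_codons(genetic_code)  # validate code up front
    if frame_policy != ANY_FRAME and frame_policy not in (0, 1, 2):
        raise ValueError(f"frame_policy must be 'any' or 0/1/2, got {frame_policy!r}")
    passed: list[SpecimenRecord] = []
    failed: list[tuple[SpecimenRecord, list[int]]] = []
    for rec in records:
        bad_frames = frames_with_stops(rec.sequence, genetic_code)
        if frame_policy == ANY_FRAME:
            ok = len(bad_frames) < 3
        else:
            ok = frame_policy not in bad_frames
        if ok:
            passed.append(rec)
        else:
            failed.append((rec, bad_frames))
    return passed, failed


def read_partition_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"specimen_id", "motu_id"}.issubset(df.columns):
        raise ValueError(f"partition table {path} must have columns specimen_id, motu_id")
    mapping: dict[str, str] = {}
    for sid, motu in zip(df["specimen_id"], df["motu_id"]):
        if sid in mapping and mapping[sid] != motu:
            raise ValueError(
                f"specimen {sid!r} listed with conflicting MOTUs "
                f"{mapping[sid]!r} and {motu!r}"
            )
        mapping[sid] = motu
    return mapping


def import_partition(path: str | Path, specimen_ids: list[str]):
    """Load an externally produced partition (e.g. ABGD or PTP output).

    The file must assign every specimen exactly one MOTU; the returned
    partition is tagged ``method="imported"``.
    """
    from .cluster import Partition

    mapping = read_partition_tsv(path)
    missing = [sid for sid in specimen_ids if sid not in mapping]
    if missing:
        raise ValueError(f"partition file {path} missing specimens: {missing}")
    extra = sorted(set(mapping) - set(specimen_ids))
    if extra:
        raise ValueError(f"partition file {path} names unknown specimens: {extra}")
    return Partition(
        method="imported",
        threshold=None,
        assignment={sid: mapping[sid] for sid in specimen_ids},
    )
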