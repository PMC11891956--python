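"""Core specimen record type shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Characters accepted in a validated barcode sequence: canonical bases,
#: IUPAC ambiguity codes, alignment gaps and N.
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-")

UNASSIGNED_BATCH = "unassigned"


@dataclass(frozen=True, slots=True)
class SpecimenRecord:
    """One sequenced specimen: a minibarcode plus collection metadata.

    ``sequence`` is an uppercase string over the IUPAC DNA alphabet
    (gaps and Ns allowed); within a dataset all sequences share one
    length so that positions are comparable without re-alignment.
    """

    specimen_id: str
    sequence: str
    batch: str = UNASSIGNED_BATCH
    site: str = ""
    habitat: str = ""

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for specimen {self.specimen_id!r}")
        bad = set(self.sequence) - ALLOWED_CHARS
        if bad:
            raise ValueError(
                f"specimen {self.specimen_id!r}: disallowed characters "
                f"{sorted(bad)} in sequence"
            )

    def with_metadata(self, batch: str, site: str = "", habitat: str = "") -> "SpecimenRecord":
        return replace(self, batch=batch, site=site, habitat=habitat)


def check_unique_ids(records: list[SpecimenRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.specimen_id in seen:
            raise ValueError(f"duplicate specimen id: {rec.specimen_id!r}")
        seen.add(rec.specimen_id)


def check_common_length(
    records: list[SpecimenRecord], expected_length: int | None = None
) -> int:
    """Validate that all sequences share one length; return that length.

    When ``expected_length`` is given every sequence must match it;
    otherwise the modal length is taken as the dataset length and any
    deviating records are reported.
    """
    if not records:
        raise ValueError("no records to validate")
    lengths = [len(r.sequence) for r in records]
    if expected_length is not None:
        target = expected_length
    else:
        target = max(set(lengths), key=lengths.count)
    offenders = [r.specimen_id for r, n in zip(records, lengths) if n != target]
    if offenders:
        raise ValueError(
            f"sequence length mismatch (expected {target}): {offenders}"
        )
    return target
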