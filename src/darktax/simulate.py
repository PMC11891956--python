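"""Synthetic barcode communities with known species truth.

The generator emulates the structure of a Malaise-trap minibarcode
dataset: many species with a long tail of rare ones, tight
intraspecific haplotype clouds, a wide barcode gap between species,
and — on request — the two anomalies that make threshold clustering
fail in practice:

* *cryptic pairs*: two good species separated by less than 2%, which
  fuse into one MOTU at a 3% threshold and must be re-split at a finer
  one;
* *divergent conspecifics*: one species containing an internal lineage
  more than 3% apart, which splits into two MOTUs at 3% and must be
  re-fused at a coarser threshold.

Sequences are protein-coding by construction (sense codons of the
invertebrate mitochondrial code in frame 0, substitutions only, no
indels), so the stop-codon QC passes by design; a flag injects
pseudogene-like sequences bearing stops in every frame to exercise the
filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .records import SpecimenRecord

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
SENSE_CODONS = sorted(set(_TABLE5.forward_table) - set(_TABLE5.stop_codons))
STOP_CODONS = frozenset(_TABLE5.stop_codons)
_BASES = "ACGT"


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a simulated barcode community.

    Divergences are p-distance fractions. Defaults mirror a typical
    tropical Malaise-trap insect family: a geometric rank-abundance
    curve dominated by a few species with a long rare tail,
    intraspecific variation within 1% and interspecific divergence of
    at least 5%.
    """

    n_species: int
    total_specimens: int
    seed: int
    abundance: str = "geometric"  # geometric | logseries | uniform
    abundance_param: float = 0.05  # geometric p, or log-series shape
    seq_length: int = 313
    max_intra_divergence: float = 0.01
    min_inter_divergence: float = 0.05
    n_cryptic_pairs: int = 0
    cryptic_divergence: float = 0.018  # within (max_intra, 0.02)
    n_divergent_conspecifics: int = 0
    lineage_divergence: float = 0.04  # > 0.03, below min_inter
    batch1_fraction: float = 0.5
    n_pseudogenes: int = 0
    morph_error_rate: float = 0.0
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.total_specimens < self.n_species:
            raise ValueError("need n_species >= 1 and total_specimens >= n_species")
        if not self.max_intra_divergence < self.min_inter_divergence:
            raise ValueError("divergence bounds out of order")
        if self.n_cryptic_pairs and not (
            self.max_intra_divergence < self.cryptic_divergence < 0.02
        ):
            raise ValueError("cryptic_divergence must lie in (max_intra, 0.02)")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated community."""

    species_of: dict[str, str]  # specimen -> true species
    ancestors: dict[str, list[str]]  # species -> ancestor sequence(s)
    anomalies: dict[str, str]  # species -> anomaly tag
    haplotype_of: dict[str, str]  # specimen -> haplotype sequence


@dataclass
class SimulatedCommunity:
    spec: CommunitySpec
    records: list[SpecimenRecord]
    truth: SyntheticTruth
    morphospecies: dict[str, str]  # specimen -> label (truth, maybe with error)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    n_codons, extra = divmod(length, 3)
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    tail = "".join(rng.choice(list(_BASES), size=extra))
    return "".join(codons) + tail


def _frame0_has_stop(seq: str) -> bool:
    return any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


def _mutate(seq: str, n_sites: int, rng: np.random.Generator, max_tries: int = 100) -> str:
    """Substitute ``n_sites`` distinct positions, keeping frame 0 stop-free."""
    if n_sites == 0:
        return seq
    for _ in range(max_tries):
        sites = rng.choice(len(seq), size=n_sites, replace=False)
        chars = list(seq)
        for s in sites:
            chars[s] = rng.choice([b for b in _BASES if b != chars[s]])
        out = "".join(chars)
        if not _frame0_has_stop(out):
            return out
    raise RuntimeError("could not place mutations without creating a stop codon")


def _abundances(spec: CommunitySpec, rng: np.random.Generator) -> list[int]:
    """Per-species specimen counts summing to the total, each >= 1."""
    s, total = spec.n_species, spec.total_specimens
    if spec.abundance == "uniform":
        weights = np.ones(s)
    elif spec.abundance == "geometric":
        p = spec.abundance_param
        weights = p * (1 - p) ** np.arange(s)
    elif spec.abundance == "logseries":
        x = spec.abundance_param if spec.abundance_param < 1 else 0.95
        k = np.arange(1, s + 1)
        weights = x**k / k
    else:
        raise ValueError(f"unknown abundance model {spec.abundance!r}")
    weights = weights / weights.sum()
    raw = weights * (total - s)  # reserve one specimen per species
    counts = np.ones(s, dtype=int) + np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    counts[order[:remainder]] += 1
    return counts.tolist()


def _species_ancestors(
    spec: CommunitySpec, rng: np.random.Generator
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Ancestor haplotype(s) per species, respecting divergence bounds."""
    n_ordinary = spec.n_species - spec.n_cryptic_pairs
    if n_ordinary < spec.n_cryptic_pairs or n_ordinary < spec.n_divergent_conspecifics:
        raise ValueError("too many anomalies for n_species")
    L = spec.seq_length
    min_sites = int(np.ceil(spec.min_inter_divergence * L))
    ancestors: dict[str, list[str]] = {}
    anomalies: dict[str, str] = {}
    base_seqs: list[str] = []
    for i in range(n_ordinary):
        name = f"sp{i + 1:03d}"
        for attempt in range(spec.max_retries):
            cand = _random_coding_sequence(L, rng)
            if all(_hamming(cand, s) >= min_sites for s in base_seqs):
                break
        else:
            raise RuntimeError(
                f"could not place species {name} at >= {spec.min_inter_divergence} "
                f"from all others after {spec.max_retries} tries"
            )
        ancestors[name] = [cand]
        base_seqs.append(cand)
    # Cryptic partners: each derived from one ordinary species at a small
    # fixed divergence, far from everything else by inheritance.
    k_cryptic = int(round(spec.cryptic_divergence * L))
    parents = rng.choice(n_ordinary, size=spec.n_cryptic_pairs, replace=False)
    for j, parent_idx in enumerate(parents):
        parent = f"sp{parent_idx + 1:03d}"
        name = f"sp{n_ordinary + j + 1:03d}"
        ancestors[name] = [_mutate(ancestors[parent][0], k_cryptic, rng)]
        anomalies[parent] = f"cryptic_pair_{j + 1}"
        anomalies[name] = f"cryptic_pair_{j + 1}"
    # Divergent conspecifics: an ordinary species gains a second internal
    # lineage beyond 3% but inside the interspecific gap.
    k_lineage = int(round(spec.lineage_divergence * L))
    eligible = [
        f"sp{i + 1:03d}" for i in range(n_ordinary) if f"sp{i + 1:03d}" not in anomalies
    ]
    chosen = rng.choice(len(eligible), size=spec.n_divergent_conspecifics, replace=False)
    for j, idx in enumerate(chosen):
        name = eligible[idx]
        ancestors[name].append(_mutate(ancestors[name][0], k_lineage, rng))
        anomalies[name] = f"divergent_conspecific_{j + 1}"
    return ancestors, anomalies


def simulate_community(spec: CommunitySpec) -> SimulatedCommunity:
    """Generate a community; same seed gives byte-identical output.

    Each specimen samples a haplotype at most ``max_intra/2`` (in
    sites) from its lineage ancestor, so any two conspecifics of one
    lineage stay within the intraspecific bound.
    """
    rng = np.random.default_rng(spec.seed)
    ancestors, anomalies = _species_ancestors(spec, rng)
    counts = _abundances(spec, rng)
    radius = int(spec.max_intra_divergence * spec.seq_length / 2)
    species_names = sorted(ancestors)
    records: list[SpecimenRecord] = []
    species_of: dict[str, str] = {}
    haplotype_of: dict[str, str] = {}
    idx = 0
    for name, count in zip(species_names, counts):
        lineages = ancestors[name]
        for k in range(count):
            idx += 1
            sid = f"spec{idx:05d}"
            anc = lineages[k % len(lineages)]
            n_mut = min(int(rng.poisson(0.6)), radius)
            seq = _mutate(anc, n_mut, rng)
            records.append(SpecimenRecord(specimen_id=sid, sequence=seq))
            species_of[sid] = name
            haplotype_of[sid] = seq
    # Pseudogene-like contaminants: stops in every frame, fail QC.
    for j in range(spec.n_pseudogenes):
        idx += 1
        sid = f"pseudo{j + 1:03d}"
        seq = list(_random_coding_sequence(spec.seq_length, rng))
        for frame in (0, 1, 2):
            pos = 3 * (10 + 2 * frame) + frame
            seq[pos : pos + 3] = "TAA"
        records.append(SpecimenRecord(specimen_id=sid, sequence="".join(seq)))
        species_of[sid] = "pseudogene"
    # Batch labels: uniform random split at the requested sizes.
    n_total = len(records)
    n1 = int(round(spec.batch1_fraction * n_total))
    perm = rng.permutation(n_total)
    batch = np.full(n_total, "2", dtype=object)
    batch[perm[:n1]] = "1"
    records = [r.with_metadata(batch=b, site="simulated") for r, b in zip(records, batch)]
    # Morphospecies table = truth, optionally with identification errors.
    morphospecies: dict[str, str] = {}
    for rec in records:
        if species_of[rec.specimen_id] == "pseudogene":
            continue
        label = species_of[rec.specimen_id]
        if spec.morph_error_rate > 0 and rng.random() < spec.morph_error_rate:
            others = [s for s in species_names if s != label]
            label = others[int(rng.integers(len(others)))]
        morphospecies[rec.specimen_id] = label
    truth = SyntheticTruth(
        species_of=species_of,
        ancestors=ancestors,
        anomalies=anomalies,
        haplotype_of=haplotype_of,
    )
    return SimulatedCommunity(
        spec=spec, records=records, truth=truth, morphospecies=morphospecies
    )
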