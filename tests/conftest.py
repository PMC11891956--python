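import numpy as np
import pytest

from darktax import CommunitySpec, distance_matrix, simulate_community


def naive_pdistance(a: str, b: str):
    """Independent per-site recount: pairwise deletion, mismatch fraction."""
    assert len(a) == len(b)
    compared = mism = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            compared += 1
            if x != y:
                mism += 1
    return (mism / compared if compared else float("nan")), compared


def naive_single_linkage(ids, link) -> set[frozenset]:
    """Brute-force transitive closure: merge clusters until fixpoint."""
    clusters = [{i} for i in ids]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(link(a, b) for a in clusters[i] for b in clusters[j]):
                    clusters[i] |= clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in clusters}


def random_sequences(rng: np.random.Generator, n: int, length: int, p_special=0.05):
    """Random DNA with occasional Ns/gaps to exercise pairwise deletion."""
    alphabet = np.array(list("ACGT"))
    seqs = []
    for _ in range(n):
        chars = rng.choice(alphabet, size=length)
        mask = rng.random(length) < p_special
        chars[mask] = rng.choice(np.array(list("N-RY")), size=mask.sum())
        seqs.append("".join(chars))
    return seqs


@pytest.fixture(scope="session")
def clean_community():
    """Well-separated community: no anomalies, wide barcode gap."""
    spec = CommunitySpec(n_species=15, total_specimens=180, seed=42)
    return simulate_community(spec)


@pytest.fixture(scope="session")
def clean_matrix(clean_community):
    return distance_matrix(clean_community.records)


@pytest.fixture(scope="session")
def anomalous_community():
    """Community with one cryptic pair and one divergent conspecific."""
    spec = CommunitySpec(
        n_species=12,
        total_specimens=150,
        seed=11,
        n_cryptic_pairs=1,
        n_divergent_conspecifics=1,
    )
    return simulate_community(spec)


@pytest.fixture(scope="session")
def anomalous_matrix(anomalous_community):
    return distance_matrix(anomalous_community.records)
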