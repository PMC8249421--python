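"""Synthetic equal-length sequence families with controlled divergence.

Emulates the layout of the real test sets (a handful of families of
equal-length homologous sequences, e.g. the 10-species beta-hemoglobin
panel) without any downloads: a uniform random root sequence is mutated at
a high rate to give each family ancestor, and each ancestor is mutated at
a low rate to give the family members.  Substitutions are Jukes–Cantor
style — each base flips independently to one of the three other bases with
the given probability — so lengths are preserved (no indels, no rate
heterogeneity).

A single integer seed drives everything through a documented splitting
rule: stream 0 draws the root, stream (1 + family) derives ancestor
``family``, and stream (1 + n_families + member_index) derives each member,
so any one sequence is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qgramfir.dissimilarity_phylo import ClusterAssignment
from qgramfir.sequence_io import SequenceRecord, SequenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FamilySpec:
    """Layout and divergence parameters for a clustered synthetic dataset.

    ``intra_rate`` is the per-base substitution probability between a family
    ancestor and its members; ``inter_rate`` the probability between the
    shared root and each ancestor.  Rates are capped at 0.75, the saturation
    point of uniform substitution over four bases.
    """

    n_families: int = 4
    family_size: int = 3
    seq_length: int = 300
    intra_rate: float = 0.01
    inter_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.family_size < 1 or self.seq_length < 1:
            raise ValueError("n_families, family_size and seq_length must be positive")
        if not 0.0 <= self.intra_rate < self.inter_rate <= 0.75:
            raise ValueError(
                f"need 0 <= intra_rate < inter_rate <= 0.75, "
                f"got intra={self.intra_rate}, inter={self.inter_rate}"
            )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(seq: str, rate: float, seed: int) -> str:
    """Substitute each base independently with probability ``rate``.

    Replacements are uniform over the three other bases; the same
    (seq, rate, seed) triple always returns the same output.
    """
    if not 0.0 <= rate <= 0.75:
        raise ValueError(f"substitution rate must be in [0, 0.75], got {rate}")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.searchsorted(_BASES, arr[hit])  # current base as 0..3
        shift = rng.integers(1, 4, size=int(hit.sum()))  # never the same base
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def generate_clustered_dataset(spec: FamilySpec) -> tuple[SequenceSet, ClusterAssignment]:
    """Generate the family dataset and its true cluster labels.

    Sequence ids are ``f<family>_m<member>`` (both 1-based); labels map each
    id to its generating family, numbered 1..n_families.
    """
    root = _random_sequence(spec.seq_length, _rng(spec.seed, 0))
    records: list[SequenceRecord] = []
    labels: dict[str, int] = {}
    member_stream = 1 + spec.n_families
    for fam in range(spec.n_families):
        anc_seed = int(_rng(spec.seed, 1 + fam).integers(0, 2**31))
        ancestor = mutate(root, spec.inter_rate, anc_seed)
        for mem in range(spec.family_size):
            mem_seed = int(_rng(spec.seed, member_stream).integers(0, 2**31))
            member_stream += 1
            seq = mutate(ancestor, spec.intra_rate, mem_seed)
            rid = f"f{fam + 1}_m{mem + 1}"
            records.append(SequenceRecord(rid, seq))
            labels[rid] = fam + 1
    return SequenceSet(records), ClusterAssignment(labels=labels, n_clusters=spec.n_families)


def write_labels_tsv(labels: ClusterAssignment, path) -> None:
    with open(path, "w") as out:
        out.write("seq_id\tcluster\n")
        for rid, lab in labels.labels.items():
            out.write(f"{rid}\t{lab}\n")
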