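"""End-to-end driver: FASTA -> densities -> PCA -> distances -> UPGMA tree.

Each stage's artifacts are written as plain text (TSV / Newick / JSON) with
12 significant digits, so chaining stages through files reproduces the
in-memory pipeline within round-off.  Identical input and configuration
give byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from qgramfir.dissimilarity_phylo import (
    ClusterAssignment,
    CondensedDistances,
    UPGMATree,
    cut_tree,
    pairwise_euclidean_condensed,
    to_square,
    upgma,
    write_newick,
)
from qgramfir.pca_embedding import ScoreMatrix, build_data_matrix, pca_scores, write_scores_tsv
from qgramfir.qgram_density import density_profile, uniform_window
from qgramfir.sequence_io import SequenceSet, read_fasta, write_json, write_matrix_tsv
from qgramfir.synthetic_fixtures import write_labels_tsv

logger = logging.getLogger("qgramfir")

_version = "0.1.0"  # kept in sync with the package metadata


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    The window width W has no canonical value; it is always logged so the
    choice stays visible.  Defaults: q = 1 (the four single-nucleotide
    densities analysed simultaneously), W = 10 unit taps, k = 3 retained
    components.
    """

    fasta: Path
    q: int = 1
    window: int = 10
    normalize: bool = False
    components: int = 3
    clusters: int | None = None
    outdir: Path = field(default_factory=lambda: Path("qgramfir_out"))

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.outdir = Path(self.outdir)
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.window < 1:
            raise ValueError("window width must be >= 1")
        if self.components < 1:
            raise ValueError("components must be >= 1")


@dataclass
class PipelineResult:
    """In-memory results plus the paths of every written artifact."""

    sequences: SequenceSet
    scores: ScoreMatrix
    distances: CondensedDistances
    tree: UPGMATree
    clusters: ClusterAssignment | None
    artifacts: dict[str, Path]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(name, exc) from exc

    return wrap


def write_density_tsv(profiles, path) -> None:
    """Long-format density table: seq_id, bin, position (1-based), density."""
    with open(path, "w") as out:
        out.write("seq_id\tbin\tposition\tdensity\n")
        for prof in profiles:
            from qgramfir.qgram_density import enumerate_bins

            bins = enumerate_bins(prof.q).bins
            for b, row in zip(bins, prof.rows):
                for pos, val in enumerate(row, start=1):
                    out.write(f"{prof.seq_id}\t{b}\t{pos}\t{val:.12g}\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full flow and write every artifact under ``config.outdir``."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    art: dict[str, Path] = {}

    seqs = _stage("read")(read_fasta, config.fasta)
    logger.info(
        "read %d sequences of length %d (q=%d, W=%d%s, k=%d)",
        seqs.m, seqs.n, config.q, config.window,
        " normalized" if config.normalize else "", config.components,
    )

    coeffs = uniform_window(config.window, normalize=config.normalize)
    profiles = _stage("density")(
        lambda: [density_profile(rec, config.q, coeffs) for rec in seqs]
    )
    art["density"] = config.outdir / "density.tsv"
    write_density_tsv(profiles, art["density"])

    D = _stage("data_matrix")(build_data_matrix, profiles)
    logger.info("data matrix: %d x %d (p = 4^q * (n - q + 1))", D.m, D.p)

    S = _stage("pca")(pca_scores, D, config.components)
    logger.info(
        "explained variance fractions: %s",
        ", ".join(f"{f:.4f}" for f in S.explained_fraction),
    )
    art["scores"] = config.outdir / "scores.tsv"
    write_scores_tsv(S, art["scores"])
    art["variance"] = config.outdir / "variance.json"
    write_json(
        {"explained_fraction": [float(f) for f in S.explained_fraction]},
        art["variance"],
    )

    d = _stage("distances")(pairwise_euclidean_condensed, S)
    dm = to_square(d)
    art["distances"] = config.outdir / "dist.tsv"
    write_matrix_tsv(dm.values, dm.ids, art["distances"])

    tree = _stage("upgma")(upgma, dm)
    art["newick"] = config.outdir / "tree.nwk"
    art["newick"].write_text(write_newick(tree) + "\n")

    clusters = None
    if config.clusters is not None:
        clusters = _stage("cut_tree")(cut_tree, tree, config.clusters)
        art["clusters"] = config.outdir / "clusters.tsv"
        write_labels_tsv(clusters, art["clusters"])

    art["metadata"] = config.outdir / "run_metadata.json"
    write_json(
        {
            "tool": "qgramfir",
            "version": _version,
            "q": config.q,
            "window": config.window,
            "normalize": config.normalize,
            "components": config.components,
            "clusters": config.clusters,
            "m": seqs.m,
            "n": seqs.n,
            "input_sha256": hashlib.sha256(config.fasta.read_bytes()).hexdigest(),
        },
        art["metadata"],
    )

    return PipelineResult(
        sequences=seqs, scores=S, distances=d, tree=tree, clusters=clusters, artifacts=art
    )


def partitions_equal(a: ClusterAssignment, b: ClusterAssignment) -> bool:
    """True if two assignments induce the same partition (labels may differ)."""
    if set(a.labels) != set(b.labels):
        return False
    map_ab: dict[int, int] = {}
    map_ba: dict[int, int] = {}
    for rid in sorted(a.labels):
        la, lb = a.labels[rid], b.labels[rid]
        if map_ab.setdefault(la, lb) != lb or map_ba.setdefault(lb, la) != la:
            return False
    return True
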