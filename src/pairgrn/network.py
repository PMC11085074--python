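"""Genome-scale scanning, thresholding, and network summary statistics.

After training, every (TF, candidate gene) pair is featurized and scored,
giving a complete scored edge list. Two thresholding routes produce the
final regulatory network: retaining the top fraction of edges by score
(reporting the implied score cutoff), or keeping edges strictly above a
fixed score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .featurize import HistogramConfig, iter_pair_images, images_to_array

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


@dataclass
class EdgeList:
    """Scored TF -> target predictions."""

    edges: pd.DataFrame  # columns: tf_id, target_id, score
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.edges[["tf_id", "target_id", "score"]].astype(
            {"tf_id": str, "target_id": str, "score": float}
        )
        if df.duplicated(subset=["tf_id", "target_id"]).any():
            raise NetworkError("duplicate (tf_id, target_id) edge")
        if (df["tf_id"] == df["target_id"]).any():
            raise NetworkError("self-edges are not allowed")
        if ((df["score"] < 0) | (df["score"] > 1)).any():
            raise NetworkError("scores must lie in [0, 1]")
        self.edges = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.edges["tf_id"].unique())

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf_id"], self.edges["target_id"]))

    def targets_of(self) -> dict[str, set[str]]:
        """Mapping tf_id -> set of predicted targets."""
        out: dict[str, set[str]] = {}
        for tf, grp in self.edges.groupby("tf_id", sort=False):
            out[str(tf)] = set(grp["target_id"])
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key}: {value}\n")
            self.edges.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EdgeList":
        metadata: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition(":")
                    metadata[key.strip()] = value.strip()
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh, sep="\t")
        return cls(df, metadata)


def scan_all_pairs(
    model,
    tf_ids: Sequence[str],
    candidate_ids: Sequence[str],
    bulk,
    sc,
    hist_config: HistogramConfig | None = None,
    chunk_size: int = 1000,
) -> EdgeList:
    """Score every TF x candidate pair (self-pairs skipped), streamed in chunks."""
    hist_config = hist_config or HistogramConfig()
    digest = hist_config.digest()
    model_digest = getattr(model, "histogram_digest", None)
    if model_digest is not None and model_digest != digest:
        raise NetworkError(
            "model was trained under a different histogram configuration "
            f"({model_digest} != {digest})"
        )
    pair_iter = (
        (tf, cand, None)
        for tf in tf_ids
        for cand in candidate_ids
        if tf != cand
    )
    rows: list[tuple[str, str, float]] = []
    for chunk in iter_pair_images(pair_iter, bulk, sc, hist_config, chunk_size):
        scores = model.predict_scores(images_to_array(chunk))
        rows.extend(
            (im.tf_id, im.target_id, float(s)) for im, s in zip(chunk, scores)
        )
    logger.info("scanned %d pairs", len(rows))
    return EdgeList(
        pd.DataFrame(rows, columns=["tf_id", "target_id", "score"]),
        metadata={"histogram_digest": digest, "n_scanned": len(rows)},
    )


def threshold_top_fraction(
    edges: EdgeList, fraction: float = 0.10
) -> tuple[EdgeList, float]:
    """Retain the ``ceil(fraction * N)`` highest-scoring edges.

    Ties at the retention boundary are broken by (tf_id, target_id)
    lexicographic order so the result is exactly reproducible; the minimum
    retained score is reported as the implied cutoff.
    """
    if not 0 < fraction <= 1:
        raise NetworkError("fraction must lie in (0, 1]")
    if len(edges) == 0:
        raise NetworkError("cannot threshold an empty edge list")
    n_keep = math.ceil(fraction * len(edges))
    ordered = edges.edges.sort_values(
        by=["score", "tf_id", "target_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    kept = ordered.iloc[:n_keep]
    cutoff = float(kept["score"].min())
    metadata = dict(edges.metadata)
    metadata.update(threshold_mode="top_fraction", fraction=fraction, cutoff=cutoff)
    return EdgeList(kept.reset_index(drop=True), metadata), cutoff


def threshold_by_score(edges: EdgeList, cutoff: float = 0.5) -> EdgeList:
    """Edges with score strictly greater than ``cutoff``."""
    if not 0 <= cutoff <= 1:
        raise NetworkError("cutoff must lie in [0, 1]")
    kept = edges.edges[edges.edges["score"] > cutoff]
    metadata = dict(edges.metadata)
    metadata.update(threshold_mode="score", cutoff=cutoff)
    return EdgeList(kept.reset_index(drop=True), metadata)


_DEGREE_BINS = (("1-100", 1, 100), ("101-1000", 101, 1000), (">1000", 1001, None))


def target_degree_distribution(edges: EdgeList) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-target regulator counts plus a binned percentage summary.

    The summary bins targets by how many TFs regulate them (1-100,
    101-1000, >1000); percentages are over targets with at least one
    predicted regulator and sum to 100.
    """
    if len(edges) == 0:
        raise NetworkError("empty edge list")
    counts = (
        edges.edges.groupby("target_id", sort=True)
        .size()
        .rename("n_tfs")
        .reset_index()
    )
    total = len(counts)
    rows = []
    for name, lo, hi in _DEGREE_BINS:
        mask = counts["n_tfs"] >= lo
        if hi is not None:
            mask &= counts["n_tfs"] <= hi
        n = int(mask.sum())
        rows.append((name, n, 100.0 * n / total))
    summary = pd.DataFrame(rows, columns=["bin", "n_targets", "percentage"])
    return counts, summary


def tf_summary(
    edges: EdgeList, family_map: Mapping[str, str] | None = None
) -> dict:
    """Per-TF target counts; mean/median; optional per-family breakdown."""
    if len(edges) == 0:
        raise NetworkError("empty edge list")
    per_tf = (
        edges.edges.groupby("tf_id", sort=True).size().rename("n_targets").reset_index()
    )
    result: dict = {
        "per_tf": per_tf,
        "n_tfs": len(per_tf),
        "mean_targets_per_tf": float(per_tf["n_targets"].mean()),
        "median_targets_per_tf": float(per_tf["n_targets"].median()),
    }
    if family_map is not None:
        known = set(per_tf["tf_id"])
        unknown = [tf for tf in family_map if tf not in known]
        if unknown:
            logger.warning(
                "family map references %d TF(s) absent from the network", len(unknown)
            )
        fam = per_tf.assign(
            family=per_tf["tf_id"].map(lambda t: family_map.get(t))
        ).dropna(subset=["family"])
        result["per_family"] = (
            fam.groupby("family")["n_targets"]
            .agg(members="size", mean_targets="mean", median_targets="median")
            .reset_index()
        )
    return result
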