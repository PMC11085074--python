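"""Gene-pair joint-expression histogram images.

A (TF, target) pair is featurized as the 2D histogram of its joint
expression across samples: TF values on the first axis, target values on
the second, with equal-width bins spanning each gene's own (per-modality)
min-max range. With both modalities requested, the bulk block is stacked
above the single-cell block, giving a (2*bins) x bins image — e.g. 64 x 32
at the default 32 bins. Histogram counts are log10(1+c)-compressed by
default so the single-cell block (thousands of cells) and the bulk block
(hundreds of samples) live on comparable scales.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from .matrix import ExpressionMatrix
from .pairs import GenePairLabelSet

logger = logging.getLogger(__name__)

CountTransform = Literal["raw", "log10_1p"]
CombineMode = Literal["bulk_only", "sc_only", "stacked"]


class FeaturizeError(ValueError):
    pass


@dataclass(frozen=True)
class HistogramConfig:
    """Featurization settings.

    ``bins`` is the per-axis bin count (32 gives the canonical 32 x 32
    single-modality and 64 x 32 stacked images). ``range_policy`` is fixed
    to per-gene min/max: each gene's own observed range defines its bin
    edges, which makes the image invariant to per-gene scale.
    """

    bins: int = 32
    count_transform: CountTransform = "log10_1p"
    range_policy: Literal["per_gene_min_max"] = "per_gene_min_max"
    combine: CombineMode = "stacked"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise FeaturizeError("bins must be at least 2")
        if self.count_transform not in ("raw", "log10_1p"):
            raise FeaturizeError(f"unknown count_transform {self.count_transform!r}")
        if self.combine not in ("bulk_only", "sc_only", "stacked"):
            raise FeaturizeError(f"unknown combine mode {self.combine!r}")

    @property
    def image_shape(self) -> tuple[int, int]:
        rows = 2 * self.bins if self.combine == "stacked" else self.bins
        return (rows, self.bins)

    def digest(self) -> str:
        """Stable hash of the config, used to key image caches/checkpoints."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PairImage:
    """The histogram tensor for one (TF, target) pair."""

    tf_id: str
    target_id: str
    tensor: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if (self.tensor < 0).any():
            raise FeaturizeError("pair image entries must be non-negative")


def _safe_range(values: np.ndarray) -> tuple[float, float]:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        logger.warning("degenerate histogram range [%g, %g]; widening", lo, hi)
        hi = lo + 1.0
    return lo, hi


def histogram2d(
    x: np.ndarray,
    y: np.ndarray,
    bins: int,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
) -> np.ndarray:
    """Equal-width 2D histogram with half-open bins (last bin closed).

    Entry (i, j) counts samples whose x falls in x-bin i and y in y-bin j;
    the total count equals ``len(x)`` when every value lies within range.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise FeaturizeError(
            f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}"
        )
    if x.size < 1:
        raise FeaturizeError("need at least one observation")
    x_lo, x_hi = x_range
    y_lo, y_hi = y_range
    if x_lo == x_hi:
        x_lo, x_hi = _safe_range(np.array([x_lo]))
    if y_lo == y_hi:
        y_lo, y_hi = _safe_range(np.array([y_lo]))
    if x_lo > x_hi or y_lo > y_hi:
        raise FeaturizeError("histogram range lower bound exceeds upper bound")
    counts, _, _ = np.histogram2d(
        x, y, bins=bins, range=[[x_lo, x_hi], [y_lo, y_hi]]
    )
    return counts


def _modality_block(
    matrix: ExpressionMatrix, tf_id: str, target_id: str, config: HistogramConfig
) -> np.ndarray:
    for gid in (tf_id, target_id):
        if gid not in matrix:
            raise FeaturizeError(
                f"gene {gid!r} absent from the {matrix.modality} matrix"
            )
    x = matrix.gene_vector(tf_id)
    y = matrix.gene_vector(target_id)
    counts = histogram2d(x, y, config.bins, _safe_range(x), _safe_range(y))
    if config.count_transform == "log10_1p":
        counts = np.log10(1.0 + counts)
    return counts


def make_pair_image(
    bulk: ExpressionMatrix | None,
    sc: ExpressionMatrix | None,
    tf_id: str,
    target_id: str,
    config: HistogramConfig,
    label: int | None = None,
) -> PairImage:
    """Build the pair image for one (TF, target) under ``config``.

    Stacked mode concatenates the bulk block above the single-cell block
    along the first axis.
    """
    blocks: list[np.ndarray] = []
    if config.combine in ("bulk_only", "stacked"):
        if bulk is None:
            raise FeaturizeError("bulk matrix required for this combine mode")
        blocks.append(_modality_block(bulk, tf_id, target_id, config))
    if config.combine in ("sc_only", "stacked"):
        if sc is None:
            raise FeaturizeError("single-cell matrix required for this combine mode")
        blocks.append(_modality_block(sc, tf_id, target_id, config))
    tensor = blocks[0] if len(blocks) == 1 else np.concatenate(blocks, axis=0)
    return PairImage(tf_id, target_id, tensor, label)


def iter_pair_images(
    pairs: Iterable[tuple[str, str, int | None]],
    bulk: ExpressionMatrix | None,
    sc: ExpressionMatrix | None,
    config: HistogramConfig,
    chunk_size: int = 1000,
) -> Iterator[list[PairImage]]:
    """Yield pair images in chunks; pairs naming absent genes are skipped.

    Peak memory is bounded by ``chunk_size`` images, never the corpus size.
    The number of skipped pairs is logged at WARN after exhaustion.
    """
    chunk: list[PairImage] = []
    n_skipped = 0
    for record in pairs:
        tf_id, target_id = record[0], record[1]
        label = record[2] if len(record) > 2 else None
        present = all(
            gid in m
            for m in ((bulk,) if config.combine == "bulk_only"
                      else (sc,) if config.combine == "sc_only"
                      else (bulk, sc))
            for gid in (tf_id, target_id)
        )
        if not present:
            n_skipped += 1
            continue
        chunk.append(make_pair_image(bulk, sc, tf_id, target_id, config, label))
        if len(chunk) >= chunk_size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk
    if n_skipped:
        logger.warning("skipped %d pair(s) referencing absent genes", n_skipped)


def build_image_corpus(
    pairs: GenePairLabelSet,
    bulk: ExpressionMatrix | None,
    sc: ExpressionMatrix | None,
    config: HistogramConfig,
    chunk_size: int = 1000,
) -> tuple[list[PairImage], int]:
    """Materialize one image per labeled pair, order preserved.

    Returns (images, n_skipped) where skipped pairs referenced genes absent
    from the required matrices.
    """
    images: list[PairImage] = []
    for chunk in iter_pair_images(iter(pairs), bulk, sc, config, chunk_size):
        images.extend(chunk)
    n_skipped = len(pairs) - len(images)
    return images, n_skipped


def images_to_array(images: Sequence[PairImage]) -> np.ndarray:
    """Stack images into an (n, rows, cols) array for the classifier."""
    if not images:
        return np.empty((0, 0, 0))
    return np.stack([im.tensor for im in images])
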