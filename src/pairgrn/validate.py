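"""Statistical comparison of a predicted network against references.

Two complementary statistics validate a predicted edge list against an
experimentally derived reference network (ChIP binding, perturbation DE
sets, Y1H, DAP-seq):

* network-level overlap against a degree-preserving permutation null —
  each permutation replaces every TF's predicted target set with a uniform
  same-size sample from the gene universe, yielding the expected chance
  overlap, its range, a fold enrichment (observed / expected) and an
  empirical p-value;
* per-TF hypergeometric overlap of predicted vs reference target sets,
  with Benjamini-Hochberg adjustment across TFs.

Under the uniform degree-preserving null, each TF's per-permutation
overlap with its reference target set is exactly hypergeometric
(population = universe, successes = reference targets, draws = predicted
out-degree), so permutations are drawn from that distribution directly;
this is an exact realization of the null, not an approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import EdgeList

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass
class ReferenceNetwork:
    """Gene-level reference: mapping tf_id -> non-empty set of target ids."""

    targets: dict[str, set[str]]
    source: str = "other"

    def __post_init__(self) -> None:
        for tf, tgts in self.targets.items():
            if not tgts:
                raise ValidationError(f"reference TF {tf!r} has an empty target set")

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.targets.values())

    def edge_set(self) -> set[tuple[str, str]]:
        return {(tf, t) for tf, tgts in self.targets.items() for t in tgts}

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None) -> "ReferenceNetwork":
        """Read ``tf_id<TAB>target_id[<TAB>source]`` records."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("reference TSV needs at least 2 columns")
        # tolerate a header row
        if df.iloc[0, 0] in ("tf_id", "tf"):
            df = df.iloc[1:]
        targets: dict[str, set[str]] = {}
        for tf, tgt in zip(df.iloc[:, 0], df.iloc[:, 1]):
            targets.setdefault(str(tf), set()).add(str(tgt))
        src = source or (str(df.iloc[0, 2]) if df.shape[1] > 2 else "other")
        return cls(targets, src)


def count_overlap(
    predicted: EdgeList, reference: ReferenceNetwork
) -> tuple[int, int]:
    """Observed edge overlap and the comparable reference edge count.

    The comparable count (the denominator for an overlap percentage) is
    the number of reference edges whose TF appears in the predicted
    network at all.
    """
    pred_edges = predicted.edge_set()
    pred_tfs = {tf for tf, _ in pred_edges}
    observed = 0
    comparable = 0
    for tf, tgts in reference.targets.items():
        if tf not in pred_tfs:
            continue
        comparable += len(tgts)
        observed += sum(1 for t in tgts if (tf, t) in pred_edges)
    return observed, comparable


def overlap_percentage(observed: int, comparable_edge_count: int) -> float:
    """Observed overlap as a percentage of the comparable reference edges."""
    if comparable_edge_count <= 0:
        raise ValidationError("comparable edge count must be positive")
    return 100.0 * observed / comparable_edge_count


def fold_enrichment(observed: float, expected: float) -> float:
    """Observed / expected overlap; infinite (flagged, not raised) at expected 0."""
    if expected < 0:
        raise ValidationError("expected overlap cannot be negative")
    if expected == 0:
        return float("inf")
    return observed / expected


@dataclass(frozen=True)
class OverlapEnrichmentResult:
    observed_overlap: int
    expected_overlap: float
    range: tuple[int, int]
    fold_enrichment: float
    empirical_p: float
    p_label: str
    n_permutations: int
    seed: int


def permutation_expected_overlap(
    predicted: EdgeList,
    reference: ReferenceNetwork,
    universe: Sequence[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> OverlapEnrichmentResult:
    """Degree-preserving permutation test of the network overlap.

    Every permutation redraws each predicted TF's target set uniformly
    without replacement from ``universe`` (same out-degree) and records the
    total overlap with the reference. The empirical p-value is the
    fraction of permutations whose overlap strictly exceeds the observed
    one; when that count is zero it is additionally reported as
    ``< 1/n_permutations``.
    """
    universe_set = set(universe)
    n_universe = len(universe_set)
    pred_targets = predicted.targets_of()
    for tf, tgts in pred_targets.items():
        missing = tgts - universe_set
        if missing:
            raise ValidationError(
                f"predicted targets of {tf!r} outside the universe, "
                f"e.g. {sorted(missing)[:3]}"
            )
        if len(tgts) > n_universe:
            raise ValidationError(f"TF {tf!r} degree exceeds the universe size")
    observed, _ = count_overlap(predicted, reference)

    rng = np.random.default_rng(seed)
    perm_overlap = np.zeros(n_permutations, dtype=np.int64)
    for tf, tgts in pred_targets.items():
        ref = reference.targets.get(tf)
        if not ref:
            continue
        n_good = len(ref & universe_set)
        if n_good == 0:
            continue
        # overlap of a uniform without-replacement redraw is hypergeometric
        perm_overlap += rng.hypergeometric(
            ngood=n_good, nbad=n_universe - n_good, nsample=len(tgts),
            size=n_permutations,
        )
    expected = float(perm_overlap.mean())
    n_greater = int(np.sum(perm_overlap > observed))
    empirical_p = n_greater / n_permutations
    p_label = (
        f"< {1 / n_permutations:g}" if n_greater == 0 else f"{empirical_p:g}"
    )
    return OverlapEnrichmentResult(
        observed_overlap=observed,
        expected_overlap=expected,
        range=(int(perm_overlap.min()), int(perm_overlap.max())),
        fold_enrichment=fold_enrichment(observed, expected),
        empirical_p=empirical_p,
        p_label=p_label,
        n_permutations=n_permutations,
        seed=seed,
    )


def hypergeometric_target_overlap(
    predicted_targets: set[str],
    reference_targets: set[str],
    universe: set[str],
) -> float:
    """Upper-tail P(X >= k) for the overlap of two gene sets in a universe.

    X is hypergeometric with population ``|universe|``, successes
    ``|reference|``, draws ``|predicted|``; k is the observed overlap.
    """
    if not predicted_targets <= universe:
        raise ValidationError("predicted targets must lie within the universe")
    if not reference_targets <= universe:
        raise ValidationError("reference targets must lie within the universe")
    n_universe = len(universe)
    k = len(predicted_targets & reference_targets)
    return float(
        hypergeom.sf(k - 1, n_universe, len(reference_targets), len(predicted_targets))
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class TFEnrichmentRecord:
    tf_id: str
    overlap: int
    n_predicted: int
    n_reference: int
    n_universe: int
    p: float
    q: float


def per_tf_enrichment_table(
    predicted: EdgeList,
    reference: ReferenceNetwork,
    universe: Sequence[str],
    q_cutoff: float = 0.05,
) -> tuple[list[TFEnrichmentRecord], dict]:
    """Per-TF hypergeometric overlap with BH adjustment across the table.

    One record per TF present in both networks; the summary counts shared
    TFs, their fraction of the reference TFs, and TFs significant at
    ``q < q_cutoff``.
    """
    universe_set = set(universe)
    pred_targets = predicted.targets_of()
    shared = [tf for tf in reference.targets if tf in pred_targets]
    records_raw = []
    for tf in shared:
        pred = pred_targets[tf] & universe_set
        ref = reference.targets[tf] & universe_set
        p = hypergeometric_target_overlap(pred, ref, universe_set)
        records_raw.append((tf, len(pred & ref), len(pred), len(ref), p))
    q_values = bh_adjust([r[4] for r in records_raw]) if records_raw else np.empty(0)
    records = [
        TFEnrichmentRecord(
            tf_id=tf, overlap=k, n_predicted=n_pred, n_reference=n_ref,
            n_universe=len(universe_set), p=p, q=float(q),
        )
        for (tf, k, n_pred, n_ref, p), q in zip(records_raw, q_values)
    ]
    n_ref_tfs = len(reference.targets)
    n_significant = sum(1 for r in records if r.q < q_cutoff)
    summary = {
        "n_reference_tfs": n_ref_tfs,
        "n_shared_tfs": len(shared),
        "shared_tf_percentage": 100.0 * len(shared) / n_ref_tfs if n_ref_tfs else 0.0,
        "n_significant": n_significant,
        "significant_tf_percentage": (
            100.0 * n_significant / n_ref_tfs if n_ref_tfs else 0.0
        ),
    }
    return records, summary


def enrichment_table_to_frame(records: list[TFEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
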