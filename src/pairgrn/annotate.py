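"""TF function inference by GO enrichment of predicted targets.

A TF whose predicted targets are enriched for a biological-process (BP)
term is inferred to act in that process. Recovery rate measures, per
term, how many of the TFs already annotated with it are re-derived this
way; enriched terms absent from a TF's known annotation are reported as
novel function candidates.

Only BP-aspect annotations passing an experimental/curated evidence
whitelist are used, and terms at the root of the GO hierarchy (too generic
to be informative) are excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .network import EdgeList
from .validate import ValidationError, bh_adjust, hypergeometric_target_overlap

logger = logging.getLogger(__name__)

#: GO BP terms at or near the hierarchy root, excluded from all output
ROOT_TERMS: frozenset[str] = frozenset({
    "GO:0008150", "GO:0009987", "GO:0008152", "GO:0044237", "GO:0071704",
    "GO:0050896", "GO:0065007", "GO:0032502", "GO:0050789", "GO:0032501",
    "GO:0007275", "GO:0050794", "GO:0006355", "GO:0045893", "GO:0045892",
})

#: "experimental and curated" evidence codes
DEFAULT_EVIDENCE_WHITELIST: frozenset[str] = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}
)

_BP_ASPECTS = {"P", "BP", "biological_process"}


class AnnotationError(ValueError):
    pass


@dataclass
class GOAnnotationSet:
    """Gene -> set of BP term ids, after evidence and root filtering."""

    gene_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    evidence_whitelist: frozenset[str] = DEFAULT_EVIDENCE_WHITELIST
    root_exclusion: frozenset[str] = ROOT_TERMS

    def __post_init__(self) -> None:
        leaked = {
            t for terms in self.gene_terms.values() for t in terms
        } & self.root_exclusion
        if leaked:
            raise AnnotationError(f"root terms present after filtering: {leaked}")

    def terms_of(self, gene_id: str) -> set[str]:
        return self.gene_terms.get(gene_id, set())

    def annotated_genes(self, term_id: str) -> set[str]:
        return {g for g, terms in self.gene_terms.items() if term_id in terms}


def load_annotations(
    path: str | Path,
    evidence_whitelist: Sequence[str] | None = None,
    root_exclusion: Sequence[str] | None = None,
) -> GOAnnotationSet:
    """Load BP annotations from GAF 2.x or a 4-column TSV.

    The simplified TSV carries ``gene_id, term_id, aspect, evidence``
    columns (header optional, ``#`` comments ignored). GAF lines are
    detected by their 15+ columns and ``!`` comment prefix. Rows failing
    the BP-aspect or evidence filters are dropped silently; malformed rows
    are skipped with a warning count.
    """
    whitelist = frozenset(evidence_whitelist or DEFAULT_EVIDENCE_WHITELIST)
    excluded = frozenset(root_exclusion if root_exclusion is not None else ROOT_TERMS)
    gene_terms: dict[str, set[str]] = {}
    n_malformed = 0
    with open(Path(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("!", "#")):
                continue
            parts = line.split("\t")
            if len(parts) >= 15:  # GAF 2.x
                gene, term, evidence, aspect = parts[1], parts[4], parts[6], parts[8]
            elif len(parts) >= 4:
                gene, term, aspect, evidence = parts[0], parts[1], parts[2], parts[3]
            else:
                n_malformed += 1
                continue
            gene, term = gene.strip(), term.strip()
            if not gene or not term.startswith("GO:"):
                if gene in ("gene_id", "gene"):  # header row
                    continue
                n_malformed += 1
                continue
            if aspect.strip() not in _BP_ASPECTS:
                continue
            if evidence.strip() not in whitelist:
                continue
            if term in excluded:
                continue
            gene_terms.setdefault(gene, set()).add(term)
    if n_malformed:
        logger.warning("skipped %d malformed annotation row(s)", n_malformed)
    return GOAnnotationSet(
        gene_terms, evidence_whitelist=whitelist, root_exclusion=excluded
    )


@dataclass(frozen=True)
class EnrichmentRecord:
    tf_id: str
    term_id: str
    k: int  # annotated targets
    n: int  # targets tested
    K: int  # annotated genes in universe
    N: int  # universe size
    p: float
    q: float


def enrich_targets(
    target_set: set[str],
    annotations: GOAnnotationSet,
    universe: Sequence[str],
    q_cutoff: float = 0.05,
    tf_id: str = "",
) -> list[EnrichmentRecord]:
    """Hypergeometric BP enrichment of one target set.

    Candidate terms are those annotating at least one target; p-values are
    BH-adjusted across that candidate family, and records with
    ``q < q_cutoff`` are returned (sorted by q then term id).
    """
    universe_set = set(universe)
    if not universe_set:
        raise AnnotationError("empty universe")
    targets = target_set & universe_set
    if not target_set <= universe_set:
        raise ValidationError("target set must lie within the universe")
    candidate_terms = sorted(
        {t for g in targets for t in annotations.terms_of(g)}
    )
    if not candidate_terms:
        return []
    raw = []
    for term in candidate_terms:
        annotated = annotations.annotated_genes(term) & universe_set
        p = hypergeometric_target_overlap(targets, annotated, universe_set)
        raw.append((term, len(targets & annotated), len(annotated), p))
    q_values = bh_adjust([r[3] for r in raw])
    records = [
        EnrichmentRecord(
            tf_id=tf_id, term_id=term, k=k, n=len(targets), K=K,
            N=len(universe_set), p=p, q=float(q),
        )
        for (term, k, K, p), q in zip(raw, q_values)
        if q < q_cutoff
    ]
    records.sort(key=lambda r: (r.q, r.term_id))
    return records


def infer_tf_functions(
    edges: EdgeList,
    annotations: GOAnnotationSet,
    universe: Sequence[str],
    q_cutoff: float = 0.05,
) -> dict[str, set[str]]:
    """Per-TF enriched BP term sets over its predicted targets."""
    result: dict[str, set[str]] = {}
    for tf, targets in edges.targets_of().items():
        records = enrich_targets(
            set(targets), annotations, universe, q_cutoff, tf_id=tf
        )
        result[tf] = {r.term_id for r in records}
    return result


@dataclass
class RecoveryReport:
    """Per-term recovery of known TF annotations."""

    per_term: pd.DataFrame  # term_id, n_tfs_with_term, n_recovered, recovery_rate
    mean_rate: float
    fraction_terms_above: float
    rate_threshold: float


def recovery_report(
    inferred: Mapping[str, set[str]],
    known: Mapping[str, set[str]],
    rate_threshold: float = 0.05,
) -> RecoveryReport:
    """Recovery rate per term: recovered TFs / TFs annotated with the term.

    A TF is recovered for a term when the term is both in its known
    annotation and among the terms enriched in its predicted targets.
    Terms annotated to zero TFs are omitted.
    """
    term_tfs: dict[str, set[str]] = {}
    for tf, terms in known.items():
        for term in terms:
            term_tfs.setdefault(term, set()).add(tf)
    rows = []
    for term in sorted(term_tfs):
        with_term = term_tfs[term]
        recovered = {tf for tf in with_term if term in inferred.get(tf, set())}
        rows.append((term, len(with_term), len(recovered),
                     len(recovered) / len(with_term)))
    per_term = pd.DataFrame(
        rows, columns=["term_id", "n_tfs_with_term", "n_recovered", "recovery_rate"]
    )
    if len(per_term):
        mean_rate = float(per_term["recovery_rate"].mean())
        frac_above = float((per_term["recovery_rate"] > rate_threshold).mean())
    else:
        mean_rate = 0.0
        frac_above = 0.0
    return RecoveryReport(per_term, mean_rate, frac_above, rate_threshold)


def novel_function_report(
    inferred: Mapping[str, set[str]],
    known: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Enriched-but-unannotated (tf_id, term_id) rows.

    TFs with no known BP annotation at all have every enriched term
    reported and are flagged ``fully_novel``.
    """
    rows = []
    for tf in sorted(inferred):
        known_terms = known.get(tf, set())
        fully_novel = len(known_terms) == 0
        for term in sorted(inferred[tf] - known_terms):
            rows.append((tf, term, fully_novel))
    return pd.DataFrame(rows, columns=["tf_id", "term_id", "fully_novel"])
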