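"""Partition annotated genes into positive / negative / candidate sets.

Positives are the genes listed in the gene–disease table (intersected with
the annotation).  Every other annotated gene is scored by its *relevance*:
the maximum network correlation score over its edges to any positive gene
(0 if it has none).  Genes whose relevance falls below the threshold
(default 1.0) are negatives — weakly connected to the known disease genes,
hence safe non-disease training examples — and the rest are candidates to
be scored by the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelSets:
    """Pairwise-disjoint gene partitions; together a subset of the annotation."""

    positives: frozenset[str]
    negatives: frozenset[str]
    candidates: frozenset[str]
    #: gene-disease / network genes absent from the annotation (reported, unlabeled)
    unannotated: frozenset[str] = field(default=frozenset())

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "positive") for g in sorted(self.positives)] + \
               [(g, "negative") for g in sorted(self.negatives)] + \
               [(g, "candidate") for g in sorted(self.candidates)]
        return pd.DataFrame(rows, columns=["gene_id", "label"])


def build_label_sets(gene_disease: pd.DataFrame, network: pd.DataFrame,
                     annotation: pd.DataFrame, score_threshold: float = 1.0,
                     min_disease_score: float | None = None,
                     isolated: str = "negative") -> LabelSets:
    """Construct the positive / negative / candidate partition.

    Parameters
    ----------
    score_threshold
        Genes whose maximum edge score to a positive is below this are
        negatives; at or above it, candidates.
    min_disease_score
        Optional floor on the gene–disease score for a gene to count as
        positive (default: any listed gene is positive).
    isolated
        Policy for genes with no edge to any positive: ``"negative"``
        (relevance 0 falls below any positive threshold) or ``"candidate"``
        (treat absence of evidence as undetermined).

    Raises
    ------
    ValueError
        If no positive gene survives (training would be impossible), or on
        an invalid threshold/policy.
    """
    if score_threshold <= 0:
        raise ValueError("score_threshold must be positive")
    if isolated not in ("negative", "candidate"):
        raise ValueError(f"unknown isolated-gene policy {isolated!r}")

    annotated = set(annotation["gene_id"])
    listed = gene_disease
    if min_disease_score is not None:
        listed = listed[listed["score"] >= min_disease_score]
    listed_ids = set(listed["gene_id"])
    positives = listed_ids & annotated
    unannotated = listed_ids - annotated
    if not positives:
        raise ValueError("no positive gene is present in the annotation; "
                         "cannot construct a training set")

    # relevance of a non-positive gene: max edge score to any positive
    relevance: dict[str, float] = {}
    for r in network.itertuples(index=False):
        for g, other in ((r.gene_a, r.gene_b), (r.gene_b, r.gene_a)):
            if other in positives and g not in positives:
                if g in annotated:
                    relevance[g] = max(relevance.get(g, 0.0), r.score)
                else:
                    unannotated.add(g)

    negatives, candidates = set(), set()
    for g in annotated - positives:
        if g in relevance:
            (negatives if relevance[g] < score_threshold else candidates).add(g)
        else:
            (negatives if isolated == "negative" else candidates).add(g)
    if unannotated:
        logger.warning("%d gene(s) referenced by the label inputs are absent "
                       "from the annotation and were left unlabeled",
                       len(unannotated))
    return LabelSets(positives=frozenset(positives),
                     negatives=frozenset(negatives),
                     candidates=frozenset(candidates),
                     unannotated=frozenset(unannotated))


def write_labels(label_sets: LabelSets, path) -> None:
    label_sets.to_frame().to_csv(path, sep="\t", index=False)
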