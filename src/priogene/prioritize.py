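"""Candidate-gene scoring and ranking with a trained classifier."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import FittedModel

RANKED_COLUMNS = ["rank", "gene_id", "score", "n_mapped_snps", "selected_snps"]


def predict_candidates(model: FittedModel,
                       candidate_features: pd.DataFrame) -> pd.DataFrame:
    """Score candidate genes and rank them by descending positive-class score.

    ``candidate_features`` is a feature-matrix slice (gene_id index) and may
    carry the provenance columns ``n_mapped_snps`` / ``selected_snps``,
    which are passed through to the output.  Ranking is deterministic: ties
    in the score are broken by gene_id, and ranks run 1..n without gaps.
    """
    if len(candidate_features) == 0:
        raise ValueError("candidate set is empty; nothing to score")
    X = candidate_features.reindex(columns=list(model.feature_columns))
    if X.isna().any().any():
        missing = [c for c in model.feature_columns
                   if c not in candidate_features.columns]
        raise ValueError(f"candidate features lack model columns {missing}")
    scores = model.predict_scores(X)
    out = pd.DataFrame({
        "gene_id": candidate_features.index.astype(str),
        "score": scores,
        "n_mapped_snps": candidate_features.get(
            "n_mapped_snps", pd.Series(np.nan, index=candidate_features.index)
        ).to_numpy(),
        "selected_snps": candidate_features.get(
            "selected_snps", pd.Series("", index=candidate_features.index)
        ).to_numpy(),
    })
    out = out.sort_values(["score", "gene_id"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def top_n(ranked: pd.DataFrame, n: int) -> pd.DataFrame:
    """The head of the ranking (e.g. a top-24 shortlist)."""
    return ranked.head(n).reset_index(drop=True)


def call_novel_genes(ranked: pd.DataFrame, threshold: float = 0.5) -> set[str]:
    """Genes whose positive-class score reaches the probability threshold.

    The returned set shrinks (weakly) as the threshold rises.
    """
    if len(ranked) == 0:
        raise ValueError("ranking is empty")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return set(ranked.loc[ranked["score"] >= threshold, "gene_id"])


def write_ranking(ranked: pd.DataFrame, path, threshold: float | None = None,
                  n_top: int | None = None) -> None:
    """Write the ranked table with a header recording the selection rule."""
    with open(path, "w") as fh:
        if threshold is not None:
            fh.write(f"# selection: score >= {threshold}\n")
        if n_top is not None:
            fh.write(f"# selection: top {n_top}\n")
        ranked[RANKED_COLUMNS].to_csv(fh, sep="\t", index=False)
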