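"""End-to-end glue: synthetic study -> features -> labels -> CV -> ranking.

These helpers wire the individual modules together exactly as the CLI does,
and are what the calibration experiments and the reproduction script run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import (ClassifierSpec, CvReport, FittedModel, cross_validate,
                       train_final)
from .features import build_feature_matrix
from .labels import LabelSets, build_label_sets
from .prioritize import predict_candidates
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset


@dataclass
class TrainingTable:
    """Feature matrix rows admitted to training, with binary labels
    (1 = positive / disease gene, 0 = negative)."""

    X: pd.DataFrame                 # feature columns only, gene_id index
    y: np.ndarray
    feature_columns: list[str]


def feature_columns_of(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns
            if c not in ("n_mapped_snps", "selected_snps")]


def make_training_table(features: pd.DataFrame,
                        label_sets: LabelSets) -> TrainingTable:
    """Intersect the admitted (>=1 mapped SNP) genes with the labeled sets."""
    cols = feature_columns_of(features)
    genes = [g for g in features.index
             if g in label_sets.positives or g in label_sets.negatives]
    if not genes:
        raise ValueError("no labeled gene has an admissible feature vector")
    y = np.array([1 if g in label_sets.positives else 0 for g in genes])
    return TrainingTable(X=features.loc[genes, cols], y=y, feature_columns=cols)


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    features: pd.DataFrame
    excluded_genes: list[str]
    label_sets: LabelSets
    training: TrainingTable
    report: CvReport


def evaluate_synthetic(config: SimulationConfig,
                       spec: ClassifierSpec = ClassifierSpec("random_forest"),
                       k: int = 10, cv_seed: int | None = None,
                       permute_labels: bool = False,
                       permutation_seed: int = 0) -> PipelineResult:
    """Simulate a study and cross-validate the classifier on it.

    ``permute_labels`` destroys the feature–label association (a null
    calibration run) while keeping the class balance and fold structure.
    """
    ds = simulate_dataset(config)
    features, excluded = build_feature_matrix(ds.annotation, ds.gwas, ds.eqtl)
    label_sets = build_label_sets(ds.gene_disease, ds.network, ds.annotation)
    training = make_training_table(features, label_sets)
    y = training.y
    if permute_labels:
        y = np.random.default_rng(permutation_seed).permutation(y)
    seed = config.seed if cv_seed is None else cv_seed
    report = cross_validate(training.X, y, spec, k=k, seed=seed)
    return PipelineResult(dataset=ds, features=features,
                          excluded_genes=excluded, label_sets=label_sets,
                          training=training, report=report)


@dataclass
class RankingResult:
    model: FittedModel
    ranked: pd.DataFrame
    unscorable: list[str]           # candidates with no admissible feature vector
    causal_candidates: set[str]     # planted causal genes hidden among candidates


def rank_synthetic_candidates(result: PipelineResult,
                              spec: ClassifierSpec = ClassifierSpec("random_forest"),
                              seed: int = 0) -> RankingResult:
    """Train the final model on positives vs negatives and rank the candidates."""
    model = train_final(result.training.X, result.training.y, spec, seed=seed)
    cand = sorted(result.label_sets.candidates)
    scorable = [g for g in cand if g in result.features.index]
    unscorable = [g for g in cand if g not in result.features.index]
    ranked = predict_candidates(model, result.features.loc[scorable])
    causal = result.dataset.truth.causal_genes & set(scorable)
    return RankingResult(model=model, ranked=ranked, unscorable=unscorable,
                         causal_candidates=causal)
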