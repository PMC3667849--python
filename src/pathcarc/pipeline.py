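"""End-to-end pipeline: synthetic study -> features -> model -> ROC.

Glue used by the worked example, the acceptance script and the heavier
simulation tests; each stage is the corresponding module's public surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import enrichment, evaluation, pathways, prediction
from .carcinogenicity import binary_call
from .synthetic import GeneratorConfig, GroundTruth, generate_cross_species_panel, generate_study

__all__ = [
    "study_feature_matrix",
    "bioassay_targets",
    "StudyOutcome",
    "run_study",
    "cross_species_scores",
]


def study_feature_matrix(
    truth: GroundTruth,
    species: str | None = None,
    K: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Chemicals x pathways z-feature matrix for one species of a study."""
    species = species or truth.config.reference_species
    collection = truth.collections[species]
    weightings = {pid: pathways.node_weights(net) for pid, net in collection.items()}
    dists = {pid: pathways.pairwise_distances(net) for pid, net in collection.items()}
    score_tables = {}
    for chem in truth.chemicals:
        if species not in chem.expression:
            raise ValueError(
                f"no {species} expression for {chem.chemical_id}; "
                "run generate_cross_species_panel first"
            )
        score_tables[chem.chemical_id] = enrichment.gene_scores(chem.expression[species])
    return enrichment.pathway_feature_matrix(
        collection, weightings, dists, score_tables, truth.panel, K=K, seed=seed
    )


def bioassay_targets(truth: GroundTruth) -> tuple:
    """(capped z target Series, binary call Series) from the study bioassays."""
    targets = {}
    calls = {}
    for chem in truth.chemicals:
        tgt = binary_call(chem.bioassay)
        targets[chem.chemical_id] = tgt.z_capped
        calls[chem.chemical_id] = tgt.call
    return pd.Series(targets, name="z_capped"), pd.Series(calls, name="call")


@dataclass
class StudyOutcome:
    truth: GroundTruth
    features: pd.DataFrame
    targets: pd.Series
    calls: pd.Series
    results: prediction.PathwayCarcinogenicityResults
    honest_auc: float


def run_study(
    config: GeneratorConfig,
    K: int = 1000,
    selector: str = "discrete",
    library=None,
) -> StudyOutcome:
    """Generate a study, fit the model, and score honest predictions.

    The ROC labels are the poly-3 binary calls (one-sided p <= 0.01) of the
    simulated bioassays, exactly the thresholding the prediction target uses.
    """
    truth = generate_study(config)
    X = study_feature_matrix(truth, K=K, seed=config.seed)
    y, calls = bioassay_targets(truth)
    model = prediction.PathwayCarcinogenicityModel(
        X, y, library=library, seed=config.seed
    )
    results = model.fit(selector=selector)
    scored = evaluation.LabeledScores(
        list(X.index), list(results.honest.loc[X.index]), list(calls.loc[X.index])
    )
    return StudyOutcome(truth, X, y, calls, results, evaluation.roc_auc(scored))


def cross_species_scores(
    outcome: StudyOutcome,
    species: str,
    K: int = 1000,
) -> evaluation.LabeledScores:
    """Predict another species' panel with the mouse-fitted model.

    Ground-truth carcinogen flags label the instances for ROC use.
    """
    truth = outcome.truth
    generate_cross_species_panel(truth, species)
    X_new = study_feature_matrix(truth, species=species, K=K, seed=truth.config.seed)
    X_new = X_new.loc[:, outcome.features.columns]
    preds = outcome.results.predict(X_new)
    labels = truth.labels
    return evaluation.LabeledScores(
        list(X_new.index),
        [float(preds[c]) for c in X_new.index],
        [labels[c] for c in X_new.index],
    )
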