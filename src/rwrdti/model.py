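"""Model/Results interface tying the pipeline together.

:class:`DTIPropagationModel` is built from data (known interactions, drug
fingerprints, protein descriptors and the two interactomes) plus the
weighting configuration; :meth:`DTIPropagationModel.fit` weights the
features, samples the replicate negative sets and trains one cubic-kNN
classifier per replicate, returning a :class:`DTIPropagationResults` that
scores new pairs, evaluates held-out sets and prints a summary table.

Typical use::

    world = generate_world(rng_seed=7)
    model = DTIPropagationModel.from_world(world, weighting="rwr", restart_c=0.25)
    res = model.fit(rng_seed=7)
    report = res.evaluate_world(world, rng_seed=7)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .containers import AffinityMatrix, BipartiteDTI, FeatureMatrix, InteractionNetwork
from .dti_model import (
    CubicKNN,
    DEFAULT_SCORE_THRESHOLD,
    PairDataset,
    build_pair_dataset,
    make_pair_vectors,
)
from .evaluation import EvalReport, cross_validate, evaluate_on_test, roc_auc
from .propagation import RWRConfig, affinity_matrix, gba_weighting, weight_features

__all__ = ["DTIPropagationModel", "DTIPropagationResults", "sample_test_negatives"]


def sample_test_negatives(
    train_dti: BipartiteDTI,
    test_dti: BipartiteDTI,
    n: int | None = None,
    rng_seed: int = 0,
) -> list[tuple[str, str]]:
    """Random (drug, protein) pairs disjoint from both the training and the
    held-out positives, over the training entity sets. Defaults to as many
    negatives as there are held-out positives."""
    drugs = train_dti.drug_ids
    prots = train_dti.protein_ids
    forbidden = set(train_dti.pairs) | set(test_dti.pairs)
    if n is None:
        n = test_dti.n_pairs
    available = len(drugs) * len(prots) - len(forbidden)
    if available < n:
        raise ValueError(f"only {available} candidate negatives for n={n}")
    rng = np.random.default_rng(rng_seed)
    chosen: set[tuple[str, str]] = set()
    ordered: list[tuple[str, str]] = []
    n_p = len(prots)
    while len(ordered) < n:
        for flat in rng.integers(0, len(drugs) * n_p, size=2 * (n - len(ordered))):
            pair = (drugs[flat // n_p], prots[flat % n_p])
            if pair in forbidden or pair in chosen:
                continue
            chosen.add(pair)
            ordered.append(pair)
            if len(ordered) == n:
                break
    return ordered


class DTIPropagationModel:
    """Drug-target interaction classifier with network-weighted features.

    Parameters
    ----------
    dti : known positive (drug, protein) pairs used for training.
    drug_features : binary fingerprint matrix (one row per drug).
    protein_features : descriptor matrix (one row per protein).
    ppi, ddi : the interactomes the random walk runs on. The DDI network
        defaults to the shared-target construction from ``dti``; entities
        present in the feature matrices/DTI but absent from a network are
        added as isolated nodes (their features pass through unchanged).
    weighting : ``"rwr"`` (affinity-matrix product), ``"gba"`` (one-hop
        guilt-by-association baseline) or ``"none"`` (raw features).
    restart_c : restart probability for RWR weighting (default 0.25).
    knn_k : neighbors of the cubic kNN.
    n_negative_sets : replicate negative sets sampled at fit time.
    """

    def __init__(
        self,
        dti: BipartiteDTI,
        drug_features: FeatureMatrix,
        protein_features: FeatureMatrix,
        ppi: InteractionNetwork | None = None,
        ddi: InteractionNetwork | None = None,
        weighting: str = "rwr",
        restart_c: float = 0.25,
        rwr_config: RWRConfig | None = None,
        gba_self_weight: float = 1.0,
        knn_k: int = 10,
        n_negative_sets: int = 20,
        score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    ) -> None:
        if weighting not in {"rwr", "gba", "none"}:
            raise ValueError("weighting must be 'rwr', 'gba' or 'none'")
        from .io import build_ddi_shared_target

        self.dti = dti
        self.drug_features = drug_features
        self.protein_features = protein_features
        self.ddi = ddi if ddi is not None else build_ddi_shared_target(dti)
        self.ppi = ppi
        self.weighting = weighting
        self.rwr_config = rwr_config or RWRConfig(restart_c=restart_c)
        self.gba_self_weight = gba_self_weight
        self.knn_k = knn_k
        self.n_negative_sets = n_negative_sets
        self.score_threshold = score_threshold

    @classmethod
    def from_world(cls, world, protein_features: FeatureMatrix | None = None, **kwargs):
        """Build from a :class:`~rwrdti.synthetic.SyntheticWorld`, computing
        protein descriptors from its sequences unless supplied."""
        if protein_features is None:
            from .descriptors import descriptor_matrix

            protein_features = descriptor_matrix(world.sequences)
        return cls(
            world.dti,
            world.fingerprints,
            protein_features,
            ppi=world.ppi,
            ddi=world.ddi,
            **kwargs,
        )

    # -- feature weighting -------------------------------------------------

    def _extended(self, net: InteractionNetwork | None, ids: Sequence[str]):
        if net is None:
            return None
        extra = [i for i in ids if i not in net]
        return net.with_nodes(extra) if extra else net

    def weighted_features(self) -> tuple[FeatureMatrix, FeatureMatrix]:
        """Apply the configured weighting to both feature matrices."""
        if self.weighting == "none":
            return self.drug_features, self.protein_features
        ddi = self._extended(self.ddi, self.dti.drug_ids)
        ppi = (
            self._extended(self.ppi, self.dti.protein_ids)
            if self.ppi is not None
            else None
        )
        if self.weighting == "rwr":
            drug_w = weight_features(affinity_matrix(ddi, self.rwr_config), self.drug_features)
            if ppi is not None:
                prot_w = weight_features(
                    affinity_matrix(ppi, self.rwr_config), self.protein_features
                )
            else:
                prot_w = self.protein_features
            return drug_w, prot_w
        # guilt-by-association baseline
        drug_w = gba_weighting(ddi, self.drug_features, self.gba_self_weight)
        prot_w = (
            gba_weighting(ppi, self.protein_features, self.gba_self_weight)
            if ppi is not None
            else self.protein_features
        )
        return drug_w, prot_w

    # -- fitting -----------------------------------------------------------

    def fit(self, rng_seed: int = 0) -> "DTIPropagationResults":
        """Weight features, sample the replicate negative sets and train one
        cubic kNN per replicate."""
        drug_w, prot_w = self.weighted_features()
        dataset = build_pair_dataset(
            self.dti,
            drug_w,
            prot_w,
            n_negative_sets=self.n_negative_sets,
            rng_seed=rng_seed,
        )
        models = []
        for j in range(dataset.n_negative_sets):
            Xr, yr = dataset.replicate(j)
            models.append(
                CubicKNN(k=self.knn_k, threshold=self.score_threshold).fit(Xr, yr)
            )
        return DTIPropagationResults(self, dataset, models, drug_w, prot_w, rng_seed)

    # -- restart-probability sweep ------------------------------------------

    def sweep_restart_c(
        self,
        c_grid: Sequence[float],
        test_pairs: Sequence[tuple[str, str]] | None = None,
        test_labels: Sequence[int] | None = None,
        rng_seed: int = 0,
        cv_folds: int = 5,
    ):
        """Full weight -> train -> evaluate pipeline per restart probability.

        Returns a DataFrame with one row per ``c`` (sorted ascending):
        the mean cross-validated training AUC and, if a held-out labeled
        pair set is given, the mean test AUC across replicates. At c = 1
        the affinity matrix is the identity, so that row reproduces the
        unweighted model exactly.
        """
        import pandas as pd

        rows = []
        for c in sorted(c_grid):
            m = DTIPropagationModel(
                self.dti,
                self.drug_features,
                self.protein_features,
                ppi=self.ppi,
                ddi=self.ddi,
                weighting="rwr",
                rwr_config=RWRConfig(
                    restart_c=c,
                    tolerance=self.rwr_config.tolerance,
                    max_iter=self.rwr_config.max_iter,
                ),
                knn_k=self.knn_k,
                n_negative_sets=self.n_negative_sets,
            )
            res = m.fit(rng_seed=rng_seed)
            train = res.cross_validation(n_folds=cv_folds, rng_seed=rng_seed)
            row = {"c": c, "train_auc": train.mean_auc}
            if test_pairs is not None:
                rep = res.evaluate(test_pairs, test_labels)
                row["test_auc"] = rep.mean_auc
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class DTIPropagationResults:
    """Fitted replicate kNN models plus the weighted feature space.

    All scoring happens in the weighted feature space of the parent model:
    a query pair is vectorized with the same weighted drug/protein rows the
    models were trained on, scored by every replicate model, and the scores
    averaged.
    """

    model: DTIPropagationModel
    dataset: PairDataset
    knn_models: list[CubicKNN]
    drug_features_w: FeatureMatrix
    protein_features_w: FeatureMatrix
    rng_seed: int

    def pair_vectors(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        kept, X = make_pair_vectors(
            pairs, self.drug_features_w, self.protein_features_w, strict=True
        )
        return X

    def score_pairs(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """Mean kNN positive-fraction score across replicate models."""
        X = self.pair_vectors(pairs)
        return np.mean([m.score_samples(X) for m in self.knn_models], axis=0)

    def predict_pairs(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        return (self.score_pairs(pairs) >= self.model.score_threshold).astype(int)

    # -- evaluation ---------------------------------------------------------

    def evaluate(
        self,
        pairs: Sequence[tuple[str, str]],
        labels: Sequence[int],
    ) -> EvalReport:
        """AUC of each replicate model on a fixed labeled pair set."""
        X = self.pair_vectors(pairs)
        y = np.asarray(labels, dtype=int)
        return evaluate_on_test(self.dataset, X, y, k=self.model.knn_k)

    def evaluate_world(self, world, rng_seed: int = 0) -> EvalReport:
        """Evaluate on a synthetic world's held-out positives plus an equal
        number of freshly sampled negatives."""
        negs = sample_test_negatives(world.dti, world.test_dti, rng_seed=rng_seed)
        pairs = world.test_dti.sorted_pairs() + negs
        labels = [1] * world.test_dti.n_pairs + [0] * len(negs)
        return self.evaluate(pairs, labels)

    def cross_validation(self, n_folds: int = 10, rng_seed: int = 0) -> EvalReport:
        """Per-replicate mean cross-validated training AUC."""
        aucs = []
        for j in range(self.dataset.n_negative_sets):
            Xr, yr = self.dataset.replicate(j)
            rep = cross_validate(
                Xr, yr, n_folds=n_folds, rng_seed=rng_seed, k=self.model.knn_k
            )
            aucs.append(rep.mean_auc)
        return EvalReport(aucs, [], {"n_folds": n_folds, "rng_seed": rng_seed})

    def resubstitution(self) -> EvalReport:
        """Per-replicate AUC of each model on its own training data."""
        aucs = []
        for j, m in enumerate(self.knn_models):
            Xr, yr = self.dataset.replicate(j)
            a, _ = roc_auc(m.score_samples(Xr), yr)
            aucs.append(a)
        return EvalReport(aucs, [], {"mode": "resubstitution"})

    # -- reporting ----------------------------------------------------------

    def summary(self, test_report: EvalReport | None = None) -> str:
        """Human-readable fit summary (statsmodels-style text table)."""
        m = self.model
        lines = [
            "      DTI propagation model — cubic kNN on weighted features",
            "=" * 68,
            f"{'weighting:':<24}{m.weighting}"
            + (f" (c = {m.rwr_config.restart_c})" if m.weighting == "rwr" else ""),
            f"{'drugs / proteins:':<24}{m.drug_features.n_entities} / "
            f"{m.protein_features.n_entities}",
            f"{'positive pairs:':<24}{m.dti.n_pairs}",
            f"{'negative replicates:':<24}{self.dataset.n_negative_sets} "
            f"x {m.dti.n_pairs} pairs",
            f"{'pair vector width:':<24}{self.dataset.n_features} "
            f"({m.drug_features.n_features} drug + "
            f"{m.protein_features.n_features} protein)",
            f"{'kNN neighbors (k):':<24}{m.knn_k}",
            f"{'score threshold:':<24}{m.score_threshold}",
            f"{'fit rng seed:':<24}{self.rng_seed}",
        ]
        if test_report is not None:
            lines += [
                "-" * 68,
                f"{'held-out AUC:':<24}{test_report.mean_auc:.4f} "
                f"(+/- {test_report.sd_auc:.4f}, "
                f"{len(test_report.auc_per_negative_set)} replicates)",
            ]
        lines.append("=" * 68)
        return "\n".join(lines)
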