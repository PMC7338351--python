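"""Greedy adaptive search for interacting feature networks.

Given an importance-ranked candidate list (top-M SNPs followed by the
demographic features of one risk-factor group), the search selects the
subset — a "feature network" — that maximizes average precision on held-out
validation data.  The procedure is greedy forward selection in rank order:
the top candidate seeds the network, each remaining candidate is accepted
iff refitting the classifier from scratch on the enlarged set improves
validation AP by more than ``epsilon`` (default 0, i.e. strict improvement).
Each examined candidate costs one full refit; nothing is cached, so the
runtime is bounded by one fit per candidate.

Selection against validation data is what lets genuinely interacting
features in: a feature that is uninformative alone but informative jointly
with an already-selected one improves the refit score and is kept, while a
redundant or noise feature is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CombinedFeatureMatrix, FeatureDescriptor
from .engine import HyperParams, fit, predict
from .metrics import average_precision_score

__all__ = ["FeatureNetwork", "concat_candidates", "adaptive_search"]


class SearchError(ValueError):
    pass


@dataclass
class FeatureNetwork:
    """An ordered selected feature subset and the validation AP it achieved."""

    features: list[FeatureDescriptor]
    validation_ap: float
    trace: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.features]

    def to_dict(self) -> dict:
        return {
            "features": [
                {"source": d.source, "name": d.name, "group": d.group}
                for d in self.features
            ],
            "validation_ap": self.validation_ap,
            "trace": self.trace,
            "provenance": self.provenance,
        }


def concat_candidates(
    ranked_snps,
    m: int,
    group_features: list[FeatureDescriptor],
) -> list[FeatureDescriptor]:
    """Top-m SNPs in rank order, then the group's demographic features."""
    if m <= 0:
        raise SearchError(f"top-SNP count m must be positive, got {m}")
    if m > len(ranked_snps):
        raise SearchError(
            f"m={m} exceeds the ranked list length {len(ranked_snps)}"
        )
    return [rf.descriptor for rf in ranked_snps[:m]] + list(group_features)


def adaptive_search(
    candidates: list[FeatureDescriptor],
    train: CombinedFeatureMatrix,
    train_labels: np.ndarray,
    validation: CombinedFeatureMatrix,
    validation_labels: np.ndarray,
    params: HyperParams,
    epsilon: float = 0.0,
    seed: int = 0,
) -> FeatureNetwork:
    """Greedy forward selection over ``candidates`` in list order.

    ``train``/``validation`` are designs over the full candidate set (their
    descriptors must contain every candidate); subsets are taken by column.
    Returns the selected network, its validation AP, and the full
    acceptance trace.  The result's AP never falls below the AP of the top
    candidate alone.
    """
    if not candidates:
        raise SearchError("candidate list is empty")
    val_labels = np.asarray(validation_labels)
    if len(np.unique(val_labels)) < 2:
        raise SearchError("validation subset contains a single class")

    def score(names: list[str]) -> float:
        model = fit(train, train_labels, params, feature_subset=names, seed=seed)
        val_design = _subset(validation, names)
        return average_precision_score(predict(model, val_design), val_labels)

    selected = [candidates[0]]
    best = score([candidates[0].name])
    trace = [
        {
            "candidate": candidates[0].name,
            "validation_ap": best,
            "accepted": True,
            "network_size": 1,
        }
    ]
    for cand in candidates[1:]:
        trial = [d.name for d in selected] + [cand.name]
        ap = score(trial)
        accepted = ap > best + epsilon
        if accepted:
            selected.append(cand)
            best = ap
        trace.append(
            {
                "candidate": cand.name,
                "validation_ap": ap,
                "accepted": accepted,
                "network_size": len(selected),
            }
        )
    return FeatureNetwork(features=selected, validation_ap=best, trace=trace)


def _subset(design: CombinedFeatureMatrix, names: list[str]) -> CombinedFeatureMatrix:
    index = {d.name: j for j, d in enumerate(design.descriptors)}
    try:
        cols = [index[n] for n in names]
    except KeyError as exc:
        raise SearchError(f"candidate {exc.args[0]!r} missing from design") from None
    return design.subset_columns(cols)
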