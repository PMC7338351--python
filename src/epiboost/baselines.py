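"""Comparison systems: polygenic risk score and fixed-feature-list models.

The PRS is the classical weighted allele-dosage sum: for subject s,

    score_s = sum_j d_sj * ln(OR_j)

where d_sj counts copies of SNP j's effect (risk) allele and OR_j is its
published per-allele odds ratio.  When the effect allele is the declared
major allele the additive code is flipped (d = 2 - code).  The score is used
directly as a ranking statistic — no intercept, no refitting — and evaluated
by average precision.

The fixed-feature-list model trains the boosted-tree classifier on a given
feature set (published SNPs, a demographic group, or their union) under the
same split plan as the discovery pipeline, but with no ranking and no
adaptive search — the feature set never changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, GenotypeMatrix, MISSING_CODE, assemble_features
from .engine import HyperParamGrid, HyperParams, fit, predict, tune_sequential
from .metrics import APScore, average_precision, mean_ap, pr_curve
from .pipeline import SplitPlan

__all__ = [
    "PRSWeights",
    "load_prs_weights",
    "prs_scores",
    "evaluate_prs",
    "fixed_feature_model",
]

logger = logging.getLogger(__name__)


class BaselineError(ValueError):
    pass


@dataclass
class PRSWeights:
    """Published SNP effect alleles and odds ratios (one row per SNP)."""

    snp_ids: list[str]
    effect_alleles: list[str]
    odds_ratios: np.ndarray

    def __post_init__(self) -> None:
        self.odds_ratios = np.asarray(self.odds_ratios, dtype=float)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise BaselineError("duplicate SNP ids in PRS weights")
        if not np.all(np.isfinite(self.odds_ratios)) or (self.odds_ratios <= 0).any():
            raise BaselineError("odds ratios must be finite and positive")

    def __len__(self) -> int:
        return len(self.snp_ids)


def load_prs_weights(path: str | Path) -> PRSWeights:
    """Read the weights TSV: columns snp_id, effect_allele, OR."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_id", "effect_allele", "OR"):
        if col not in df.columns:
            raise BaselineError(f"{path}: missing column {col!r}")
    return PRSWeights(
        snp_ids=df["snp_id"].astype(str).tolist(),
        effect_alleles=df["effect_allele"].astype(str).tolist(),
        odds_ratios=df["OR"].to_numpy(),
    )


def prs_scores(gm: GenotypeMatrix, weights: PRSWeights) -> np.ndarray:
    """Weighted effect-allele dosage sum per subject.

    Weighted SNPs absent from the genotype panel are skipped with a logged
    count; an effect allele matching neither declared allele of a present
    SNP is an error.  Missing calls contribute 0 for that SNP.
    """
    index = {s.snp_id: j for j, s in enumerate(gm.snps)}
    scores = np.zeros(gm.n_subjects)
    skipped = 0
    for snp_id, allele, oratio in zip(
        weights.snp_ids, weights.effect_alleles, weights.odds_ratios
    ):
        j = index.get(snp_id)
        if j is None:
            skipped += 1
            continue
        snp = gm.snps[j]
        codes = gm.codes[:, j].astype(float)
        observed = codes != MISSING_CODE
        if allele == snp.minor_allele:
            dosage = codes
        elif allele == snp.major_allele:
            dosage = 2.0 - codes
        else:
            raise BaselineError(
                f"effect allele {allele!r} of {snp_id} matches neither declared "
                f"allele ({snp.major_allele}/{snp.minor_allele})"
            )
        scores[observed] += dosage[observed] * math.log(oratio)
    if skipped:
        logger.warning(
            "%d of %d weighted SNPs absent from the genotype panel; skipped",
            skipped,
            len(weights),
        )
    return scores


def evaluate_prs(scores: np.ndarray, labels: np.ndarray) -> APScore:
    """AP of the raw PRS as a ranking statistic (no refitting)."""
    return average_precision(pr_curve(scores, labels))


def fixed_feature_model(
    cohort: Cohort,
    feature_names: list[str],
    plan: SplitPlan,
    grid: HyperParamGrid | None = None,
    params: HyperParams | None = None,
    seed: int = 0,
    tune_folds: int = 5,
) -> tuple[float, float, list[float]]:
    """mAP +- std of a classifier trained on a fixed feature list.

    ``feature_names`` may mix SNP ids and demographic names.  Per split the
    model is tuned (unless ``params`` fixes the setting), fit on
    train+validation, and scored on the test fold.  Returns
    (mAP, std, per-split APs).
    """
    if not feature_names:
        raise BaselineError("fixed feature list is empty")
    snp_set = set(cohort.genotypes.snp_ids)
    demog_set = {f.name for f in cohort.demographics}
    snps = [n for n in feature_names if n in snp_set]
    demogs = [n for n in feature_names if n in demog_set]
    unknown = [n for n in feature_names if n not in snp_set and n not in demog_set]
    if unknown:
        raise BaselineError(f"unknown features in fixed list: {unknown[:5]}")

    y = cohort.labels
    fit_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    aps: list[float] = []
    for split in plan:
        trainval = split.train_val
        design_tv = assemble_features(cohort, snps, demogs, trainval, trainval)
        design_te = assemble_features(cohort, snps, demogs, split.test, trainval)
        if params is None:
            split_params, _ = tune_sequential(
                design_tv, y[trainval], grid=grid, folds=tune_folds,
                seed=fit_seed + split.rep,
            )
        else:
            split_params = params
        model = fit(design_tv, y[trainval], split_params, seed=fit_seed)
        prob = predict(model, design_te)
        aps.append(average_precision(pr_curve(prob, y[split.test])).value)
    m, s = mean_ap(aps)
    return m, s, aps
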