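"""Orchestration: repeated stratified splits, per-split network discovery,
test evaluation, mAP aggregation, leave-one-out importance, and sensitivity
sweeps.

One experiment is K1 repetitions of stratified K2-fold cross-validation
(defaults 10 x 5 = 50 splits).  Within a repetition, each outer fold in turn
is the test set; one stratified inner fold (1/K2) of the remaining data is
held out as validation and the rest is the training set, so the three
subject sets are pairwise disjoint and the outer geometry is 80:20 at K2=5.
Per split the pipeline

1. tunes hyperparameters (once per repetition by default),
2. ranks all SNPs on the training set by ensemble gain importance,
3. concatenates the top-M SNPs with the chosen demographic group,
4. runs the greedy adaptive search against the validation set,
5. refits on train+validation with the selected network and scores average
   precision on the test fold.

The mAP over all K1*K2 test folds, its sample standard deviation, and the
per-feature selection counts summarize the run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .cohort import Cohort, assemble_features, filter_missing_snps
from .engine import (
    HyperParamGrid,
    HyperParams,
    fit,
    predict,
    rank_features,
    tune_sequential,
)
from .metrics import average_precision_score, mean_ap
from .search import FeatureNetwork, adaptive_search, concat_candidates

__all__ = [
    "Split",
    "SplitPlan",
    "SplitResult",
    "PipelineResult",
    "make_splits",
    "run_pipeline",
    "leave_one_out_importance",
    "sensitivity_sweep",
]

#: smallest admissible test fold in a custom split geometry
MIN_TEST_SIZE = 3


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class Split:
    rep: int
    fold: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise PipelineError(
                f"split (rep {self.rep}, fold {self.fold}): subject index sets overlap"
            )

    @property
    def train_val(self) -> np.ndarray:
        return np.concatenate([self.train, self.validation])


@dataclass
class SplitPlan:
    splits: list[Split]
    k1: int
    k2: int
    seed: int

    def __iter__(self):
        return iter(self.splits)

    def __len__(self) -> int:
        return len(self.splits)


def make_splits(labels, k1: int, k2: int, seed: int = 0) -> SplitPlan:
    """K1 independent stratified K2-fold partitions with an inner validation
    fold carved out of each outer training portion."""
    y = np.asarray(labels)
    for cls in (0, 1):
        if (y == cls).sum() < k2:
            raise PipelineError(
                f"class {cls} has only {(y == cls).sum()} subjects; "
                f"needs at least k2={k2}"
            )
    states = np.random.SeedSequence(seed).generate_state(2 * k1) % (2**31)
    splits: list[Split] = []
    for i in range(k1):
        outer = StratifiedKFold(n_splits=k2, shuffle=True, random_state=int(states[2 * i]))
        inner = StratifiedKFold(
            n_splits=k2, shuffle=True, random_state=int(states[2 * i + 1])
        )
        for j, (trainval, test) in enumerate(outer.split(y, y)):
            yt = y[trainval]
            min_class = min((yt == 0).sum(), (yt == 1).sum())
            if min_class >= k2:
                rest_rel, val_rel = next(iter(inner.split(yt, yt)))
            else:
                # degenerate small cohort: plain 1/k2 holdout for validation
                rng = np.random.default_rng(int(states[2 * i + 1]))
                perm = rng.permutation(len(trainval))
                n_val = max(1, len(trainval) // k2)
                val_rel, rest_rel = perm[:n_val], perm[n_val:]
            splits.append(
                Split(
                    rep=i,
                    fold=j,
                    train=trainval[rest_rel],
                    validation=trainval[val_rel],
                    test=test,
                )
            )
    return SplitPlan(splits=splits, k1=k1, k2=k2, seed=seed)


@dataclass
class SplitResult:
    split: Split
    network: FeatureNetwork
    test_ap: float
    train_ap: float
    params: HyperParams


@dataclass
class PipelineResult:
    splits: list[SplitResult]
    map_test: float
    std_test: float
    map_validation: float
    std_validation: float
    selection_counts: Counter
    group: str
    m: int
    seed: int
    provenance: str = ""
    params_per_rep: dict[int, HyperParams] = field(default_factory=dict)

    @property
    def test_aps(self) -> list[float]:
        return [s.test_ap for s in self.splits]

    @property
    def validation_aps(self) -> list[float]:
        return [s.network.validation_ap for s in self.splits]

    @property
    def networks(self) -> list[FeatureNetwork]:
        return [s.network for s in self.splits]

    def selected_features(self) -> pd.DataFrame:
        """Union of selected features with selection counts, descending."""
        rows = [
            {"feature": name, "count": count}
            for name, count in self.selection_counts.most_common()
        ]
        return pd.DataFrame(rows, columns=["feature", "count"])

    def to_dict(self) -> dict:
        return {
            "map_test": self.map_test,
            "std_test": self.std_test,
            "map_validation": self.map_validation,
            "std_validation": self.std_validation,
            "group": self.group,
            "m": self.m,
            "seed": self.seed,
            "provenance": self.provenance,
            "test_aps": self.test_aps,
            "networks": [s.network.to_dict() for s in self.splits],
            "selection_counts": dict(self.selection_counts),
        }


def _resolve_group_names(cohort: Cohort, group: str) -> list[str]:
    if group not in ("group1", "group2", "both", "none"):
        raise PipelineError(f"unknown group {group!r}")
    if group == "none":
        return []
    return [f.name for f in cohort.group_features(group)]


def run_pipeline(
    cohort: Cohort,
    group: str = "group1",
    m: int = 18,
    k1: int = 10,
    k2: int = 5,
    grid: HyperParamGrid | None = None,
    params: HyperParams | None = None,
    epsilon: float = 0.0,
    seed: int = 0,
    tune_per: str = "repetition",
    tune_folds: int = 5,
    plan: SplitPlan | None = None,
) -> PipelineResult:
    """Run the full discovery pipeline; see the module docstring.

    ``params`` fixes the hyperparameters and skips tuning entirely;
    otherwise ``grid`` (default: the full published search ranges) is tuned
    once per repetition on that repetition's first training set, or per
    fold with ``tune_per='fold'``.  ``group='both'`` concatenates Group 1
    and Group 2 features after the SNPs (typically with a smaller ``m``);
    ``group='none'`` runs a SNP-only discovery.
    """
    gm, _removed = filter_missing_snps(cohort.genotypes)
    if m > gm.n_snps:
        raise PipelineError(f"m={m} exceeds the {gm.n_snps} complete SNPs available")
    snp_ids = gm.snp_ids
    group_names = _resolve_group_names(cohort, group)
    filtered = Cohort(
        genotypes=gm,
        demographics=cohort.demographics,
        labels=cohort.labels,
        provenance=cohort.provenance,
    )
    if plan is None:
        plan = make_splits(cohort.labels, k1, k2, seed)

    y = cohort.labels
    results: list[SplitResult] = []
    params_per_rep: dict[int, HyperParams] = {}
    fit_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))

    for split in plan:
        try:
            split_params = _params_for_split(
                filtered, snp_ids, group_names, split, params, grid,
                tune_per, tune_folds, fit_seed, params_per_rep,
            )
            # rank all SNPs on the training set
            snp_train = assemble_features(
                filtered, snp_ids, [], split.train, scaler_source=split.train
            )
            ranked = rank_features(snp_train, y[split.train], split_params, seed=fit_seed)
            ranked_snps = [rf for rf in ranked if rf.descriptor.source == "snp"]
            group_desc = assemble_features(
                filtered, [], group_names, split.train, scaler_source=split.train
            ).descriptors
            candidates = concat_candidates(ranked_snps, m, group_desc)

            cand_snps = [d.name for d in candidates if d.source == "snp"]
            train_design = assemble_features(
                filtered, cand_snps, group_names, split.train, split.train
            )
            val_design = assemble_features(
                filtered, cand_snps, group_names, split.validation, split.train
            )
            network = adaptive_search(
                candidates,
                train_design,
                y[split.train],
                val_design,
                y[split.validation],
                split_params,
                epsilon=epsilon,
                seed=fit_seed,
            )
            network.provenance = {
                "rep": split.rep,
                "fold": split.fold,
                "candidates": [d.name for d in candidates],
            }
            test_ap, train_ap = _refit_and_score(
                filtered, network, split, y, split_params, fit_seed
            )
            results.append(
                SplitResult(
                    split=split,
                    network=network,
                    test_ap=test_ap,
                    train_ap=train_ap,
                    params=split_params,
                )
            )
        except (PipelineError, ValueError) as exc:
            raise PipelineError(
                f"(rep {split.rep}, fold {split.fold}): {exc}"
            ) from exc

    counts = Counter()
    for r in results:
        counts.update(r.network.names)
    map_test, std_test = mean_ap([r.test_ap for r in results])
    map_val, std_val = mean_ap([r.network.validation_ap for r in results])
    return PipelineResult(
        splits=results,
        map_test=map_test,
        std_test=std_test,
        map_validation=map_val,
        std_validation=std_val,
        selection_counts=counts,
        group=group,
        m=m,
        seed=seed,
        provenance=cohort.provenance,
        params_per_rep=params_per_rep,
    )


def _params_for_split(
    cohort: Cohort,
    snp_ids: list[str],
    group_names: list[str],
    split: Split,
    params: HyperParams | None,
    grid: HyperParamGrid | None,
    tune_per: str,
    tune_folds: int,
    seed: int,
    params_per_rep: dict[int, HyperParams],
) -> HyperParams:
    if params is not None:
        params_per_rep.setdefault(split.rep, params)
        return params
    if tune_per == "repetition" and split.rep in params_per_rep:
        return params_per_rep[split.rep]
    design = assemble_features(
        cohort, snp_ids, group_names, split.train, scaler_source=split.train
    )
    tuned, _trace = tune_sequential(
        design,
        cohort.labels[split.train],
        grid=grid,
        folds=tune_folds,
        seed=seed + split.rep,
    )
    if tune_per == "repetition":
        params_per_rep[split.rep] = tuned
    return tuned


def _refit_and_score(
    cohort: Cohort,
    network: FeatureNetwork,
    split: Split,
    y: np.ndarray,
    params: HyperParams,
    seed: int,
) -> tuple[float, float]:
    """Refit on train+validation with the network, score AP on the test fold
    (and on the refit data, for the overfitting-direction sanity check)."""
    snps = [d.name for d in network.features if d.source == "snp"]
    demogs = [d.name for d in network.features if d.source == "demographic"]
    trainval = split.train_val
    design_tv = assemble_features(cohort, snps, demogs, trainval, trainval)
    design_te = assemble_features(cohort, snps, demogs, split.test, trainval)
    # column order must match the network's selected order
    order = [network.names.index(n) for n in design_tv.names]
    inverse = np.argsort(order)
    design_tv = design_tv.subset_columns(inverse)
    design_te = design_te.subset_columns(inverse)
    model = fit(design_tv, y[trainval], params, seed=seed)
    test_ap = average_precision_score(predict(model, design_te), y[split.test])
    train_ap = average_precision_score(predict(model, design_tv), y[trainval])
    return test_ap, train_ap


def leave_one_out_importance(result: PipelineResult, cohort: Cohort) -> pd.DataFrame:
    """Per-feature mean relative change in test AP when the feature is
    removed from each network that selected it.

    For feature f in the network of split s:  refit on train+validation
    without f, rescore the test fold, and record
    (AP_without_f - AP_full) / AP_full.  The reported importance is the mean
    over the splits where f was selected; negative values mean removing the
    feature hurts.  Removing the only feature of a singleton network leaves
    an empty model, scored as a constant (prevalence-ranking) baseline and
    flagged.
    """
    gm, _ = filter_missing_snps(cohort.genotypes)
    filtered = Cohort(
        genotypes=gm,
        demographics=cohort.demographics,
        labels=cohort.labels,
        provenance=cohort.provenance,
    )
    y = cohort.labels
    fit_seed = int(np.random.SeedSequence(result.seed).generate_state(1)[0] % (2**31))
    changes: dict[str, list[float]] = {}
    flagged: set[str] = set()
    for sr in result.splits:
        names = sr.network.names
        for f in names:
            kept = [n for n in names if n != f]
            if kept:
                reduced = FeatureNetwork(
                    features=[d for d in sr.network.features if d.name != f],
                    validation_ap=np.nan,
                )
                ap_wo, _ = _refit_and_score(
                    filtered, reduced, sr.split, y, sr.params, fit_seed
                )
            else:
                # empty model: constant scores rank nothing, AP = prevalence
                ap_wo = average_precision_score(
                    np.zeros(len(sr.split.test)), y[sr.split.test]
                )
                flagged.add(f)
            changes.setdefault(f, []).append((ap_wo - sr.test_ap) / sr.test_ap)
    rows = [
        {
            "feature": f,
            "mean_relative_change": float(np.mean(vals)),
            "n_selected": len(vals),
            "flagged_empty_model": f in flagged,
        }
        for f, vals in changes.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=["feature", "mean_relative_change", "n_selected", "flagged_empty_model"],
    )
    return df.sort_values("mean_relative_change").reset_index(drop=True)


# ---------------------------------------------------------------------------
# sensitivity sweeps


def _ratio_plan(labels, ratio: float, k1: int, k2: int, seed: int) -> SplitPlan:
    """K1 stratified shuffle splits at a given train fraction, validation
    carved from the training portion as one stratified 1/k2 fold."""
    y = np.asarray(labels)
    n_test = int(round((1 - ratio) * y.size))
    if n_test < MIN_TEST_SIZE:
        raise PipelineError(
            f"split ratio {ratio} leaves a test fold of {n_test} subjects "
            f"(< minimum {MIN_TEST_SIZE})"
        )
    states = np.random.SeedSequence(seed).generate_state(2 * k1) % (2**31)
    splits: list[Split] = []
    for i in range(k1):
        outer = StratifiedShuffleSplit(
            n_splits=1, train_size=ratio, random_state=int(states[2 * i])
        )
        trainval, test = next(iter(outer.split(y, y)))
        inner = StratifiedKFold(
            n_splits=k2, shuffle=True, random_state=int(states[2 * i + 1])
        )
        rest_rel, val_rel = next(iter(inner.split(y[trainval], y[trainval])))
        splits.append(
            Split(
                rep=i,
                fold=0,
                train=trainval[rest_rel],
                validation=trainval[val_rel],
                test=test,
            )
        )
    return SplitPlan(splits=splits, k1=k1, k2=1, seed=seed)


def sensitivity_sweep(
    cohort: Cohort,
    axis: str,
    values,
    **fixed,
) -> pd.DataFrame:
    """One full pipeline evaluation per value of a single swept setting.

    ``axis`` is ``top_m`` (number of top-ranked SNPs), ``split_ratio``
    (outer train fraction, K1 shuffle splits) or ``repetitions`` (K1).
    All other settings come from ``fixed`` (same keywords as
    :func:`run_pipeline`).  Returns one row per value with validation and
    test mAP +- std; validation mAP is the curve the sweeps are usually
    plotted on.
    """
    if axis not in ("top_m", "split_ratio", "repetitions"):
        raise PipelineError(f"unknown sweep axis {axis!r}")
    rows = []
    for value in values:
        kwargs = dict(fixed)
        if axis == "top_m":
            result = run_pipeline(cohort, m=int(value), **kwargs)
        elif axis == "repetitions":
            result = run_pipeline(cohort, k1=int(value), **kwargs)
        else:
            k1 = kwargs.pop("k1", 10)
            k2 = kwargs.pop("k2", 5)
            seed = kwargs.get("seed", 0)
            plan = _ratio_plan(cohort.labels, float(value), k1, k2, seed)
            result = run_pipeline(cohort, k1=k1, k2=k2, plan=plan, **kwargs)
        rows.append(
            {
                "axis": axis,
                "value": value,
                "map_validation": result.map_validation,
                "std_validation": result.std_validation,
                "map_test": result.map_test,
                "std_test": result.std_test,
            }
        )
    return pd.DataFrame(rows)
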