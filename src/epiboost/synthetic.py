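"""Synthetic case-control cohorts with known ground truth.

Real genotype + risk-factor cohorts of this kind are held under controlled
access, so every downstream stage of the package is developed and validated
against simulated cohorts in which the disease-generating mechanism is known
exactly.  Two generators are provided:

``generate_cohort``
    draws genotypes as independent Binomial(2, MAF) minor-allele counts,
    demographic features from a declared schema, and case/control labels from
    a logistic disease model whose linear predictor contains main effects and
    mean-centred product interactions (SNP x SNP epistasis and
    SNP x demographic terms).  Centring keeps interaction terms orthogonal to
    main effects in expectation, so a planted "pure" interaction carries
    signal that single-feature marginal tests miss.

``emulate_reference_margins``
    draws the 9 familial-history (Group 1) and 11 oestrogen-metabolism
    (Group 2) risk factors class-conditionally from the published
    case/control marginal distributions of the reference breast-cancer
    cohort (445 cases / 250 controls), plus label-independent null
    genotypes.  Labels are fixed by construction, so the demographic
    marginals — not a latent disease model — carry the class signal.  Used
    for association-test checks and pipeline smoke runs.

Both are reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort, DemographicFeature, GenotypeMatrix, SNPRecord

__all__ = [
    "EffectTerm",
    "DemographicSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "calibrate_intercept",
    "emulate_reference_margins",
    "planted_epistasis_spec",
    "null_spec",
    "REFERENCE_PREVALENCE",
    "REFERENCE_MARGINS",
]

#: 445 cases / 250 controls of the reference cohort.
REFERENCE_PREVALENCE: float = 445 / 695


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class EffectTerm:
    """One term of the log-odds linear predictor.

    ``kind`` is one of ``main_snp``, ``main_demog``, ``snp_snp``,
    ``snp_demog``; ``features`` names one feature for main effects and
    exactly two distinct features for interactions; ``beta`` is the
    log-odds coefficient applied to the (product of) mean-centred values.
    """

    kind: Literal["main_snp", "main_demog", "snp_snp", "snp_demog"]
    features: tuple[str, ...]
    beta: float

    def __post_init__(self) -> None:
        expected = 1 if self.kind.startswith("main") else 2
        if len(self.features) != expected:
            raise SyntheticSpecError(
                f"{self.kind} term must name {expected} feature(s), "
                f"got {self.features}"
            )
        if expected == 2 and self.features[0] == self.features[1]:
            raise SyntheticSpecError("interaction term must name distinct features")


@dataclass(frozen=True)
class DemographicSpec:
    """Schema entry: categorical features carry category probabilities,
    continuous features carry (mean, std)."""

    name: str
    kind: Literal["categorical", "continuous"]
    group: Literal["group1", "group2", "other"]
    probs: tuple[float, ...] | None = None
    mean: float = 0.0
    std: float = 1.0

    def population_mean(self) -> float:
        if self.kind == "categorical":
            return float(sum(i * p for i, p in enumerate(self.probs)))
        return self.mean


@dataclass
class SyntheticSpec:
    n_subjects: int = 695
    target_prevalence: float = REFERENCE_PREVALENCE
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    demographics: list[DemographicSpec] = field(default_factory=list)
    effects: list[EffectTerm] = field(default_factory=list)
    intercept: float | Literal["auto"] = "auto"
    seed: int = 0
    #: fixed MAFs for named SNPs (e.g. planted causal variants); the rest
    #: are drawn uniformly from maf_range
    maf_overrides: dict[str, float] = field(default_factory=dict)
    #: optional LD emulation: Gaussian-copula block correlation among SNPs
    ld_block_size: int = 1
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SyntheticSpecError("n_subjects must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SyntheticSpecError("maf_range must be ordered within (0, 0.5]")
        if not (0 < self.target_prevalence < 1):
            raise SyntheticSpecError("target_prevalence must lie in (0,1)")
        names = {f"snp{j + 1:05d}" for j in range(self.n_snps)} | {
            d.name for d in self.demographics
        }
        for term in self.effects:
            for f in term.features:
                if f not in names:
                    raise SyntheticSpecError(f"effect names unknown feature {f!r}")
        for name, maf in self.maf_overrides.items():
            if name not in names:
                raise SyntheticSpecError(f"maf_overrides names unknown SNP {name!r}")
            if not (0 < maf <= 0.5):
                raise SyntheticSpecError(f"override MAF for {name} outside (0, 0.5]")

    def snp_name(self, j: int) -> str:
        return f"snp{j + 1:05d}"


@dataclass
class GroundTruth:
    """The realized generative state: intercept, effects, per-SNP MAFs, and
    the per-subject linear predictor / case probability."""

    intercept: float
    effects: list[EffectTerm]
    mafs: np.ndarray
    linear_predictor: np.ndarray
    probability: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "effects": [
                {"kind": e.kind, "features": list(e.features), "beta": e.beta}
                for e in self.effects
            ],
            "mafs": self.mafs.tolist(),
            "linear_predictor": self.linear_predictor.tolist(),
            "probability": self.probability.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------


def _draw_genotypes(spec: SyntheticSpec, rng: np.random.Generator, n: int):
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=spec.n_snps)
    for name, maf in spec.maf_overrides.items():
        mafs[int(name.removeprefix("snp")) - 1] = maf
    if spec.ld_block_size > 1 and spec.ld_rho > 0:
        codes = _draw_ld_blocks(spec, mafs, rng, n)
    else:
        codes = rng.binomial(2, mafs, size=(n, spec.n_snps)).astype(np.int8)
    return mafs, codes


def _draw_ld_blocks(
    spec: SyntheticSpec, mafs: np.ndarray, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Gaussian-copula block correlation: latent N(0, R) per block with
    exchangeable correlation rho, each margin thresholded to Binomial(2, MAF)
    quantiles."""
    from scipy.stats import norm

    codes = np.empty((n, spec.n_snps), dtype=np.int8)
    b = spec.ld_block_size
    for start in range(0, spec.n_snps, b):
        stop = min(start + b, spec.n_snps)
        k = stop - start
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, k))
        z = np.sqrt(spec.ld_rho) * shared + np.sqrt(1 - spec.ld_rho) * noise
        u = norm.cdf(z)
        for local, j in enumerate(range(start, stop)):
            p = mafs[j]
            # inverse CDF of Binomial(2, p): P(0)=(1-p)^2, P(0 or 1)=1-p^2
            c0 = (1 - p) ** 2
            c1 = 1 - p**2
            col = np.where(u[:, local] < c0, 0, np.where(u[:, local] < c1, 1, 2))
            codes[:, j] = col
    return codes


def _draw_demographics(
    spec: SyntheticSpec, rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for d in spec.demographics:
        if d.kind == "categorical":
            probs = np.asarray(d.probs, dtype=float)
            probs = probs / probs.sum()
            out[d.name] = rng.choice(len(probs), size=n, p=probs).astype(float)
        else:
            out[d.name] = rng.normal(d.mean, d.std, size=n)
    return out


def _centred_feature(
    name: str,
    spec: SyntheticSpec,
    mafs: np.ndarray,
    codes: np.ndarray,
    demog: dict[str, np.ndarray],
) -> np.ndarray:
    if name in demog:
        d = next(s for s in spec.demographics if s.name == name)
        return demog[name] - d.population_mean()
    j = int(name.removeprefix("snp")) - 1
    return codes[:, j].astype(float) - 2.0 * mafs[j]


def _effect_sum(
    spec: SyntheticSpec,
    mafs: np.ndarray,
    codes: np.ndarray,
    demog: dict[str, np.ndarray],
) -> np.ndarray:
    eta = np.zeros(codes.shape[0])
    for term in spec.effects:
        value = _centred_feature(term.features[0], spec, mafs, codes, demog)
        if len(term.features) == 2:
            value = value * _centred_feature(term.features[1], spec, mafs, codes, demog)
        eta += term.beta * value
    return eta


def calibrate_intercept(
    spec: SyntheticSpec,
    n_mc: int = 20000,
    tol: float = 1e-3,
    max_expansions: int = 6,
) -> float:
    """Intercept beta0 such that mean case probability matches the target.

    A Monte-Carlo sample of the effect sum is drawn once with an internal
    seed derived from ``spec.seed``; ``beta0 -> mean(expit(beta0 + s))`` is
    then continuous and strictly increasing, so plain root bracketing
    converges.  Raises if no bracket is found within the expansion budget.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x1C]))
    mafs, codes = _draw_genotypes(spec, rng, n_mc)
    demog = _draw_demographics(spec, rng, n_mc)
    s = _effect_sum(spec, mafs, codes, demog)

    def prevalence_gap(b0: float) -> float:
        return float(np.mean(expit(b0 + s))) - spec.target_prevalence

    lo, hi = -2.0, 2.0
    for _ in range(max_expansions):
        if prevalence_gap(lo) < 0 < prevalence_gap(hi):
            b0 = float(brentq(prevalence_gap, lo, hi, xtol=tol / 10))
            if abs(prevalence_gap(b0)) > tol:
                raise SyntheticSpecError(
                    f"intercept calibration residual {prevalence_gap(b0):.2g} "
                    f"exceeds tolerance {tol}"
                )
            return b0
        lo *= 2
        hi *= 2
    raise SyntheticSpecError(
        f"intercept calibration failed to bracket the target prevalence "
        f"{spec.target_prevalence} within [-{lo}, {hi}]"
    )


def generate_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort and its generative ground truth, reproducibly."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x2A]))
    mafs, codes = _draw_genotypes(spec, rng, spec.n_subjects)
    demog_values = _draw_demographics(spec, rng, spec.n_subjects)

    intercept = (
        calibrate_intercept(spec) if spec.intercept == "auto" else float(spec.intercept)
    )
    eta = intercept + _effect_sum(spec, mafs, codes, demog_values)
    prob = expit(eta)
    labels = rng.binomial(1, prob).astype(np.int64)

    chroms = rng.integers(1, 23, size=spec.n_snps)
    positions = rng.integers(1, 250_000_000, size=spec.n_snps)
    alleles = np.array(list("ACGT"))
    snps = []
    for j in range(spec.n_snps):
        major, minor = rng.choice(4, size=2, replace=False)
        snps.append(
            SNPRecord(
                snp_id=spec.snp_name(j),
                chrom=f"chr{chroms[j]}",
                pos=int(positions[j]),
                major_allele=str(alleles[major]),
                minor_allele=str(alleles[minor]),
            )
        )
    gm = GenotypeMatrix(
        subjects=[f"S{i + 1:05d}" for i in range(spec.n_subjects)],
        snps=snps,
        codes=codes,
    )
    demographics = [
        DemographicFeature(
            name=d.name, kind=d.kind, group=d.group, values=demog_values[d.name]
        )
        for d in spec.demographics
    ]
    cohort = Cohort(
        genotypes=gm,
        demographics=demographics,
        labels=labels,
        provenance=f"synthetic logistic cohort, seed={spec.seed}",
    )
    truth = GroundTruth(
        intercept=intercept,
        effects=list(spec.effects),
        mafs=mafs,
        linear_predictor=eta,
        probability=prob,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# benchmark study conditions


def planted_epistasis_spec(
    n_subjects: int = 700,
    n_null_snps: int = 500,
    seed: int = 0,
) -> SyntheticSpec:
    """The planted-signal recovery benchmark.

    Three causal SNPs (MAF 0.3) carry moderate main effects (log-OR
    ln 1.8 per allele) and pairwise epistatic interactions (log-OR ln 2.2
    on each of the three pairs) amid ``n_null_snps`` null SNPs; two
    informative demographic features (a binary factor at log-OR ln 2.2 and
    a continuous factor at 0.8 per SD) complete the signal.  Prevalence
    mirrors the 445/695 reference class balance.  A pipeline run on this
    cohort should select all five planted features far more often than any
    null feature.
    """
    causal = ["snp00001", "snp00002", "snp00003"]
    effects = [EffectTerm("main_snp", (s,), float(np.log(1.8))) for s in causal]
    effects += [
        EffectTerm("snp_snp", (a, b), float(np.log(2.2)))
        for a, b in (("snp00001", "snp00002"),
                     ("snp00001", "snp00003"),
                     ("snp00002", "snp00003"))
    ]
    effects += [
        EffectTerm("main_demog", ("family_history",), float(np.log(2.2))),
        EffectTerm("main_demog", ("hormone_exposure",), 0.8),
    ]
    return SyntheticSpec(
        n_subjects=n_subjects,
        n_snps=3 + n_null_snps,
        maf_range=(0.05, 0.5),
        demographics=[
            DemographicSpec("family_history", "categorical", "group1",
                            probs=(0.5, 0.5)),
            DemographicSpec("hormone_exposure", "continuous", "group2",
                            mean=0.0, std=1.0),
        ],
        effects=effects,
        maf_overrides={s: 0.3 for s in causal},
        seed=seed,
    )


def null_spec(n_subjects: int = 400, n_snps: int = 50, seed: int = 0) -> SyntheticSpec:
    """No effects at all: labels independent of every feature (calibration)."""
    return SyntheticSpec(
        n_subjects=n_subjects,
        n_snps=n_snps,
        demographics=[
            DemographicSpec("family_history", "categorical", "group1",
                            probs=(0.5, 0.5)),
            DemographicSpec("hormone_exposure", "continuous", "group2",
                            mean=0.0, std=1.0),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# published reference marginals (Group 1: familial history; Group 2:
# oestrogen metabolism).  Categorical entries: per-category case/control
# counts over 445 cases / 250 controls.  Continuous entries: class mean (std).

REFERENCE_MARGINS: list[dict] = [
    # --- Group 1: familial history of breast cancer (all categorical)
    {"name": "cancer_in_family", "group": "group1", "kind": "categorical",
     "cases": [196, 249], "controls": [136, 114]},
    {"name": "cancer_type_1", "group": "group1", "kind": "categorical",
     "cases": [394, 51], "controls": [235, 15]},
    {"name": "cancer_type_2", "group": "group1", "kind": "categorical",
     "cases": [437, 8], "controls": [249, 1]},
    {"name": "first_degree_relative_1", "group": "group1", "kind": "categorical",
     "cases": [398, 47], "controls": [238, 12]},
    {"name": "first_degree_relative_2", "group": "group1", "kind": "categorical",
     "cases": [438, 7], "controls": [249, 1]},
    {"name": "n_bc_in_family", "group": "group1", "kind": "categorical",
     "cases": [393, 45, 7], "controls": [235, 14, 1]},
    {"name": "bc_risk_score", "group": "group1", "kind": "categorical",
     "cases": [396, 44, 5], "controls": [238, 11, 1]},
    {"name": "lateral_1", "group": "group1", "kind": "categorical",
     "cases": [394, 48, 3], "controls": [235, 14, 1]},
    {"name": "lateral_2", "group": "group1", "kind": "categorical",
     "cases": [437, 7, 1], "controls": [249, 1, 0]},
    # --- Group 2: oestrogen metabolism (categorical + continuous)
    {"name": "oral_contraceptive_use", "group": "group2", "kind": "categorical",
     "cases": [300, 145], "controls": [124, 126]},
    {"name": "oral_contraceptive_months", "group": "group2", "kind": "continuous",
     "cases": (48.27, 51.50), "controls": (40.86, 38.91)},
    {"name": "menopausal_status", "group": "group2", "kind": "categorical",
     "cases": [127, 318], "controls": [109, 141]},
    {"name": "breast_feeding", "group": "group2", "kind": "categorical",
     "cases": [107, 338], "controls": [39, 211]},
    {"name": "pregnancy", "group": "group2", "kind": "categorical",
     "cases": [85, 360], "controls": [31, 219]},
    {"name": "hrt_oestrogen_months", "group": "group2", "kind": "continuous",
     "cases": (53.94, 58.03), "controls": (39.85, 47.86)},
    {"name": "menstrual_cycle_days", "group": "group2", "kind": "continuous",
     "cases": (26.94, 2.27), "controls": (27.26, 2.65)},
    {"name": "pregnancy_1_weeks", "group": "group2", "kind": "continuous",
     "cases": (39.20, 3.37), "controls": (39.18, 3.88)},
    {"name": "pregnancy_2_weeks", "group": "group2", "kind": "continuous",
     "cases": (39.66, 1.95), "controls": (38.99, 4.64)},
    {"name": "pregnancy_3_weeks", "group": "group2", "kind": "continuous",
     "cases": (38.97, 3.93), "controls": (38.64, 5.70)},
    {"name": "bmi", "group": "group2", "kind": "continuous",
     "cases": (26.49, 4.60), "controls": (26.04, 4.29)},
]


def emulate_reference_margins(
    n_cases: int = 445,
    n_controls: int = 250,
    n_snps: int = 100,
    seed: int = 0,
) -> Cohort:
    """Cohort whose demographics follow the published class-conditional
    marginals; genotypes are label-independent (null) Binomial draws.

    Each feature is drawn independently within its class, so the joint
    dependence structure of the real cohort is NOT reproduced — only the
    per-feature margins that the published tables constrain.
    """
    if n_cases < 1 or n_controls < 1:
        raise SyntheticSpecError("both classes need at least one subject")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3B]))
    n = n_cases + n_controls
    labels = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    perm = rng.permutation(n)
    labels = labels[perm]

    demographics = []
    for margin in REFERENCE_MARGINS:
        values = np.empty(n, dtype=float)
        for cls, key, count in ((1, "cases", n_cases), (0, "controls", n_controls)):
            idx = np.nonzero(labels == cls)[0]
            if margin["kind"] == "categorical":
                counts = np.asarray(margin[key], dtype=float)
                probs = counts / counts.sum()
                values[idx] = rng.choice(len(probs), size=count, p=probs)
            else:
                mean, std = margin[key]
                values[idx] = rng.normal(mean, std, size=count)
        demographics.append(
            DemographicFeature(
                name=margin["name"],
                kind=margin["kind"],
                group=margin["group"],
                values=values,
            )
        )

    mafs = rng.uniform(0.05, 0.5, size=n_snps)
    codes = rng.binomial(2, mafs, size=(n, n_snps)).astype(np.int8)
    alleles = np.array(list("ACGT"))
    snps = []
    for j in range(n_snps):
        major, minor = rng.choice(4, size=2, replace=False)
        snps.append(
            SNPRecord(
                snp_id=f"snp{j + 1:05d}",
                chrom=f"chr{1 + j % 22}",
                pos=1 + j * 10_000,
                major_allele=str(alleles[major]),
                minor_allele=str(alleles[minor]),
            )
        )
    gm = GenotypeMatrix(
        subjects=[f"S{i + 1:05d}" for i in range(n)], snps=snps, codes=codes
    )
    return Cohort(
        genotypes=gm,
        demographics=demographics,
        labels=labels,
        provenance=(
            f"margins-emulated cohort ({n_cases} cases / {n_controls} controls), "
            f"seed={seed}"
        ),
    )
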