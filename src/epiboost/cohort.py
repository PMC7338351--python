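"""Case-control cohort data model and genotype/demographic/label I/O.

A cohort couples three per-subject components that must share one ordered
subject list:

* a :class:`GenotypeMatrix` of additively coded SNP genotypes (minor-allele
  counts 0/1/2, with an explicit missing marker),
* a list of :class:`DemographicFeature` columns, each tagged as categorical
  (small non-negative integer codes) or continuous, and as belonging to a
  named risk-factor group ("group1" = familial history, "group2" = oestrogen
  metabolism, "other"),
* binary case(1)/control(0) labels.

Genotypes are read either from VCF (diploid GT calls, REF taken as the major
and ALT as the minor allele) or from a hand-editable TSV dialect: header row
of SNP ids, first column of subject ids, cells in {0,1,2,NA} or allele pairs
such as "AG".  Demographics come as a TSV plus a sidecar schema TSV declaring
each feature's kind and group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_CODE",
    "SNPRecord",
    "GenotypeMatrix",
    "DemographicFeature",
    "Cohort",
    "FeatureDescriptor",
    "CombinedFeatureMatrix",
    "MinMaxScaler",
    "encode_additive",
    "filter_missing_snps",
    "fit_minmax",
    "apply_minmax",
    "assemble_features",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_demographics",
    "write_demographics",
    "read_labels",
    "write_labels",
]

#: Sentinel for a missing genotype call in the integer code matrix.
MISSING_CODE: int = -1


class CohortError(ValueError):
    """Malformed cohort input (parse errors, unknown features, bad calls)."""


@dataclass(frozen=True)
class SNPRecord:
    """A single biallelic variant with a declared allele orientation."""

    snp_id: str
    chrom: str
    pos: int  # 1-based bp
    major_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.major_allele == self.minor_allele:
            raise CohortError(f"{self.snp_id}: major and minor allele are identical")


def encode_additive(call: str, snp: SNPRecord) -> int:
    """Additive (minor-allele count) encoding of a diploid call.

    ``call`` is a two-character allele pair, e.g. ``"AG"``.  Homozygous major
    maps to 0, heterozygous to 1, homozygous minor to 2.
    """
    if len(call) != 2:
        raise CohortError(f"{snp.snp_id}: call {call!r} is not a diploid allele pair")
    count = 0
    for allele in call:
        if allele == snp.minor_allele:
            count += 1
        elif allele != snp.major_allele:
            raise CohortError(
                f"{snp.snp_id}: allele {allele!r} matches neither declared allele "
                f"({snp.major_allele}/{snp.minor_allele})"
            )
    return count


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs table of additive codes with ``MISSING_CODE`` gaps."""

    subjects: list[str]
    snps: list[SNPRecord]
    codes: np.ndarray  # int8/int16, shape (n_subjects, n_snps)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.subjects), len(self.snps)):
            raise CohortError(
                f"code table shape {self.codes.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING_CODE])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortError(
                f"invalid genotype code {self.codes[i, j]} for subject "
                f"{self.subjects[i]!r}, SNP {self.snps[j].snp_id!r}"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate SNP ids in genotype matrix")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def minor_allele_frequencies(self, warn: bool = True) -> np.ndarray:
        """Column-wise MAF = sum(codes) / (2 * non-missing subjects).

        A frequency above 0.5 means the declared minor allele is in fact the
        common one; such columns are reported with a warning, never silently
        re-oriented.
        """
        codes = np.ma.masked_equal(self.codes, MISSING_CODE)
        n = (~codes.mask).sum(axis=0) if codes.mask is not np.ma.nomask else np.full(
            self.n_snps, self.n_subjects
        )
        with np.errstate(invalid="ignore"):
            maf = np.asarray(codes.sum(axis=0), dtype=float) / (2.0 * np.maximum(n, 1))
        if warn:
            flipped = np.nonzero(maf > 0.5)[0]
            if flipped.size:
                names = [self.snps[j].snp_id for j in flipped[:5]]
                warnings.warn(
                    f"{flipped.size} SNP(s) have declared-minor frequency > 0.5 "
                    f"(e.g. {names}); allele orientation may be wrong",
                    stacklevel=2,
                )
        return maf

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s.snp_id: j for j, s in enumerate(self.snps)}
        try:
            cols = [index[i] for i in snp_ids]
        except KeyError as exc:
            raise CohortError(f"unknown SNP id {exc.args[0]!r}") from None
        return GenotypeMatrix(
            subjects=list(self.subjects),
            snps=[self.snps[j] for j in cols],
            codes=self.codes[:, cols].copy(),
        )


def filter_missing_snps(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Drop every SNP column containing at least one missing call.

    Returns the filtered matrix and the number of SNPs removed.  Subject
    order is unchanged.  Removing every SNP is legal (a warning, not an
    error): downstream modelling will then see an empty genotype block.
    """
    keep = ~(gm.codes == MISSING_CODE).any(axis=0)
    removed = int((~keep).sum())
    if not keep.any() and gm.n_snps > 0:
        warnings.warn("all SNPs contain missing calls; 0 SNPs retained", stacklevel=2)
    filtered = GenotypeMatrix(
        subjects=list(gm.subjects),
        snps=[s for s, k in zip(gm.snps, keep) if k],
        codes=gm.codes[:, keep].copy(),
    )
    return filtered, removed


@dataclass
class DemographicFeature:
    """One demographic risk factor column.

    ``values`` is a float array over subjects; ``nan`` marks missing.
    Categorical features hold small non-negative integer codes (as floats).
    """

    name: str
    kind: Literal["categorical", "continuous"]
    group: Literal["group1", "group2", "other"]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise CohortError(f"{self.name}: unknown kind {self.kind!r}")
        if self.group not in ("group1", "group2", "other"):
            raise CohortError(f"{self.name}: unknown group {self.group!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "categorical":
            observed = self.values[~np.isnan(self.values)]
            if observed.size and (
                (observed < 0).any() or (observed != np.round(observed)).any()
            ):
                raise CohortError(
                    f"{self.name}: categorical codes must be non-negative integers"
                )


@dataclass
class Cohort:
    """Genotypes + demographics + labels over one ordered subject list."""

    genotypes: GenotypeMatrix
    demographics: list[DemographicFeature]
    labels: np.ndarray  # 0/1 per subject
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = self.genotypes.n_subjects
        if self.labels.shape != (n,):
            raise CohortError("labels do not match subject count")
        if not np.isin(self.labels, [0, 1]).all():
            raise CohortError("labels must be 0 (control) or 1 (case)")
        for f in self.demographics:
            if f.values.shape != (n,):
                raise CohortError(f"feature {f.name!r} does not match subject count")
        names = [f.name for f in self.demographics]
        if len(set(names)) != len(names):
            raise CohortError("duplicate demographic feature names")

    @property
    def subjects(self) -> list[str]:
        return self.genotypes.subjects

    @property
    def n_subjects(self) -> int:
        return self.genotypes.n_subjects

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == 0).sum())

    def demographic(self, name: str) -> DemographicFeature:
        for f in self.demographics:
            if f.name == name:
                return f
        raise CohortError(f"unknown demographic feature {name!r}")

    def group_features(self, group: str) -> list[DemographicFeature]:
        if group == "both":
            return [f for f in self.demographics if f.group in ("group1", "group2")]
        return [f for f in self.demographics if f.group == group]


# ---------------------------------------------------------------------------
# min-max scaling


@dataclass(frozen=True)
class MinMaxScaler:
    """Min-max scaler to [0,1] with clipping; degenerate columns map to 0."""

    vmin: float
    vmax: float

    @property
    def degenerate(self) -> bool:
        return self.vmax == self.vmin


def fit_minmax(values: np.ndarray) -> MinMaxScaler:
    """Fit min/max over non-missing values; errors if all are missing."""
    values = np.asarray(values, dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        raise CohortError("cannot fit min-max scaler: all values missing")
    return MinMaxScaler(float(observed.min()), float(observed.max()))


def apply_minmax(scaler: MinMaxScaler, values: np.ndarray) -> np.ndarray:
    """(x - min)/(max - min), clipped to [0,1]; NaN passes through."""
    values = np.asarray(values, dtype=float)
    if scaler.degenerate:
        out = np.zeros_like(values)
        out[np.isnan(values)] = np.nan
        return out
    return np.clip((values - scaler.vmin) / (scaler.vmax - scaler.vmin), 0.0, 1.0)


# ---------------------------------------------------------------------------
# combined design matrices


@dataclass(frozen=True)
class FeatureDescriptor:
    source: Literal["snp", "demographic"]
    name: str
    group: str  # "snp" for SNPs, else the demographic group tag

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class CombinedFeatureMatrix:
    """Numeric design over a subject subset, SNP columns first.

    Continuous demographic columns are min-max scaled with scalers fitted on
    the declared scaler source (normally the training subset), never on the
    rows being transformed.
    """

    descriptors: list[FeatureDescriptor]
    X: np.ndarray
    subject_index: np.ndarray  # positions into the cohort subject list

    def subset_columns(self, which: Sequence[int]) -> "CombinedFeatureMatrix":
        which = list(which)
        return CombinedFeatureMatrix(
            descriptors=[self.descriptors[j] for j in which],
            X=self.X[:, which],
            subject_index=self.subject_index,
        )

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]


def assemble_features(
    cohort: Cohort,
    snp_ids: Sequence[str],
    demographic_names: Sequence[str],
    subject_subset: Sequence[int],
    scaler_source: Sequence[int],
) -> CombinedFeatureMatrix:
    """Build a design matrix: SNP columns in the given order, then demographics.

    Scalers (continuous features) and missing-value fills are fitted on
    ``scaler_source`` rows only and applied to ``subject_subset`` rows.
    Missing categorical codes become an explicit extra code (max observed + 1);
    missing continuous values become the scaler-source median.  SNP columns
    must contain no missing calls — run :func:`filter_missing_snps` first.
    """
    rows = np.asarray(subject_subset, dtype=np.intp)
    src = np.asarray(scaler_source, dtype=np.intp)
    columns: list[np.ndarray] = []
    descriptors: list[FeatureDescriptor] = []

    if snp_ids:
        sub = cohort.genotypes.subset_snps(snp_ids)
        if (sub.codes == MISSING_CODE).any():
            raise CohortError(
                "selected SNPs contain missing calls; apply filter_missing_snps first"
            )
        for j, snp in enumerate(sub.snps):
            columns.append(sub.codes[rows, j].astype(float))
            descriptors.append(FeatureDescriptor("snp", snp.snp_id, "snp"))

    for name in demographic_names:
        feat = cohort.demographic(name)
        values = feat.values
        if feat.kind == "continuous":
            scaler = fit_minmax(values[src])
            train_obs = values[src][~np.isnan(values[src])]
            fill = float(np.median(train_obs))
            col = values[rows].copy()
            col[np.isnan(col)] = fill
            col = apply_minmax(scaler, col)
        else:
            obs = values[src][~np.isnan(values[src])]
            missing_code = float(obs.max() + 1) if obs.size else 0.0
            col = values[rows].copy()
            col[np.isnan(col)] = missing_code
        columns.append(col)
        descriptors.append(FeatureDescriptor("demographic", feat.name, feat.group))

    X = (
        np.column_stack(columns)
        if columns
        else np.empty((len(rows), 0), dtype=float)
    )
    return CombinedFeatureMatrix(descriptors=descriptors, X=X, subject_index=rows)


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(path: str | Path, format: str = "tabular") -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or the ``tabular`` TSV dialect."""
    if format == "vcf":
        return _read_vcf(Path(path))
    if format == "tabular":
        return _read_tabular(Path(path))
    raise CohortError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snps: list[SNPRecord] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise CohortError(
                f"multi-allelic site {variant.CHROM}:{variant.POS} "
                f"({variant.REF}->{variant.ALT}) is not supported"
            )
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snps.append(
            SNPRecord(
                snp_id=snp_id,
                chrom=variant.CHROM,
                pos=variant.POS,
                major_allele=variant.REF,
                minor_allele=variant.ALT[0],
            )
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        col = np.full(len(subjects), MISSING_CODE, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        cols.append(col)
    codes = (
        np.column_stack(cols)
        if cols
        else np.empty((len(subjects), 0), dtype=np.int8)
    )
    return GenotypeMatrix(subjects=subjects, snps=snps, codes=codes)


def _read_tabular(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise CohortError(f"{path}: no columns found")
    subject_col = df.columns[0]
    subjects = df[subject_col].tolist()
    snp_ids = list(df.columns[1:])
    n = len(subjects)
    codes = np.full((n, len(snp_ids)), MISSING_CODE, dtype=np.int8)
    snps: list[SNPRecord] = []
    for j, snp_id in enumerate(snp_ids):
        raw = df[snp_id].tolist()
        numeric = all(c in ("0", "1", "2", "NA", "") for c in raw)
        if numeric:
            # pre-coded column; synthesize a placeholder record
            record = SNPRecord(snp_id, "unknown", j + 1, "A", "B")
            for i, cell in enumerate(raw):
                if cell in ("NA", ""):
                    continue
                codes[i, j] = int(cell)
        else:
            record = _orient_allele_pairs(snp_id, j, raw, path)
            for i, cell in enumerate(raw):
                if cell in ("NA", ""):
                    continue
                try:
                    codes[i, j] = encode_additive(cell, record)
                except CohortError as exc:
                    raise CohortError(
                        f"{path}: row {i + 2}, column {snp_id!r}: {exc}"
                    ) from None
        snps.append(record)
    return GenotypeMatrix(subjects=subjects, snps=snps, codes=codes)


def _orient_allele_pairs(
    snp_id: str, col: int, raw: list[str], path: Path
) -> SNPRecord:
    """Infer major/minor orientation from allele counts (tie → alphabetical)."""
    counts: dict[str, int] = {}
    for i, cell in enumerate(raw):
        if cell in ("NA", ""):
            continue
        if len(cell) != 2 or not cell.isalpha():
            raise CohortError(
                f"{path}: row {i + 2}, column {snp_id!r}: malformed call {cell!r}"
            )
        for allele in cell:
            counts[allele] = counts.get(allele, 0) + 1
    if len(counts) > 2:
        raise CohortError(
            f"{path}: column {snp_id!r}: more than two alleles observed "
            f"({sorted(counts)})"
        )
    if len(counts) == 1:
        (only,) = counts
        other = "A" if only != "A" else "C"
        return SNPRecord(snp_id, "unknown", col + 1, only, other)
    (a, na), (b, nb) = sorted(counts.items())
    if na == nb:
        major, minor = a, b  # alphabetical tie-break
    elif na > nb:
        major, minor = a, b
    else:
        major, minor = b, a
    return SNPRecord(snp_id, "unknown", col + 1, major, minor)


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT-only; major allele as REF, minor as ALT)."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_CODE: "./."}
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        for chrom in dict.fromkeys(s.chrom for s in gm.snps):
            out.write(f"##contig=<ID={chrom}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.subjects)
            + "\n"
        )
        for j, snp in enumerate(gm.snps):
            calls = "\t".join(code_to_gt[int(c)] for c in gm.codes[:, j])
            out.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.major_allele}\t"
                f"{snp.minor_allele}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the pre-coded tabular dialect (0/1/2/NA)."""
    cells = gm.codes.astype(object)
    cells[gm.codes == MISSING_CODE] = "NA"
    df = pd.DataFrame(cells, columns=gm.snp_ids)
    df.insert(0, "subject_id", gm.subjects)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# demographic and label I/O


def read_demographics(
    values_path: str | Path, schema_path: str | Path
) -> tuple[list[str], list[DemographicFeature]]:
    """Read feature values and the sidecar schema (feature, kind, group)."""
    values = pd.read_csv(values_path, sep="\t")
    schema = pd.read_csv(schema_path, sep="\t")
    for col in ("feature", "kind", "group"):
        if col not in schema.columns:
            raise CohortError(f"{schema_path}: schema is missing column {col!r}")
    subjects = values.iloc[:, 0].astype(str).tolist()
    features: list[DemographicFeature] = []
    for row in schema.itertuples(index=False):
        if row.feature not in values.columns:
            raise CohortError(
                f"{values_path}: schema feature {row.feature!r} not in table"
            )
        features.append(
            DemographicFeature(
                name=row.feature,
                kind=row.kind,
                group=row.group,
                values=pd.to_numeric(values[row.feature], errors="coerce").to_numpy(),
            )
        )
    return subjects, features


def write_demographics(
    subjects: Sequence[str],
    features: Iterable[DemographicFeature],
    values_path: str | Path,
    schema_path: str | Path,
) -> None:
    features = list(features)
    df = pd.DataFrame({"subject_id": list(subjects)})
    schema_rows = []
    for f in features:
        col = pd.Series(f.values)
        if f.kind == "categorical":
            col = col.astype("Int64")
        df[f.name] = col
        schema_rows.append({"feature": f.name, "kind": f.kind, "group": f.group})
    df.to_csv(values_path, sep="\t", index=False, na_rep="NA")
    pd.DataFrame(schema_rows).to_csv(schema_path, sep="\t", index=False)


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    subjects = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, 1].to_numpy(dtype=np.int64)
    if not np.isin(labels, [0, 1]).all():
        raise CohortError(f"{path}: labels must be 0/1")
    return subjects, labels


def write_labels(subjects: Sequence[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"subject_id": list(subjects), "label": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def load_cohort_dir(directory: str | Path) -> Cohort:
    """Load a cohort written by :func:`save_cohort_dir` (or hand-built files)."""
    d = Path(directory)
    gm = read_genotypes(d / "genotypes.tsv", "tabular")
    subj_d, features = read_demographics(d / "demographics.tsv", d / "schema.tsv")
    subj_l, labels = read_labels(d / "labels.tsv")
    if subj_d != gm.subjects or subj_l != gm.subjects:
        raise CohortError(f"{d}: subject lists disagree across component files")
    prov_file = d / "provenance.txt"
    prov = prov_file.read_text().strip() if prov_file.exists() else str(d)
    return Cohort(genotypes=gm, demographics=features, labels=labels, provenance=prov)


def save_cohort_dir(cohort: Cohort, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_genotypes_tsv(cohort.genotypes, d / "genotypes.tsv")
    write_demographics(
        cohort.subjects, cohort.demographics, d / "demographics.tsv", d / "schema.tsv"
    )
    write_labels(cohort.subjects, cohort.labels, d / "labels.tsv")
    (d / "provenance.txt").write_text(cohort.provenance + "\n")
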