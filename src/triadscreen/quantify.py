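"""Sample design, expression containers, and abundance normalization.

Count matrices for the three RNA layers (mRNA, lncRNA, miRNA) are held in an
:class:`ExpressionMatrix`, a thin wrapper around a features x samples
:class:`pandas.DataFrame` carrying a unit tag and the sample design.  Three
normalizations are provided:

* median-of-ratios size factors (the standard reference-sample normalization
  used by negative-binomial differential-expression tests),
* FPKM (fragments per kilobase of transcript per million mapped fragments)
  for length-bearing transcripts, and
* read-count TPM (count / library total x 1e6) for mature miRNAs, whose
  near-constant length makes the per-kilobase term superfluous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError

GENOTYPES = ("DT", "DS")
CONDITIONS = ("CK", "drought")

_DESIGN_COLUMNS = ["sample", "genotype", "condition", "replicate"]


@dataclass(frozen=True)
class SampleDesign:
    """The experimental layout: genotype x condition x replicate per sample.

    The canonical design is 2 genotypes (DT = drought tolerant,
    DS = drought sensitive) x 2 conditions (CK = control, drought) x 3
    biological replicates = 12 samples.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        if t["sample"].duplicated().any():
            dup = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(f"duplicate sample ids in design: {dup}")
        key = t[["genotype", "condition", "replicate"]]
        if key.duplicated().any():
            raise ValidationError(
                "duplicate (genotype, condition, replicate) triples in design"
            )
        cells = t.groupby(["genotype", "condition"]).size()
        if (cells < 2).any():
            thin = cells[cells < 2].index.tolist()
            raise ValidationError(
                f"each genotype x condition cell needs >= 2 replicates; thin cells: {thin}"
            )

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype"].unique())

    def samples_for(self, genotype: str, condition: str | None = None) -> list[str]:
        t = self.table
        mask = t["genotype"] == genotype
        if condition is not None:
            mask &= t["condition"] == condition
        return t.loc[mask, "sample"].tolist()

    def subset(self, samples: list[str]) -> "SampleDesign":
        t = self.table.set_index("sample").loc[samples].reset_index()
        return SampleDesign(t)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"replicate": int}))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Features x samples abundance table with a unit tag and its design.

    ``unit`` is one of ``counts``, ``FPKM``, ``TPM``.  Values are
    non-negative; when the unit is ``counts`` they must be integral.
    """

    values: pd.DataFrame = field(repr=False)
    unit: str
    design: SampleDesign

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "FPKM", "TPM"):
            raise ValidationError(f"unknown unit tag {self.unit!r}")
        v = self.values
        if list(v.columns) != self.design.samples:
            raise ValidationError(
                "matrix columns do not match design sample ids: "
                f"{list(v.columns)} vs {self.design.samples}"
            )
        arr = v.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValidationError("expression values must be non-negative")
        if self.unit == "counts" and arr.size and not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")

    @property
    def features(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return replace(
            self, values=self.values[samples], design=self.design.subset(samples)
        )

    def subset_features(self, features: list[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[features])

    @classmethod
    def from_tsv(
        cls, path: str | Path, unit: str, design: SampleDesign
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values[design.samples], unit=unit, design=design)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature, the ratio of its count in a sample to its geometric
    mean across samples is formed; the size factor of a sample is the median
    of these ratios over features whose geometric mean is nonzero (i.e.
    features with no zero count).  Columns of a matrix that are all equal get
    factor exactly 1.
    """
    if counts.unit != "counts":
        raise ValidationError(f"size factors require counts, got {counts.unit}")
    arr = counts.values.to_numpy(dtype=float)
    if arr.size == 0 or not arr.any():
        raise DegenerateInputError("all-zero count matrix")
    if (arr.sum(axis=0) == 0).any():
        zero = [s for s, t in zip(counts.samples, arr.sum(axis=0)) if t == 0]
        raise DegenerateInputError(f"samples with zero total count: {zero}")
    with np.errstate(divide="ignore"):
        log = np.log(arr)
    finite = np.all(np.isfinite(log), axis=1)
    if not finite.any():
        raise DegenerateInputError(
            "no feature has nonzero counts in every sample; "
            "median-of-ratios reference is undefined"
        )
    geo = np.exp(log[finite].mean(axis=1))  # geometric mean per usable feature
    factors = np.median(arr[finite] / geo[:, None], axis=0)
    return pd.Series(factors, index=counts.samples, name="size_factor")


def fpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_ij = count_ij * 1e9 / (column_total_j * length_i).
    """
    if counts.unit != "counts":
        raise ValidationError(f"fpkm requires counts, got {counts.unit}")
    missing = [f for f in counts.features if f not in lengths.index]
    if missing:
        raise ValidationError(f"missing transcript length for features: {missing[:5]}")
    lens = lengths.loc[counts.features].astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0].tolist()
        raise ValidationError(f"non-positive lengths for features: {bad[:5]}")
    totals = counts.values.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise DegenerateInputError(f"zero column total in samples: {zero}")
    values = counts.values * 1e9
    values = values.div(totals, axis=1).div(lens, axis=0)
    return ExpressionMatrix(values=values, unit="FPKM", design=counts.design)


def tpm_small_rna(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Read-count TPM for small RNAs: count * 1e6 / column total.

    Mature miRNAs are all ~21-24 nt, so the transcript-length term of the
    conventional TPM cancels and per-million read scaling is the appropriate
    depth normalization.
    """
    if counts.unit != "counts":
        raise ValidationError(f"tpm requires counts, got {counts.unit}")
    totals = counts.values.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise DegenerateInputError(f"zero column total in samples: {zero}")
    values = counts.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=values, unit="TPM", design=counts.design)
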