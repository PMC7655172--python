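"""Core domain types and text-format readers/writers.

The exchange object throughout the package is :class:`MethylationMatrix`:
a CpG-by-sample grid of beta values (methylated read fraction, in [0, 1])
with an explicit missingness mask, locus coordinates and sample metadata.
Matrices and sample sheets live on disk as TSV; fitted clock models as a
versioned JSON text file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

WEEKS_PER_MONTH = 4.345  # configurable week->month conversion

TISSUES = ("cortex", "hippocampus")
STRAINS = ("B6", "AD")
SEXES = ("M", "F")

MISSING_SENTINELS = ("", "NA")


class ValidationError(ValueError):
    """Raised when an input file or object violates a domain invariant."""


@dataclass(frozen=True)
class CpGLocus:
    """A single assayed cytosine (1-based point coordinate)."""

    id: str
    chrom: str
    pos: int
    strand: str = "."

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"CpG {self.id}: pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"CpG {self.id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata; ages are stored in months."""

    sample_id: str
    tissue: str
    strain: str
    sex: str
    age: float

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValidationError(f"sample {self.sample_id}: unknown tissue {self.tissue!r}")
        if self.strain not in STRAINS:
            raise ValidationError(f"sample {self.sample_id}: unknown strain {self.strain!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"sample {self.sample_id}: unknown sex {self.sex!r}")
        if not self.age > 0:
            raise ValidationError(f"sample {self.sample_id}: age must be > 0, got {self.age}")


def weeks_to_months(weeks: float, weeks_per_month: float = WEEKS_PER_MONTH) -> float:
    """Convert an age in weeks to months (default 4.345 weeks/month)."""
    return weeks / weeks_per_month


@dataclass
class MethylationMatrix:
    """CpG x sample beta-value grid with missingness mask.

    ``values[i, j]`` is the beta value of locus ``i`` in sample ``j``;
    ``mask[i, j]`` is True where the value is missing (the corresponding
    value entry is NaN and must not be used).
    """

    loci: list[CpGLocus]
    samples: list[SampleMeta]
    values: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_loci, n_samples = len(self.loci), len(self.samples)
        if self.values.shape != (n_loci, n_samples):
            raise ValidationError(
                f"values shape {self.values.shape} != (loci, samples) = ({n_loci}, {n_samples})"
            )
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape differs from values shape")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValidationError(f"duplicate CpG id(s): {list(dup[dup > 1].index)}")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate sample id(s)")
        obs = self.values[~self.mask]
        bad = (obs < 0) | (obs > 1)
        if bad.any():
            i, j = np.argwhere(~self.mask)[np.flatnonzero(bad)[0]]
            raise ValidationError(
                f"beta value out of [0,1] at CpG {ids[i]}, sample {sids[j]}: {self.values[i, j]}"
            )
        # NaN under the mask keeps masked entries inert in arithmetic
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    # ---- convenience accessors -------------------------------------------------
    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.samples])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "tissue": [s.tissue for s in self.samples],
                "strain": [s.strain for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "age": self.ages,
            }
        )

    def subset_samples(self, keep: np.ndarray) -> "MethylationMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MethylationMatrix(
            loci=list(self.loci),
            samples=[self.samples[j] for j in keep],
            values=self.values[:, keep],
            mask=self.mask[:, keep],
        )

    def subset_loci(self, keep: np.ndarray) -> "MethylationMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MethylationMatrix(
            loci=[self.loci[i] for i in keep],
            samples=list(self.samples),
            values=self.values[keep, :],
            mask=self.mask[keep, :],
        )

    def restrict_tissue(self, tissue: str) -> "MethylationMatrix":
        keep = np.array([s.tissue == tissue for s in self.samples])
        return self.subset_samples(keep)


def drop_missing_cpgs(m: MethylationMatrix) -> MethylationMatrix:
    """Keep only loci observed in every sample (order preserved).

    Mirrors the study's filter that reduced its 2,031-CpG panel to the
    1,696 fully observed loci before ANOVA/PCA/clustering.
    """
    complete = ~m.mask.any(axis=1)
    if not complete.any():
        warnings.warn("drop_missing_cpgs removed every locus", stacklevel=2)
    return m.subset_loci(complete)


# ---- TSV readers / writers -----------------------------------------------------

_MATRIX_META_COLS = ["cpg_id", "chrom", "pos", "strand"]
_SAMPLE_COLS = ["sample_id", "tissue", "strain", "sex", "age"]


def read_sample_sheet(path, age_unit: str = "months",
                      weeks_per_month: float = WEEKS_PER_MONTH) -> list[SampleMeta]:
    """Read a TSV sample sheet (columns sample_id/tissue/strain/sex/age).

    ``age_unit`` may be "months" (default) or "weeks"; weeks are converted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SAMPLE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet {path}: missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        age = float(row["age"])
        if age_unit == "weeks":
            age = weeks_to_months(age, weeks_per_month)
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                tissue=row["tissue"],
                strain=row["strain"],
                sex=row["sex"],
                age=age,
            )
        )
    return out


def read_methylation_matrix(path_matrix, path_samples, **sheet_kwargs) -> MethylationMatrix:
    """Read a beta-value TSV plus its sample sheet into a MethylationMatrix.

    The matrix file has columns [cpg_id, chrom, pos, strand, <sample ids...>];
    an empty cell or "NA" marks a missing value. Every sample column must
    appear in the sheet and vice versa.
    """
    samples = read_sample_sheet(path_samples, **sheet_kwargs)
    by_id = {s.sample_id: s for s in samples}
    df = pd.read_csv(path_matrix, sep="\t", dtype={"cpg_id": str, "chrom": str},
                     na_values=list(MISSING_SENTINELS), keep_default_na=False)
    for c in _MATRIX_META_COLS:
        if c not in df.columns:
            raise ValidationError(f"matrix {path_matrix}: missing column {c!r}")
    sample_cols = [c for c in df.columns if c not in _MATRIX_META_COLS]
    unknown = [c for c in sample_cols if c not in by_id]
    if unknown:
        raise ValidationError(f"matrix {path_matrix}: sample(s) not in sheet: {unknown}")
    loci = [
        CpGLocus(id=r.cpg_id, chrom=r.chrom, pos=int(r.pos), strand=r.strand)
        for r in df.itertuples()
    ]
    ordered = [by_id[c] for c in sample_cols]
    values = df[sample_cols].to_numpy(dtype=float)
    return MethylationMatrix(loci=loci, samples=ordered, values=values)


def write_methylation_matrix(m: MethylationMatrix, path_matrix, path_samples=None) -> None:
    """Write a matrix (and optionally its sample sheet) back to TSV."""
    df = pd.DataFrame(
        {
            "cpg_id": m.locus_ids,
            "chrom": [l.chrom for l in m.loci],
            "pos": [l.pos for l in m.loci],
            "strand": [l.strand for l in m.loci],
        }
    )
    vals = pd.DataFrame(m.values, columns=m.sample_ids)
    vals = vals.mask(pd.DataFrame(m.mask, columns=m.sample_ids))
    df = pd.concat([df, vals], axis=1)
    df.to_csv(path_matrix, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    if path_samples is not None:
        write_sample_sheet(m.samples, path_samples)


def write_sample_sheet(samples: list[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "tissue": [s.tissue for s in samples],
            "strain": [s.strain for s in samples],
            "sex": [s.sex for s in samples],
            "age": [s.age for s in samples],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---- clock-model serialization --------------------------------------------------

CLOCK_FORMAT_VERSION = 1


@dataclass
class ClockModel:
    """A fitted tissue-specific clock: age transform + sparse linear model.

    ``coefficients`` maps CpG id -> coefficient on the beta scale; loci the
    penalty zeroed out are omitted. ``training_means`` stores per-CpG training
    beta means used to impute missing values at prediction time.
    """

    tissue: str
    transform: dict          # AgeTransform parameters (kind, adult_age, offset)
    intercept: float
    coefficients: dict[str, float]
    training_means: dict[str, float] = field(default_factory=dict)
    training_info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}")


def save_clock(model: ClockModel, path) -> None:
    payload = {
        "format": "tissueclock.model",
        "version": CLOCK_FORMAT_VERSION,
        "tissue": model.tissue,
        "transform": model.transform,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "training_means": model.training_means,
        "training_info": model.training_info,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_clock(path) -> ClockModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValidationError(f"malformed clock file {path}: {e}") from None
    if payload.get("format") != "tissueclock.model":
        raise ValidationError(f"{path}: not a clock model file")
    if payload.get("version") != CLOCK_FORMAT_VERSION:
        raise ValidationError(
            f"{path}: unsupported clock format version {payload.get('version')}"
        )
    return ClockModel(
        tissue=payload["tissue"],
        transform=payload["transform"],
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        training_means={k: float(v) for k, v in payload.get("training_means", {}).items()},
        training_info=payload.get("training_info", {}),
    )
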