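"""Synthetic methylation cohorts with the statistical structure of a
two-tissue, two-strain, age-structured mouse brain study.

Each CpG locus belongs to one archetype:

* ``null``        -- constant mean methylation.
* ``age``         -- mean drifts with transformed age, shared by strains.
* ``tissue``      -- constant offset between cortex and hippocampus.
* ``strain``      -- constant offset between B6 and AD.
* ``interaction`` -- age trend whose slope differs between strains
  (the strain x age interaction class).

The per-sample, per-locus mean is

    mu = clamp(base + d_tissue*1[hippocampus] + d_strain*1[AD]
               + (s_age + s_int*1[AD]) * F(age_eff), eps, 1-eps)

with F the default log-linear age transform and age_eff = age
(+ ad_age_shift_months for AD samples, to inject a known epigenetic-age
shift). Observed values are Beta-distributed with mean mu and concentration
``noise_precision`` (read-fraction-like bounded noise), then a configurable
fraction of cells is masked completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import AgeTransform
from .io import CpGLocus, MethylationMatrix, SampleMeta

MU_EPS = 0.01  # clamp bound keeping Beta parameters proper

DEFAULT_AGES_MONTHS = (3.0, 6.0, 12.0, 15.0)
DEFAULT_TOTAL_LOCI = 2031


@dataclass(frozen=True)
class CohortDesign:
    """Factorial cohort layout: tissues x strains x ages x replicates."""

    tissues: tuple = ("cortex", "hippocampus")
    strains: tuple = ("B6", "AD")
    ages_months: tuple = DEFAULT_AGES_MONTHS
    n_per_cell: int = 6
    sex: str = "F"
    ad_age_shift_months: float = 0.0  # injected epigenetic-age shift for AD

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        ages = tuple(self.ages_months)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages_months must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * len(self.strains) * len(self.ages_months) * self.n_per_cell


@dataclass(frozen=True)
class CpGArchetypeSpec:
    """Counts and effect-size ranges for the locus archetypes.

    Slopes are in beta units per unit transformed age; offsets in beta
    units. Signs are drawn at random per locus. ``noise_precision`` is the
    Beta concentration (higher = tighter around the mean).
    """

    n_null: int = 1121
    n_age: int = 300
    n_tissue: int = 400
    n_strain: int = 150
    n_interaction: int = 60
    age_slope_range: tuple = (0.03, 0.08)
    tissue_offset_range: tuple = (0.10, 0.30)
    strain_offset_range: tuple = (0.05, 0.15)
    interaction_slope_range: tuple = (0.04, 0.08)
    base_range: tuple = (0.2, 0.8)
    noise_precision: float = 100.0
    missing_fraction: float = 0.002

    def __post_init__(self):
        for name in ("n_null", "n_age", "n_tissue", "n_strain", "n_interaction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if not self.noise_precision > 0:
            raise ValueError("noise_precision must be positive")

    @property
    def n_loci(self) -> int:
        return self.n_null + self.n_age + self.n_tissue + self.n_strain + self.n_interaction

    @classmethod
    def training_default(cls) -> "CpGArchetypeSpec":
        """Panel used for clock-training simulations: 200 age-trending loci
        among the 2,031-locus panel, no group-contrast archetypes."""
        return cls(n_null=DEFAULT_TOTAL_LOCI - 200, n_age=200,
                   n_tissue=0, n_strain=0, n_interaction=0)


@dataclass
class GroundTruth:
    """Per-locus archetype labels and true effect parameters."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def loci_of(self, archetype: str) -> list[str]:
        t = self.table
        return t.loc[t["archetype"] == archetype, "cpg_id"].tolist()


def _draw_signed(rng, lo, hi, size):
    mag = rng.uniform(lo, hi, size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def _draw_effects(spec: CpGArchetypeSpec, rng) -> pd.DataFrame:
    """Assign archetypes and effect parameters to the locus panel."""
    n = spec.n_loci
    labels = (
        ["null"] * spec.n_null + ["age"] * spec.n_age + ["tissue"] * spec.n_tissue
        + ["strain"] * spec.n_strain + ["interaction"] * spec.n_interaction
    )
    base = rng.uniform(*spec.base_range, size=n)
    tissue_off = np.zeros(n)
    strain_off = np.zeros(n)
    age_slope = np.zeros(n)
    inter_slope = np.zeros(n)
    lab = np.array(labels)
    idx = {k: np.flatnonzero(lab == k) for k in ("age", "tissue", "strain", "interaction")}
    age_slope[idx["age"]] = _draw_signed(rng, *spec.age_slope_range, size=len(idx["age"]))
    tissue_off[idx["tissue"]] = _draw_signed(rng, *spec.tissue_offset_range,
                                             size=len(idx["tissue"]))
    strain_off[idx["strain"]] = _draw_signed(rng, *spec.strain_offset_range,
                                             size=len(idx["strain"]))
    # interaction loci: opposite-trend profiles between strains, mirroring
    # loci whose methylation rises with age in one strain and falls in the other
    s = _draw_signed(rng, *spec.interaction_slope_range, size=len(idx["interaction"]))
    age_slope[idx["interaction"]] = s / 2.0
    inter_slope[idx["interaction"]] = -s

    positions = rng.integers(3_000_000, 150_000_000, size=n)
    chroms = rng.integers(1, 20, size=n)
    ids = [f"chr{c}:{p}" for c, p in zip(chroms, positions)]
    # regenerate any collisions deterministically
    seen, out = set(), []
    for k, i in enumerate(ids):
        while i in seen:
            positions[k] += 1
            i = f"chr{chroms[k]}:{positions[k]}"
        seen.add(i)
        out.append(i)
    return pd.DataFrame(
        {
            "cpg_id": out,
            "chrom": [f"chr{c}" for c in chroms],
            "pos": positions,
            "archetype": lab,
            "base": base,
            "tissue_offset": tissue_off,
            "strain_offset": strain_off,
            "age_slope": age_slope,
            "interaction_slope": inter_slope,
        }
    )


def _sample_table(design: CohortDesign) -> pd.DataFrame:
    rows = []
    for tissue in design.tissues:
        for strain in design.strains:
            for age in design.ages_months:
                for r in range(1, design.n_per_cell + 1):
                    rows.append(
                        {
                            "sample_id": f"{tissue}_{strain}_{age:g}mo_r{r}",
                            "tissue": tissue,
                            "strain": strain,
                            "sex": design.sex,
                            "age": float(age),
                        }
                    )
    return pd.DataFrame(rows)


def expected_means(effects: pd.DataFrame, samples: pd.DataFrame,
                   transform: AgeTransform | None = None,
                   ad_age_shift: float = 0.0) -> np.ndarray:
    """Noise-free expected beta grid (loci x samples) for a sample table."""
    transform = transform or AgeTransform()
    is_hip = (samples["tissue"] == "hippocampus").to_numpy(float)
    is_ad = (samples["strain"] == "AD").to_numpy(float)
    age_eff = samples["age"].to_numpy(float) + ad_age_shift * is_ad
    f_age = np.asarray(transform(age_eff))
    mu = (
        effects["base"].to_numpy()[:, None]
        + effects["tissue_offset"].to_numpy()[:, None] * is_hip[None, :]
        + effects["strain_offset"].to_numpy()[:, None] * is_ad[None, :]
        + (
            effects["age_slope"].to_numpy()[:, None]
            + effects["interaction_slope"].to_numpy()[:, None] * is_ad[None, :]
        )
        * f_age[None, :]
    )
    return np.clip(mu, MU_EPS, 1.0 - MU_EPS)


def expected_cohort(truth: "GroundTruth", design: CohortDesign,
                    transform: AgeTransform | None = None) -> MethylationMatrix:
    """The noise-free, fully observed cohort implied by a ground truth.

    Useful for measuring the shift in *expected* epigenetic age a design
    injects, independent of observation noise.
    """
    samples = _sample_table(design)
    mu = expected_means(truth.table, samples, transform,
                        ad_age_shift=design.ad_age_shift_months)
    return _build_matrix(truth.table, samples, mu, np.zeros(mu.shape, dtype=bool))


def _simulate(effects: pd.DataFrame, samples: pd.DataFrame,
              spec: CpGArchetypeSpec, rng, transform: AgeTransform,
              ad_age_shift: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Draw the beta-value grid and missingness mask for a sample table."""
    mu = expected_means(effects, samples, transform, ad_age_shift)
    nu = spec.noise_precision
    if np.isinf(nu):
        values = mu.copy()
    else:
        values = rng.beta(mu * nu, (1.0 - mu) * nu)
        values = np.clip(values, 0.0, 1.0)
    mask = rng.random(mu.shape) < spec.missing_fraction
    return values, mask


def _build_matrix(effects: pd.DataFrame, samples: pd.DataFrame,
                  values: np.ndarray, mask: np.ndarray) -> MethylationMatrix:
    loci = [
        CpGLocus(id=r.cpg_id, chrom=r.chrom, pos=int(r.pos))
        for r in effects.itertuples()
    ]
    metas = [
        SampleMeta(sample_id=r.sample_id, tissue=r.tissue, strain=r.strain,
                   sex=r.sex, age=r.age)
        for r in samples.itertuples()
    ]
    return MethylationMatrix(loci=loci, samples=metas, values=values, mask=mask)


def simulate_cohort(design: CohortDesign | None = None,
                    spec: CpGArchetypeSpec | None = None,
                    seed: int = 0,
                    transform: AgeTransform | None = None
                    ) -> tuple[MethylationMatrix, GroundTruth]:
    """Simulate a full factorial cohort (tissues x strains x ages x reps).

    Deterministic in (design, spec, seed). Returns the matrix plus the
    ground-truth archetype/effect table.
    """
    design = design or CohortDesign()
    spec = spec or CpGArchetypeSpec()
    transform = transform or AgeTransform()
    rng = np.random.default_rng(seed)
    effects = _draw_effects(spec, rng)
    samples = _sample_table(design)
    values, mask = _simulate(effects, samples, spec, rng, transform,
                             ad_age_shift=design.ad_age_shift_months)
    return _build_matrix(effects, samples, values, mask), GroundTruth(effects)


@dataclass
class StudyData:
    """A full simulated study sharing one locus-effect table.

    ``training`` and ``validation`` map tissue -> single-strain cohorts for
    clock fitting/evaluation; ``experiment`` is the factorial two-strain
    cohort the clocks are applied to.
    """

    truth: GroundTruth
    training: dict
    validation: dict
    experiment: MethylationMatrix


TRAINING_AGES_WEEKS = (12.0, 24.0, 64.0)
VALIDATION_AGES_WEEKS = (24.0, 36.0, 70.0, 91.0, 105.0)


def simulate_study(design: CohortDesign | None = None,
                   spec: CpGArchetypeSpec | None = None,
                   training_ages_months=None, n_train: int = 4,
                   validation_ages_months=None, n_validation: int = 4,
                   seed: int = 0,
                   transform: AgeTransform | None = None) -> StudyData:
    """Simulate training, validation and experiment cohorts over one panel.

    All cohorts are drawn from the same per-locus effect table, so clocks
    trained on the training cohorts transfer to the experiment cohort.
    Training/validation default to the 12/24/64- and 24/36/70/91/105-week
    male designs (converted to months); the experiment cohort follows
    ``design``.
    """
    from .io import weeks_to_months

    design = design or CohortDesign()
    spec = spec or CpGArchetypeSpec()
    transform = transform or AgeTransform()
    if training_ages_months is None:
        training_ages_months = [weeks_to_months(w) for w in TRAINING_AGES_WEEKS]
    if validation_ages_months is None:
        validation_ages_months = [weeks_to_months(w) for w in VALIDATION_AGES_WEEKS]
    rng = np.random.default_rng(seed)
    effects = _draw_effects(spec, rng)
    truth = GroundTruth(effects)

    def single_strain(tissue, ages, n):
        rows = []
        for age in ages:
            for r in range(1, n + 1):
                rows.append({"sample_id": f"{tissue}_B6_{age:.3g}mo_r{r}",
                             "tissue": tissue, "strain": "B6", "sex": "M",
                             "age": float(age)})
        samples = pd.DataFrame(rows)
        vals, mask = _simulate(effects, samples, spec, rng, transform)
        return _build_matrix(effects, samples, vals, mask)

    training = {t: single_strain(t, training_ages_months, n_train) for t in design.tissues}
    validation = {t: single_strain(t, validation_ages_months, n_validation)
                  for t in design.tissues}
    samples = _sample_table(design)
    vals, mask = _simulate(effects, samples, spec, rng, transform,
                           ad_age_shift=design.ad_age_shift_months)
    experiment = _build_matrix(effects, samples, vals, mask)
    return StudyData(truth=truth, training=training, validation=validation,
                     experiment=experiment)


def simulate_annotation(loci, seed: int = 0):
    """Synthetic genomic annotation for a locus panel.

    Places a CpG island over ~25% of the loci, a gene (random strand) with
    its TSS within 10 kb of ~20% of the loci, and reports chromosome sizes
    padded 2 Mb beyond the last locus. Returns (islands FeatureAnnotation,
    genes list, chrom_sizes dict).
    """
    from .annotation import FeatureAnnotation, GeneModel

    rng = np.random.default_rng(seed)
    chrom_sizes: dict[str, int] = {}
    for l in loci:
        chrom_sizes[l.chrom] = max(chrom_sizes.get(l.chrom, 0), l.pos + 2_000_000)
    rows, genes = [], []
    for i, l in enumerate(sorted(loci, key=lambda x: (x.chrom, x.pos))):
        u = rng.random()
        if u < 0.25:
            start = max(l.pos - 1 - int(rng.integers(0, 800)), 0)
            rows.append({"chrom": l.chrom, "start": start, "end": start + 1_000,
                         "feature_class": "cpg_island", "name": f"island_{i}"})
        if rng.random() < 0.20:
            tss = max(int(l.pos + rng.integers(-10_000, 10_000)), 1)
            genes.append(GeneModel(gene_id=f"gene_{i}", chrom=l.chrom,
                                   strand=str(rng.choice(["+", "-"])), tss=tss))
    islands = FeatureAnnotation(pd.DataFrame(rows)) if rows else FeatureAnnotation.empty()
    return islands, genes, chrom_sizes


def simulate_training_cohort(tissue: str, ages_months, n_per_age: int,
                             spec: CpGArchetypeSpec | None = None,
                             seed: int = 0,
                             strain: str = "B6", sex: str = "M",
                             transform: AgeTransform | None = None
                             ) -> tuple[MethylationMatrix, GroundTruth]:
    """Single-tissue, single-strain cohort for clock training/validation.

    Same generative model restricted to one design cell per age; intended
    as direct input to :func:`tissueclock.clock.fit_clock`.
    """
    spec = spec or CpGArchetypeSpec.training_default()
    transform = transform or AgeTransform()
    rng = np.random.default_rng(seed)
    effects = _draw_effects(spec, rng)
    rows = []
    for age in ages_months:
        for r in range(1, n_per_age + 1):
            rows.append(
                {
                    "sample_id": f"{tissue}_{strain}_{age:g}mo_r{r}",
                    "tissue": tissue,
                    "strain": strain,
                    "sex": sex,
                    "age": float(age),
                }
            )
    samples = pd.DataFrame(rows)
    values, mask = _simulate(effects, samples, spec, rng, transform)
    return _build_matrix(effects, samples, values, mask), GroundTruth(effects)
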