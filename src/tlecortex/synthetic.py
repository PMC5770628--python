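"""Synthetic TLE cohorts with known ground truth.

Region-level MRI morphometry from the study population this package targets
is not publicly deposited, so recovery and calibration experiments run on
simulated cohorts that reproduce the cohort structure the analysis assumes:
41 left-TLE patients, 34 right-TLE patients and 58 normal controls scanned
on two field strengths, with group-matched age/sex distributions.

Per measure, features are multivariate normal with equicorrelation rho
across the 68 regional features (cortical measures are regionally
correlated; equicorrelation keeps the covariance positive-definite and
cheap to sample).  On top of the correlated noise the generator adds linear
age and sex effects, an additive scanner (batch) shift, and planted group
effects expressed as Cohen's d at chosen (region, hemisphere, measure)
features.  The default effect map plants 15 effects per comparison at the
features this analysis family reports as most discriminative, with |d|
decaying linearly from 1.5 (rank 1) to 0.5 (rank 15), negative for
thickness/area/volume (atrophy) and positive for curvature.

Ground truth (which features carry a planted effect for a comparison) is
queryable, so selector-recovery experiments can score rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_COMPARISONS,
    MEASURES,
    CorticalFeatureTable,
    FeatureLabel,
    GroupComparison,
    SubjectRecord,
    canonical_labels,
    parse_label,
)

__all__ = [
    "EffectSpec",
    "SyntheticCohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "ground_truth",
    "SUBCORTICAL_LABELS",
    "generate_subcortical_table",
]

# Cohort demographics: sizes, 1.5T scanner counts, male counts, age mean/SD.
GROUP_SIZES = {"LTLE": 41, "RTLE": 34, "NC": 58}
_SCANNER_15T = {"LTLE": 21, "RTLE": 18, "NC": 28}
_MALES = {"LTLE": 23, "RTLE": 18, "NC": 29}
_AGE = {"LTLE": (25.5, 8.2), "RTLE": (25.0, 8.5), "NC": (23.2, 4.1)}

# Per-measure baseline location/scale in natural units (mm, mm^2, mm^3, 1/mm).
DEFAULT_BASE_MEAN = {"CTh": 2.5, "CSA": 700.0, "GMV": 2000.0, "MCu": 0.13}
DEFAULT_BASE_SD = {"CTh": 0.15, "CSA": 80.0, "GMV": 250.0, "MCu": 0.02}


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect at one feature for one comparison.

    ``effect_size`` is Cohen's d; its sign is the direction of the
    patient-minus-control (positive-minus-negative group) shift.
    """

    target: FeatureLabel
    comparison: GroupComparison
    effect_size: float


# Top-15 discriminative features per comparison (rank order), used as the
# default planted-effect locations.  Entries are lh/rh_region_measure labels.
_TOP15 = {
    "LTLE-NC": [
        "lh_entorhinal_CSA",
        "lh_insula_CTh",
        "lh_rostralmiddlefrontal_CTh",
        "lh_parahippocampal_GMV",
        "lh_caudalmiddlefrontal_MCu",
        "rh_superiorfrontal_GMV",
        "rh_entorhinal_CTh",
        "lh_lateralorbitofrontal_GMV",
        "lh_superiorfrontal_GMV",
        "lh_parstriangularis_CSA",
        "rh_fusiform_CSA",
        "lh_middletemporal_GMV",
        "rh_caudalmiddlefrontal_GMV",
        "lh_paracentral_CTh",
        "rh_cuneus_CTh",
    ],
    "RTLE-NC": [
        "rh_rostralmiddlefrontal_CSA",
        "rh_superiorparietal_MCu",
        "lh_insula_CTh",
        "rh_superiorfrontal_CTh",
        "lh_inferiorparietal_CSA",
        "lh_parsopercularis_GMV",
        "rh_lateraloccipital_CTh",
        "lh_inferiortemporal_MCu",
        "rh_posteriorcingulate_MCu",
        "lh_postcentral_CSA",
        "lh_rostralmiddlefrontal_MCu",
        "lh_medialorbitofrontal_GMV",
        "rh_supramarginal_MCu",
        "rh_cuneus_CSA",
        "rh_parahippocampal_MCu",
    ],
    "LTLE-RTLE": [
        "rh_cuneus_CSA",
        "rh_superiorfrontal_CSA",
        "lh_parsorbitalis_GMV",
        "rh_parahippocampal_MCu",
        "lh_parstriangularis_CSA",
        "rh_precentral_MCu",
        "rh_rostralmiddlefrontal_CSA",
        "lh_isthmuscingulate_CSA",
        "rh_lateraloccipital_CTh",
        "lh_entorhinal_CSA",
        "rh_superiorfrontal_GMV",
        "lh_parsopercularis_MCu",
        "lh_postcentral_CSA",
        "lh_cuneus_CSA",
        "rh_lateraloccipital_GMV",
    ],
}


def default_effects(
    comparisons: Sequence[GroupComparison] = DEFAULT_COMPARISONS,
    d_max: float = 1.5,
    d_min: float = 0.5,
) -> list[EffectSpec]:
    """The default planted-effect map: 15 effects per comparison with |d|
    decaying linearly from ``d_max`` to ``d_min``; atrophy-signed."""
    effects = []
    for comparison in comparisons:
        names = _TOP15[comparison.name]
        for rank, name in enumerate(names):
            label = parse_label(name)
            d = d_max - rank * (d_max - d_min) / (len(names) - 1)
            sign = 1.0 if label.measure == "MCu" else -1.0
            effects.append(EffectSpec(target=label, comparison=comparison, effect_size=sign * d))
    return effects


@dataclass
class SyntheticCohortSpec:
    """Full description of a synthetic cohort; one seed governs all draws."""

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    effects: list[EffectSpec] = field(default_factory=default_effects)
    base_mean: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_MEAN))
    base_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_SD))
    correlation: float = 0.3
    # Covariate coefficients in per-measure SD units: value shift per year of
    # age, and additive shift for males relative to females.
    age_beta_sd: float = -0.01
    sex_beta_sd: float = 0.1
    # Additive 3.0T-minus-1.5T scanner offset, in SD units.
    batch_shift_sd: float = 0.2
    # Fraction of each group scanned at 1.5T; None uses the study's split.
    scanner_fraction: Mapping[str, float] | float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError(f"equicorrelation must be in [0, 1), got {self.correlation}")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {g!r} must be positive, got {n}")


def default_cohort_spec(seed: int = 0, **overrides) -> SyntheticCohortSpec:
    """The study-condition cohort: study group sizes and the default effect map."""
    return SyntheticCohortSpec(seed=seed, **overrides)


def _scanner_count_15t(spec: SyntheticCohortSpec, group: str, n: int) -> int:
    if spec.scanner_fraction is None:
        if group in _SCANNER_15T and spec.group_sizes.get(group) == GROUP_SIZES.get(group):
            return _SCANNER_15T[group]
        frac = _SCANNER_15T.get(group, GROUP_SIZES.get(group, n) // 2) / GROUP_SIZES.get(group, n)
        return int(round(frac * n))
    frac = spec.scanner_fraction if isinstance(spec.scanner_fraction, float) else spec.scanner_fraction[group]
    return int(round(frac * n))


def _male_count(group: str, n: int) -> int:
    if group in _MALES and n == GROUP_SIZES[group]:
        return _MALES[group]
    frac = _MALES.get(group, n // 2) / GROUP_SIZES.get(group, n)
    return int(round(frac * n))


def generate_cohort(spec: SyntheticCohortSpec) -> CorticalFeatureTable:
    """Draw one synthetic cohort; identical spec + seed gives identical tables."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = canonical_labels()
    label_index = {l: j for j, l in enumerate(labels)}

    subjects: list[SubjectRecord] = []
    for group in ("LTLE", "RTLE", "NC"):
        n = int(spec.group_sizes.get(group, 0))
        if n == 0:
            continue
        mean, sd = _AGE.get(group, (25.0, 8.0))
        ages = rng.normal(mean, sd, size=n)
        ages = np.clip(ages, 6.0, None)  # ages are positive; floor at school age
        sexes = np.array(["M"] * _male_count(group, n) + ["F"] * (n - _male_count(group, n)))
        rng.shuffle(sexes)
        n15 = _scanner_count_15t(spec, group, n)
        scanners = np.array(["1.5T"] * n15 + ["3.0T"] * (n - n15))
        rng.shuffle(scanners)
        for i in range(n):
            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}{i + 1:03d}",
                    group=group,
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    scanner=str(scanners[i]),
                )
            )

    n_total = len(subjects)
    groups = np.asarray([s.group for s in subjects])
    ages = np.asarray([s.age for s in subjects])
    is_male = np.asarray([s.sex == "M" for s in subjects], dtype=float)
    is_3t = np.asarray([s.scanner == "3.0T" for s in subjects], dtype=float)
    age_centered = ages - ages.mean()

    values = np.empty((n_total, len(labels)))
    rho = spec.correlation
    for m_idx, measure in enumerate(MEASURES):
        cols = slice(m_idx * 68, (m_idx + 1) * 68)
        shared = rng.standard_normal((n_total, 1))  # per-subject regional factor
        noise = rng.standard_normal((n_total, 68))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        sd = spec.base_sd[measure]
        block = spec.base_mean[measure] + sd * z
        block += sd * (
            spec.age_beta_sd * age_centered[:, None]
            + spec.sex_beta_sd * is_male[:, None]
            + spec.batch_shift_sd * is_3t[:, None]
        )
        values[:, cols] = block

    # Planted effects shift the positive group's subjects only, leaving the
    # negative group (typically NC, shared across comparisons) as reference.
    for eff in spec.effects:
        j = label_index[eff.target]
        rows = groups == eff.comparison.positive_group
        values[rows, j] += eff.effect_size * spec.base_sd[eff.target.measure]

    return CorticalFeatureTable(subjects=subjects, labels=labels, values=values)


def ground_truth(spec: SyntheticCohortSpec, comparison: GroupComparison) -> set[FeatureLabel]:
    """Features carrying a nonzero planted effect for ``comparison``."""
    return {
        e.target
        for e in spec.effects
        if e.comparison.name == comparison.name and e.effect_size != 0.0
    }


# ---------------------------------------------------------------------------
# Subcortical volume tables (40 segmentation labels)
# ---------------------------------------------------------------------------

# FreeSurfer-style subcortical segmentation labels (40 structures).
SUBCORTICAL_LABELS: tuple[str, ...] = (
    "Left-Cerebral-White-Matter",
    "Left-Cerebral-Cortex",
    "Left-Lateral-Ventricle",
    "Left-Inf-Lat-Vent",
    "Left-Cerebellum-White-Matter",
    "Left-Cerebellum-Cortex",
    "Left-Thalamus",
    "Left-Caudate",
    "Left-Putamen",
    "Left-Pallidum",
    "Left-Hippocampus",
    "Left-Amygdala",
    "Left-Accumbens-area",
    "Left-VentralDC",
    "Left-vessel",
    "Left-choroid-plexus",
    "Right-Cerebral-White-Matter",
    "Right-Cerebral-Cortex",
    "Right-Lateral-Ventricle",
    "Right-Inf-Lat-Vent",
    "Right-Cerebellum-White-Matter",
    "Right-Cerebellum-Cortex",
    "Right-Thalamus",
    "Right-Caudate",
    "Right-Putamen",
    "Right-Pallidum",
    "Right-Hippocampus",
    "Right-Amygdala",
    "Right-Accumbens-area",
    "Right-VentralDC",
    "Right-vessel",
    "Right-choroid-plexus",
    "3rd-Ventricle",
    "4th-Ventricle",
    "Brain-Stem",
    "CSF",
    "Posterior-Cerebral-Cortex",
    "Central-Cerebral-Cortex",
    "Optic-Chiasm",
    "Corpus-Callosum",
)


def generate_subcortical_table(
    seed: int = 0,
    group_sizes: Mapping[str, int] | None = None,
    effects: Sequence[tuple[str, GroupComparison, float]] = (),
    correlation: float = 0.3,
    base_mean: float = 5000.0,
    base_sd: float = 600.0,
) -> pd.DataFrame:
    """Synthetic 40-structure volume table (same machinery, generic labels).

    ``effects`` is a sequence of ``(structure_name, comparison, cohens_d)``;
    the positive group is shifted by ``d * base_sd``.  Returns a DataFrame
    with the standard metadata columns followed by the 40 volume columns,
    suitable for the group-statistics functions.
    """
    spec = SyntheticCohortSpec(
        group_sizes=dict(group_sizes or GROUP_SIZES),
        effects=[],
        correlation=correlation,
        seed=seed,
    )
    spec.validate()
    rng = np.random.default_rng(seed)
    d = len(SUBCORTICAL_LABELS)
    rows = []
    for group in ("LTLE", "RTLE", "NC"):
        n = int(spec.group_sizes.get(group, 0))
        if n == 0:
            continue
        mean, sd = _AGE.get(group, (25.0, 8.0))
        ages = np.clip(rng.normal(mean, sd, size=n), 6.0, None)
        sexes = np.array(["M"] * _male_count(group, n) + ["F"] * (n - _male_count(group, n)))
        rng.shuffle(sexes)
        n15 = _scanner_count_15t(spec, group, n)
        scanners = np.array(["1.5T"] * n15 + ["3.0T"] * (n - n15))
        rng.shuffle(scanners)
        for i in range(n):
            rows.append((f"{group}{i + 1:03d}", group, float(ages[i]), str(sexes[i]), str(scanners[i])))
    meta = pd.DataFrame(rows, columns=["subject_id", "group", "age", "sex", "scanner"])
    n_total = len(meta)
    shared = rng.standard_normal((n_total, 1))
    noise = rng.standard_normal((n_total, d))
    z = np.sqrt(correlation) * shared + np.sqrt(1.0 - correlation) * noise
    values = base_mean + base_sd * z
    groups = meta["group"].to_numpy()
    col = {name: j for j, name in enumerate(SUBCORTICAL_LABELS)}
    for name, comparison, eff_d in effects:
        if name not in col:
            raise ValueError(f"unknown subcortical structure {name!r}")
        values[groups == comparison.positive_group, col[name]] += eff_d * base_sd
    vols = pd.DataFrame(values, columns=list(SUBCORTICAL_LABELS))
    return pd.concat([meta, vols], axis=1)
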