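"""Synthetic cohort generators.

Three generators emulate the statistical structure the analysis needs:

* screening cohorts — an OSA-diagnosed group and a smaller control
  group whose neck circumference (NC) marginals follow published
  summary moments, for ROC/cutoff analysis;
* a CPAP-titration cohort with AHI before and after one treatment
  night, where the probability of dropping from severe to norm/mild
  depends on the patient's thick-neck class, and NC–AHI rank
  dependence is induced by a Gaussian copula;
* a planted-partition cohort that copies class archetypes with
  independent per-slot noise, for community-recovery experiments.

All physiological marginals are truncated-at-zero normals; the Epworth
score is a rounded truncated normal clipped to [0, 24]. Generators are
bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import (
    DEFAULT_RULES,
    ClassProfile,
    DiscretizationRules,
    PatientRecord,
    Severity,
    classify_ahi_severity,
)

__all__ = [
    "CohortSpec",
    "ResponseModelSpec",
    "ClusteredCohort",
    "D1_SPEC",
    "D2_SPEC",
    "D3_SPEC",
    "D1_ARCHETYPES",
    "D1_COMMUNITY_SIZES",
    "generate_screening_cohorts",
    "generate_d1_like",
    "generate_clustered_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Marginal moments and structure of one synthetic cohort.

    Means/SDs are (mean, sd) pairs in the units of the measurement:
    age in years, BMI in kg/m², NC in cm, ESS in scale points, AHI in
    events/h. ``nc_ahi_rank_corr`` is the target Spearman correlation
    between NC and pre-treatment AHI. ``severe_fraction`` is the share
    of patients whose pre-treatment AHI is in the severe class (the
    remainder are moderate); ``None`` leaves the AHI marginal an
    unconstrained truncated normal.
    """

    n: int
    gender_mix: float  # fraction male
    age: tuple[float, float]
    bmi: tuple[float, float]
    nc: tuple[float, float]
    ess: tuple[float, float]
    ahi_before: tuple[float, float]
    nc_ahi_rank_corr: float = 0.35
    hbp_prevalence: float = 0.6
    severe_fraction: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        for name in ("gender_mix", "hbp_prevalence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("age", "bmi", "nc", "ess", "ahi_before"):
            _, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name} SD must be positive")
        if not (-1.0 < self.nc_ahi_rank_corr < 1.0):
            raise ValueError("nc_ahi_rank_corr must lie in (-1, 1)")
        if self.severe_fraction is not None and not (
            0.0 <= self.severe_fraction <= 1.0
        ):
            raise ValueError("severe_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ResponseModelSpec:
    """One-night CPAP response model.

    A patient who is severe before treatment ends in the norm/mild
    band with probability ``p_improve_thick_neck`` or
    ``p_improve_thin_neck`` according to their thick-neck class;
    otherwise they remain in the moderate/severe band. Defaults sit in
    the middle of the 87–89% (thick) and 68–78% (thin) improvement
    ranges the community analysis produces.
    """

    p_improve_thick_neck: float = 0.88
    p_improve_thin_neck: float = 0.73
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_improve_thick_neck", "p_improve_thin_neck"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# Cohort summary moments (CPAP-titration cohort; OSA-diagnosed male
# screening cohort; non-OSA male control cohort).
D1_SPEC = CohortSpec(
    n=145,
    gender_mix=0.7724,
    age=(52.79, 12.32),
    bmi=(33.17, 6.64),
    nc=(43.12, 5.06),
    ess=(11.81, 4.98),
    ahi_before=(52.28, 23.58),
    nc_ahi_rank_corr=0.35,
    hbp_prevalence=0.65,
    severe_fraction=0.9793,
)
D2_SPEC = CohortSpec(
    n=836,
    gender_mix=1.0,
    age=(51.75, 12.47),
    bmi=(33.13, 6.37),
    nc=(44.91, 4.45),
    ess=(10.01, 5.07),
    ahi_before=(41.68, 24.07),
    nc_ahi_rank_corr=0.35,
    hbp_prevalence=0.6,
)
D3_SPEC = CohortSpec(
    n=65,
    gender_mix=1.0,
    age=(43.63, 18.66),
    bmi=(27.81, 6.37),
    nc=(40.67, 5.77),
    ess=(6.73, 5.06),
    ahi_before=(6.01, 2.42),
    nc_ahi_rank_corr=0.35,
    hbp_prevalence=0.4,
)

#: Archetype class profiles of the four CPAP-response communities
#: (majority class per slot in each community) and their sizes.
D1_ARCHETYPES = (
    ClassProfile("M", 2, True, True, True, True),  # C1
    ClassProfile("M", 2, True, True, True, False),  # C2
    ClassProfile("M", 2, False, False, False, False),  # C3
    ClassProfile("F", 2, True, True, False, True),  # C4
)
D1_COMMUNITY_SIZES = (55, 32, 29, 29)


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula correlation with a given Spearman rho: r = 2 sin(pi*rho_s/6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _truncnorm(mean: float, sd: float, lo: float = 0.0, hi: float = math.inf):
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def _copula_uniforms(rng: np.random.Generator, n: int, rho_s: float):
    """Pairs of uniforms with Gaussian-copula dependence at Spearman rho_s."""
    r = spearman_to_pearson(rho_s)
    z = rng.standard_normal((n, 2))
    z2 = r * z[:, 0] + math.sqrt(1.0 - r * r) * z[:, 1]
    return stats.norm.cdf(z[:, 0]), stats.norm.cdf(z2)


def _sample_ess(rng: np.random.Generator, mean: float, sd: float, n: int):
    raw = _truncnorm(mean, sd, lo=-0.49, hi=24.49).ppf(rng.uniform(size=n))
    return np.clip(np.rint(raw), 0, 24).astype(int)


def _ahi_ppf(u: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Inverse CDF of the pre-treatment AHI marginal.

    When ``severe_fraction`` is set, the marginal is the truncated
    normal conditioned to [30, inf) with that probability and to
    [15, 30) otherwise; the mapping is strictly monotone in *u*, so
    copula rank dependence is preserved.
    """
    mean, sd = spec.ahi_before
    if spec.severe_fraction is None:
        return _truncnorm(mean, sd).ppf(u)
    sf = spec.severe_fraction
    out = np.empty_like(u)
    low = u < (1.0 - sf)
    if low.any():
        v = u[low] / (1.0 - sf)
        out[low] = _truncnorm(mean, sd, lo=15.0, hi=30.0).ppf(v)
    if (~low).any():
        v = (u[~low] - (1.0 - sf)) / sf
        out[~low] = _truncnorm(mean, sd, lo=30.0).ppf(v)
    return out


def _base_records(
    spec: CohortSpec,
    rng: np.random.Generator,
    prefix: str,
    osa_label: Optional[bool],
) -> list[PatientRecord]:
    n = spec.n
    u_nc, u_ahi = _copula_uniforms(rng, n, spec.nc_ahi_rank_corr)
    nc = _truncnorm(*spec.nc).ppf(u_nc)
    ahi = _ahi_ppf(u_ahi, spec)
    age = _truncnorm(*spec.age).ppf(rng.uniform(size=n))
    bmi = _truncnorm(*spec.bmi).ppf(rng.uniform(size=n))
    ess = _sample_ess(rng, *spec.ess, n)
    male = rng.uniform(size=n) < spec.gender_mix
    hbp = rng.uniform(size=n) < spec.hbp_prevalence
    return [
        PatientRecord(
            id=f"{prefix}{i:04d}",
            gender="male" if male[i] else "female",
            age=float(age[i]),
            bmi=float(bmi[i]),
            neck_circumference=float(nc[i]),
            ess=int(ess[i]),
            ahi_before=float(ahi[i]),
            hbp_flag=bool(hbp[i]),
            osa_label=osa_label,
        )
        for i in range(n)
    ]


def generate_screening_cohorts(
    spec_osa: CohortSpec = D2_SPEC,
    spec_control: CohortSpec = D3_SPEC,
    seed: Optional[int] = None,
) -> list[PatientRecord]:
    """Generate an OSA-labeled screening cohort and its control cohort.

    Returns one list with ``osa_label`` set to True for the diagnosed
    group and False for the controls. The NC marginal of each group is
    a truncated-at-zero normal at the spec's moments.
    """
    rng = np.random.default_rng(spec_osa.seed if seed is None else seed)
    osa = _base_records(spec_osa, rng, "osa-", osa_label=True)
    ctl = _base_records(spec_control, rng, "ctl-", osa_label=False)
    return osa + ctl


def _draw_ahi_after(
    rng: np.random.Generator, improved: np.ndarray, spec: CohortSpec
) -> np.ndarray:
    """Post-treatment AHI: norm/mild band if improved, mod/sev band otherwise."""
    n = improved.size
    u = rng.uniform(size=n)
    out = np.empty(n)
    out[improved] = _truncnorm(7.0, 5.0, lo=0.0, hi=15.0).ppf(u[improved])
    out[~improved] = _truncnorm(32.0, 14.0, lo=15.0).ppf(u[~improved])
    return out


def generate_d1_like(
    spec: CohortSpec = D1_SPEC,
    response: ResponseModelSpec = ResponseModelSpec(),
    seed: Optional[int] = None,
    rules: DiscretizationRules = DEFAULT_RULES,
) -> list[PatientRecord]:
    """Generate a CPAP-titration cohort with AHI before and after.

    Pre-treatment AHI is drawn so that ``spec.severe_fraction`` of
    patients are severe; each severe patient improves to the norm/mild
    band with the response-model probability of their thick-neck
    class. Moderate-before patients follow the same improvement rule.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    base = _base_records(spec, rng, "d1-", osa_label=True)
    thick = np.array(
        [
            r.neck_circumference
            >= (rules.nc_thick_male if r.gender == "male" else rules.nc_thick_female)
            for r in base
        ]
    )
    p = np.where(
        thick, response.p_improve_thick_neck, response.p_improve_thin_neck
    )
    improved = rng.uniform(size=len(base)) < p
    ahi_after = _draw_ahi_after(rng, improved, spec)
    return [
        replace(r, ahi_after=float(a)) for r, a in zip(base, ahi_after)
    ]


@dataclass(frozen=True)
class ClusteredCohort:
    """A planted-partition cohort: records, their class profiles, and truth."""

    records: list[PatientRecord]
    profiles: dict[str, ClassProfile]
    labels: dict[str, int]  # ground-truth community per patient id


_AGE_RANGES = {0: (8.0, 20.0), 1: (20.0, 40.0), 2: (40.0, 60.0), 3: (60.0, 84.0)}


def _flip_profile(
    p: ClassProfile, flip_prob: float, rng: np.random.Generator
) -> ClassProfile:
    gender = p.gender_class
    if rng.random() < flip_prob:
        gender = "F" if gender == "M" else "M"
    age = p.age_group
    if rng.random() < flip_prob:
        age = int(rng.choice([g for g in range(4) if g != p.age_group]))
    flips = rng.random(4) < flip_prob
    return ClassProfile(
        gender_class=gender,
        age_group=age,
        hbp=p.hbp ^ bool(flips[0]),
        obese=p.obese ^ bool(flips[1]),
        thick_neck=p.thick_neck ^ bool(flips[2]),
        sleepiness=p.sleepiness ^ bool(flips[3]),
    )


def _materialize(
    pid: str,
    prof: ClassProfile,
    spec: CohortSpec,
    rng: np.random.Generator,
    rules: DiscretizationRules,
) -> PatientRecord:
    """Continuous measurements consistent with a class profile.

    Each value is drawn from the cohort marginal conditioned to the
    side of the class cutoff the profile dictates, so re-discretizing
    the record recovers the profile exactly.
    """
    lo, hi = _AGE_RANGES[prof.age_group]
    age = rng.uniform(lo + 1e-6, hi)
    bmean, bsd = spec.bmi
    bmi = (
        _truncnorm(bmean, bsd, lo=rules.bmi_obese + 1e-9).ppf(rng.random())
        if prof.obese
        else _truncnorm(bmean, bsd, lo=12.0, hi=rules.bmi_obese).ppf(rng.random())
    )
    cutoff = rules.nc_thick_male if prof.gender_class == "M" else rules.nc_thick_female
    nmean, nsd = spec.nc
    nc = (
        _truncnorm(nmean, nsd, lo=cutoff).ppf(rng.random())
        if prof.thick_neck
        else _truncnorm(nmean, nsd, lo=25.0, hi=cutoff - 1e-9).ppf(rng.random())
    )
    emean, esd = spec.ess
    ess = (
        int(np.rint(_truncnorm(emean, esd, lo=rules.ess_sleepy, hi=24.4).ppf(rng.random())))
        if prof.sleepiness
        else int(np.rint(_truncnorm(emean, esd, lo=-0.4, hi=rules.ess_sleepy - 0.6).ppf(rng.random())))
    )
    amean, asd = spec.ahi_before
    ahi = _truncnorm(amean, asd, lo=30.0).ppf(rng.random())
    return PatientRecord(
        id=pid,
        gender="male" if prof.gender_class == "M" else "female",
        age=float(age),
        bmi=float(bmi),
        neck_circumference=float(nc),
        ess=ess,
        ahi_before=float(ahi),
        hbp_flag=prof.hbp,
        osa_label=True,
    )


def generate_clustered_cohort(
    archetypes: Sequence[ClassProfile] = D1_ARCHETYPES,
    sizes: Sequence[int] = D1_COMMUNITY_SIZES,
    flip_prob: float = 0.05,
    seed: int = 0,
    response: Optional[ResponseModelSpec] = None,
    spec: CohortSpec = D1_SPEC,
    rules: DiscretizationRules = DEFAULT_RULES,
) -> ClusteredCohort:
    """Planted-partition cohort for community-recovery experiments.

    Each patient copies its archetype's six classes with every slot
    independently perturbed with probability *flip_prob* (booleans
    flip; the age group is resampled among the other three groups).
    Continuous measurements are drawn conditional on the realized
    classes; all patients are severe before treatment. When *response*
    is given, post-treatment AHI is attached according to the realized
    thick-neck class.

    Recovery of the planted partition by modularity maximization is
    only expected when archetypes differ pairwise in at least three of
    the six slots; closer archetypes produce densely interconnected
    blocks that a resolution-1 modularity optimum merges.
    """
    if len(archetypes) == 0:
        raise ValueError("need at least one archetype")
    if len(archetypes) != len(sizes):
        raise ValueError("archetypes and sizes must have equal length")
    if not (0.0 <= flip_prob < 0.5):
        raise ValueError("flip_prob must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    profiles: dict[str, ClassProfile] = {}
    labels: dict[str, int] = {}
    i = 0
    for k, (arch, size) in enumerate(zip(archetypes, sizes)):
        for _ in range(size):
            pid = f"pp-{i:04d}"
            prof = _flip_profile(arch, flip_prob, rng)
            records.append(_materialize(pid, prof, spec, rng, rules))
            profiles[pid] = prof
            labels[pid] = k
            i += 1
    if response is not None:
        p = np.array(
            [
                response.p_improve_thick_neck
                if profiles[r.id].thick_neck
                else response.p_improve_thin_neck
                for r in records
            ]
        )
        improved = rng.uniform(size=len(records)) < p
        after = _draw_ahi_after(rng, improved, spec)
        records = [replace(r, ahi_after=float(a)) for r, a in zip(records, after)]
    return ClusteredCohort(records=records, profiles=profiles, labels=labels)
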