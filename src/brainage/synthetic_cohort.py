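"""Synthetic multimodal brain-aging cohort generator.

Real cohorts of this kind (adult-lifespan controls plus amyloid-negative /
amyloid-positive cognitively normal and cognitively impaired groups) are
access-restricted, so this module generates cohorts carrying the statistical
structure the downstream analysis assumes:

* an adult-lifespan training set (default ages 18-89) of amyloid-negative
  controls, and three analysis groups (CN/A-, CN/A+, CI) with realistic
  age/sex/education demographics;
* per-modality latent "effective brain ages": each participant's functional
  and structural features are driven by ``age + planted group shift +
  participant-level dispersion``, so that a brain-age-gap construct is well
  defined and its recovery testable;
* a biphasic functional-connectivity effect (younger-appearing CN/A+,
  older-appearing CI) and a monotone structural effect in CI;
* site/scanner batch location-scale effects on every feature;
* a head-motion confound injected into a subset of FC edges;
* amyloid/tau biomarkers and a cognitive composite coupled to the structural
  effective-age gap within the CI group only.

All randomness is routed through a single integer seed; identical specs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable

GENERATOR_VERSION = "1.0"

GROUPS = ("CN_Aneg", "CN_Apos", "CI")

#: Analysis-group age distributions (mean, SD in years): CN/A-, CN/A+, CI.
DEFAULT_GROUP_AGES = {
    "CN_Aneg": (66.93, 8.53),
    "CN_Apos": (72.56, 7.15),
    "CI": (75.67, 6.86),
}

#: Fraction female per analysis group (CN/A- 89/144, CN/A+ 91/154, CI 68/154).
_FEMALE_FRAC = {"CN_Aneg": 89 / 144, "CN_Apos": 91 / 154, "CI": 68 / 154}

#: Education (mean, SD years) per analysis group.
_EDU = {"CN_Aneg": (15.71, 2.65), "CN_Apos": (15.90, 2.64), "CI": (15.05, 2.97)}

#: CDR staging probabilities within the CI group (0.5 / 1 / 2).
_CDR_CI_P = np.array([119, 35, 2], dtype=float) / 156.0

#: Biomarker availability fractions per group: amyloid PET, CSF, tau PET, cognition.
_AVAIL = {
    "CN_Aneg": {"pet": 1.0, "csf": 120 / 144, "tau": 42 / 144, "cog": 1.0},
    "CN_Apos": {"pet": 1.0, "csf": 137 / 154, "tau": 40 / 154, "cog": 153 / 154},
    "CI": {"pet": 57 / 154, "csf": 43 / 154, "tau": 17 / 154, "cog": 148 / 154},
}

# Synthetic centiloid -> tracer SUVR maps. The published centiloid conversion
# coefficients are tracer- and pipeline-specific and are not modelled here;
# these linear maps place both published positivity cutoffs (PIB > 1.42,
# AV45 > 1.19) at a centiloid of ~24, so PET and CSF status agree by design.
_PIB_OF_CL = lambda cl: 1.0 + 0.0175 * cl
_AV45_OF_CL = lambda cl: 1.0 + 0.008 * cl


@dataclass
class PlantedEffects:
    """Magnitudes of the effects planted in a synthetic cohort.

    Latent brain-age shifts are in years; biomarker/cognition slopes are per
    year of structural effective-age gap, on each outcome's natural scale
    (centiloid, tau-PET SUVR, composite z).
    """

    fc_bag_shift_cnApos: float = -1.64
    fc_bag_shift_ci: float = 2.17
    s_bag_shift_ci: float = 5.10
    batch_loc_sd: float = 1.0     # site location shift, units of feature noise SD
    batch_scale_sd: float = 0.15  # SD of log site scale factor
    tau_slope_ci: float = 0.02
    amyloid_slope_ci: float = 0.79
    cog_slope_ci: float = -0.03
    fd_confound_strength: float = 0.5

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"PlantedEffects.{f.name} must be finite, got {v}")
        if self.batch_loc_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("batch effect SDs must be >= 0")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; same seed => identical output.

    Defaults are desk scale: 390 training participants, 150 per analysis
    group, 50 ROIs (1,225 FC edges) and 101 structural features (68 cortical
    thickness + 33 subcortical volumes).
    """

    n_train: int = 390
    n_per_group: tuple[int, int, int] = (150, 150, 150)
    n_roi: int = 50
    n_struct_thickness: int = 68
    n_struct_volume: int = 33
    n_sites: int = 3
    age_range_train: tuple[float, float] = (18.0, 89.0)
    group_age_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_AGES))
    planted_effects: PlantedEffects = field(default_factory=PlantedEffects)
    #: participant-level dispersion of each latent effective age (years)
    fc_latent_sd: float = 8.0
    s_latent_sd: float = 5.0
    #: correlation between the two latent dispersions
    latent_coupling: float = 0.1
    #: fraction of FC edges carrying age signal / motion confound
    fc_signal_frac: float = 0.30
    fc_motion_frac: float = 0.20
    #: fraction of CI participants who are amyloid-positive
    ci_amyloid_pos_frac: float = 0.90
    seed: int = 0

    @property
    def n_struct(self) -> int:
        return self.n_struct_thickness + self.n_struct_volume

    @property
    def n_edges(self) -> int:
        return self.n_roi * (self.n_roi - 1) // 2

    def validate(self) -> None:
        counts = (self.n_train, *self.n_per_group, self.n_roi,
                  self.n_struct_thickness, self.n_sites)
        if any(c < 1 for c in counts):
            raise ValueError("all cohort counts must be >= 1")
        lo, hi = self.age_range_train
        if not (0 < lo < hi):
            raise ValueError("age_range_train must be positive and increasing")
        for g in GROUPS:
            m, s = self.group_age_params[g]
            if s <= 0 or m <= 0:
                raise ValueError(f"group_age_params[{g}] must be positive")
        if not (0 <= self.latent_coupling < 1):
            raise ValueError("latent_coupling must be in [0, 1)")
        self.planted_effects.validate()


@dataclass
class BiomarkerPanel:
    """Per-participant amyloid/tau biomarker measures; ``None`` = unavailable."""

    pib_suvr: float | None = None
    av45_suvr: float | None = None
    amyloid_centiloid: float | None = None
    csf_ab42_ab40: float | None = None
    tau_pet_suvr: float | None = None
    csf_ptau_ab40: float | None = None

    def has_amyloid_measure(self) -> bool:
        return any(v is not None for v in
                   (self.pib_suvr, self.av45_suvr, self.csf_ab42_ab40))


@dataclass
class ParticipantRecord:
    id: str
    age: float
    sex: str                 # "female" | "male"
    education: float
    group: str               # CN_Aneg | CN_Apos | CI
    cdr: float               # 0 / 0.5 / 1 / 2
    amyloid_positive: bool
    site: str
    mean_fd: float
    biomarkers: BiomarkerPanel = field(default_factory=BiomarkerPanel)
    cognition: float | None = None
    role: str = "analysis"   # "train" | "analysis"

    def __post_init__(self) -> None:
        if self.group.startswith("CN") and self.cdr != 0:
            raise ValueError(f"{self.id}: CN participant with CDR {self.cdr}")
        if self.group == "CN_Aneg" and self.amyloid_positive:
            raise ValueError(f"{self.id}: CN_Aneg participant flagged amyloid-positive")
        if self.mean_fd <= 0:
            raise ValueError(f"{self.id}: mean FD must be > 0")


@dataclass
class Cohort:
    """A generated cohort plus its ground-truth latents (for validation only)."""

    spec: CohortSpec
    participants: list[ParticipantRecord]
    fc: FeatureTable
    struct: FeatureTable
    latents: pd.DataFrame  # columns: eff_fc, eff_s, gap_fc, gap_s

    @property
    def frame(self) -> pd.DataFrame:
        return participants_to_frame(self.participants)


def participants_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Flatten ParticipantRecords to one row per participant."""
    rows = []
    for p in records:
        b = p.biomarkers
        rows.append({
            "id": p.id, "role": p.role, "group": p.group, "age": p.age,
            "sex": p.sex, "education": p.education, "cdr": p.cdr,
            "amyloid_positive": p.amyloid_positive, "site": p.site,
            "mean_fd": p.mean_fd, "pib_suvr": b.pib_suvr,
            "av45_suvr": b.av45_suvr, "amyloid_centiloid": b.amyloid_centiloid,
            "csf_ab42_ab40": b.csf_ab42_ab40, "tau_pet_suvr": b.tau_pet_suvr,
            "csf_ptau_ab40": b.csf_ptau_ab40, "cognition": p.cognition,
        })
    return pd.DataFrame(rows).set_index("id")


# --------------------------------------------------------------------------
# latent structure

def _latent_shifts(group: str, eff: PlantedEffects) -> tuple[float, float]:
    """(FC shift, structural shift) in years for one analysis group."""
    if group == "CN_Apos":
        return eff.fc_bag_shift_cnApos, 0.0
    if group == "CI":
        return eff.fc_bag_shift_ci, eff.s_bag_shift_ci
    return 0.0, 0.0


def _draw_latents(rng, ages, shifts_fc, shifts_s, spec: CohortSpec):
    n = len(ages)
    cov = np.array([[1.0, spec.latent_coupling], [spec.latent_coupling, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    eff_fc = ages + shifts_fc + z[:, 0] * spec.fc_latent_sd
    eff_s = ages + shifts_s + z[:, 1] * spec.s_latent_sd
    return eff_fc, eff_s


# --------------------------------------------------------------------------
# feature synthesis

def _fc_feature_names(n_roi: int) -> list[str]:
    i, j = np.triu_indices(n_roi, k=1)
    return [f"roi{a + 1}__roi{b + 1}" for a, b in zip(i, j)]


def _struct_feature_names(spec: CohortSpec) -> list[str]:
    return ([f"ct_region_{k + 1:02d}" for k in range(spec.n_struct_thickness)]
            + [f"vol_region_{k + 1:02d}" for k in range(spec.n_struct_volume)])


def _make_fc_features(rng, eff_fc, mean_fd, sites, spec: CohortSpec) -> np.ndarray:
    """FC edges: smooth functions of FC-effective-age on a random edge subset,
    plus edge noise, site location/scale effects, and an FD confound."""
    pe = spec.planted_effects
    m = spec.n_edges
    lo, hi = spec.age_range_train
    u = (eff_fc - (lo + hi) / 2) / ((hi - lo) / 2)   # ~[-1, 1] over the lifespan

    baseline = rng.normal(0.3, 0.15, size=m)
    noise_sd = 0.08
    signal = np.zeros((len(u), m))
    sig_idx = rng.choice(m, size=int(round(spec.fc_signal_frac * m)),
                         replace=False)
    # every signal edge mixes a lifespan-wide linear trend with a smooth ramp
    # centred at an edge-specific age, so sensitivity to effective age never
    # vanishes anywhere on the adult range (edges change at different life
    # stages, but none saturates completely)
    slopes = rng.uniform(0.05, 0.15, size=sig_idx.size) * rng.choice([-1, 1], size=sig_idx.size)
    w_lin = rng.uniform(0.3, 0.7, size=sig_idx.size)
    centers = rng.uniform(lo + 7, hi - 4, size=sig_idx.size)
    widths = rng.uniform(10.0, 30.0, size=sig_idx.size)
    ramp = np.tanh((eff_fc[:, None] - centers[None, :]) / widths[None, :])
    signal[:, sig_idx] = (w_lin * u[:, None] + (1.0 - w_lin) * ramp) * slopes

    fd_idx = rng.choice(m, size=int(round(spec.fc_motion_frac * m)),
                        replace=False)
    fd_term = np.zeros((len(u), m))
    fd_term[:, fd_idx] = pe.fd_confound_strength * (mean_fd - 0.15)[:, None]

    site_codes = pd.Categorical(sites).codes
    gamma = rng.normal(0.0, pe.batch_loc_sd * noise_sd, size=(spec.n_sites, m))
    delta = np.exp(rng.normal(0.0, pe.batch_scale_sd, size=(spec.n_sites, m)))
    eps = rng.normal(0.0, noise_sd, size=(len(u), m))
    return (baseline + signal + fd_term
            + gamma[site_codes] + delta[site_codes] * eps)


def _make_struct_features(rng, eff_s, sites, spec: CohortSpec) -> np.ndarray:
    """Structural features: monotone decreasing in structural effective age."""
    pe = spec.planted_effects
    lo, hi = spec.age_range_train
    span = hi - lo
    site_codes = pd.Categorical(sites).codes
    n = len(eff_s)

    # cortical thickness (mm): linear thinning with feature-specific rates
    n_t = spec.n_struct_thickness
    base_t = rng.normal(2.5, 0.25, size=n_t)
    rate_t = np.exp(rng.normal(np.log(0.004), 0.4, size=n_t))
    noise_t = 0.05
    thick = base_t + np.outer(-(eff_s - lo), rate_t)

    # subcortical volumes (mm^3): fractional linear decline
    n_v = spec.n_struct_volume
    base_v = np.exp(rng.normal(np.log(3000.0), 0.8, size=n_v))
    frac_v = rng.uniform(0.10, 0.35, size=n_v)
    noise_v = 0.02 * base_v
    vol = base_v * (1.0 - np.outer((eff_s - lo) / span, frac_v))

    x = np.concatenate([thick, vol], axis=1)
    noise_sd = np.concatenate([np.full(n_t, noise_t), noise_v])
    m = x.shape[1]
    gamma = rng.normal(0.0, pe.batch_loc_sd, size=(spec.n_sites, m)) * noise_sd
    delta = np.exp(rng.normal(0.0, pe.batch_scale_sd, size=(spec.n_sites, m)))
    eps = rng.normal(0.0, 1.0, size=(n, m)) * noise_sd
    return x + gamma[site_codes] + delta[site_codes] * eps


# --------------------------------------------------------------------------
# biomarkers, cognition

def _amyloid_biomarkers(rng, positive: bool, group: str, s_gap: float,
                        pe: PlantedEffects, avail_pet: bool, avail_csf: bool):
    """Centiloid / tracer SUVRs / CSF ratio consistent with intended status."""
    if positive:
        if group == "CI":
            cl = 30.0 + np.exp(rng.normal(np.log(25.0), 0.6)) + pe.amyloid_slope_ci * s_gap
        else:
            cl = 25.0 + np.exp(rng.normal(np.log(20.0), 0.6))
        cl = max(cl, 28.0)
        csf = float(np.clip(rng.normal(0.055, 0.007), 0.020, 0.066))
    else:
        cl = -5.0 + np.exp(rng.normal(np.log(9.0), 0.5))
        cl = min(cl, 18.0)
        csf = float(np.clip(rng.normal(0.085, 0.008), 0.070, 0.120))
    pib = av45 = centiloid = csf_out = None
    if avail_pet:
        centiloid = float(cl)
        # one tracer per participant, PIB twice as common as AV45
        if rng.uniform() < 2 / 3:
            pib = float(_PIB_OF_CL(cl) + rng.normal(0, 0.01))
        else:
            av45 = float(_AV45_OF_CL(cl) + rng.normal(0, 0.01))
    if avail_csf:
        csf_out = csf
    return pib, av45, centiloid, csf_out


def _tau_cog(rng, group: str, s_gap: float, pe: PlantedEffects,
             avail_tau: bool, avail_csf: bool, avail_cog: bool):
    if group == "CI":
        tau = 1.25 + pe.tau_slope_ci * s_gap + rng.normal(0, 0.12)
        logp = np.log(0.035) + pe.tau_slope_ci * s_gap + rng.normal(0, 0.30)
        cog = -1.2 + pe.cog_slope_ci * s_gap + rng.normal(0, 0.7)
    else:
        mu = 1.15 if group == "CN_Apos" else 1.10
        tau = rng.normal(mu, 0.09)
        logp = np.log(0.025 if group == "CN_Apos" else 0.015) + rng.normal(0, 0.30)
        cog = rng.normal(-0.1 if group == "CN_Apos" else 0.0, 0.6)
    tau_out = float(max(tau, 0.6)) if avail_tau else None
    ptau_out = float(np.exp(logp)) if avail_csf else None
    cog_out = float(cog) if avail_cog else None
    return tau_out, ptau_out, cog_out


# --------------------------------------------------------------------------
# public API

def generate_cohort(spec: CohortSpec):
    """Generate participants plus FC and structural feature tables.

    Returns ``(participants, fc_table, struct_table)``; use
    :func:`generate_cohort_full` to also obtain the ground-truth latents.
    """
    c = generate_cohort_full(spec)
    return c.participants, c.fc, c.struct


def generate_cohort_full(spec: CohortSpec) -> Cohort:
    spec.validate()
    pe = spec.planted_effects
    for g, n in zip(GROUPS, spec.n_per_group):
        shifts = _latent_shifts(g, pe)
        if n == 0 and any(s != 0 for s in shifts):
            raise ValueError(f"group {g} has a planted effect but n_per_group=0")

    ss = np.random.SeedSequence(spec.seed)
    (r_demo, r_lat, r_fc, r_st, r_bio) = [np.random.default_rng(s) for s in ss.spawn(5)]

    lo, hi = spec.age_range_train
    sites = [f"site{k + 1}" for k in range(spec.n_sites)]

    ids, roles, groups_, ages, sexes, edus, cdrs, site_l, fds = ([] for _ in range(9))
    # training set: amyloid-negative controls across the adult lifespan
    for i in range(spec.n_train):
        ids.append(f"sub-{i + 1:04d}")
        roles.append("train")
        groups_.append("CN_Aneg")
        ages.append(r_demo.uniform(lo, hi))
        sexes.append("female" if r_demo.uniform() < 0.55 else "male")
        edus.append(float(np.clip(r_demo.normal(15.0, 2.7), 8, 22)))
        cdrs.append(0.0)
        site_l.append(sites[r_demo.integers(spec.n_sites)])
        fds.append(float(np.clip(np.exp(r_demo.normal(np.log(0.13), 0.30)), 0.03, 0.295)))
    # analysis groups
    k = spec.n_train
    for g, n in zip(GROUPS, spec.n_per_group):
        m, s = spec.group_age_params[g]
        fd_loc = np.log(0.16) if g == "CI" else np.log(0.13)
        for _ in range(n):
            ids.append(f"sub-{k + 1:04d}")
            k += 1
            roles.append("analysis")
            groups_.append(g)
            ages.append(float(np.clip(r_demo.normal(m, s), lo, hi)))
            sexes.append("female" if r_demo.uniform() < _FEMALE_FRAC[g] else "male")
            em, es = _EDU[g]
            edus.append(float(np.clip(r_demo.normal(em, es), 8, 22)))
            cdrs.append(float(r_demo.choice([0.5, 1.0, 2.0], p=_CDR_CI_P))
                        if g == "CI" else 0.0)
            site_l.append(sites[r_demo.integers(spec.n_sites)])
            fds.append(float(np.clip(np.exp(r_demo.normal(fd_loc, 0.30)), 0.03, 0.295)))

    ages = np.asarray(ages)
    fds_a = np.asarray(fds)
    shift_fc = np.array([_latent_shifts(g, pe)[0] for g in groups_])
    shift_s = np.array([_latent_shifts(g, pe)[1] for g in groups_])
    eff_fc, eff_s = _draw_latents(r_lat, ages, shift_fc, shift_s, spec)

    fc_vals = _make_fc_features(r_fc, eff_fc, fds_a, site_l, spec)
    st_vals = _make_struct_features(r_st, eff_s, site_l, spec)

    # biomarkers / cognition, coupled to the structural gap within CI only
    from .bagstats import amyloid_positivity  # deferred: avoid import cycle at module load

    records: list[ParticipantRecord] = []
    for i, pid in enumerate(ids):
        g, role = groups_[i], roles[i]
        s_gap = float(eff_s[i] - ages[i])
        if role == "train":
            # controls: amyloid-negative by design; older ones carry measures
            has_bio = ages[i] > 50
            pib, av45, cl, csf = _amyloid_biomarkers(
                r_bio, False, g, s_gap, pe, avail_pet=has_bio, avail_csf=has_bio)
            panel = BiomarkerPanel(pib, av45, cl, csf, None, None)
            pos = False
            cog = None
        else:
            av = _AVAIL[g]
            intended_pos = (g == "CN_Apos"
                            or (g == "CI" and r_bio.uniform() < spec.ci_amyloid_pos_frac))
            avail_pet = r_bio.uniform() < av["pet"]
            avail_csf = r_bio.uniform() < av["csf"]
            if g != "CI" and not (avail_pet or avail_csf):
                avail_csf = True          # CN groups are biomarker-defined
            pib, av45, cl, csf = _amyloid_biomarkers(
                r_bio, intended_pos, g, s_gap, pe, avail_pet, avail_csf)
            tau, ptau, cog = _tau_cog(r_bio, g, s_gap, pe,
                                      r_bio.uniform() < av["tau"], avail_csf,
                                      r_bio.uniform() < av["cog"])
            panel = BiomarkerPanel(pib, av45, cl, csf, tau, ptau)
            if panel.has_amyloid_measure():
                pos, _ = amyloid_positivity(panel)
            else:
                pos = intended_pos        # CI without measures: clinical diagnosis
        records.append(ParticipantRecord(
            id=pid, age=float(ages[i]), sex=sexes[i], education=edus[i],
            group=g, cdr=cdrs[i], amyloid_positive=bool(pos), site=site_l[i],
            mean_fd=float(fds_a[i]), biomarkers=panel,
            cognition=cog if role == "analysis" else None, role=role))

    idx = pd.Index(ids, name="id")
    batch = pd.Series(site_l, index=idx, name="batch")
    fc = FeatureTable(pd.DataFrame(fc_vals, index=idx,
                                   columns=_fc_feature_names(spec.n_roi)),
                      batch, modality="FC")
    st = FeatureTable(pd.DataFrame(st_vals, index=idx,
                                   columns=_struct_feature_names(spec)),
                      batch.copy(), modality="S")
    latents = pd.DataFrame({"eff_fc": eff_fc, "eff_s": eff_s,
                            "gap_fc": eff_fc - ages, "gap_s": eff_s - ages},
                           index=idx)
    return Cohort(spec=spec, participants=records, fc=fc, struct=st, latents=latents)


def generate_motion(spec: CohortSpec, n_frames: int,
                    fraction_high_motion: float = 0.0) -> dict[str, pd.DataFrame]:
    """Per-participant frame series of FD (mm) and DVARS.

    FD is gamma-distributed (positive, right-skewed) around each participant's
    mean FD; DVARS is a noisy series with spikes co-occurring with large FD
    excursions. ``fraction_high_motion`` relabels a random subset of
    participants to high motion (mean FD ~0.45 mm) so QC-exclusion paths can
    be exercised.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    cohort = generate_cohort_full(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x_F0)))
    out: dict[str, pd.DataFrame] = {}
    for p in cohort.participants:
        mean_fd = p.mean_fd
        if rng.uniform() < fraction_high_motion:
            mean_fd = rng.uniform(0.38, 0.55)
        shape = 3.0
        fd = rng.gamma(shape, mean_fd / shape, size=n_frames)
        dvars = rng.normal(100.0, 5.0, size=n_frames)
        spikes = fd > 2.0 * mean_fd
        dvars[spikes] += rng.uniform(15.0, 30.0, size=int(spikes.sum()))
        out[p.id] = pd.DataFrame({"frame": np.arange(n_frames), "fd": fd,
                                  "dvars": dvars}).set_index("frame")
    return out


def write_fixture(outdir: str | Path, spec: CohortSpec) -> dict[str, Path]:
    """Generate a cohort and write the standard fixture files.

    Emits ``participants.tsv``, ``fc_features.tsv``, ``struct_features.tsv``,
    ``latents.tsv`` (ground truth, for validation), a config snapshot and a
    ``manifest.json`` carrying the seed and generator version. Tables
    round-trip through :func:`read_fixture` / :meth:`FeatureTable.from_tsv`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort_full(spec)
    paths = {
        "participants": outdir / "participants.tsv",
        "fc": outdir / "fc_features.tsv",
        "struct": outdir / "struct_features.tsv",
        "latents": outdir / "latents.tsv",
        "config": outdir / "cohort_spec.json",
        "manifest": outdir / "manifest.json",
    }
    cohort.frame.to_csv(paths["participants"], sep="\t")
    cohort.fc.to_tsv(paths["fc"])
    cohort.struct.to_tsv(paths["struct"])
    cohort.latents.to_csv(paths["latents"], sep="\t")
    paths["config"].write_text(json.dumps(_spec_to_dict(spec), indent=2))
    paths["manifest"].write_text(json.dumps(
        {"seed": spec.seed, "generator_version": GENERATOR_VERSION,
         "n_participants": len(cohort.participants),
         "n_fc_features": spec.n_edges, "n_struct_features": spec.n_struct},
        indent=2))
    return paths


def read_fixture(outdir: str | Path):
    """Read back a fixture directory: (participants frame, FC, STRUCT, manifest)."""
    outdir = Path(outdir)
    part = pd.read_csv(outdir / "participants.tsv", sep="\t", index_col="id")
    fc = FeatureTable.from_tsv(outdir / "fc_features.tsv", modality="FC")
    st = FeatureTable.from_tsv(outdir / "struct_features.tsv", modality="S")
    manifest = json.loads((outdir / "manifest.json").read_text())
    return part, fc, st, manifest


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["n_per_group"] = list(d["n_per_group"])
    d["age_range_train"] = list(d["age_range_train"])
    return d


def spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    if "planted_effects" in d and isinstance(d["planted_effects"], dict):
        d["planted_effects"] = PlantedEffects(**d["planted_effects"])
    if "n_per_group" in d:
        d["n_per_group"] = tuple(d["n_per_group"])
    if "age_range_train" in d:
        d["age_range_train"] = tuple(d["age_range_train"])
    if "group_age_params" in d:
        d["group_age_params"] = {k: tuple(v) for k, v in d["group_age_params"].items()}
    return CohortSpec(**d)
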