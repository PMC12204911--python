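"""Synthetic twin cohorts with known A/D/C/E structure.

The generator draws MZ and DZ pairs whose latent trait components have the
textbook cross-twin correlations (A: 1 in MZ / 0.5 in DZ; D: 1 / 0.25;
C: shared; E: independent), adds linear sex/age/height mean effects for
continuous traits, and thresholds a unit-variance liability at a target
prevalence — with probit covariate effects on the threshold — for binary
traits.  The exact generating parameters are returned alongside the
cohort, so every pipeline stage can be tested for parameter recovery
without any external data.

``study_preset()`` mimics the marginals of a nationwide middle-aged twin
survey: 12,449 subjects aged 40-80, ~48% male, smoking 20/38/42
current/former/never, 991 asthmatics (assigned by exact count so the
exclusion funnel is reproducible), chronic bronchitis prevalence 3.7%,
clinical COPD about 2.5%, and generating heritabilities set to the
reported AE estimates (FEV1 0.64, FVC 0.61, FEV1/FVC 0.50, chronic
bronchitis 0.48 on the liability scale).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .continuous import MeanModel, VarianceComponents
from .liability import ThresholdModel, prevalence_to_threshold


@dataclass(frozen=True)
class ContinuousTraitSpec:
    """A continuous trait: variance fractions, scale and mean effects."""

    name: str
    components: VarianceComponents
    mean: MeanModel = MeanModel()


@dataclass(frozen=True)
class BinaryTraitSpec:
    """A binary trait generated by thresholding a latent liability.

    ``prevalence`` is the marginal case fraction; threshold covariate
    effects (probit scale, original units) shift individual thresholds
    around the base value implied by the prevalence.  ``column`` names the
    boolean cohort column receiving the indicator.
    """

    name: str
    components: VarianceComponents
    prevalence: float
    threshold: ThresholdModel = ThresholdModel()
    column: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class SimulationConfig:
    """Ground-truth generative parameters for a synthetic twin cohort."""

    n_mz_pairs: int = 1000
    n_dz_pairs: int = 1000
    dz_opposite_sex_fraction: float = 0.0
    n_singletons: int = 0
    male_fraction: float = 0.48
    age_range: tuple[float, float] = (40.0, 80.0)
    height_mean: dict = field(default_factory=lambda: {
        "female": 165.9, "male": 179.3})
    height_sd: dict = field(default_factory=lambda: {
        "female": 6.1, "male": 6.6})
    continuous_traits: list[ContinuousTraitSpec] = field(default_factory=list)
    binary_traits: list[BinaryTraitSpec] = field(default_factory=list)
    smoking_fractions: tuple[float, float, float] = (0.20, 0.38, 0.42)
    pack_years_mean: float = 19.2
    pack_years_sd: float = 18.0
    bmi_mean: float = 26.6
    bmi_sd: float = 4.4
    asthma_count: int | None = None     # exact count; None disables
    symptom_prevalence: float | None = None
    symptom_obstruction_link: float = 0.0   # corr(symptom liability, low ratio)
    ratio_intercept: float | None = None    # fev1_fvc_ratio = a + b * ratio_z
    ratio_slope: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for t in self.continuous_traits:
            _ = t.components          # VarianceComponents validates itself
        for t in self.binary_traits:
            _ = t.components
        if not 0.0 <= self.dz_opposite_sex_fraction <= 1.0:
            raise ValueError("dz_opposite_sex_fraction must be in [0, 1]")
        if abs(sum(self.smoking_fractions) - 1.0) > 1e-9:
            raise ValueError("smoking fractions must sum to 1")

    def to_json(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            raise TypeError(type(o).__name__)
        return json.dumps(asdict(self), default=default, indent=2)


# ---------------------------------------------------------------------------
# Latent machinery
# ---------------------------------------------------------------------------

_COMPONENT_CORR = {"a": (1.0, 0.5), "d": (1.0, 0.25),
                   "c": (1.0, 1.0), "e": (0.0, 0.0)}


def _pair_latent(components: VarianceComponents, is_mz: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """(n, 2) unit-variance latent trait with twin-design correlations."""
    n = len(is_mz)
    total = np.zeros((n, 2))
    fracs = {"a": components.a2, "d": components.d2,
             "c": components.c2, "e": components.e2}
    for comp, frac in fracs.items():
        z0 = rng.standard_normal(n)
        z1 = rng.standard_normal(n)      # drawn unconditionally: fixed stream
        if frac <= 0.0:
            continue
        r_mz, r_dz = _COMPONENT_CORR[comp]
        r = np.where(is_mz, r_mz, r_dz)
        first = z0
        second = r * z0 + np.sqrt(1.0 - r ** 2) * z1
        total[:, 0] += np.sqrt(frac) * first
        total[:, 1] += np.sqrt(frac) * second
    return total


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> tuple[Cohort, dict]:
    """Draw a twin cohort and return it with its ground-truth record.

    All randomness comes from one generator seeded with ``seed`` (falling
    back to ``config.seed``); draws are vectorized in a fixed order, so the
    same (config, seed) always yields the identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_dz_os = int(round(config.n_dz_pairs * config.dz_opposite_sex_fraction))
    n_dz_ss = config.n_dz_pairs - n_dz_os
    zyg_pairs = np.concatenate([
        np.repeat("MZ", config.n_mz_pairs),
        np.repeat("DZ_same_sex", n_dz_ss),
        np.repeat("DZ_opposite_sex", n_dz_os)])
    n_pairs = len(zyg_pairs)
    is_mz = zyg_pairs == "MZ"

    # -- demographics (twins share age; sex identical unless opposite-sex DZ)
    pair_sex = (rng.random(n_pairs) < config.male_fraction).astype(int)
    sex = np.stack([pair_sex, pair_sex], axis=1)
    os_mask = zyg_pairs == "DZ_opposite_sex"
    flip = rng.random(n_pairs) < 0.5        # which member is male
    sex[os_mask, 0] = flip[os_mask].astype(int)
    sex[os_mask, 1] = 1 - flip[os_mask].astype(int)

    lo, hi = config.age_range
    age = np.repeat(rng.uniform(lo, hi, n_pairs)[:, None], 2, axis=1)
    h_mean = np.array([config.height_mean["female"], config.height_mean["male"]])
    h_sd = np.array([config.height_sd["female"], config.height_sd["male"]])
    hm, hs = (lambda s: h_mean[s]), (lambda s: h_sd[s])
    height = hm(sex) + hs(sex) * rng.standard_normal((n_pairs, 2))

    n_single = config.n_singletons
    s_sex = (rng.random(n_single) < config.male_fraction).astype(int)
    s_age = rng.uniform(lo, hi, n_single)
    s_height = hm(s_sex) + hs(s_sex) * rng.standard_normal(n_single)
    s_zyg = np.where(rng.random(n_single) < 0.5, "MZ", "DZ_same_sex")

    n_subj = 2 * n_pairs + n_single
    df = pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n_subj)],
        "pair_id": (np.repeat([f"P{i:05d}" for i in range(n_pairs)], 2)
                    .tolist()
                    + [f"P{n_pairs + i:05d}" for i in range(n_single)]),
        "zygosity": np.concatenate([np.repeat(zyg_pairs, 2), s_zyg]),
        "sex": np.where(np.concatenate([sex.reshape(-1), s_sex]) == 1,
                        "male", "female"),
        "age": np.concatenate([age.reshape(-1), s_age]),
        "height": np.concatenate([height.reshape(-1), s_height]),
    })
    sex_all = np.concatenate([sex.reshape(-1), s_sex]).astype(float)
    age_all = df["age"].to_numpy()
    height_all = df["height"].to_numpy()
    x_all = np.column_stack([sex_all, age_all, height_all])

    truth: dict = {"seed": int(config.seed if seed is None else seed),
                   "n_mz_pairs": int(config.n_mz_pairs),
                   "n_dz_same_sex_pairs": int(n_dz_ss),
                   "n_dz_opposite_sex_pairs": int(n_dz_os),
                   "n_singletons": int(n_single),
                   "traits": {}}

    # -- continuous traits
    latents: dict[str, np.ndarray] = {}
    for spec in config.continuous_traits:
        lat_pairs = _pair_latent(spec.components, is_mz, rng)
        lat_single = rng.standard_normal(n_single)
        lat = np.concatenate([lat_pairs.reshape(-1), lat_single])
        latents[spec.name] = lat
        mu = spec.mean.predict(x_all)
        df[spec.name] = mu + spec.components.total_sd * lat
        truth["traits"][spec.name] = {
            "kind": "continuous",
            "components": asdict(spec.components),
            "mean": asdict(spec.mean)}

    # -- binary traits via liability thresholds
    for spec in config.binary_traits:
        lat_pairs = _pair_latent(spec.components, is_mz, rng)
        lat_single = rng.standard_normal(n_single)
        lat = np.concatenate([lat_pairs.reshape(-1), lat_single])
        t = spec.threshold
        shift = (t.gamma_sex * (sex_all - sex_all.mean())
                 + t.gamma_age * (age_all - age_all.mean())
                 + t.gamma_height * (height_all - height_all.mean()))
        # base threshold corrected for the covariate-induced variance so
        # the marginal prevalence hits the target
        scale = np.sqrt(1.0 + shift.var())
        t_base = prevalence_to_threshold(spec.prevalence) * scale
        case = lat + shift > t_base
        col = spec.column or spec.name
        df[col] = case
        truth["traits"][spec.name] = {
            "kind": "binary",
            "components": asdict(spec.components),
            "prevalence": spec.prevalence,
            "threshold_base": float(t_base),
            "threshold": asdict(t),
            "column": col}

    # -- derived raw ratio from its z-score
    if config.ratio_intercept is not None and "ratio_z" in df.columns:
        df["fev1_fvc_ratio"] = (config.ratio_intercept
                                + config.ratio_slope * df["ratio_z"])

    # -- respiratory symptom flags, optionally linked to low ratio
    if config.symptom_prevalence is not None:
        lam = config.symptom_obstruction_link
        if "ratio_z" in latents and lam:
            z = df["ratio_z"].to_numpy()
            u = -(z - z.mean()) / z.std()       # higher = worse obstruction
            s_lat = lam * u + np.sqrt(1 - lam ** 2) * rng.standard_normal(n_subj)
        else:
            s_lat = rng.standard_normal(n_subj)
        any_symptom = s_lat > prevalence_to_threshold(config.symptom_prevalence)
        dysp = any_symptom & (rng.random(n_subj) < 0.55)
        cough = any_symptom & (rng.random(n_subj) < 0.60)
        noct = any_symptom & (rng.random(n_subj) < 0.25)
        none_set = any_symptom & ~(dysp | cough | noct)
        cough = cough | none_set
        df["dyspnea"], df["cough"], df["nocturnal_symptoms"] = dysp, cough, noct
        truth["symptom_prevalence"] = config.symptom_prevalence
    elif "dyspnea" not in df.columns:
        df["dyspnea"] = df["cough"] = df["nocturnal_symptoms"] = False

    # -- smoking, pack-years, BMI
    cur, fmr, nvr = config.smoking_fractions
    smoking = rng.choice(np.array(["current", "former", "never"]),
                         size=n_subj, p=[cur, fmr, nvr])
    df["smoking"] = smoking
    ever = smoking != "never"
    shape = (config.pack_years_mean / config.pack_years_sd) ** 2
    scale_g = config.pack_years_sd ** 2 / config.pack_years_mean
    py = rng.gamma(shape, scale_g, n_subj)
    df["pack_years"] = np.where(ever, py, 0.0)
    df["bmi"] = config.bmi_mean + config.bmi_sd * rng.standard_normal(n_subj)

    # -- asthma by exact count (reproducible exclusion funnel)
    df["asthma"] = False
    if config.asthma_count:
        k = min(int(config.asthma_count), n_subj)
        idx = rng.choice(n_subj, size=k, replace=False)
        df.loc[df.index[idx], "asthma"] = True
        truth["asthma_count"] = int(k)

    if "chronic_cough_sputum" not in df.columns:
        df["chronic_cough_sputum"] = False
    for col in ("asthma", "chronic_cough_sputum", "dyspnea", "cough",
                "nocturnal_symptoms"):
        df[col] = df[col].astype("boolean")

    return Cohort(df), truth


# ---------------------------------------------------------------------------
# Study preset
# ---------------------------------------------------------------------------

#: reported AE heritabilities used as generating values in the preset
PRESET_HERITABILITY = {"fev1_z": 0.64, "fvc_z": 0.61, "ratio_z": 0.50,
                       "chronic_bronchitis": 0.48}


def study_preset(seed: int = 0, scale: float = 1.0) -> SimulationConfig:
    """The survey-mimicking configuration ("survey2011" preset).

    2,000 MZ + 2,600 same-sex DZ + 1,600 opposite-sex DZ pairs plus 49
    singletons (12,449 subjects; the survey's zygosity split is not
    published, these counts are declared assumptions), z-score traits with
    the reported AE heritabilities, chronic bronchitis at 3.7% liability
    prevalence, asthma as an exact 991-subject subset, and symptom flags
    weakly linked to low FEV1/FVC so that clinical COPD lands near 2.5%.
    ``scale`` shrinks all counts proportionally for quick runs.
    """
    def sc(n):
        return max(int(round(n * scale)), 1)

    ae = lambda a2, sd: VarianceComponents(a2=a2, e2=1 - a2, total_sd=sd)
    cfg = SimulationConfig(
        n_mz_pairs=sc(2000),
        n_dz_pairs=sc(2600) + sc(1600),
        dz_opposite_sex_fraction=sc(1600) / (sc(2600) + sc(1600)),
        n_singletons=max(int(round(49 * scale)), 1),
        continuous_traits=[
            ContinuousTraitSpec("fev1_z", ae(0.64, 1.11),
                                MeanModel(intercept=-0.30)),
            ContinuousTraitSpec("fvc_z", ae(0.61, 1.01),
                                MeanModel(intercept=-0.08)),
            ContinuousTraitSpec("ratio_z", ae(0.50, 1.01),
                                MeanModel(intercept=-0.42)),
        ],
        binary_traits=[
            BinaryTraitSpec("chronic_bronchitis", ae(0.48, 1.0),
                            prevalence=0.037,
                            threshold=ThresholdModel(0.0, 0.20, 0.015, -0.01),
                            column="chronic_cough_sputum"),
        ],
        asthma_count=int(round(991 * scale)),
        symptom_prevalence=0.30,
        symptom_obstruction_link=0.10,
        ratio_intercept=0.76,
        ratio_slope=0.0445,
        seed=seed,
    )
    return cfg


def simulate_study(seed: int = 0, scale: float = 1.0,
                   config: SimulationConfig | None = None
                   ) -> tuple[Cohort, dict]:
    """Simulate the survey-mimicking cohort (see :func:`study_preset`)."""
    cfg = config or study_preset(seed=seed, scale=scale)
    return simulate_cohort(cfg, seed=seed)
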