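"""Synthetic pre/post cohorts with known glymphatic ground truth.

Emulates the statistical structure of a three-group insomnia study:
healthy controls (HC, one visit) and two insomnia-disorder treatment
arms (true_rTMS, sham_rTMS; pre and post visits). Each subject carries
a perivascular diffusivity parameter ``alpha`` drawn from their
group/timepoint distribution, which fixes the subject's true ALPS index
through the phantom construction (alps_true = 1 + alpha/lambda_perp).

Two polysomnography fields — N2 sleep duration and the arousal index —
are generated *from* alps_true with known linear coefficients, so the
regression machinery downstream has a known signal to recover; every
other clinical covariate is drawn independently of alps_true from
group-specific normal distributions. The true-treatment arm's post
alpha distribution is shifted upward, the sham arm's is not, giving the
paired pre/post contrast a known effect to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gradients import GradientScheme, make_gradient_scheme
from .phantom import DWIVolume, GroundTruth, PhantomSpec, build_tensor_phantom, simulate_dwi

__all__ = ["CohortSpec", "simulate_cohort", "GROUPS", "PSG_FIELDS", "QUESTIONNAIRE_FIELDS"]

GROUPS = ("HC", "true_rTMS", "sham_rTMS")

QUESTIONNAIRE_FIELDS = ("moca", "mmse", "bai", "bdi", "psqi", "ess", "isi")
PSG_FIELDS = (
    "total_sleep_time",
    "sleep_efficiency",
    "sleep_onset_latency",
    "waso",
    "n1_duration",
    "n2_duration",
    "n3_duration",
    "rem_duration",
    "arousal_index",
    "ahi",
    "odi3",
    "mean_spo2",
    "max_oa_duration",
    "plms_index",
)

# group-specific covariate distributions (mean, sd), HC / true_rTMS / sham_rTMS,
# echoing the magnitudes typical of an insomnia cohort with healthy controls
_COV = {
    "age": ((41.6, 9.2), (44.4, 11.6), (50.0, 12.2)),
    "education": ((14.2, 4.3), (13.1, 4.2), (11.2, 3.1)),
    "moca": ((29.5, 2.5), (27.4, 2.3), (25.2, 2.7)),
    "mmse": ((28.9, 1.8), (28.3, 1.8), (28.4, 1.6)),
    "bai": ((27.0, 2.5), (35.8, 8.5), (34.0, 5.4)),
    "bdi": ((4.1, 3.7), (12.5, 7.2), (17.3, 9.4)),
    "psqi": ((3.0, 1.7), (14.7, 3.0), (14.8, 3.9)),
    "ess": ((5.3, 3.1), (8.0, 4.6), (8.7, 5.0)),
    "isi": ((1.7, 1.3), (17.4, 4.0), (14.4, 2.5)),
    "total_sleep_time": ((373.7, 59.1), (286.0, 58.5), (292.8, 42.0)),
    "sleep_efficiency": ((85.1, 7.8), (71.1, 8.8), (66.9, 6.6)),
    "sleep_onset_latency": ((16.4, 6.7), (38.7, 15.7), (41.3, 13.2)),
    "waso": ((58.4, 41.1), (73.6, 36.4), (84.0, 44.0)),
    "n1_duration": ((32.7, 12.4), (33.8, 15.2), (36.0, 12.9)),
    "n2_duration": ((261.9, 32.8), (163.5, 52.9), (142.7, 30.2)),
    "n3_duration": ((54.0, 10.6), (30.0, 13.6), (27.2, 11.4)),
    "rem_duration": ((85.7, 21.6), (41.7, 19.4), (50.3, 15.3)),
    "arousal_index": ((5.0, 4.0), (15.0, 7.2), (16.3, 7.0)),
    "ahi": ((1.1, 1.6), (3.0, 5.7), (1.4, 1.3)),
    "odi3": ((3.0, 4.4), (2.4, 5.0), (1.0, 1.1)),
    "mean_spo2": ((96.7, 1.4), (96.5, 1.5), (97.0, 1.1)),
    "max_oa_duration": ((0.09, 0.19), (0.08, 0.17), (0.11, 0.16)),
    "plms_index": ((6.8, 12.4), (7.4, 11.6), (7.0, 7.1)),
}

_NONNEGATIVE = set(_COV) - {"age"}
_PERCENT = {"sleep_efficiency", "mean_spo2"}

# default perivascular parameter per (group, timepoint): alpha = lambda_perp*(ALPS-1)
# mapped from group ALPS ~ 1.67 (HC), 1.45 (true pre), 1.39 (sham), true post + ~0.13
_LAMBDA_PERP = 0.46
_DEFAULT_ALPHA = {
    ("HC", "pre"): (0.3082, 0.0736),
    ("true_rTMS", "pre"): (0.2070, 0.0782),
    ("true_rTMS", "post"): (0.2668, 0.0782),
    ("sham_rTMS", "pre"): (0.1794, 0.0644),
    ("sham_rTMS", "post"): (0.1794, 0.0644),
}

_DEFAULT_FEMALE_FRACTION = {"HC": 0.50, "true_rTMS": 0.75, "sham_rTMS": 0.667}

# mean post-pre change applied to covariates in the true-treatment arm
_DEFAULT_TREATMENT_DELTAS = {
    "psqi": -4.0,
    "isi": -5.0,
    "ess": -2.0,
    "total_sleep_time": 40.0,
    "n2_duration": 0.0,  # N2 change flows through alpha, not an extra shift
}


def _default_cov() -> dict:
    return {k: {g: v[i] for i, g in enumerate(GROUPS)} for k, v in _COV.items()}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    effect_n2 / effect_arousal are the generative slopes (min per ALPS
    unit, events/h per ALPS unit) linking alps_true to N2 duration and
    the arousal index; noise sds are the residual scatter around those
    lines. alps measurement noise models rater/fit variability when no
    imaging is simulated.
    """

    n_per_group: dict = field(default_factory=lambda: {"HC": 20, "true_rTMS": 28, "sham_rTMS": 9})
    group_alpha: dict = field(default_factory=lambda: dict(_DEFAULT_ALPHA))
    within_subject_alpha_sd: float = 0.015
    effect_n2: float = 120.0
    effect_arousal: float = -25.0
    n2_noise_sd: float = 30.0
    arousal_noise_sd: float = 5.0
    covariate_distributions: dict = field(default_factory=_default_cov)
    female_fraction: dict = field(default_factory=lambda: dict(_DEFAULT_FEMALE_FRACTION))
    treatment_deltas: dict = field(default_factory=lambda: dict(_DEFAULT_TREATMENT_DELTAS))
    within_subject_cov_sd_frac: float = 0.15
    alps_measurement_sd: float = 0.02
    lambda_parallel: float = 1.05
    lambda_perp: float = _LAMBDA_PERP
    snr: float = 30.0
    noise_model: str = "rician"
    n_directions: int = 32
    b_value: float = 1000.0
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_per_group) - set(GROUPS):
            raise ValueError(f"groups must be from {GROUPS}")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("all group sizes must be >= 2")
        for key, (mu, sd) in self.group_alpha.items():
            if sd < 0:
                raise ValueError(f"negative alpha sd for {key}")
        if self.n2_noise_sd < 0 or self.arousal_noise_sd < 0 or self.alps_measurement_sd < 0:
            raise ValueError("noise sds must be >= 0")


def _clip_field(name: str, value: float) -> float:
    if name in _PERCENT:
        return float(np.clip(value, 0.0, 100.0))
    if name in _NONNEGATIVE:
        return float(max(value, 0.0))
    return float(value)


def simulate_cohort(
    cspec: CohortSpec,
    imaging: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Draw a full cohort table and, optionally, per-visit phantom DWI.

    Returns ``(table, imaging_data)`` where ``imaging_data`` maps
    ``(subject_id, timepoint)`` to ``(GroundTruth, DWIVolume)`` when
    ``imaging`` is true (empty dict otherwise). With imaging disabled
    the ``alps`` column is alps_true plus Gaussian measurement noise;
    the pipeline driver overwrites it with the fitted index when
    imaging is processed. Fully reproducible from ``cspec.seed``.
    """
    cspec.validate()
    rng = np.random.default_rng(cspec.seed)
    scheme = make_gradient_scheme(cspec.n_directions, cspec.b_value, seed=cspec.seed) if imaging else None

    # reference ALPS level per group for centering the generated PSG fields
    group_alps_ref = {
        g: 1.0 + cspec.group_alpha[(g, "pre")][0] / cspec.lambda_perp for g in GROUPS if (g, "pre") in cspec.group_alpha
    }

    rows = []
    imaging_data: dict = {}
    sid = 0
    for group in GROUPS:
        n = int(cspec.n_per_group.get(group, 0))
        timepoints = ("pre",) if group == "HC" else ("pre", "post")
        for _ in range(n):
            sid += 1
            subject_id = f"S{sid:04d}"
            mu_pre, sd_pre = cspec.group_alpha[(group, "pre")]
            alpha_pre = max(float(rng.normal(mu_pre, sd_pre)), 0.0)
            gender = "female" if rng.random() < cspec.female_fraction[group] else "male"
            # subject-level covariate baselines, independent of alpha
            base = {
                name: float(rng.normal(*dists[group]))
                for name, dists in cspec.covariate_distributions.items()
            }
            alphas = {"pre": alpha_pre}
            if "post" in timepoints:
                mu_post = cspec.group_alpha[(group, "post")][0]
                alphas["post"] = max(alpha_pre + (mu_post - mu_pre) + float(rng.normal(0.0, cspec.within_subject_alpha_sd)), 0.0)

            for tp in timepoints:
                alps_true = 1.0 + alphas[tp] / cspec.lambda_perp
                row = {"subject_id": subject_id, "group": group, "timepoint": tp, "gender": gender}
                centered = alps_true - group_alps_ref[group]
                for name in cspec.covariate_distributions:
                    val = base[name]
                    if tp == "post":
                        delta = cspec.treatment_deltas.get(name, 0.0) if group == "true_rTMS" else 0.0
                        sd = cspec.covariate_distributions[name][group][1]
                        val = val + delta + float(rng.normal(0.0, cspec.within_subject_cov_sd_frac * sd))
                    # the two alps-linked PSG fields are generated entirely from
                    # alps_true: group mean + slope * (alps - group reference)
                    # + residual noise, so their association with the index is
                    # the known ground truth rather than an incidental overlay
                    if name == "n2_duration":
                        val = cspec.covariate_distributions[name][group][0] + cspec.effect_n2 * centered + float(
                            rng.normal(0.0, cspec.n2_noise_sd)
                        )
                    elif name == "arousal_index":
                        val = cspec.covariate_distributions[name][group][0] + cspec.effect_arousal * centered + float(
                            rng.normal(0.0, cspec.arousal_noise_sd)
                        )
                    row[name] = _clip_field(name, val)
                row["alps_true"] = alps_true
                row["alps"] = alps_true + float(rng.normal(0.0, cspec.alps_measurement_sd))
                rows.append(row)

                if imaging:
                    pspec = PhantomSpec(
                        grid_shape=cspec.grid_shape,
                        lambda_parallel=cspec.lambda_parallel,
                        lambda_perp=cspec.lambda_perp,
                        alpha=alphas[tp],
                        seed=cspec.seed,
                    )
                    truth = build_tensor_phantom(pspec)
                    dwi_seed = int(rng.integers(0, 2**31 - 1))
                    dwi = simulate_dwi(
                        truth,
                        scheme,
                        s0=1.0,
                        noise_sigma=1.0 / cspec.snr,
                        noise_model=cspec.noise_model,
                        seed=dwi_seed,
                    )
                    imaging_data[(subject_id, tp)] = (truth, dwi)

    table = pd.DataFrame(rows)
    return table, imaging_data
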