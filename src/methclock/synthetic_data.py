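"""Synthetic methylation cohorts with analytically consistent clocks.

The generator emulates the structure a clock analysis assumes: each
clock CpG's beta value tracks transformed chronological age linearly,

    beta_ij = clip(mu_j + s_j * F(age_i) + eps_ij),   eps ~ N(0, sigma^2),

where F is the Horvath log-linear transform (or the identity for
Hannum-style linear clocks).  Because the model is linear in F, a clock
with weights satisfying ``sum_j w_j * s_j = 1`` and intercept
``-sum_j w_j * mu_j`` recovers chronological age exactly on noiseless
data — an exact oracle for every downstream pipeline stage.

Two ready-made study scenarios reproduce the qualitative behaviour seen
when clocks built for the 450k/27k arrays are applied to EPIC-restricted
data:

* :func:`horvath_like_scenario` — the platform-missing probes carry
  clock weight but no net age signal, and the reference means used to
  impute them are offset from the cohort's true baselines (a reference
  cohort drawn from a different population).  The resulting deviation is
  a constant in transformed-score units, which the inverse transform
  turns into the characteristic shape of Horvath-clock underestimation:
  rising through childhood, flat (~3.5 y) in adults.
* :func:`hannum_like_scenario` — the missing probes carry a tunable
  fraction of the age signal and are imputed at cohort-mean reference
  values, giving a deviation that changes sign across the age range, as
  observed for the Hannum clock.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clock_core import (
    BetaMatrix,
    ClockDefinition,
    SampleAnnotation,
    mask_probes,
    transform_age,
)

logger = logging.getLogger(__name__)

BETA_CLIP_LO = 0.001
BETA_CLIP_HI = 0.999


@dataclass(frozen=True)
class GenerativeSpec:
    """Parameters of the synthetic cohort model.

    ``baselines`` (mu_j, beta units) and ``age_slopes`` (s_j, beta per
    transformed-age unit) may be given explicitly; if ``None`` they are
    drawn reproducibly from the seed (mu ~ U(0.2, 0.8); s with random
    sign and magnitude U(slope_lo, slope_hi)).  Ages are uniform on
    [age_low, age_high] unless an explicit ``ages`` pool is supplied, in
    which case samples are drawn from it with replacement.  The seed
    fully determines the generated cohort.
    """

    n_samples: int = 1000
    n_probes: int = 353
    age_low: float = 0.0
    age_high: float = 100.0
    ages: tuple[float, ...] | None = None
    baselines: tuple[float, ...] | None = None
    age_slopes: tuple[float, ...] | None = None
    slope_lo: float = 0.01
    slope_hi: float = 0.03
    noise_sd: float = 0.01
    adult_age: float = 20.0
    transform: str = "horvath"  # "horvath" | "identity"
    dropped_probes: tuple[str, ...] = ()
    probe_prefix: str = "cgS"
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_probes < 1:
            raise ValueError("n_samples and n_probes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.transform not in ("horvath", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "horvath" and self.adult_age <= 0:
            raise ValueError("adult_age must be positive")
        for fld in ("ages", "baselines", "age_slopes", "dropped_probes"):
            val = getattr(self, fld)
            if val is not None and not isinstance(val, tuple):
                object.__setattr__(self, fld, tuple(val))
        for fld in ("baselines", "age_slopes"):
            val = getattr(self, fld)
            if val is not None and len(val) != self.n_probes:
                raise ValueError(f"{fld} must have length n_probes={self.n_probes}")

    @property
    def probe_ids(self) -> list[str]:
        return [f"{self.probe_prefix}{i:06d}" for i in range(self.n_probes)]

    def transform_ages(self, ages: np.ndarray) -> np.ndarray:
        if self.transform == "identity":
            return np.asarray(ages, dtype=float)
        return np.asarray(transform_age(ages, self.adult_age), dtype=float)


def _param_rng(spec: GenerativeSpec) -> np.random.Generator:
    return np.random.default_rng((spec.seed, 101))


def _cohort_rng(spec: GenerativeSpec) -> np.random.Generator:
    return np.random.default_rng((spec.seed, 202))


def resolve_probe_params(spec: GenerativeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Baselines mu_j and slopes s_j, drawing from the seed when unset."""
    rng = _param_rng(spec)
    if spec.baselines is None:
        mu = rng.uniform(0.2, 0.8, size=spec.n_probes)
    else:
        mu = np.asarray(spec.baselines, dtype=float)
        rng.uniform(0.2, 0.8, size=spec.n_probes)  # keep stream position fixed
    if spec.age_slopes is None:
        mag = rng.uniform(spec.slope_lo, spec.slope_hi, size=spec.n_probes)
        sign = rng.choice([-1.0, 1.0], size=spec.n_probes)
        s = mag * sign
    else:
        s = np.asarray(spec.age_slopes, dtype=float)
    return mu, s


def generate_cohort(spec: GenerativeSpec) -> tuple[BetaMatrix, SampleAnnotation]:
    """Draw a cohort: beta matrix plus sample annotation.

    Betas follow ``mu_j + s_j * F(age_i) + noise`` clipped to
    [0.001, 0.999].  It is an error for the parameters to drive every
    value out of range.  Output is bit-reproducible from the spec.
    """
    mu, s = resolve_probe_params(spec)
    rng = _cohort_rng(spec)
    if spec.ages is not None:
        ages = rng.choice(np.asarray(spec.ages, dtype=float), size=spec.n_samples,
                          replace=True)
    else:
        ages = rng.uniform(spec.age_low, spec.age_high, size=spec.n_samples)
    f = spec.transform_ages(ages)
    clean = mu[:, None] + s[:, None] * f[None, :]
    if np.all((clean <= 0.0) | (clean >= 1.0)):
        raise ValueError("generative parameters drive all beta values out of (0, 1)")
    noise = rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 \
        else 0.0
    betas = np.clip(clean + noise, BETA_CLIP_LO, BETA_CLIP_HI)
    n_clipped = int(np.sum((clean + noise) != betas)) if spec.noise_sd > 0 else \
        int(np.sum(clean != betas))
    if n_clipped:
        logger.warning("generate_cohort: clipped %d beta values", n_clipped)

    sample_ids = [f"S{i:05d}" for i in range(spec.n_samples)]
    sex = np.where(rng.random(spec.n_samples) < 0.5, "female", "male")
    ann = SampleAnnotation(pd.DataFrame(
        {"age": ages, "sex": sex, "platform": "synthetic", "dataset": "synthetic"},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    return BetaMatrix.from_arrays(spec.probe_ids, sample_ids, betas,
                                  validate=False), ann


def construct_consistent_clock(
    spec: GenerativeSpec,
    probe_subset: Sequence[str] | None = None,
    weight_overrides: Mapping[str, float] | None = None,
    name: str = "synthetic-clock",
) -> ClockDefinition:
    """Closed-form clock exactly consistent with the generative model.

    Weights are ``w_j = s_j / sum(s^2)`` over the subset (so
    ``sum w_j s_j = 1``) and the intercept is ``-sum w_j mu_j``; applied
    to noiseless data the clock returns chronological age exactly.
    Probes with zero age slope get zero weight by this rule; because any
    weight on a zero-slope probe leaves the clock consistent (its
    baseline is absorbed by the intercept), ``weight_overrides`` may
    assign them nonzero weights — overriding a probe with nonzero slope
    would break consistency and is rejected.
    """
    mu, s = resolve_probe_params(spec)
    ids = spec.probe_ids
    pos = {p: i for i, p in enumerate(ids)}
    subset = list(probe_subset) if probe_subset is not None else ids
    unknown = [p for p in subset if p not in pos]
    if unknown:
        raise ValueError(f"subset probes not in spec: {unknown[:5]}")
    idx = np.array([pos[p] for p in subset])
    s_sub, mu_sub = s[idx], mu[idx]
    ss = float(np.sum(s_sub ** 2))
    if ss <= 0:
        raise ValueError("all age slopes are zero on the subset; no signal to invert")
    w = s_sub / ss
    if weight_overrides:
        for p, wv in weight_overrides.items():
            if p not in subset:
                raise ValueError(f"override for probe {p!r} outside the subset")
            j = subset.index(p)
            if s_sub[j] != 0.0:
                raise ValueError(
                    f"cannot override weight of probe {p!r} with nonzero age slope"
                )
            w[j] = float(wv)
    intercept = -float(np.dot(w, mu_sub))
    return ClockDefinition(
        name=name,
        intercept=intercept,
        weights=dict(zip(subset, w.tolist())),
        transform=spec.transform if spec.transform in ("horvath", "identity")
        else "horvath",
        adult_age=spec.adult_age,
    )


def emulate_platforms(
    betas: BetaMatrix, dropped_probe_ids: Iterable[str]
) -> tuple[BetaMatrix, BetaMatrix]:
    """(full, reduced) pair: the reduced matrix lacks the dropped probes.

    Mimics re-assaying the same samples on an array generation whose
    manifest lacks part of the clock's probe set.
    """
    dropped = list(dropped_probe_ids)
    extra = set(dropped) - set(betas.probe_ids)
    if extra:
        raise ValueError(f"dropped probes not in matrix: {sorted(extra)[:5]}")
    reduced = mask_probes(betas, dropped) if dropped else betas.copy()
    return betas, reduced


# ---------------------------------------------------------------------------
# Ready-made study scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A generative spec bundled with its clock and imputation reference."""

    spec: GenerativeSpec
    clock: ClockDefinition
    reference_means: dict[str, float]
    dropped_probes: tuple[str, ...]

    @property
    def dropped_weight_fraction(self) -> float:
        """Share of total absolute clock weight on the dropped probes."""
        total = sum(abs(v) for v in self.clock.weights.values())
        dropped = sum(abs(self.clock.weights[p]) for p in self.dropped_probes)
        return dropped / total


#: Calibration of the Horvath-like scenario: adult-cohort mean and SD of
#: the full-minus-reduced DNAm-age deviation, in years, matching the
#: magnitudes observed when the Horvath clock is restricted to the EPIC
#: probe set (approx. 3.5 y mean underestimation, 1.1 y spread).
ADULT_MEAN_DEVIATION_Y = 3.46
ADULT_DEVIATION_SD_Y = 1.13


def horvath_like_scenario(
    seed: int = 0,
    n_samples: int = 1000,
    n_probes: int = 353,
    n_dropped: int = 17,
    noise_sd: float = 0.01,
    adult_age: float = 20.0,
    age_low: float = 0.0,
    age_high: float = 100.0,
    adult_mean_deviation: float = ADULT_MEAN_DEVIATION_Y,
    adult_deviation_sd: float = ADULT_DEVIATION_SD_Y,
) -> Scenario:
    """Platform-dropout scenario with a flat adult deviation.

    The last ``n_dropped`` probes carry clock weight but no age signal;
    the reference means used to impute them are offset from the cohort
    baselines so that masking-plus-imputation shifts every transformed
    score down by a constant delta = adult_mean_deviation /
    (adult_age + 1).  Dropped-probe weight magnitudes are sized so the
    measurement noise they feed into the deviation reproduces
    ``adult_deviation_sd`` at the given ``noise_sd``.
    """
    if not 0 < n_dropped < n_probes:
        raise ValueError("need 0 < n_dropped < n_probes")
    base = GenerativeSpec(
        n_samples=n_samples, n_probes=n_probes, age_low=age_low, age_high=age_high,
        noise_sd=noise_sd, adult_age=adult_age, seed=seed,
    )
    mu, s = resolve_probe_params(base)
    ids = base.probe_ids
    drop_idx = np.arange(n_probes - n_dropped, n_probes)
    s = s.copy()
    s[drop_idx] = 0.0  # dropped probes: level, not trend
    dropped = tuple(ids[i] for i in drop_idx)

    spec = replace(base, baselines=tuple(mu), age_slopes=tuple(s),
                   dropped_probes=dropped)

    delta = adult_mean_deviation / (adult_age + 1.0)
    if noise_sd > 0:
        w_mag = adult_deviation_sd / ((adult_age + 1.0) * noise_sd
                                      * math.sqrt(n_dropped))
    else:
        w_mag = 0.3
    sign_rng = np.random.default_rng((seed, 303))
    w_signs = sign_rng.choice([-1.0, 1.0], size=n_dropped)
    overrides = {ids[i]: float(w_mag * w_signs[k])
                 for k, i in enumerate(drop_idx)}
    clock = construct_consistent_clock(spec, weight_overrides=overrides,
                                       name="synthetic-horvath")

    # reference means: true baselines, biased on the dropped probes so that
    # sum_dropped w_j * (mu_j - ref_j) = delta, split evenly per probe
    ref = {ids[i]: float(mu[i]) for i in range(n_probes)}
    for i in drop_idx:
        bias = delta / (n_dropped * clock.weights[ids[i]])
        ref_val = mu[i] - bias
        if not 0.0 <= ref_val <= 1.0:
            raise ValueError(
                "calibrated reference mean falls outside [0, 1]; reduce "
                "adult_mean_deviation or raise the dropped-probe weights"
            )
        ref[ids[i]] = float(ref_val)

    return Scenario(spec=spec, clock=clock, reference_means=ref,
                    dropped_probes=dropped)


def hannum_like_scenario(
    seed: int = 0,
    n_samples: int = 1000,
    n_probes: int = 71,
    n_dropped: int = 6,
    noise_sd: float = 0.01,
    age_low: float = 0.0,
    age_high: float = 100.0,
    dropped_signal_fraction: float = 0.10,
) -> Scenario:
    """Dropout scenario whose deviation changes sign across the age range.

    An identity-transform (Hannum-style) clock; the dropped probes carry
    ``dropped_signal_fraction`` of the age signal (rho = sum of w_j s_j
    over dropped probes) and are imputed at cohort-mean reference values,
    so the full-minus-reduced deviation is rho * (age - mean age):
    overestimation by the reduced set in the young, underestimation in
    the old.
    """
    if not 0 < n_dropped < n_probes:
        raise ValueError("need 0 < n_dropped < n_probes")
    if not 0 < dropped_signal_fraction < 1:
        raise ValueError("dropped_signal_fraction must be in (0, 1)")
    base = GenerativeSpec(
        n_samples=n_samples, n_probes=n_probes, age_low=age_low, age_high=age_high,
        noise_sd=noise_sd, transform="identity",
        slope_lo=0.0005, slope_hi=0.002, probe_prefix="cgH", seed=seed,
    )
    mu, s = resolve_probe_params(base)
    ids = base.probe_ids
    drop_idx = np.arange(n_probes - n_dropped, n_probes)
    keep_idx = np.arange(0, n_probes - n_dropped)

    # rescale dropped slopes so they carry exactly the requested share of
    # the clock signal: rho = sum_D s^2 / sum_all s^2
    rho = dropped_signal_fraction
    ss_keep = float(np.sum(s[keep_idx] ** 2))
    ss_drop = float(np.sum(s[drop_idx] ** 2))
    scale = math.sqrt(rho * ss_keep / ((1.0 - rho) * ss_drop))
    s = s.copy()
    s[drop_idx] *= scale

    spec = replace(base, baselines=tuple(mu), age_slopes=tuple(s),
                   dropped_probes=tuple(ids[i] for i in drop_idx))
    clock = construct_consistent_clock(spec, name="synthetic-hannum")

    mean_age = float(np.mean(spec.ages)) if spec.ages is not None \
        else 0.5 * (age_low + age_high)
    ref = {ids[i]: float(np.clip(mu[i] + s[i] * mean_age, 0.0, 1.0))
           for i in range(n_probes)}
    return Scenario(spec=spec, clock=clock, reference_means=ref,
                    dropped_probes=spec.dropped_probes)
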