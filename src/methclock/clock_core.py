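"""Linear DNA-methylation-age clocks and probe masking.

An epigenetic clock is a linear predictor over CpG beta values: the
transformed score for sample *i* is ``intercept + sum_j w_j * beta_ij``
over the clock's probe set.  Horvath-style clocks map this score back to
years through the inverse of a log-linear age transform with an "adult
age" inflection (20 years by default); Hannum-style clocks report the
score directly as years.

This module holds the clock and cohort containers, the age transform and
its inverse, clock application (with pluggable imputation of missing
probes), probe masking for cross-array sensitivity analyses, and the
clock-vs-manifest diff that identifies which clock probes a given array
platform lacks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .imputation import ImputationPolicy

logger = logging.getLogger(__name__)

#: Tolerance within which out-of-range beta values are clipped rather than
#: rejected.  GEO series matrices occasionally carry rounding spill such as
#: 1.0000001; anything further outside [0, 1] is a data error.
BETA_CLIP_TOL = 1e-6

TransformName = Literal["identity", "horvath"]


# ---------------------------------------------------------------------------
# Age transform
# ---------------------------------------------------------------------------

def transform_age(age: float | np.ndarray, adult_age: float = 20.0):
    """Horvath log-linear transform of chronological age.

    F(age) = log(age + 1) - log(adult_age + 1)      for age <= adult_age
    F(age) = (age - adult_age) / (adult_age + 1)    for age >  adult_age

    Natural logarithm; continuous and strictly increasing, with
    F(adult_age) = 0.  ``age`` may be a scalar or array of years >= 0.
    """
    if adult_age <= 0:
        raise ValueError(f"adult_age must be positive, got {adult_age}")
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise ValueError("chronological age must be non-negative")
    out = np.where(
        age_arr <= adult_age,
        np.log(age_arr + 1.0) - math.log(adult_age + 1.0),
        (age_arr - adult_age) / (adult_age + 1.0),
    )
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


def inverse_transform_age(m: float | np.ndarray, adult_age: float = 20.0):
    """Inverse of :func:`transform_age`, defined on all reals.

    Maps a transformed score back to years:
    (adult_age + 1) * exp(m) - 1 for m <= 0, else
    adult_age + m * (adult_age + 1).
    """
    if adult_age <= 0:
        raise ValueError(f"adult_age must be positive, got {adult_age}")
    m_arr = np.asarray(m, dtype=float)
    out = np.where(
        m_arr <= 0,
        (adult_age + 1.0) * np.exp(m_arr) - 1.0,
        adult_age + m_arr * (adult_age + 1.0),
    )
    return float(out) if np.isscalar(m) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockDefinition:
    """A named linear methylation clock.

    Parameters
    ----------
    name
        Clock label used in reports and logs.
    intercept
        Intercept of the linear predictor, in transformed-age units.
    weights
        Mapping probe ID -> coefficient.  Probe IDs are opaque,
        case-sensitive strings.
    transform
        ``"horvath"`` for the log-linear age transform (scores are mapped
        to years through its inverse) or ``"identity"`` (scores are years).
    adult_age
        Inflection point of the Horvath transform, in years.  Ignored for
        identity clocks.
    """

    name: str
    intercept: float
    weights: Mapping[str, float]
    transform: TransformName = "horvath"
    adult_age: float = 20.0

    def __post_init__(self):
        if len(self.weights) < 1:
            raise ValueError("a clock needs at least one probe weight")
        if self.transform not in ("identity", "horvath"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "horvath" and self.adult_age <= 0:
            raise ValueError("adult_age must be positive for the horvath transform")
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights)

    @property
    def size(self) -> int:
        return len(self.weights)

    def score_to_age(self, score):
        """Map transformed scores to years under this clock's transform."""
        if self.transform == "identity":
            return score
        return inverse_transform_age(score, self.adult_age)

    def age_to_score(self, age):
        if self.transform == "identity":
            return age
        return transform_age(age, self.adult_age)


class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    Values lie in [0, 1]; missing measurements are NaN.  Backed by a
    pandas DataFrame with probe IDs as the index and sample IDs as the
    columns; both must be unique.
    """

    def __init__(self, data: pd.DataFrame, *, validate: bool = True, copy: bool = True):
        if copy:
            data = data.copy()
        data = data.astype(float)
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        data.index.name = None
        data.columns.name = None
        if validate:
            if data.index.has_duplicates:
                dups = data.index[data.index.duplicated()].unique().tolist()
                raise ValueError(f"duplicate probe IDs: {dups[:5]}")
            if data.columns.has_duplicates:
                dups = data.columns[data.columns.duplicated()].unique().tolist()
                raise ValueError(f"duplicate sample IDs: {dups[:5]}")
            vals = data.to_numpy()
            with np.errstate(invalid="ignore"):
                too_low = vals < -BETA_CLIP_TOL
                too_high = vals > 1.0 + BETA_CLIP_TOL
            if np.any(too_low) or np.any(too_high):
                bad = vals[(too_low | too_high) & ~np.isnan(vals)]
                raise ValueError(
                    f"beta values outside [0, 1] beyond tolerance {BETA_CLIP_TOL}: "
                    f"e.g. {bad.flat[0]!r}"
                )
            # rounding spill within tolerance is clipped, not rejected
            data = data.clip(lower=0.0, upper=1.0)
        self._data = data

    @classmethod
    def from_arrays(
        cls,
        probe_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        **kwargs,
    ) -> "BetaMatrix":
        frame = pd.DataFrame(np.asarray(values, dtype=float),
                             index=list(probe_ids), columns=list(sample_ids))
        return cls(frame, **kwargs)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def probe_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def n_probes(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def has_missing(self) -> bool:
        return bool(self._data.isna().any().any())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self._data, validate=False, copy=True)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples)"


SEX_VALUES = ("female", "male")
PLATFORM_VALUES = ("27k", "450k", "850k", "synthetic")


class SampleAnnotation:
    """Per-sample metadata: chronological age, sex, platform, dataset.

    Backed by a DataFrame indexed by unique sample ID with columns
    ``age`` (years, NaN when unknown), ``sex`` (``"female"``/``"male"``,
    NaN when unknown), ``platform`` and ``dataset``.  Samples with
    missing age are retained but excluded from age-dependent analyses.
    """

    def __init__(self, table: pd.DataFrame, *, copy: bool = True):
        if copy:
            table = table.copy()
        table.index = table.index.astype(str)
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs in annotation: {dups[:5]}")
        for col, default in (("age", np.nan), ("sex", np.nan),
                             ("platform", "synthetic"), ("dataset", "unknown")):
            if col not in table.columns:
                table[col] = default
        table["age"] = pd.to_numeric(table["age"], errors="coerce")
        if (table["age"].dropna() < 0).any():
            raise ValueError("negative chronological age in annotation")
        sex = table["sex"].astype("object").str.lower()
        bad_sex = sex.dropna()[~sex.dropna().isin(SEX_VALUES)]
        if len(bad_sex):
            raise ValueError(f"unrecognised sex values: {bad_sex.unique().tolist()}")
        table["sex"] = sex
        self._table = table[["age", "sex", "platform", "dataset"]]

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def sample_ids(self) -> list[str]:
        return self._table.index.tolist()

    @property
    def ages(self) -> pd.Series:
        return self._table["age"]

    def with_known_age(self) -> "SampleAnnotation":
        return SampleAnnotation(self._table[self._table["age"].notna()])

    def __len__(self) -> int:
        return len(self._table)


@dataclass(frozen=True)
class ClockAgeResult:
    """DNAm age of one sample, with provenance."""

    sample_id: str
    dnam_age: float
    transformed_score: float
    n_probes_used: int
    n_probes_imputed: int
    clock_name: str
    imputation_policy: str


def results_to_frame(results: Sequence[ClockAgeResult]) -> pd.DataFrame:
    """Tabulate per-sample clock results, indexed by sample ID."""
    frame = pd.DataFrame([r.__dict__ for r in results]).set_index("sample_id")
    return frame


# ---------------------------------------------------------------------------
# Clock application
# ---------------------------------------------------------------------------

def apply_clock(
    clock: ClockDefinition,
    betas: BetaMatrix,
    policy: "ImputationPolicy | None" = None,
) -> list[ClockAgeResult]:
    """Compute DNAm age for every sample in ``betas``.

    Clock probes absent from the matrix, and probes present but with
    missing values, are resolved through ``policy`` (see
    :mod:`methclock.imputation`) before scoring.  With no policy and a
    complete probe set the computation is a plain weighted sum.

    Raises
    ------
    ValueError
        If no clock probe overlaps the matrix and the policy cannot
        supply reference values, or if missing values remain after
        imputation (the error names the offending probes).
    """
    from .imputation import resolve_clock_probes

    probe_index = pd.Index(clock.probe_ids)
    present = probe_index.intersection(betas.data.index)
    absent = probe_index.difference(betas.data.index)

    sub = betas.data.reindex(probe_index)  # absent probes appear as NaN rows
    imputed_mask = sub.isna()

    if imputed_mask.any().any():
        if policy is None:
            missing = imputed_mask.any(axis=1)
            names = missing[missing].index.tolist()
            raise ValueError(
                f"clock '{clock.name}': {len(names)} probes missing and no "
                f"imputation policy given: {names[:10]}"
            )
        if len(present) == 0 and not policy.can_resolve_absent_probes():
            raise ValueError(
                f"clock '{clock.name}': no clock probes overlap the beta matrix "
                f"and policy '{policy.method}' has no external reference"
            )
        sub = resolve_clock_probes(sub, policy)
        still = sub.isna()
        if still.any().any():
            names = still.any(axis=1)
            names = names[names].index.tolist()
            raise ValueError(
                f"clock '{clock.name}': values still missing after "
                f"'{policy.method}' imputation for probes {names[:10]}"
            )
        n_imputed_per_sample = imputed_mask.sum(axis=0)
    else:
        n_imputed_per_sample = pd.Series(0, index=sub.columns)

    if len(absent):
        logger.info(
            "clock '%s': %d of %d probes absent from matrix, imputed via '%s'",
            clock.name, len(absent), clock.size,
            policy.method if policy is not None else "none",
        )

    w = np.array([clock.weights[p] for p in probe_index], dtype=float)
    scores = clock.intercept + w @ sub.to_numpy()
    ages = clock.score_to_age(scores)
    ages = np.broadcast_to(np.asarray(ages, dtype=float), scores.shape)

    policy_label = policy.method if policy is not None else "none"
    return [
        ClockAgeResult(
            sample_id=s,
            dnam_age=float(ages[i]),
            transformed_score=float(scores[i]),
            n_probes_used=clock.size,
            n_probes_imputed=int(n_imputed_per_sample.iloc[i]),
            clock_name=clock.name,
            imputation_policy=policy_label,
        )
        for i, s in enumerate(sub.columns)
    ]


def mask_probes(betas: BetaMatrix, drop_list: Iterable[str]) -> BetaMatrix:
    """Remove the listed probes from a beta matrix.

    IDs absent from the matrix are ignored with a warning.  The input is
    not modified.  Dropping every probe is an error.
    """
    drop = pd.Index(pd.unique(pd.Index(list(drop_list)).astype(str)))
    missing = drop.difference(betas.data.index)
    if len(missing):
        logger.warning(
            "mask_probes: %d drop-list IDs not present in matrix: %s",
            len(missing), missing.tolist()[:10],
        )
    kept = betas.data.index.difference(drop, sort=False)
    if len(kept) == 0:
        raise ValueError("masking removed every probe from the matrix")
    return BetaMatrix(betas.data.loc[kept], validate=False, copy=True)


@dataclass(frozen=True)
class ManifestDiff:
    """Clock probes absent from an array manifest."""

    clock_name: str
    clock_size: int
    missing_probe_ids: tuple[str, ...]
    n_missing: int = field(init=False)
    fraction_missing: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n_missing", len(self.missing_probe_ids))
        object.__setattr__(
            self, "fraction_missing", len(self.missing_probe_ids) / self.clock_size
        )

    def to_dict(self) -> dict:
        return {
            "clock_name": self.clock_name,
            "clock_size": self.clock_size,
            "n_missing": self.n_missing,
            "fraction_missing": self.fraction_missing,
            "missing_probe_ids": list(self.missing_probe_ids),
        }


def diff_clock_vs_manifest(
    clock: ClockDefinition, manifest_probe_ids: Iterable[str]
) -> ManifestDiff:
    """Report which clock probes a platform manifest lacks.

    The fraction is relative to the clock size, e.g. 17/353 = 4.8% for
    the Horvath clock against the EPIC manifest.
    """
    manifest = set(map(str, manifest_probe_ids))
    if not manifest:
        raise ValueError("manifest probe set is empty")
    missing = tuple(p for p in clock.probe_ids if p not in manifest)
    return ManifestDiff(clock_name=clock.name, clock_size=clock.size,
                        missing_probe_ids=missing)


def load_epic_missing_probes(clock: Literal["horvath", "hannum"]) -> list[str]:
    """Bundled lists of clock probes absent from the EPIC (850k) manifest.

    ``"horvath"`` returns the 17 of 353 Horvath-clock CpGs missing from
    the EPIC array; ``"hannum"`` the 6 of 71 Hannum-clock CpGs.
    """
    fname = {"horvath": "epic_missing_horvath.txt",
             "hannum": "epic_missing_hannum.txt"}[clock]
    text = resources.files("methclock.data").joinpath(fname).read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
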