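"""Readers and writers for clock tables, beta matrices and reports.

All formats are plain CSV/TSV or line-oriented text:

* beta matrix — first column probe IDs, remaining columns samples;
  ``NA``/empty cells are missing values;
* clock table — ``probe_id,weight`` with the intercept carried as a row
  whose probe ID is ``(Intercept)`` (the layout of published clock
  coefficient supplements is accepted through a column map);
* probe list — one probe ID per line, ``#`` comments allowed;
* annotation — ``sample_id`` plus any of ``age``, ``sex``, ``platform``,
  ``dataset``;
* reference means — ``probe_id,mean_beta``.

Readers validate and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clock_core import BetaMatrix, ClockDefinition, SampleAnnotation

logger = logging.getLogger(__name__)

INTERCEPT_ROW_ID = "(Intercept)"

#: Column-name synonyms seen in published clock coefficient tables.
CLOCK_COLUMN_SYNONYMS = {
    "probe_id": ("probe_id", "CpGmarker", "Marker", "CpG", "ID"),
    "weight": ("weight", "CoefficientTraining", "Coefficient", "coef"),
}


def _detect_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".tab", ".txt"):
        return "\t"
    return ","


def read_beta_matrix(path: str | Path, sep: str | None = None) -> BetaMatrix:
    """Read a probes x samples beta matrix from CSV/TSV.

    ``NA`` and empty cells become missing values.  Duplicate probe IDs
    and non-numeric cells are hard errors naming the offending location.
    """
    frame = pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0,
                        dtype=str, keep_default_na=False)
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate probe IDs: {dups[:5]}")
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        raw = frame[col].str.strip()
        missing = raw.isin(("", "NA", "NaN", "nan", "null", "NULL"))
        vals = pd.to_numeric(raw.mask(missing), errors="coerce")
        bad = vals.isna() & ~missing
        if bad.any():
            probe = bad[bad].index[0]
            raise ValueError(
                f"{path}: non-numeric value {raw[probe]!r} at probe "
                f"{probe!r}, sample {col!r}"
            )
        numeric[col] = vals
    return BetaMatrix(numeric, copy=False)


def write_beta_matrix(betas: BetaMatrix, path: str | Path,
                      sep: str | None = None) -> None:
    betas.data.to_csv(path, sep=_detect_sep(path, sep), index_label="probe_id",
                      na_rep="NA", float_format="%.17g")


def read_clock(
    path: str | Path,
    transform: str = "horvath",
    adult_age: float = 20.0,
    name: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ClockDefinition:
    """Read a clock coefficient table.

    The intercept is taken from the ``(Intercept)`` row.  A missing
    intercept is a hard error for Horvath-transform clocks; for identity
    clocks it defaults to 0 with a warning.
    """
    frame = pd.read_csv(path, sep=_detect_sep(path, sep),
                        float_precision="round_trip")
    cols = {c.strip(): c for c in frame.columns}

    def _find(role: str) -> str:
        if column_map and role in column_map:
            if column_map[role] not in cols:
                raise ValueError(f"{path}: mapped column {column_map[role]!r} absent")
            return cols[column_map[role]]
        for syn in CLOCK_COLUMN_SYNONYMS[role]:
            if syn in cols:
                return cols[syn]
        raise ValueError(
            f"{path}: no recognisable {role} column among {list(cols)}"
        )

    pcol, wcol = _find("probe_id"), _find("weight")
    probes = frame[pcol].astype(str).str.strip()
    weights = pd.to_numeric(frame[wcol], errors="coerce")
    if weights.isna().any():
        bad = probes[weights.isna()].tolist()
        raise ValueError(f"{path}: non-numeric weights for {bad[:5]}")

    is_intercept = probes == INTERCEPT_ROW_ID
    if is_intercept.sum() > 1:
        raise ValueError(f"{path}: multiple {INTERCEPT_ROW_ID} rows")
    if is_intercept.any():
        intercept = float(weights[is_intercept].iloc[0])
    elif transform == "horvath":
        raise ValueError(
            f"{path}: no {INTERCEPT_ROW_ID} row; an intercept is required for "
            f"a horvath-transform clock"
        )
    else:
        logger.warning("%s: no %s row; intercept defaults to 0", path,
                       INTERCEPT_ROW_ID)
        intercept = 0.0

    probes, weights = probes[~is_intercept], weights[~is_intercept]
    if probes.duplicated().any():
        dups = probes[probes.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate probe IDs: {dups[:5]}")
    return ClockDefinition(
        name=name or Path(path).stem,
        intercept=intercept,
        weights=dict(zip(probes, weights.astype(float))),
        transform=transform,  # type: ignore[arg-type]
        adult_age=adult_age,
    )


def write_clock(clock: ClockDefinition, path: str | Path) -> None:
    rows = [{"probe_id": INTERCEPT_ROW_ID, "weight": clock.intercept}]
    rows += [{"probe_id": p, "weight": w} for p, w in clock.weights.items()]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_probe_list(path: str | Path) -> list[str]:
    """One probe ID per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        stripped = line.split("#", 1)[0].strip()
        if stripped:
            out.append(stripped)
    return out


def write_probe_list(probe_ids, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(p) for p in probe_ids) + "\n")


def read_annotation(path: str | Path, sep: str | None = None) -> SampleAnnotation:
    frame = pd.read_csv(path, sep=_detect_sep(path, sep))
    id_col = next((c for c in frame.columns
                   if c.strip().lower() in ("sample_id", "sample", "id")), None)
    if id_col is None:
        raise ValueError(f"{path}: no sample_id column")
    frame = frame.set_index(frame[id_col].astype(str)).drop(columns=[id_col])
    return SampleAnnotation(frame)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, index_label="sample_id", na_rep="NA")


def read_reference_means(path: str | Path, sep: str | None = None) -> dict[str, float]:
    frame = pd.read_csv(path, sep=_detect_sep(path, sep))
    cols = [c.strip().lower() for c in frame.columns]
    try:
        pcol = frame.columns[cols.index("probe_id")]
        mcol = frame.columns[cols.index("mean_beta")]
    except ValueError as exc:
        raise ValueError(f"{path}: expected columns probe_id,mean_beta") from exc
    probes = frame[pcol].astype(str)
    if probes.duplicated().any():
        raise ValueError(f"{path}: duplicate probe IDs in reference means")
    means = pd.to_numeric(frame[mcol], errors="raise").astype(float)
    if ((means < 0) | (means > 1)).any():
        raise ValueError(f"{path}: reference means outside [0, 1]")
    return dict(zip(probes, means))


def write_reference_means(means: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame({"probe_id": list(means), "mean_beta": list(means.values())}
                 ).to_csv(path, index=False)


def write_age_results(results, path: str | Path, decimals: int = 4) -> None:
    """Per-sample DNAm ages as CSV (ages rounded to ``decimals`` places)."""
    from .clock_core import results_to_frame

    frame = results_to_frame(list(results)).copy()
    for col in ("dnam_age", "transformed_score"):
        frame[col] = frame[col].round(decimals)
    frame.to_csv(path, index_label="sample_id")


def read_age_results(path: str | Path) -> pd.Series:
    """Read a per-sample DNAm-age CSV back as a Series indexed by sample."""
    frame = pd.read_csv(path)
    id_col = frame.columns[0]
    age_col = "dnam_age" if "dnam_age" in frame.columns else frame.columns[1]
    return pd.Series(pd.to_numeric(frame[age_col]).to_numpy(),
                     index=frame[id_col].astype(str), name="dnam_age")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default,
                                     allow_nan=True) + "\n")
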