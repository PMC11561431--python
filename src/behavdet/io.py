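"""Questionnaire data input/output and harmonization.

Reads respondent-by-item tables and their codebooks, harmonizes 5-point
Likert scales so that 1 is always the most favorable answer, dichotomizes
the behavioral-intention outcome, and computes descriptive statistics.

Conventions
-----------
* Likert items are stored as integers 1..5 after harmonization, with 1 the
  most favorable end of the scale.  Reverse-coded items are mapped
  ``v -> 6 - v`` on input.
* Analysis is complete-case: respondents missing any predictor, demographic
  or outcome value are dropped and counted, never imputed.  Items with role
  ``followup`` are exempt (they are only asked of a subset of respondents).
* Standard deviations use the sample (n-1) convention throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "ResponseMatrix",
    "CodebookError",
    "UnknownColumnError",
    "OutOfRangeError",
    "MissingOutcomeError",
    "read_responses",
    "dichotomize_intention",
    "is_positive_intention",
    "describe",
]

ROLES = {"predictor", "outcome", "followup", "demographic"}
SCALES = {"likert5", "categorical", "binary"}

#: Ordered intention levels, most to least favorable.  Level 1/2 = positive.
INTENTION_LEVELS = (
    "very willing",
    "willing",
    "neutral",
    "unwilling",
    "very unwilling",
)

POSITIVE = "positive"
NEUTRAL_NEGATIVE = "neutral_negative"


class CodebookError(ValueError):
    """Invalid codebook structure or content."""


class UnknownColumnError(KeyError):
    """A data column is absent from the codebook, or vice versa."""


class OutOfRangeError(ValueError):
    """A Likert value outside 1..5 was found."""


class MissingOutcomeError(ValueError):
    """The outcome column is missing from the data."""


@dataclass(frozen=True)
class Codebook:
    """Per-item metadata: role, scale, and reverse-coding flag.

    Parameters
    ----------
    table
        DataFrame with columns ``id``, ``label``, ``role``, ``scale``,
        ``reverse_coded``; one row per questionnaire item.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "label", "role", "scale", "reverse_coded"}
        missing = required - set(self.table.columns)
        if missing:
            raise CodebookError(f"codebook missing columns: {sorted(missing)}")
        ids = self.table["id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise CodebookError(f"duplicate item ids: {dupes}")
        bad_role = set(self.table["role"]) - ROLES
        if bad_role:
            raise CodebookError(f"unknown roles: {sorted(bad_role)}")
        bad_scale = set(self.table["scale"]) - SCALES
        if bad_scale:
            raise CodebookError(f"unknown scales: {sorted(bad_scale)}")
        n_outcome = int((self.table["role"] == "outcome").sum())
        if n_outcome != 1:
            raise CodebookError(
                f"codebook must declare exactly one outcome item, found {n_outcome}"
            )
        rev = self.table[self.table["reverse_coded"].astype(bool)]
        not_likert = rev[rev["scale"] != "likert5"]
        if len(not_likert):
            raise CodebookError(
                "reverse_coded items must be likert5: "
                f"{sorted(not_likert['id'])}"
            )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "Codebook":
        df = pd.DataFrame(list(records))
        if "reverse_coded" not in df.columns:
            df["reverse_coded"] = False
        if "label" not in df.columns:
            df["label"] = df["id"]
        df["label"] = df["label"].fillna(df["id"])
        df["reverse_coded"] = (
            df["reverse_coded"].map(lambda v: bool(v) if pd.notna(v) else False)
        )
        return cls(df.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Codebook":
        df = pd.read_csv(path)
        df["reverse_coded"] = (
            df.get("reverse_coded", False)
            .map({True: True, False: False, "True": True, "False": False,
                  "true": True, "false": False, 1: True, 0: False})
            .fillna(False)
            .astype(bool)
        )
        return cls(df)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "Codebook":
        with open(path) as fh:
            return cls.from_records(json.load(fh))

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.table.to_dict(orient="records"), fh, indent=1)

    # -- accessors ----------------------------------------------------

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    @property
    def outcome(self) -> str:
        return str(self.table.loc[self.table["role"] == "outcome", "id"].iloc[0])

    def ids_with_role(self, role: str) -> list:
        return list(self.table.loc[self.table["role"] == role, "id"])

    @property
    def predictors(self) -> list:
        return self.ids_with_role("predictor")

    @property
    def demographics(self) -> list:
        return self.ids_with_role("demographic")

    @property
    def followups(self) -> list:
        return self.ids_with_role("followup")

    def scale_of(self, item: str) -> str:
        row = self.table.loc[self.table["id"] == item]
        if row.empty:
            raise UnknownColumnError(item)
        return str(row["scale"].iloc[0])

    @property
    def reverse_coded(self) -> list:
        return list(self.table.loc[self.table["reverse_coded"].astype(bool), "id"])


@dataclass
class ResponseMatrix:
    """Harmonized respondent-by-item table plus its codebook.

    ``data`` holds one column per codebook item; likert5 columns are integer
    1..5 with 1 the most favorable answer.  ``n_dropped`` counts respondents
    removed by the complete-case rule at read time.
    """

    data: pd.DataFrame
    codebook: Codebook
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("response matrix must contain at least one row")
        data_cols = set(self.data.columns)
        cb_cols = set(self.codebook.ids)
        if data_cols != cb_cols:
            extra = sorted(data_cols - cb_cols)
            missing = sorted(cb_cols - data_cols)
            raise UnknownColumnError(
                f"column mismatch with codebook: extra={extra} missing={missing}"
            )
        for item in self.codebook.ids:
            if self.codebook.scale_of(item) != "likert5":
                continue
            col = self.data[item].dropna()
            bad = col[~col.isin([1, 2, 3, 4, 5])]
            if len(bad):
                raise OutOfRangeError(
                    f"likert5 item {item!r} has values outside 1..5 "
                    f"(first offending row: {bad.index[0]})"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_respondents(self) -> int:
        return len(self.data)

    @property
    def outcome_raw(self) -> pd.Series:
        return self.data[self.codebook.outcome]

    @property
    def positive(self) -> pd.Series:
        """Boolean per respondent: positive intention (very willing/willing)."""
        return is_positive_intention(self.outcome_raw)

    def predictor_frame(self) -> pd.DataFrame:
        """Numeric design matrix for the forest stage.

        Likert predictors enter as numeric 1..5; categorical/binary
        demographics are expanded into one-hot indicator columns.  The
        outcome and follow-up items are excluded.
        """
        cols = []
        for item in self.codebook.predictors + self.codebook.demographics:
            if self.codebook.scale_of(item) == "likert5":
                cols.append(self.data[item].astype(float))
            else:
                dummies = pd.get_dummies(self.data[item], prefix=item).astype(float)
                cols.extend(dummies[c] for c in dummies.columns)
        if not cols:
            raise ValueError("no predictor columns available")
        return pd.concat(cols, axis=1)


def _harmonize(df: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    out = df.copy()
    for item in codebook.reverse_coded:
        out[item] = 6 - out[item]
    return out


def read_responses(
    path: Union[str, Path],
    codebook: Codebook,
    sep: str = ",",
) -> ResponseMatrix:
    """Read a responses CSV, harmonize scales, and apply the complete-case rule.

    Rows with any missing predictor, demographic or outcome value are dropped
    and counted in ``n_dropped``; missing follow-up answers are tolerated
    (those questions are only shown to a subset of respondents).

    Raises
    ------
    MissingOutcomeError
        If the outcome column is absent.
    UnknownColumnError
        If the data columns do not match the codebook.
    OutOfRangeError
        If a likert5 column contains values outside 1..5.
    """
    df = pd.read_csv(path, sep=sep)
    if "respondent_id" in df.columns:
        df = df.set_index("respondent_id")
    if codebook.outcome not in df.columns:
        raise MissingOutcomeError(
            f"outcome column {codebook.outcome!r} not present in {path}"
        )
    data_cols = set(df.columns)
    cb_cols = set(codebook.ids)
    if data_cols != cb_cols:
        extra = sorted(data_cols - cb_cols)
        missing = sorted(cb_cols - data_cols)
        raise UnknownColumnError(
            f"columns do not match codebook: extra={extra} missing={missing}"
        )

    # range check before harmonization so the error names raw values
    for item in codebook.ids:
        if codebook.scale_of(item) != "likert5":
            continue
        col = pd.to_numeric(df[item], errors="coerce")
        notna = col.dropna()
        bad = notna[~notna.isin([1, 2, 3, 4, 5])]
        if len(bad):
            raise OutOfRangeError(
                f"value {bad.iloc[0]!r} out of range 1..5 in column {item!r} "
                f"(row {bad.index[0]})"
            )
        df[item] = col

    required = (
        codebook.predictors + codebook.demographics + [codebook.outcome]
    )
    complete = df[required].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    kept = df.loc[complete].copy()
    for item in codebook.ids:
        if codebook.scale_of(item) == "likert5" and item not in codebook.followups:
            kept[item] = kept[item].astype(int)
    kept = _harmonize(kept, codebook)
    return ResponseMatrix(data=kept, codebook=codebook, n_dropped=n_dropped)


_LEVEL_TO_CLASS = {
    "very willing": POSITIVE,
    "willing": POSITIVE,
    "neutral": NEUTRAL_NEGATIVE,
    "unwilling": NEUTRAL_NEGATIVE,
    "very unwilling": NEUTRAL_NEGATIVE,
    1: POSITIVE,
    2: POSITIVE,
    3: NEUTRAL_NEGATIVE,
    4: NEUTRAL_NEGATIVE,
    5: NEUTRAL_NEGATIVE,
}


def dichotomize_intention(raw):
    """Map a 5-level intention response to ``positive`` / ``neutral_negative``.

    ``positive`` covers "very willing" and "willing" (harmonized codes 1 and
    2); everything else on the scale is ``neutral_negative``.  Accepts a
    scalar (string level or integer code) or an array-like.
    """
    if np.ndim(raw) == 0:
        key = raw.strip().lower() if isinstance(raw, str) else int(raw)
        try:
            return _LEVEL_TO_CLASS[key]
        except KeyError:
            raise ValueError(f"unmapped intention level: {raw!r}") from None
    return pd.Series(raw).map(dichotomize_intention)


def is_positive_intention(raw) -> pd.Series:
    """Vectorized boolean form of :func:`dichotomize_intention`."""
    classes = dichotomize_intention(raw)
    if isinstance(classes, str):
        return classes == POSITIVE
    out = classes == POSITIVE
    out.index = pd.Series(raw).index if not hasattr(raw, "index") else raw.index
    return out


def describe(matrix: ResponseMatrix) -> pd.DataFrame:
    """Per-item descriptive statistics.

    Likert items get n, mean and SD (sample convention); categorical items
    get one row per level with its proportion.  The outcome item additionally
    yields proportion rows for the dichotomized positive / neutral-negative
    classes.
    """
    rows = []
    for item in matrix.codebook.ids:
        scale = matrix.codebook.scale_of(item)
        col = matrix.data[item].dropna()
        if scale == "likert5":
            rows.append(
                {
                    "item": item,
                    "scale": scale,
                    "level": "",
                    "n": int(len(col)),
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                    "proportion": np.nan,
                }
            )
        else:
            props = col.value_counts(normalize=True).sort_index()
            for level, prop in props.items():
                rows.append(
                    {
                        "item": item,
                        "scale": scale,
                        "level": str(level),
                        "n": int(len(col)),
                        "mean": np.nan,
                        "sd": np.nan,
                        "proportion": float(prop),
                    }
                )
        if item == matrix.codebook.outcome:
            classes = dichotomize_intention(col)
            props = classes.value_counts(normalize=True)
            for cls in (POSITIVE, NEUTRAL_NEGATIVE):
                rows.append(
                    {
                        "item": item,
                        "scale": "dichotomized",
                        "level": cls,
                        "n": int(len(col)),
                        "mean": np.nan,
                        "sd": np.nan,
                        "proportion": float(props.get(cls, 0.0)),
                    }
                )
    return pd.DataFrame(rows)
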