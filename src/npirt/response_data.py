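"""Containers for ordinal questionnaire responses and the level sum score.

The central object is :class:`ResponseMatrix`: an N persons x J items matrix of
integer response levels (EQ-5D-5L convention: 1 = "no problems" ... 5 =
"extreme problems"/"unable to").  The level sum score (LSS) of a person is the
unweighted sum of their J levels (range ``J*level_min`` .. ``J*level_max``,
i.e. 5..25 for the EQ-5D-5L); the rest score used by every manifest check is
the LSS minus the item(s) under inspection.

Levels are kept 1-based as questionnaires print them.  All covariance-based
statistics downstream are invariant to a common shift of an item's levels, so
no internal re-coding is needed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ConfigError",
    "ParseError",
    "HealthProfile",
    "ResponseMatrix",
    "ReaderConfig",
    "encode_profile",
    "decode_profile",
    "enumerate_profiles",
    "level_sum_score",
    "rest_scores",
    "read_responses",
    "write_scores",
]


class ValidationError(ValueError):
    """Raised when response data violate the declared level bounds or shape."""


class ConfigError(ValueError):
    """Raised when a reader/analysis configuration does not match the data."""


class ParseError(ValueError):
    """Raised when a delimited-text cell cannot be parsed as an integer level."""


@dataclass(frozen=True)
class HealthProfile:
    """A health-state profile: one digit per item (e.g. ``"11121"``).

    Bijective with a length-J level vector as long as ``level_max <= 9``;
    ``decode_profile(encode_profile(x)) == x`` exactly.
    """

    digits: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.digits


def encode_profile(
    levels: Sequence[int], level_min: int = 1, level_max: int = 5
) -> HealthProfile:
    """Encode a level vector as a digit-string profile.

    Raises :class:`ValidationError` naming the first offending item when a
    level falls outside ``[level_min, level_max]``.
    """
    if level_max > 9 or level_min < 0:
        raise ConfigError("digit-string profiles require levels within 0..9")
    out = []
    for idx, lev in enumerate(levels):
        lev = int(lev)
        if not (level_min <= lev <= level_max):
            raise ValidationError(
                f"item {idx}: level {lev} outside [{level_min}, {level_max}]"
            )
        out.append(str(lev))
    return HealthProfile("".join(out))


def decode_profile(profile: HealthProfile | str) -> tuple[int, ...]:
    """Inverse of :func:`encode_profile`."""
    digits = profile.digits if isinstance(profile, HealthProfile) else profile
    return tuple(int(d) for d in digits)


def enumerate_profiles(
    n_items: int, level_min: int = 1, level_max: int = 5
) -> Iterator[HealthProfile]:
    """Yield every possible profile; there are ``(level_max-level_min+1)**n_items``
    of them (3125 for the EQ-5D-5L)."""
    rng = [str(v) for v in range(level_min, level_max + 1)]
    for combo in itertools.product(rng, repeat=n_items):
        yield HealthProfile("".join(combo))


@dataclass
class ResponseMatrix:
    """N x J ordinal responses with level bounds and optional person groupings.

    Parameters
    ----------
    values
        Integer array of shape (N, J); every entry in ``[level_min, level_max]``.
    level_min, level_max
        Inclusive response-level bounds (EQ-5D-5L default 1..5).
    item_labels
        J item identifiers; defaults to ``item1..itemJ``.
    group_labels
        Optional mapping from grouping-column name (e.g. ``"disease"``,
        ``"country"``) to a length-N array of categorical tags.
    """

    values: np.ndarray
    level_min: int = 1
    level_max: int = 5
    item_labels: list[str] = field(default_factory=list)
    group_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D (persons x items) array")
        if not np.issubdtype(self.values.dtype, np.integer):
            as_int = self.values.astype(np.int64)
            if not np.array_equal(as_int, self.values):
                raise ValidationError("response levels must be integers")
            self.values = as_int
        n, j = self.values.shape
        if n < 1 or j < 2:
            raise ValidationError(f"need N >= 1 persons and J >= 2 items, got {n} x {j}")
        if self.level_min >= self.level_max:
            raise ValidationError("level_min must be < level_max")
        bad = (self.values < self.level_min) | (self.values > self.level_max)
        if bad.any():
            p, i = np.argwhere(bad)[0]
            raise ValidationError(
                f"person {p}, item {i} ({self._label(i)}): level "
                f"{self.values[p, i]} outside [{self.level_min}, {self.level_max}]"
            )
        if not self.item_labels:
            self.item_labels = [f"item{k + 1}" for k in range(j)]
        if len(self.item_labels) != j:
            raise ValidationError("item_labels length must match number of items")
        for name, tags in self.group_labels.items():
            tags = np.asarray(tags)
            if tags.shape != (n,):
                raise ValidationError(f"group column {name!r} must have length N={n}")
            self.group_labels[name] = tags

    # -- basic geometry -----------------------------------------------------

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_levels(self) -> int:
        return self.level_max - self.level_min + 1

    def _label(self, i: int) -> str:
        return self.item_labels[i] if self.item_labels else f"item{i + 1}"

    def item_index(self, item: int | str) -> int:
        if isinstance(item, str):
            try:
                return self.item_labels.index(item)
            except ValueError:
                raise ConfigError(f"unknown item label {item!r}") from None
        i = int(item)
        if not (0 <= i < self.n_items):
            raise ConfigError(f"item index {i} out of range 0..{self.n_items - 1}")
        return i

    # -- scores -------------------------------------------------------------

    def level_sum_score(self) -> np.ndarray:
        """Per-person LSS: sum of the J entries (5..25 for the EQ-5D-5L)."""
        return self.values.sum(axis=1)

    def rest_scores(self, exclude_items: Iterable[int | str]) -> np.ndarray:
        """LSS minus the excluded items' entries.

        One item is excluded for monotonicity checks; two for paired invariant
        item ordering checks.  Excluding every item is an error.
        """
        idx = sorted({self.item_index(i) for i in exclude_items})
        if not idx:
            raise ConfigError("exclude_items must not be empty")
        if len(idx) >= self.n_items:
            raise ConfigError("cannot exclude all items: rest set would be empty")
        return self.level_sum_score() - self.values[:, idx].sum(axis=1)

    # -- derived matrices ---------------------------------------------------

    def subset_items(self, keep: Sequence[int | str]) -> "ResponseMatrix":
        idx = [self.item_index(i) for i in keep]
        if len(idx) < 2:
            raise ConfigError("a response matrix needs at least 2 items")
        return ResponseMatrix(
            self.values[:, idx],
            self.level_min,
            self.level_max,
            [self.item_labels[i] for i in idx],
            dict(self.group_labels),
        )

    def drop_items(self, drop: Sequence[int | str]) -> "ResponseMatrix":
        rm = {self.item_index(i) for i in drop}
        return self.subset_items([i for i in range(self.n_items) if i not in rm])

    def subset_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            if mask.shape != (self.n_persons,):
                raise ValidationError("boolean mask must have length N")
        return ResponseMatrix(
            self.values[mask],
            self.level_min,
            self.level_max,
            list(self.item_labels),
            {k: np.asarray(v)[mask] for k, v in self.group_labels.items()},
        )

    def iter_groups(self, column: str) -> Iterator[tuple[str, "ResponseMatrix"]]:
        """Iterate (tag, submatrix) over the observed values of a group column."""
        if column not in self.group_labels:
            raise ConfigError(f"unknown group column {column!r}")
        tags = np.asarray(self.group_labels[column])
        for tag in sorted(map(str, set(tags.tolist()))):
            yield tag, self.subset_persons(tags.astype(str) == tag)

    def profiles(self) -> list[HealthProfile]:
        return [
            encode_profile(row, self.level_min, self.level_max) for row in self.values
        ]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_labels)
        for name, tags in self.group_labels.items():
            df[name] = tags
        return df


# -- module-level functional aliases (the documented operation surface) ------


def level_sum_score(m: ResponseMatrix) -> np.ndarray:
    return m.level_sum_score()


def rest_scores(m: ResponseMatrix, exclude_items: Iterable[int | str]) -> np.ndarray:
    return m.rest_scores(exclude_items)


# -- delimited-text I/O -------------------------------------------------------


@dataclass
class ReaderConfig:
    """Configuration for :func:`read_responses`.

    ``missing`` policy: ``"listwise"`` (drop persons with any missing item
    response, count logged; the default) or ``"error"``.
    """

    item_columns: Sequence[str]
    level_min: int = 1
    level_max: int = 5
    group_columns: Sequence[str] = ()
    missing: str = "listwise"
    delimiter: str | None = None  # None = sniff from the file

    def __post_init__(self) -> None:
        if len(self.item_columns) < 2:
            raise ConfigError("need at least 2 item columns")
        if self.missing not in ("listwise", "error"):
            raise ConfigError(f"unknown missing-data policy {self.missing!r}")


def read_responses(path, config: ReaderConfig) -> ResponseMatrix:
    """Read a delimited text file of responses into a :class:`ResponseMatrix`.

    Delimiter is sniffed unless given.  Non-integer cells raise
    :class:`ParseError` with the row/column; unknown columns raise
    :class:`ConfigError`; out-of-bounds levels raise :class:`ValidationError`.
    """
    if config.delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=config.delimiter, dtype=str)
    for col in list(config.item_columns) + list(config.group_columns):
        if col not in df.columns:
            raise ConfigError(
                f"column {col!r} not in header {list(df.columns)} of {path}"
            )
    raw = df[list(config.item_columns)]
    missing_mask = raw.isna() | raw.apply(lambda s: s.str.strip().eq(""))
    row_missing = missing_mask.any(axis=1)
    if row_missing.any():
        if config.missing == "error":
            r = int(np.argmax(row_missing.to_numpy()))
            raise ParseError(f"missing item response in data row {r}")
        logger.warning(
            "read_responses: dropped %d of %d persons with missing item responses "
            "(listwise deletion)",
            int(row_missing.sum()),
            len(df),
        )
        df = df.loc[~row_missing]
        raw = raw.loc[~row_missing]
    values = np.empty(raw.shape, dtype=np.int64)
    for jc, col in enumerate(config.item_columns):
        for ridx, cell in zip(raw.index, raw[col]):
            try:
                values[raw.index.get_loc(ridx), jc] = int(str(cell).strip())
            except (TypeError, ValueError):
                raise ParseError(
                    f"row {ridx}, column {col!r}: cannot parse {cell!r} as an "
                    "integer response level"
                ) from None
    groups = {
        col: df[col].astype(str).to_numpy() for col in config.group_columns
    }
    return ResponseMatrix(
        values,
        config.level_min,
        config.level_max,
        list(config.item_columns),
        groups,
    )


def write_scores(m: ResponseMatrix, path, delimiter: str = "\t") -> pd.DataFrame:
    """Write a per-person score table: id, LSS, and the J single-item rest scores."""
    lss = m.level_sum_score()
    out = pd.DataFrame({"person": np.arange(m.n_persons), "lss": lss})
    for i, lab in enumerate(m.item_labels):
        out[f"rest_{lab}"] = lss - m.values[:, i]
    out.to_csv(path, sep=delimiter, index=False)
    return out
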