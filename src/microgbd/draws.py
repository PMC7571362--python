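"""Helpers for draw matrices.

A draw matrix is a long-format :class:`pandas.DataFrame` with identifier
columns (``location_id``, ``year``, ``age_group_id``, ``sex`` and optionally
``cause_id`` / ``nature_id``) plus wide draw columns ``draw_0 .. draw_{n-1}``,
each holding one Monte-Carlo realisation of a rate or count.  This mirrors
the layout burden-of-disease tooling conventionally uses and keeps every
per-draw operation a vectorised frame operation.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import ValidationError

_DRAW_RE = re.compile(r"^draw_(\d+)$")

ID_COLS = ["location_id", "year", "age_group_id", "sex"]


def draw_cols(df: pd.DataFrame) -> list[str]:
    """Return the draw columns of *df* in numeric order."""
    cols = [(int(m.group(1)), c) for c in df.columns if (m := _DRAW_RE.match(c))]
    return [c for _, c in sorted(cols)]


def n_draws(df: pd.DataFrame) -> int:
    return len(draw_cols(df))


def id_cols(df: pd.DataFrame) -> list[str]:
    """Identifier columns: everything that is not a draw column."""
    draws = set(draw_cols(df))
    return [c for c in df.columns if c not in draws]


def draw_values(df: pd.DataFrame) -> np.ndarray:
    """Draws as a dense (rows x n_draws) float array."""
    return df[draw_cols(df)].to_numpy(dtype=float)


def set_draw_values(df: pd.DataFrame, values: np.ndarray) -> pd.DataFrame:
    out = df.copy()
    out[draw_cols(df)] = values
    return out


def make_draws(ids: pd.DataFrame, values: np.ndarray) -> pd.DataFrame:
    """Build a draw matrix from an id frame and a (rows x n) value array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(ids):
        raise ValidationError(
            f"draw array has {values.shape[0]} rows for {len(ids)} id rows"
        )
    vals = pd.DataFrame(
        values, columns=[f"draw_{j}" for j in range(values.shape[1])]
    )
    return pd.concat([ids.reset_index(drop=True), vals], axis=1)


def check_aligned(a: pd.DataFrame, b: pd.DataFrame, on: list[str]) -> None:
    """Require identical key sets and draw counts for two draw matrices."""
    if n_draws(a) != n_draws(b):
        raise ValidationError(
            f"draw counts differ: {n_draws(a)} vs {n_draws(b)}"
        )
    ka = a[on].apply(tuple, axis=1)
    kb = b[on].apply(tuple, axis=1)
    if set(ka) != set(kb):
        raise ValidationError("draw matrices are not aligned on " + ", ".join(on))


def summarize(df: pd.DataFrame, lower: float = 2.5, upper: float = 97.5) -> pd.DataFrame:
    """Collapse draw columns to mean / lower / upper (percentiles, linear
    interpolation between order statistics)."""
    vals = draw_values(df)
    out = df[id_cols(df)].copy()
    out["mean"] = vals.mean(axis=1)
    out["lower"] = np.percentile(vals, lower, axis=1)
    out["upper"] = np.percentile(vals, upper, axis=1)
    return out
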