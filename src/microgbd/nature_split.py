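"""Cause-nature apportionment from dual-coded data.

Dual-coded clinical records carry both an external-cause code and a
nature-of-injury code, so they identify, for each cause, the probability
that a given bodily injury is the most disabling outcome.  The full
Dirichlet regression is reduced here to its conjugate core: per (cause,
age, sex) cell the probability vector over natures is the
Dirichlet-multinomial posterior mean (n_k + alpha) / (N + K * alpha),
optionally after pooling counts across adjacent age groups with a
triangular kernel.  Rows always live on the simplex, which guarantees that
splitting incidence across natures conserves it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .draws import ID_COLS, draw_cols
from .errors import SplitError, ValidationError


@dataclass
class CauseNatureMatrix:
    """p(nature | cause, age group, sex) with rows on the simplex.

    ``probs`` is a long frame with columns cause_id, age_group_id, sex and
    one probability column per nature_id.
    """
    probs: pd.DataFrame
    nature_ids: list[str]

    def __post_init__(self):
        vals = self.probs[self.nature_ids].to_numpy(float)
        if (vals < 0).any():
            raise ValidationError("probabilities must be non-negative")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("probability rows must sum to 1")

    def lookup(self, cause_id: str, age_group_id: str, sex: str) -> np.ndarray:
        m = self.probs[
            (self.probs["cause_id"] == cause_id)
            & (self.probs["age_group_id"] == age_group_id)
            & (self.probs["sex"] == sex)
        ]
        if m.empty:
            raise SplitError(
                f"no cause-nature row for ({cause_id}, {age_group_id}, {sex})"
            )
        return m[self.nature_ids].to_numpy(float)[0]

    def to_long(self) -> pd.DataFrame:
        return self.probs.melt(
            id_vars=["cause_id", "age_group_id", "sex"],
            value_vars=self.nature_ids,
            var_name="nature_id", value_name="probability",
        )


def _triangular_weights(positions: np.ndarray, centre: int, bandwidth: int) -> np.ndarray:
    w = 1.0 - np.abs(positions - centre) / (bandwidth + 1.0)
    return np.clip(w, 0.0, None)


def estimate_cause_nature_matrix(
    dual_coded: pd.DataFrame,
    alpha: float = 0.5,
    age_smoothing: int | None = None,
    nature_ids: list[str] | None = None,
    eligibility_mask: dict[str, list[str]] | None = None,
) -> CauseNatureMatrix:
    """Posterior-mean probability of each nature per (cause, age, sex).

    *dual_coded* columns: cause_id, nature_id, age_group_id, sex, count.
    *age_smoothing*: bandwidth (in age groups) of a triangular kernel used
    to pool counts across adjacent ages before estimation; None disables.
    *eligibility_mask*: optional cause_id -> allowed nature_ids; natures
    outside the mask are zeroed and the row renormalised.
    Causes with no positive counts anywhere fall back to a uniform row.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    if (dual_coded["count"] < 0).any():
        raise ValidationError("dual-coded counts must be non-negative")
    if nature_ids is None:
        nature_ids = sorted(dual_coded["nature_id"].unique())
    K = len(nature_ids)

    wide = (
        dual_coded.pivot_table(index=["cause_id", "age_group_id", "sex"],
                               columns="nature_id", values="count",
                               aggfunc="sum", fill_value=0.0)
        .reindex(columns=nature_ids, fill_value=0.0)
        .reset_index()
    )

    # fixed age ordering for kernel pooling
    age_order = list(dict.fromkeys(dual_coded["age_group_id"]))
    age_pos = {a: i for i, a in enumerate(sorted(set(age_order), key=age_order.index))}

    rows = []
    for (cause, sex), g in wide.groupby(["cause_id", "sex"]):
        g = g.set_index("age_group_id")
        counts = g[nature_ids].to_numpy(float)
        positions = np.array([age_pos[a] for a in g.index])
        for i, age in enumerate(g.index):
            if age_smoothing:
                w = _triangular_weights(positions, positions[i], age_smoothing)
                pooled = (w[:, None] * counts).sum(axis=0)
            else:
                pooled = counts[i]
            N = pooled.sum()
            if N == 0 and alpha == 0:
                p = np.full(K, 1.0 / K)        # uniform fallback, no information
            else:
                p = (pooled + alpha) / (N + K * alpha)
            if eligibility_mask and cause in eligibility_mask:
                allowed = np.isin(nature_ids, eligibility_mask[cause])
                p = np.where(allowed, p, 0.0)
                if p.sum() == 0:
                    raise ValidationError(
                        f"eligibility mask removes every nature for {cause!r}"
                    )
                p = p / p.sum()
            rows.append({"cause_id": cause, "age_group_id": age, "sex": sex,
                         **dict(zip(nature_ids, p))})
    probs = pd.DataFrame(rows)
    return CauseNatureMatrix(probs=probs, nature_ids=nature_ids)


def apply_nature_split(
    cause_incidence_draws: pd.DataFrame,
    matrix: CauseNatureMatrix,
) -> pd.DataFrame:
    """i(cause, nature, cell) = i(cause, cell) * p(nature | cause, age, sex).

    Returns a long draw matrix with an added nature_id column; summing it
    back over natures reproduces the input exactly (simplex rows).
    """
    dcols = draw_cols(cause_incidence_draws)
    inc = cause_incidence_draws.reset_index(drop=True)
    merged = inc.merge(
        matrix.probs, on=["cause_id", "age_group_id", "sex"],
        how="left", validate="m:1",
    )
    if merged[matrix.nature_ids[0]].isna().any():
        missing = inc.loc[merged[matrix.nature_ids[0]].isna(),
                          ["cause_id", "age_group_id", "sex"]].drop_duplicates()
        raise SplitError(
            "cells missing from the cause-nature matrix: "
            + missing.to_string(index=False)
        )
    ivals = merged[dcols].to_numpy(float)
    frames = []
    for nid in matrix.nature_ids:
        f = inc[["cause_id"] + ID_COLS].copy()
        f.insert(1, "nature_id", nid)
        f[dcols] = ivals * merged[nid].to_numpy(float)[:, None]
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
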