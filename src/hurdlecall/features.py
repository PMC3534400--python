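"""Per-flow covariates for the two hurdle submodels.

From a read's ordered flow signals we derive, per flow:

* ``fg0`` — the flowgram value of the current flow;
* ``lraw0`` — log2 raw intensity of the current flow, optionally centered
  by a read-specific baseline (the median log2 raw intensity of the read's
  presumed zero flows, i.e. flows with flowgram < 0.5; the read median if
  fewer than 4 such flows exist);
* ``cum_fg`` / ``cum_lraw`` — cumulative sums over strictly earlier flows,
  capturing cycle position and the abundance of homopolymers already seen;
* ``fg_lag{1,4,8}`` / ``fg_lead{1,4,8}`` — flowgram values 1/4/8 flows
  before/after the current flow, correcting for neighboring homopolymers
  (same-nucleotide context sits 4 and 8 flows away in a 4-flow cycle).

Lags and leads beyond the read boundaries are filled with 0.0, the natural
background flowgram of a no-incorporation flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FLOW_ORDER = "TACG"

#: Predictors entering the binomial (zero vs positive) submodel by default.
BINOMIAL_DEFAULT: tuple[str, ...] = ("fg0", "lraw0", "cum_fg", "fg_lag1", "fg_lead1")

#: Predictors entering the zero-truncated Poisson submodel by default.
POISSON_DEFAULT: tuple[str, ...] = (
    "fg0",
    "lraw0",
    "cum_fg",
    "fg_lag1",
    "fg_lag4",
    "fg_lag8",
    "fg_lead1",
    "fg_lead4",
    "fg_lead8",
)

ALL_FEATURES: tuple[str, ...] = (
    "fg0",
    "lraw0",
    "cum_fg",
    "cum_lraw",
    "fg_lag1",
    "fg_lag4",
    "fg_lag8",
    "fg_lead1",
    "fg_lead4",
    "fg_lead8",
)

BOUNDARY_FILL = 0.0
ZERO_FLOW_THRESHOLD = 0.5


@dataclass(frozen=True)
class FeatureConfig:
    """Which predictors enter each submodel, and signal-handling options."""

    binomial_terms: tuple[str, ...] = BINOMIAL_DEFAULT
    poisson_terms: tuple[str, ...] = POISSON_DEFAULT
    normalize_raw: bool = True
    flow_order: str = DEFAULT_FLOW_ORDER

    def __post_init__(self) -> None:
        if sorted(self.flow_order) != sorted("TACG"):
            raise ValueError(f"flow_order must permute TACG, got {self.flow_order!r}")
        for name in (*self.binomial_terms, *self.poisson_terms):
            if name not in ALL_FEATURES:
                raise ValueError(f"unknown feature {name!r}; known: {ALL_FEATURES}")

    def to_dict(self) -> dict:
        return {
            "binomial_terms": list(self.binomial_terms),
            "poisson_terms": list(self.poisson_terms),
            "normalize_raw": self.normalize_raw,
            "flow_order": self.flow_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            binomial_terms=tuple(d["binomial_terms"]),
            poisson_terms=tuple(d["poisson_terms"]),
            normalize_raw=bool(d["normalize_raw"]),
            flow_order=str(d["flow_order"]),
        )


def normalize_raw(read_flows: pd.DataFrame) -> np.ndarray:
    """Read-normalized log2 raw intensities for one read's ordered flows.

    The baseline subtracted from each flow's log2 raw intensity is the
    median log2 raw intensity over the read's presumed zero flows
    (flowgram < 0.5); with fewer than 4 such flows, the read median.
    """
    if len(read_flows) == 0:
        return np.empty(0)
    lraw = np.log2(read_flows["raw_intensity"].to_numpy(dtype=float))
    zero_mask = read_flows["flowgram"].to_numpy(dtype=float) < ZERO_FLOW_THRESHOLD
    if zero_mask.sum() >= 4:
        baseline = float(np.median(lraw[zero_mask]))
    else:
        baseline = float(np.median(lraw))
    return lraw - baseline


def _shift(values: np.ndarray, offset: int) -> np.ndarray:
    """values shifted so out[i] = values[i + offset], boundary-filled."""
    out = np.full_like(values, BOUNDARY_FILL, dtype=float)
    if offset >= 0:
        if offset < len(values):
            out[: len(values) - offset] = values[offset:]
    else:
        if -offset < len(values):
            out[-offset:] = values[:offset]
    return out


def _read_features(read_flows: pd.DataFrame, config: FeatureConfig) -> pd.DataFrame:
    fg = read_flows["flowgram"].to_numpy(dtype=float)
    if config.normalize_raw:
        lraw = normalize_raw(read_flows)
    else:
        lraw = np.log2(read_flows["raw_intensity"].to_numpy(dtype=float))
    cum_fg = np.concatenate(([0.0], np.cumsum(fg)[:-1]))
    cum_lraw = np.concatenate(([0.0], np.cumsum(lraw)[:-1]))
    cols = {
        "fg0": fg,
        "lraw0": lraw,
        "cum_fg": cum_fg,
        "cum_lraw": cum_lraw,
    }
    for k in (1, 4, 8):
        cols[f"fg_lag{k}"] = _shift(fg, -k)
        cols[f"fg_lead{k}"] = _shift(fg, k)
    return pd.DataFrame(cols, index=read_flows.index)


def build_features(
    flows: pd.DataFrame, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature matrix (all of :data:`ALL_FEATURES`) for a flow table.

    ``flows`` must carry ``read_id``, ``flow_index``, ``flowgram`` and
    ``raw_intensity`` columns, sorted by ``flow_index`` within each read
    with no duplicates.  The output is row-aligned with ``flows``.
    """
    config = config or FeatureConfig()
    required = {"read_id", "flow_index", "flowgram", "raw_intensity"}
    missing = required - set(flows.columns)
    if missing:
        raise ValueError(f"flow table missing columns: {sorted(missing)}")
    parts = []
    for read_id, grp in flows.groupby("read_id", sort=False):
        idx = grp["flow_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValueError(
                f"read {read_id!r}: flow_index must be strictly increasing "
                "(unsorted or duplicated flows)"
            )
        parts.append(_read_features(grp, config))
    if not parts:
        return pd.DataFrame(columns=list(ALL_FEATURES))
    return pd.concat(parts).loc[flows.index]
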