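"""Quality scores from per-flow HPL probability vectors.

For the k-th base of a called homopolymer (k = 0 denotes the no-base
position of a zero call) two Phred-like scores are computed from the
error-tail probabilities:

* overcall score  ``-10 log10 P(HPL < k)`` — small when the k-th base is
  likely one too many;
* undercall score ``-10 log10 P(HPL > k)`` — small when a longer
  homopolymer is likely, i.e. a base is missing after position k.

The signed combined score is ``I_dir * round(min(over, under))`` with
``I_dir = -1`` when the undercall score is strictly smaller (an undercall
is the likelier error) and ``+1`` otherwise.  Per-base Phred scores carry
the overcall score, trimmed to the 0..40 range; tail probabilities are
floored at 1e-15 before taking logs.
"""

from __future__ import annotations

import math

import numpy as np

from .basecall import CalledRead

PROB_FLOOR = 1e-15
QS_CAP = 40


def _neg_log10(p: float) -> float:
    return -10.0 * math.log10(max(float(p), PROB_FLOOR))


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def qs_overcall(probs: np.ndarray, k: int) -> float:
    """Overcall score of position k >= 1: -10 log10 P(HPL < k)."""
    if k < 1:
        raise ValueError(f"overcall score is defined for called bases k >= 1, got {k}")
    probs = np.asarray(probs, dtype=float)
    return _neg_log10(float(probs[: min(k, len(probs))].sum()))


def qs_undercall(probs: np.ndarray, k: int) -> float:
    """Undercall score of position k >= 0: -10 log10 P(HPL > k)."""
    if k < 0:
        raise ValueError(f"position must be >= 0, got {k}")
    probs = np.asarray(probs, dtype=float)
    return _neg_log10(float(probs[k + 1 :].sum()))


def qs_signed(probs: np.ndarray, k: int) -> int:
    """Signed combined score: direction of the likelier error times the
    rounded smaller of the two tail scores, magnitude capped at 40.

    ``k = 0`` is allowed (no-base position): the overcall tail
    ``P(HPL < 0)`` is empty and sits at the probability floor.
    """
    if k < 0:
        raise ValueError(f"position must be >= 0, got {k}")
    probs = np.asarray(probs, dtype=float)
    over = _neg_log10(float(probs[:k].sum())) if k >= 1 else _neg_log10(0.0)
    under = qs_undercall(probs, k)
    sign = -1 if under < over else 1
    mag = min(round_half_away(min(over, under)), QS_CAP)
    mag = max(mag, 0)
    return sign * mag if mag > 0 else 0


def phred_scores(called_read: CalledRead) -> np.ndarray:
    """Per-base Phred-like scores (overcall semantics), trimmed to 0..40.

    Scores are ordered like the read sequence: the k-th base of each
    called homopolymer gets ``min(round(qs_overcall(probs, k)), 40)``.
    """
    flow_pos = {int(fi): row for fi, row in zip(called_read.flow_indices, called_read.prob_matrix)}
    out = np.empty(len(called_read.base_to_flow), dtype=int)
    for i, (fi, k) in enumerate(called_read.base_to_flow):
        q = round_half_away(qs_overcall(flow_pos[fi], k))
        out[i] = min(max(q, 0), QS_CAP)
    return out


def position_qualities(
    probs: np.ndarray, called_hpl: int, window_extra: int = 2
) -> list[dict]:
    """Per-position score rows for one flow's sidecar table.

    Positions k = 0..min(called_hpl + window_extra, n_max) are reported,
    mirroring the windowed layout of per-flow score tables.
    """
    n_max = len(probs) - 1
    rows = []
    for k in range(0, min(called_hpl + window_extra, n_max) + 1):
        rows.append(
            {
                "k": k,
                "qs_overcall": qs_overcall(probs, k) if k >= 1 else float("nan"),
                "qs_undercall": qs_undercall(probs, k),
                "qs_signed": qs_signed(probs, k),
            }
        )
    return rows
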