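"""Accuracy and calibration metrics for called flows.

Truth pairing is flow-aligned (the simulator carries the reference HPL of
every flow), so errors are classified per flow without an aligner:
undercall when the called HPL is below the reference, overcall when it is
above.  Quality-score calibration groups called bases by their integer
predicted Phred score and compares the predicted score to the observed
one, ``-10 log10`` of the group's overcall rate; both are trimmed at the
cap (40), and groups with zero observed errors are reported at the cap
with a flag.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

QS_CAP = 40


def error_by_hpl(called_hpls: np.ndarray, ref_hpls: np.ndarray) -> pd.DataFrame:
    """Per-reference-HPL error table plus an ``overall`` totals row."""
    called = np.asarray(called_hpls, dtype=int)
    ref = np.asarray(ref_hpls, dtype=int)
    if called.shape != ref.shape:
        raise ValueError(
            f"called and reference HPL vectors differ in length: "
            f"{called.shape} vs {ref.shape}"
        )
    rows = []
    for hpl in np.unique(ref):
        mask = ref == hpl
        n = int(mask.sum())
        under = int((called[mask] < hpl).sum())
        over = int((called[mask] > hpl).sum())
        rows.append(
            {
                "ref_hpl": int(hpl),
                "n_flows": n,
                "n_correct": n - under - over,
                "n_undercall": under,
                "n_overcall": over,
                "pct_error": 100.0 * (under + over) / n,
            }
        )
    total = len(ref)
    n_err = int((called != ref).sum())
    rows.append(
        {
            "ref_hpl": "overall",
            "n_flows": total,
            "n_correct": total - n_err,
            "n_undercall": int((called < ref).sum()),
            "n_overcall": int((called > ref).sum()),
            "pct_error": 100.0 * n_err / total if total else 0.0,
        }
    )
    return pd.DataFrame(rows)


def qs_calibration(
    predicted_phred: np.ndarray, overcall_indicator: np.ndarray, cap: int = QS_CAP
) -> pd.DataFrame:
    """Observed vs predicted quality score per integer score group.

    ``overcall_indicator`` marks, per called base, whether that base was
    an overcall (flow-aligned truth).  Observed QS is
    ``-10 log10(overcall rate)`` in the group, trimmed at ``cap``;
    zero-error groups sit at the cap and are flagged.
    """
    qs = np.asarray(predicted_phred, dtype=int)
    err = np.asarray(overcall_indicator, dtype=bool)
    if qs.shape != err.shape:
        raise ValueError("predicted scores and indicators differ in length")
    rows = []
    for score in np.unique(qs):
        mask = qs == score
        n = int(mask.sum())
        k = int(err[mask].sum())
        if k == 0:
            observed, flag = float(cap), True
        else:
            observed, flag = min(-10.0 * math.log10(k / n), float(cap)), False
        rows.append(
            {
                "predicted_qs": int(score),
                "observed_qs": observed,
                "n": n,
                "n_overcall": k,
                "zero_error": flag,
            }
        )
    return pd.DataFrame(rows)


def cumulative_qs(predicted_phred: np.ndarray, cap: int = QS_CAP) -> pd.DataFrame:
    """Fraction of called bases with score >= t for t = 0..cap."""
    qs = np.asarray(predicted_phred)
    n = len(qs)
    ts = np.arange(cap + 1)
    frac = np.array([(qs >= t).sum() / n if n else 0.0 for t in ts])
    return pd.DataFrame({"threshold": ts, "fraction_at_least": frac})


def overcall_indicators(called_reads, ref_hpl_by_flow: dict) -> np.ndarray:
    """Per-base overcall flags for called reads, flow-aligned to truth.

    ``ref_hpl_by_flow`` maps ``(read_id, flow_index)`` to the reference
    HPL.  The k-th called base of a flow is an overcall when k exceeds
    the reference HPL (the surplus bases of an overcalled homopolymer).
    """
    flags = []
    for cr in called_reads:
        for fi, k in cr.base_to_flow:
            ref = ref_hpl_by_flow[(cr.read_id, int(fi))]
            flags.append(k > ref)
    return np.asarray(flags, dtype=bool)


def plot_calibration(calibration: pd.DataFrame, path) -> None:
    """Observed-vs-predicted diagonal plot (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, QS_CAP], [0, QS_CAP], "k--", lw=1)
    ax.scatter(calibration["predicted_qs"], calibration["observed_qs"], s=12)
    ax.set_xlabel("predicted QS")
    ax.set_ylabel("observed QS")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cumulative(cumulative: pd.DataFrame, path) -> None:
    """Cumulative fraction of bases vs score threshold (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(cumulative["threshold"], cumulative["fraction_at_least"], where="post")
    ax.set_xlabel("quality score threshold")
    ax.set_ylabel("fraction of bases at or above")
    ax.set_ylim(0, 1.02)
    fig.savefig(path, dpi=120)
    plt.close(fig)
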