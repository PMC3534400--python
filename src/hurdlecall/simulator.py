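"""Synthetic flow-cycle sequencing data.

Two generation modes:

* **signal-based** — a physical noise model for end-to-end tests: random
  reference sequences with geometric homopolymer lengths are pushed
  through the fixed flow order, and each flow emits a flowgram value and
  a raw intensity.  Zero flows carry background optical noise only; the
  flowgram noise of positive flows grows like sqrt(HPL) and the raw
  signal attenuates like ``a * n**gamma`` (gamma < 1), so adjacent HPL
  signal distributions overlap increasingly with length — the rising
  miscall rate of long homopolymers.
* **model-based** — exact draws from a specified hurdle model (pi and
  lambda functions of a covariate, global theta), for parameter-recovery
  and calibration tests against a known truth.

A single seed drives everything; per-read substreams are derived by read
counter so reads are independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import flow_model
from .features import DEFAULT_FLOW_ORDER


@dataclass(frozen=True)
class SimulationConfig:
    """Generation parameters of the signal-based simulator.

    Defaults describe a desk-scale flow run: reads of ~100 bases, mostly
    short homopolymers (geometric law, mean 1/p), flowgram noise that
    makes HPL-7 miscalls reach several percent, and log-normal raw
    intensities whose per-length increase attenuates (``attenuation`` < 1).
    """

    n_reads: int = 1000
    read_length: int = 100
    hpl_geometric_p: float = 0.6
    flow_order: str = DEFAULT_FLOW_ORDER
    signal_scale: float = 1000.0
    attenuation: float = 0.8
    signal_cv: float = 0.3
    background_log2_mean: float = 6.0
    background_log2_sd: float = 0.7
    flowgram_noise_sd: float = 0.12
    seed: int = 0
    max_flows: int | None = None

    def __post_init__(self) -> None:
        if sorted(self.flow_order) != sorted("TACG"):
            raise ValueError(f"flow_order must permute TACG, got {self.flow_order!r}")
        if not (0.0 < self.hpl_geometric_p <= 1.0):
            raise ValueError("hpl_geometric_p must be in (0, 1]")
        for name in ("signal_scale", "signal_cv", "background_log2_sd", "flowgram_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.attenuation <= 1.0):
            raise ValueError("attenuation must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _read_rng(seed: int, read_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(read_index,)))


def simulate_reference(config: SimulationConfig) -> list[str]:
    """Random reference sequences with geometric homopolymer lengths.

    Run lengths are i.i.d. geometric on support >= 1 (parameter
    ``hpl_geometric_p``); each run's nucleotide is uniform among the
    three different from the previous run.  Sequences are truncated to
    ``read_length`` bases.
    """
    bases = np.array(list("ACGT"))
    seqs = []
    for i in range(config.n_reads):
        rng = _read_rng(config.seed, i)
        pieces: list[str] = []
        total = 0
        prev = None
        while total < config.read_length:
            choices = bases[bases != prev] if prev is not None else bases
            nuc = str(rng.choice(choices))
            run = int(rng.geometric(config.hpl_geometric_p))
            run = min(run, config.read_length - total)
            pieces.append(nuc * run)
            total += run
            prev = nuc
        seqs.append("".join(pieces))
    return seqs


def sequence_to_flows(
    sequence: str, flow_order: str = DEFAULT_FLOW_ORDER, max_flows: int | None = None
) -> np.ndarray:
    """True HPL per flow: walk the flow order, consuming maximal runs.

    Each flow emits the length of the run of its nucleotide at the
    template cursor (possibly 0).  Flows continue to the end of the cycle
    in which the template is exhausted (the instrument flows all four
    solutions every cycle), or stop earlier at ``max_flows``.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    hpls = []
    pos = 0
    flow = 0
    n = len(sequence)
    while (pos < n or flow % 4 != 0) and (max_flows is None or flow < max_flows):
        nuc = flow_order[flow % 4]
        run = 0
        while pos + run < n and sequence[pos + run] == nuc:
            run += 1
        hpls.append(run)
        pos += run
        flow += 1
    return np.asarray(hpls, dtype=int)


def simulate_signals(
    true_hpls: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy (flowgram, raw intensity) per flow given the true HPLs."""
    n = np.asarray(true_hpls, dtype=int)
    flowgram = np.empty(len(n), dtype=float)
    raw = np.empty(len(n), dtype=float)
    zero = n == 0
    flowgram[zero] = np.abs(rng.normal(0.0, config.flowgram_noise_sd, zero.sum()))
    raw[zero] = 2.0 ** rng.normal(
        config.background_log2_mean, config.background_log2_sd, zero.sum()
    )
    pos = ~zero
    npos = n[pos].astype(float)
    flowgram[pos] = np.maximum(
        npos + rng.normal(0.0, config.flowgram_noise_sd * np.sqrt(npos)), 0.0
    )
    raw[pos] = (
        config.signal_scale
        * npos**config.attenuation
        * np.exp(rng.normal(0.0, config.signal_cv, pos.sum()))
    )
    return flowgram, raw


def simulate_reads(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Signal-based simulation: a flow table with reference HPLs plus the
    truth sequences keyed by read id."""
    seqs = simulate_reference(config)
    frames = []
    truth = {}
    for i, seq in enumerate(seqs):
        # signals use a substream independent of the template substream
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i, 1)))
        hpls = sequence_to_flows(seq, config.flow_order, config.max_flows)
        flowgram, raw = simulate_signals(hpls, config, rng)
        read_id = f"read{i:05d}"
        truth[read_id] = seq
        idx = np.arange(len(hpls))
        frames.append(
            pd.DataFrame(
                {
                    "read_id": read_id,
                    "flow_index": idx,
                    "cycle": idx // 4,
                    "nucleotide": [config.flow_order[j % 4] for j in idx],
                    "flowgram": flowgram,
                    "raw_intensity": raw,
                    "ref_hpl": hpls,
                }
            )
        )
    flows = pd.concat(frames, ignore_index=True)
    return flows, truth


def simulate_from_model(
    pi_fn,
    lambda_fn,
    theta: float,
    covariates: np.ndarray,
    seed: int,
    n_max: int = 30,
) -> np.ndarray:
    """Counts drawn from the hurdle model itself (model-based mode).

    ``pi_fn`` and ``lambda_fn`` map the covariate array to hurdle
    probabilities and rates; positives are drawn from the zero-truncated
    weighted Poisson by inverse CDF on the truncated table.
    """
    covariates = np.asarray(covariates, dtype=float)
    rng = np.random.default_rng(seed)
    pi = np.asarray(pi_fn(covariates), dtype=float)
    lam = np.asarray(lambda_fn(covariates), dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi_fn must map into [0, 1]")
    if np.any(lam <= 0):
        raise ValueError("lambda_fn must map into (0, inf)")
    counts = np.zeros(len(covariates), dtype=int)
    z = rng.random(len(covariates)) < pi
    if z.any():
        probs = flow_model.hurdle_pmf_matrix(np.ones(z.sum()), lam[z], theta, n_max)
        zt = probs[:, 1:]
        zt = zt / zt.sum(axis=1, keepdims=True)
        cdf = np.cumsum(zt, axis=1)
        u = rng.random(z.sum())
        counts[z] = 1 + (u[:, None] > cdf).sum(axis=1)
    return counts
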