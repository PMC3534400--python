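"""From fitted model to called reads.

Each flow gets a discrete probability distribution over homopolymer
lengths 0..n_max; the call is the argmax (ties broken toward the smaller
HPL, conservative against overcalls).  Called HPLs are concatenated into
the read sequence, with a map from every base back to its flow and its
1-based position within the homopolymer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Probabilities below this are reported at the floor in output files
#: (matching the "<1E-15" display convention); raw values are used
#: internally.
PROB_FLOOR = 1e-15


@dataclass
class CalledRead:
    """One base-called read with its per-flow probability matrix."""

    read_id: str
    sequence: str
    called_hpls: np.ndarray
    nucleotides: np.ndarray  # flowed nucleotide per flow
    flow_indices: np.ndarray
    base_to_flow: list  # (flow_index, k) per base, k counting 1..HPL
    prob_matrix: np.ndarray  # (n_flows, n_max + 1)

    def __post_init__(self) -> None:
        assert len(self.sequence) == int(np.sum(self.called_hpls))
        assert len(self.base_to_flow) == len(self.sequence)


def call_hpl(probs: np.ndarray) -> int:
    """Argmax HPL of one probability vector; ties go to the smaller HPL."""
    return int(np.argmax(probs))


def assemble_read(
    read_id: str,
    called_hpls: np.ndarray,
    nucleotides: np.ndarray,
    flow_indices: np.ndarray | None = None,
    prob_matrix: np.ndarray | None = None,
) -> CalledRead:
    """Concatenate called homopolymers into a read and index its bases."""
    called_hpls = np.asarray(called_hpls, dtype=int)
    nucleotides = np.asarray(nucleotides)
    if flow_indices is None:
        flow_indices = np.arange(len(called_hpls))
    flow_indices = np.asarray(flow_indices, dtype=int)
    if prob_matrix is None:
        prob_matrix = np.zeros((len(called_hpls), 0))
    pieces = []
    base_to_flow = []
    for fi, nuc, hpl in zip(flow_indices, nucleotides, called_hpls):
        if hpl > 0:
            pieces.append(str(nuc) * int(hpl))
            base_to_flow.extend((int(fi), k) for k in range(1, int(hpl) + 1))
    return CalledRead(
        read_id=read_id,
        sequence="".join(pieces),
        called_hpls=called_hpls,
        nucleotides=nucleotides,
        flow_indices=flow_indices,
        base_to_flow=base_to_flow,
        prob_matrix=prob_matrix,
    )


def predict_probabilities(model, read_flows: pd.DataFrame) -> np.ndarray:
    """Per-flow HPL probability matrix for one read (rows sum to 1)."""
    return model.predict_proba(read_flows)


def call_reads(model, flows: pd.DataFrame) -> list[CalledRead]:
    """Call every read in a flow table with a fitted model.

    Features involve lagged/cumulative context, so prediction happens per
    read on its ordered flows.
    """
    out = []
    for read_id, grp in flows.groupby("read_id", sort=False):
        probs = model.predict_proba(grp)
        hpls = np.argmax(probs, axis=1)
        out.append(
            assemble_read(
                str(read_id),
                hpls,
                grp["nucleotide"].to_numpy(),
                grp["flow_index"].to_numpy(),
                probs,
            )
        )
    return out
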