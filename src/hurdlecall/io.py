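"""File formats: flow-table TSV, model JSON, FASTA/FASTQ, score sidecars.

The flow table is the ingestion contract (vendor binary formats are out
of scope): a UTF-8 TSV with a ``#flow_order=`` comment line, a header
row, and columns ``read_id, flow_index, cycle, nucleotide, flowgram,
raw_intensity, ref_hpl`` (``ref_hpl = -1`` when unknown).  Called reads
are emitted as FASTA plus FASTQ (Sanger encoding, Phred+33, scores
clamped to 0..40), a per-flow probability matrix TSV, and a per-position
quality-score sidecar TSV — signed scores cannot live in FASTQ, so the
sidecar is their canonical carrier.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .basecall import CalledRead, PROB_FLOOR
from .features import DEFAULT_FLOW_ORDER
from .quality import phred_scores, position_qualities

FLOW_COLUMNS = [
    "read_id",
    "flow_index",
    "cycle",
    "nucleotide",
    "flowgram",
    "raw_intensity",
    "ref_hpl",
]


class FlowTableError(ValueError):
    """Malformed flow table."""


def write_flow_table(
    flows: pd.DataFrame,
    path,
    flow_order: str = DEFAULT_FLOW_ORDER,
    header_meta: dict | None = None,
) -> None:
    """Write a flow table TSV; absent ref_hpl is encoded as -1."""
    df = flows.copy()
    if "ref_hpl" not in df.columns:
        df["ref_hpl"] = -1
    df["ref_hpl"] = df["ref_hpl"].fillna(-1).astype(int)
    df = df[FLOW_COLUMNS]
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"#{key}={val}\n")
        fh.write(f"#flow_order={flow_order}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_flow_table(path) -> tuple[pd.DataFrame, str]:
    """Read and validate a flow table; returns ``(flows, flow_order)``.

    ``ref_hpl = -1`` is mapped to missing (nullable integer).  Validation
    errors name the offending 1-based line number.
    """
    flow_order = None
    n_comment = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            if line.startswith("#flow_order="):
                flow_order = line.strip().split("=", 1)[1]
    if flow_order is None:
        raise FlowTableError(f"{path}: missing '#flow_order=' header comment")
    if sorted(flow_order) != sorted("TACG"):
        raise FlowTableError(f"{path}: flow_order {flow_order!r} must permute TACG")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"read_id": str})
    missing = set(FLOW_COLUMNS) - set(df.columns)
    if missing:
        raise FlowTableError(f"{path}: missing columns {sorted(missing)}")
    # data line number = comment lines + header row + row position + 1
    line_of = lambda i: n_comment + 1 + int(i) + 1
    for rid, grp in df.groupby("read_id", sort=False):
        dup = grp["flow_index"].duplicated()
        if dup.any():
            i = grp.index[dup][0]
            raise FlowTableError(
                f"{path}:{line_of(i)}: duplicate flow_index "
                f"{int(grp.loc[i, 'flow_index'])} in read {rid!r}"
            )
    expected = np.array([flow_order[j % 4] for j in df["flow_index"].to_numpy()])
    bad = df["nucleotide"].to_numpy() != expected
    if bad.any():
        i = int(np.argmax(bad))
        raise FlowTableError(
            f"{path}:{line_of(i)}: nucleotide {df['nucleotide'].iloc[i]!r} "
            f"inconsistent with flow order {flow_order!r} at flow_index "
            f"{int(df['flow_index'].iloc[i])} (expected {expected[i]!r})"
        )
    if (df["flowgram"] < 0).any():
        i = int(np.argmax((df["flowgram"] < 0).to_numpy()))
        raise FlowTableError(f"{path}:{line_of(i)}: negative flowgram value")
    if (df["raw_intensity"] <= 0).any():
        i = int(np.argmax((df["raw_intensity"] <= 0).to_numpy()))
        raise FlowTableError(f"{path}:{line_of(i)}: raw_intensity must be > 0")
    df["ref_hpl"] = df["ref_hpl"].astype("Int64").where(df["ref_hpl"] >= 0)
    df = (
        df.sort_values(["read_id", "flow_index"], kind="mergesort")
        .reset_index(drop=True)
    )
    return df, flow_order


# ---------------------------------------------------------------------------
# Outputs of a calling run
# ---------------------------------------------------------------------------


def _fastq_records(called_reads: list[CalledRead]):
    for cr in called_reads:
        rec = SeqRecord(Seq(cr.sequence), id=cr.read_id, description="")
        quals = phred_scores(cr) if cr.sequence else []
        rec.letter_annotations["phred_quality"] = [int(min(max(q, 0), 40)) for q in quals]
        yield rec


def write_outputs(
    called_reads: list[CalledRead],
    path_prefix,
    header_meta: dict | None = None,
) -> dict[str, Path]:
    """Emit ``<prefix>.fasta/.fastq/.probs.tsv/.qs.tsv`` for called reads.

    Probability cells are printed at 6 significant digits with a floor of
    1e-15 (the display convention for vanishing probabilities); an empty
    read set yields valid files with headers only.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": prefix.with_suffix(prefix.suffix + ".fasta"),
        "fastq": prefix.with_suffix(prefix.suffix + ".fastq"),
        "probs": prefix.with_suffix(prefix.suffix + ".probs.tsv"),
        "qs": prefix.with_suffix(prefix.suffix + ".qs.tsv"),
    }
    meta_lines = "".join(f"#{k}={v}\n" for k, v in (header_meta or {}).items())

    records = list(_fastq_records(called_reads))
    with open(paths["fasta"], "w") as fh:
        SeqIO.write([r for r in records if len(r.seq)], fh, "fasta")
    with open(paths["fastq"], "w") as fh:
        SeqIO.write([r for r in records if len(r.seq)], fh, "fastq")

    n_max = max((cr.prob_matrix.shape[1] for cr in called_reads), default=1) - 1
    with open(paths["probs"], "w", encoding="utf-8") as fh:
        fh.write(meta_lines)
        cols = ["read_id", "flow_index", "nucleotide", "called_hpl"] + [
            f"p{n}" for n in range(n_max + 1)
        ]
        fh.write("\t".join(cols) + "\n")
        for cr in called_reads:
            for fi, nuc, hpl, row in zip(
                cr.flow_indices, cr.nucleotides, cr.called_hpls, cr.prob_matrix
            ):
                cells = [cr.read_id, str(int(fi)), str(nuc), str(int(hpl))]
                cells += [f"{max(p, PROB_FLOOR):.5e}" for p in row]
                fh.write("\t".join(cells) + "\n")

    with open(paths["qs"], "w", encoding="utf-8") as fh:
        fh.write(meta_lines)
        fh.write("read_id\tflow_index\tk\tqs_overcall\tqs_undercall\tqs_signed\n")
        for cr in called_reads:
            for fi, hpl, row in zip(cr.flow_indices, cr.called_hpls, cr.prob_matrix):
                for rec in position_qualities(row, int(hpl)):
                    over = "" if np.isnan(rec["qs_overcall"]) else f"{rec['qs_overcall']:.3f}"
                    fh.write(
                        f"{cr.read_id}\t{int(fi)}\t{rec['k']}\t{over}\t"
                        f"{rec['qs_undercall']:.3f}\t{rec['qs_signed']}\n"
                    )
    return paths


def write_truth_fasta(truth: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=read_id, description="") for read_id, seq in truth.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def save_model(model, path) -> None:
    Path(path).write_text(model.to_json(), encoding="utf-8")


def load_model(path):
    from .gam import HurdleBaseCaller

    return HurdleBaseCaller.from_json(Path(path).read_text(encoding="utf-8"))
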