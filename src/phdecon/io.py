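"""File readers and writers: TSV expression tables, sample-design sheets,
FASTA proteomes (UniProt header dialect), disorder sidecars and JSON run
summaries.  All writers emit deterministic column order and Unix newlines."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .deconvolution import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    """A protein sequence with UniProt-style accession handling."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"record {self.accession!r} has empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"record {self.accession!r} has invalid residues {sorted(bad)}"
            )


def _parse_accession(header_id: str) -> str:
    # UniProt dialect "sp|ACC|NAME" / "tr|ACC|NAME"; plain ids pass through
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in {"sp", "tr"}:
        return parts[1]
    return header_id


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a protein FASTA; empty-sequence records are skipped and logged."""
    path = Path(path)
    records = []
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            n_skipped += 1
            logger.warning("read_fasta: skipping empty record %r", rec.id)
            continue
        records.append(ProteinRecord(
            accession=_parse_accession(rec.id),
            description=rec.description,
            sequence=seq,
        ))
    if not records:
        raise ValidationError(f"no usable FASTA records in {path}")
    if n_skipped:
        logger.warning("read_fasta: skipped %d empty records", n_skipped)
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression(counts_path, design_path, normalize: bool = False) -> ExpressionMatrix:
    """Read a gene x sample TSV plus its sample-design sheet and validate."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    for col in counts.columns:
        if not np.issubdtype(counts[col].dtype, np.number):
            raise ValidationError(f"non-numeric values in sample column {col!r}")
    matrix = ExpressionMatrix(counts, design)
    if normalize:
        from .deconvolution import normalize_matrix

        matrix = normalize_matrix(matrix)
    return matrix


def write_expression(matrix: ExpressionMatrix, counts_path, design_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id", lineterminator="\n")
    matrix.design.to_csv(design_path, sep="\t", index=False, lineterminator="\n")


def collapse_transcripts(
    table: pd.DataFrame, transcript_gene_map: Mapping[str, str]
) -> pd.DataFrame:
    """Sum transcript-level rows per gene (first-appearance gene order).

    Transcripts absent from the map are dropped with a logged count.
    """
    mapped = table.index.map(lambda t: transcript_gene_map.get(t))
    n_dropped = int(pd.isna(mapped).sum())
    if n_dropped:
        logger.warning("collapse_transcripts: dropped %d unmapped transcripts", n_dropped)
    kept = table[~pd.isna(mapped)]
    genes = pd.Index([transcript_gene_map[t] for t in kept.index], name="gene_id")
    if kept.empty:
        raise ValidationError("no transcripts map to any gene")
    order = genes.drop_duplicates()
    summed = kept.groupby(genes, sort=False).sum()
    return summed.loc[order]


# ---------------------------------------------------------------------------
# Disorder sidecar
# ---------------------------------------------------------------------------


def read_disorder_sidecar(path) -> dict[str, np.ndarray]:
    """TSV (protein_id, position, score) -> per-protein score arrays."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "score"}
    if not required.issubset(df.columns):
        raise ValidationError(f"sidecar must have columns {sorted(required)}")
    out = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        if positions[0] != 1 or not np.array_equal(
            positions, np.arange(1, len(positions) + 1)
        ):
            raise ValidationError(f"sidecar positions for {pid!r} are not 1..L")
        out[str(pid)] = sub["score"].to_numpy(dtype=float)
    return out


def write_disorder_sidecar(sidecar: pd.DataFrame, path) -> None:
    sidecar.to_csv(path, sep="\t", index=False, lineterminator="\n")


def fetch_uniprot_sequence(accession: str, timeout: float = 15.0) -> ProteinRecord:
    """Fetch one canonical sequence from UniProt's REST endpoint.

    Requires network access; raises ``OSError`` when unreachable.
    """
    import io as _io
    import urllib.request

    url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    rec = next(SeqIO.parse(_io.StringIO(text), "fasta"))
    return ProteinRecord(
        accession=_parse_accession(rec.id),
        description=rec.description,
        sequence=str(rec.seq),
    )


def load_reference_protein(accession: str, search_paths: Iterable = ()) -> ProteinRecord:
    """Load a reference sequence from a local FASTA if present, else UniProt.

    ``search_paths`` are tried in order; the first readable FASTA whose first
    record matches ``accession`` wins.  Falls back to a network fetch and
    raises ``FileNotFoundError`` when neither source is available.
    """
    for p in search_paths:
        p = Path(p)
        if p.is_file():
            recs = read_fasta(p)
            for rec in recs:
                if rec.accession == accession:
                    return rec
    try:
        return fetch_uniprot_sequence(accession)
    except Exception as exc:
        raise FileNotFoundError(
            f"sequence {accession} not found locally ({list(map(str, search_paths))}) "
            f"and UniProt is unreachable: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# Run summaries
# ---------------------------------------------------------------------------


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_run_summary(summary: dict, path) -> None:
    """Write a machine-readable run summary (sorted keys, stable floats)."""
    with open(path, "w", newline="\n") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
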