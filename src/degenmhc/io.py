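"""Shared readers/writers: peptide lists, prediction tables, array archives."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AA_INDEX
from .data import inverse_log50k


def read_peptides(path: str | Path) -> list[str]:
    """Read peptides from FASTA or one-per-line text.

    FASTA is detected by a leading ``>``; peptides are uppercased and
    validated against the 20-letter alphabet, reporting the line of any
    failure.
    """
    path = Path(path)
    text = path.read_text()
    peptides: list[tuple[int, str]] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            peptides.append((0, str(rec.seq).upper()))
    else:
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if line:
                peptides.append((ln, line.upper()))
    out = []
    for ln, pep in peptides:
        for pos, ch in enumerate(pep):
            if ch not in AA_INDEX:
                where = f"line {ln}" if ln else f"record {len(out) + 1}"
                raise ValueError(f"{path}: invalid character {ch!r} at {where}, position {pos + 1}")
        out.append(pep)
    return out


def write_predictions(
    records: Sequence,
    ap_scores: Sequence[float] | None,
    ba_targets: Sequence[float] | None,
    path: str | Path,
) -> None:
    """Write a prediction CSV with AP probabilities and BA affinities.

    Columns: allele, peptide, ap_probability, ba_log50k, ba_ic50_nM; the
    IC50 column is derived from the target via the inverse log50k
    transform. Missing score vectors leave their columns empty.
    """
    n = len(records)
    for name, v in (("ap_scores", ap_scores), ("ba_targets", ba_targets)):
        if v is not None and len(v) != n:
            raise ValueError(f"{name} has length {len(v)}, expected {n}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["allele", "peptide", "ap_probability", "ba_log50k", "ba_ic50_nM"])
        for i, r in enumerate(records):
            ap = repr(float(ap_scores[i])) if ap_scores is not None else ""
            if ba_targets is not None:
                t = float(np.clip(ba_targets[i], 0.0, 1.0))
                ba, ic50 = repr(t), repr(inverse_log50k(t))
            else:
                ba, ic50 = "", ""
            w.writerow([r.allele_name, r.peptide, ap, ba, ic50])


def save_encodings(path: str | Path, arrays: dict[str, np.ndarray], index_csv: str | Path,
                   records: Sequence) -> None:
    """Portable array archive (.npz) plus an index CSV naming each record."""
    np.savez_compressed(path, **arrays)
    with open(index_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "allele", "peptide"])
        for key, r in zip(arrays, records):
            w.writerow([key, r.allele_name, r.peptide])
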