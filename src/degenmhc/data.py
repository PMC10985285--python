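"""Affinity/presentation records, label transforms, decoys and augmentation.

Binding-affinity data carry IC50 values (nM; lower = stronger binding)
which are mapped to the bounded regression target

    log50k(IC50) = 1 - log(IC50) / log(50000),  clipped to [0, 1],

so that 1 nM maps to 1 and 50,000 nM maps to 0. The conventional binder
threshold is IC50 < 500 nM (boundary itself labelled non-binder).

Mass-spectrometry (MS) presentation data are binary; for semi-supervised
pretraining they are converted to pseudo-affinity records by anchoring
positives and negatives at fixed IC50 values consistent with the binder
threshold. Random decoy peptides stand in for non-binders, retained only
when an affinity model predicts them weak (> 1000 nM by default).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, validate_peptide

LOG50K_MAX_NM = 50000.0
BINDER_THRESHOLD_NM = 500.0
DECOY_RETENTION_THRESHOLD_NM = 1000.0


def log50k(ic50: float) -> float:
    """Map an IC50 in nM to the [0, 1] regression target."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    t = 1.0 - math.log(ic50) / math.log(LOG50K_MAX_NM)
    return min(1.0, max(0.0, t))


def inverse_log50k(target: float) -> float:
    """Map a [0, 1] target back to an IC50 in nM."""
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target must be in [0, 1], got {target}")
    return LOG50K_MAX_NM ** (1.0 - target)


def binarize_affinity(ic50: float, threshold: float = BINDER_THRESHOLD_NM) -> int:
    """1 iff IC50 strictly below the binder threshold (500 nM)."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return 1 if ic50 < threshold else 0


@dataclass(frozen=True)
class AffinityRecord:
    allele_name: str
    peptide: str
    ic50: float
    source: str = "observed"

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50}")
        object.__setattr__(self, "peptide", validate_peptide(self.peptide))

    @property
    def target(self) -> float:
        return log50k(self.ic50)


@dataclass(frozen=True)
class PresentationRecord:
    allele_name: str
    peptide: str
    label: int
    source: str = "observed"  # observed | decoy | pseudo-labeled

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"presentation label must be 0 or 1, got {self.label}")
        object.__setattr__(self, "peptide", validate_peptide(self.peptide))


@dataclass(frozen=True)
class DecoyConfig:
    count: int
    length_weights: dict[int, float] = field(
        default_factory=lambda: {8: 0.25, 9: 0.25, 10: 0.25, 11: 0.25}
    )
    composition: dict[str, float] | None = None  # None = uniform over 20 aa
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("decoy count must be >= 1")
        if set(self.length_weights) - {8, 9, 10, 11} or not self.length_weights:
            raise ValueError("decoy lengths must come from {8, 9, 10, 11}")
        if any(w < 0 for w in self.length_weights.values()) or sum(self.length_weights.values()) <= 0:
            raise ValueError("length weights must be nonnegative and sum > 0")
        if self.composition is not None:
            if set(self.composition) - set(AMINO_ACIDS):
                raise ValueError("composition keys must be amino-acid letters")
            total = sum(self.composition.values())
            if any(w < 0 for w in self.composition.values()) or not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError("composition must be nonnegative and sum to 1")


def generate_decoys(cfg: DecoyConfig, exclude: Iterable[str] = ()) -> list[str]:
    """Sample random peptides i.i.d. per position from a composition.

    Peptides colliding with ``exclude`` (observed positives) are resampled.
    Deterministic for a fixed config (which includes the seed).
    """
    rng = np.random.default_rng(cfg.seed)
    probs = np.zeros(len(AMINO_ACIDS))
    if cfg.composition is None:
        probs[:] = 1.0 / len(AMINO_ACIDS)
    else:
        for aa, w in cfg.composition.items():
            probs[AMINO_ACIDS.index(aa)] = w
    lengths = sorted(cfg.length_weights)
    lw = np.array([cfg.length_weights[k] for k in lengths], dtype=float)
    lw /= lw.sum()
    excluded = set(exclude)
    letters = np.array(list(AMINO_ACIDS))
    out: list[str] = []
    while len(out) < cfg.count:
        n = int(rng.choice(lengths, p=lw))
        pep = "".join(letters[rng.choice(len(letters), size=n, p=probs)])
        if pep in excluded:
            continue
        out.append(pep)
    return out


def label_decoys_by_model(
    decoys: Sequence[str],
    allele_name: str,
    ba_models: Sequence,
    threshold_nm: float = DECOY_RETENTION_THRESHOLD_NM,
) -> list[PresentationRecord]:
    """Keep decoys every provided affinity model agrees are weak binders.

    Each model must expose ``predict_ic50(allele_name, peptides) ->
    array of nM``. A decoy is retained iff its *strongest* prediction (the
    minimum IC50 over models — equivalently the maximum predicted target)
    still exceeds ``threshold_nm``; retained decoys become negatives.
    """
    if not ba_models:
        raise ValueError("at least one affinity model is required")
    preds = np.stack([np.asarray(m.predict_ic50(allele_name, list(decoys)), dtype=float)
                      for m in ba_models])
    weakest_claim = preds.min(axis=0)
    return [
        PresentationRecord(allele_name=allele_name, peptide=p, label=0, source="decoy")
        for p, ic50 in zip(decoys, weakest_claim)
        if ic50 > threshold_nm
    ]


def ms_to_affinity(
    records: Sequence[PresentationRecord],
    positive_anchor_nm: float = 100.0,
    negative_anchor_nm: float = 10000.0,
) -> list[AffinityRecord]:
    """Convert binary MS records to pseudo-labelled affinity records.

    Positives are anchored at a clear-binder IC50, negatives at a clear
    non-binder IC50; the anchors must sit on the correct sides of the
    500 nM binder boundary.
    """
    if binarize_affinity(positive_anchor_nm) != 1 or binarize_affinity(negative_anchor_nm) != 0:
        raise ValueError(
            f"anchors ({positive_anchor_nm}, {negative_anchor_nm}) nM are inconsistent "
            f"with the {BINDER_THRESHOLD_NM} nM binder boundary"
        )
    return [
        AffinityRecord(
            allele_name=r.allele_name,
            peptide=r.peptide,
            ic50=positive_anchor_nm if r.label == 1 else negative_anchor_nm,
            source="pseudo-labeled",
        )
        for r in records
    ]


def remove_overlap(train: Sequence, test: Sequence) -> list:
    """Drop train records whose (allele, peptide) key appears in test."""
    test_keys = {(r.allele_name, r.peptide) for r in test}
    kept = [r for r in train if (r.allele_name, r.peptide) not in test_keys]
    removed = len(train) - len(kept)
    if removed:
        import logging

        logging.getLogger(__name__).info("removed %d overlapping records", removed)
    return kept


# ---------------------------------------------------------------------------
# CSV io — columns fixed: allele,peptide,ic50_nM,target / allele,peptide,label,source

def write_affinity_csv(records: Sequence[AffinityRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["allele", "peptide", "ic50_nM", "target"])
        for r in records:
            w.writerow([r.allele_name, r.peptide, repr(r.ic50), repr(r.target)])


def read_affinity_csv(path: str | Path) -> list[AffinityRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(AffinityRecord(allele_name=row["allele"], peptide=row["peptide"],
                                      ic50=float(row["ic50_nM"])))
    return out


def write_presentation_csv(records: Sequence[PresentationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["allele", "peptide", "label", "source"])
        for r in records:
            w.writerow([r.allele_name, r.peptide, r.label, r.source])


def read_presentation_csv(path: str | Path) -> list[PresentationRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(PresentationRecord(allele_name=row["allele"], peptide=row["peptide"],
                                          label=int(row["label"]), source=row.get("source", "observed")))
    return out
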