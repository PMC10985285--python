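"""Model / Results objects wrapping the attention + ConvNeXt predictor.

Two estimators mirror the two prediction tasks:

* :class:`PresentationModel` — binary antigen-presentation (AP) from
  MS-style records, trained with cross-entropy;
* :class:`AffinityModel` — bounded log50k binding-affinity (BA)
  regression, trained with squared error, optionally warm-started from a
  fitted presentation model (transfer learning: the MS task pretrains the
  backbone, the affinity head is finetuned).

Both are built from record lists plus a per-allele contact-matrix library,
and ``fit()`` returns a :class:`FitResults` carrying the trained network,
training history, held-out diagnostics, provenance (data hash, seed,
config) and a ``summary()`` table. Simulation-scale defaults throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from typing import Sequence

import numpy as np

from .data import AffinityRecord, PresentationRecord, inverse_log50k
from .encoding import encode
from .evaluate import MetricsReport, evaluate_classification, evaluate_regression
from .nn.net import (
    ConvNeXtMHCNet,
    ModelConfig,
    fit_network,
    init_attention_weights,
    peptide_frequencies,
    transfer_weights,
)


def _records_hash(records: Sequence) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(repr((r.allele_name, r.peptide, getattr(r, "label", None),
                       getattr(r, "ic50", None))).encode())
    return h.hexdigest()[:16]


class _BaseMHCModel:
    """Shared plumbing: encoding, attention init, fit loop, provenance."""

    head: str
    loss: str

    def __init__(
        self,
        records: Sequence,
        contact_matrices: dict[str, np.ndarray],
        config: ModelConfig | None = None,
    ):
        if not records:
            raise ValueError("cannot build a model from zero records")
        missing = sorted({r.allele_name for r in records} - set(contact_matrices))
        if missing:
            raise ValueError(f"no contact matrix for alleles {missing}")
        self.records = list(records)
        self.contact_matrices = {k: np.asarray(v, dtype=float) for k, v in contact_matrices.items()}
        self.config = config or ModelConfig(head=self.head)
        if self.config.head != self.head:
            raise ValueError(f"config head {self.config.head!r} does not match model {self.head!r}")
        self.endog = self._targets(self.records)
        self.exog = np.stack([
            encode(r.peptide, self.contact_matrices[r.allele_name]) for r in self.records
        ]).astype(np.float32)
        self.attention_init = init_attention_weights(
            peptide_frequencies([r.peptide for r in self.records])
        )

    @classmethod
    def from_dataframe(cls, df, contact_matrices, config=None):
        """Build from a pandas DataFrame with the package's CSV columns."""
        records = [cls._record_from_row(row) for _, row in df.iterrows()]
        return cls(records, contact_matrices, config=config)

    def _targets(self, records) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _build_net(self, seed: int) -> ConvNeXtMHCNet:
        cfg = ModelConfig(**{**asdict(self.config), "seed": seed})
        cfg.stage_depths = tuple(cfg.stage_depths)
        cfg.stage_widths = tuple(cfg.stage_widths)
        cfg.dw_kernel = tuple(cfg.dw_kernel)
        return ConvNeXtMHCNet(cfg, attention_init=self.attention_init)

    def fit(
        self,
        seed: int | None = None,
        val_fraction: float = 0.15,
        epochs: int | None = None,
        net: ConvNeXtMHCNet | None = None,
    ) -> "FitResults":
        """Train the network and return a results object.

        A deterministic stratified-ish tail split of ``val_fraction``
        drives early stopping; pass ``net`` to continue training an
        existing network (e.g. a transferred backbone).
        """
        seed = self.config.seed if seed is None else seed
        net = net or self._build_net(seed)
        rng = np.random.default_rng(seed)
        n = len(self.records)
        order = rng.permutation(n)
        n_val = int(round(n * val_fraction))
        val_idx, train_idx = order[:n_val], order[n_val:]
        history = fit_network(
            net, self.exog[train_idx], self.endog[train_idx],
            self.exog[val_idx] if n_val else None,
            self.endog[val_idx] if n_val else None,
            loss=self.loss, seed=seed, epochs=epochs,
        )
        val_metrics = None
        if n_val:
            preds = net.predict(self.exog[val_idx])
            val_metrics = self._metrics(preds, self.endog[val_idx])
        return FitResults(
            model=self, net=net, history=history, seed=seed,
            val_metrics=val_metrics, data_hash=_records_hash(self.records),
        )

    def _metrics(self, preds, y) -> MetricsReport:  # pragma: no cover - abstract
        raise NotImplementedError


class PresentationModel(_BaseMHCModel):
    """Antigen-presentation (AP) classifier over peptide-allele pairs."""

    head = "ap"
    loss = "bce"

    @staticmethod
    def _record_from_row(row) -> PresentationRecord:
        return PresentationRecord(allele_name=row["allele"], peptide=row["peptide"],
                                  label=int(row["label"]), source=row.get("source", "observed"))

    def _targets(self, records) -> np.ndarray:
        return np.array([r.label for r in records], dtype=float)

    def _metrics(self, preds, y) -> MetricsReport:
        return evaluate_classification(preds, y.astype(int))


class AffinityModel(_BaseMHCModel):
    """Binding-affinity (BA) regressor on the log50k scale."""

    head = "ba"
    loss = "mse"

    @staticmethod
    def _record_from_row(row) -> AffinityRecord:
        return AffinityRecord(allele_name=row["allele"], peptide=row["peptide"],
                              ic50=float(row["ic50_nM"]))

    def _targets(self, records) -> np.ndarray:
        return np.array([r.target for r in records], dtype=float)

    def _metrics(self, preds, y) -> MetricsReport:
        return evaluate_regression(preds, y)

    def fit_from_pretrained(
        self, pretrained: "FitResults", seed: int | None = None,
        epochs: int | None = None, val_fraction: float = 0.15,
    ) -> "FitResults":
        """Finetune from a fitted presentation model's backbone."""
        net = transfer_weights(pretrained.net, target_head="ba")
        res = self.fit(seed=seed, epochs=epochs, val_fraction=val_fraction, net=net)
        res.transfer_source = pretrained.net.state_hash()
        return res


class FitResults:
    """Fitted state, history and diagnostics of an MHC model."""

    def __init__(self, model, net, history, seed, val_metrics, data_hash):
        self.model = model
        self.net = net
        self.history = history
        self.seed = seed
        self.val_metrics = val_metrics
        self.data_hash = data_hash
        self.transfer_source: str | None = None

    @property
    def n_params(self) -> int:
        return self.net.count_params()

    def predict(self, records: Sequence) -> np.ndarray:
        """Head outputs for new records: AP probability or BA log50k."""
        X = np.stack([
            encode(r.peptide, self.model.contact_matrices[r.allele_name]) for r in records
        ])
        return self.net.predict(X)

    def predict_pairs(self, allele_name: str, peptides: Sequence[str]) -> np.ndarray:
        mat = self.model.contact_matrices[allele_name]
        X = np.stack([encode(p, mat) for p in peptides])
        return self.net.predict(X)

    def predict_ic50(self, allele_name: str, peptides: Sequence[str]) -> np.ndarray:
        """Predicted IC50 in nM (BA models; AP probabilities are not affinities)."""
        targets = self.predict_pairs(allele_name, peptides)
        return np.array([inverse_log50k(float(t)) for t in np.clip(targets, 0.0, 1.0)])

    def attention_scores(self, records: Sequence) -> np.ndarray:
        """Learned per-amino-acid attention scores, shape (n_records, 20)."""
        X = np.stack([
            encode(r.peptide, self.model.contact_matrices[r.allele_name]) for r in records
        ])
        return self.net.attention.scores(X)

    def save(self, path) -> None:
        self.net.save(path, provenance={
            "seed": self.seed, "data_hash": self.data_hash,
            "transfer_source": self.transfer_source,
        })

    def summary(self) -> str:
        kind = "Presentation (AP)" if self.model.head == "ap" else "Affinity (BA)"
        lines = [
            f"{'=' * 58}",
            f"degenmhc {kind} model fit",
            f"{'-' * 58}",
            f"{'No. observations:':<28}{len(self.model.records):>10}",
            f"{'No. parameters:':<28}{self.n_params:>10}",
            f"{'Epochs run:':<28}{len(self.history['train_loss']):>10}",
            f"{'Seed:':<28}{self.seed:>10}",
            f"{'Data hash:':<28}{self.data_hash:>18}",
            f"{'State hash:':<28}{self.net.state_hash():>18}",
        ]
        if self.history["train_loss"]:
            lines.append(f"{'Final train loss:':<28}{self.history['train_loss'][-1]:>10.4f}")
        if self.history["val_loss"]:
            lines.append(f"{'Best val loss:':<28}{min(self.history['val_loss']):>10.4f}")
        if self.transfer_source:
            lines.append(f"{'Transfer source:':<28}{self.transfer_source:>18}")
        if self.val_metrics is not None:
            lines.append("-" * 58)
            for k, v in self.val_metrics.as_dict().items():
                if isinstance(v, float):
                    lines.append(f"{'val ' + k + ':':<28}{v:>10.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training-curve plot; returns the matplotlib axes."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["train_loss"], label="train")
        if self.history["val_loss"]:
            ax.plot(self.history["val_loss"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel(self.history["loss"] + " loss")
        ax.legend()
        return ax
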