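"""High-level Model / Results interface.

:class:`AffinityChangeModel` bundles a labelled record set with an embedder
spec and an architecture config; ``fit()`` runs the training engine and
returns an :class:`AffinityChangeResults` carrying the fitted parameters,
the training history, prediction / evaluation / interpretation methods and a
``summary()`` table.

    >>> records, _ = generate(SynthConfig(rng_seed=7))
    >>> model = AffinityChangeModel(records, config=AttentionConfig(d_model=32,
    ...                                                             n_heads=2))
    >>> results = model.fit(TrainConfig(learning_rate=1e-3, max_epochs=40))
    >>> print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ComplexRecord, FormatSpec, read_dataset
from .embedding import EmbedderSpec, EmbeddingCache
from .interpret import AttentionMap, attention_maps_from_state
from .model_core import AttentionConfig, AttentionState, ModelParameters, forward
from .training_eval import (
    EvalReport,
    TrainConfig,
    compute_metrics,
    predict_records,
    train,
)


class AffinityChangeModel:
    """Sequence-only ddG regressor over a labelled antibody-antigen dataset."""

    def __init__(
        self,
        records: list[ComplexRecord],
        embedder_spec: EmbedderSpec = EmbedderSpec(),
        config: AttentionConfig = AttentionConfig(),
        cache: EmbeddingCache | None = None,
    ):
        if not records:
            raise ValueError("cannot build a model from an empty record list")
        self.records = list(records)
        self.embedder_spec = embedder_spec
        self.config = config
        self.cache = cache if cache is not None else EmbeddingCache()

    @classmethod
    def from_csv(
        cls,
        path,
        format_spec: FormatSpec = FormatSpec(),
        **kwargs,
    ) -> "AffinityChangeModel":
        """Build from a dataset CSV; rejected rows raise if any are present."""
        result = read_dataset(path, format_spec)
        if result.rejections:
            raise ValueError(
                f"{len(result.rejections)} row(s) rejected:\n"
                + result.rejection_report()
            )
        return cls(result.records, **kwargs)

    def fit(
        self,
        train_config: TrainConfig = TrainConfig(),
        validation_records: list[ComplexRecord] | None = None,
    ) -> "AffinityChangeResults":
        params, history = train(
            self.records,
            self.embedder_spec,
            self.config,
            train_config,
            validation_records=validation_records,
            cache=self.cache,
        )
        return AffinityChangeResults(self, params, history, train_config)


@dataclass
class AffinityChangeResults:
    """Fitted parameters plus diagnostics for an AffinityChangeModel."""

    model: AffinityChangeModel
    params: ModelParameters
    history: list[dict]
    train_config: TrainConfig

    def predict(self, records: list[ComplexRecord]) -> np.ndarray:
        return predict_records(
            self.params, records, self.model.embedder_spec, cache=self.model.cache
        )

    def evaluate(self, records: list[ComplexRecord]) -> EvalReport:
        preds = self.predict(records)
        y = np.array([r.ddg_label for r in records])
        report = EvalReport()
        report.folds.append(compute_metrics(y, preds))
        return report

    def attention_state(self, record: ComplexRecord) -> AttentionState:
        _, state = forward(
            record, self.model.embedder_spec, self.params,
            cache=self.model.cache, capture=True,
        )
        return state

    def attention_maps(self, record: ComplexRecord) -> dict[tuple, AttentionMap]:
        return attention_maps_from_state(self.attention_state(record), record)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def summary(self) -> str:
        """Plain-text fit summary (training-set metrics, sizes, stopping)."""
        fit_report = self.evaluate(self.model.records)
        agg = fit_report.aggregate()
        cfg = self.model.config
        last = self.history[-1] if self.history else {}
        best_val = min((h["val_mse"] for h in self.history), default=float("nan"))
        lines = [
            "Affinity-change regression (dual cross-attention, frozen embedder)",
            "=" * 66,
            f"records: {len(self.model.records):>6d}    "
            f"embedder: {self.model.embedder_spec.kind} (d={self.model.embedder_spec.d})",
            f"d_model: {cfg.d_model:>6d}    heads: {cfg.n_heads}   "
            f"variant: {cfg.variant}",
            f"parameters: {self.params.n_params():>6d}  "
            f"(interaction block: {self.params.interaction_param_count()})",
            f"epochs run: {len(self.history):>4d}    best val MSE: {best_val:.4f}    "
            f"final train MSE: {last.get('train_mse', float('nan')):.4f}",
            "-" * 66,
            "training-set fit:",
        ]
        for key, (m, s) in agg.items():
            lines.append(f"  {key:9s} {m: .4f}")
        return "\n".join(lines)
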