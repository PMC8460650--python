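"""Canonical desk-scale experiment protocols.

These functions pin the study conditions used by the package's own
validation experiments so tests, scripts and documentation all run the same
protocol:

* the *strong-signal fixture* — 150 lncRNAs x 20 proteins with
  match/mismatch interaction probabilities 0.6 / 0.02 and no label noise —
  on which the pipeline must recover the planted compatibility structure;
* the *null fixture* — identical except match = mismatch at the strong
  fixture's overall density (0.165), so the two differ only in signal — on
  which cross-validated AUC must stay near chance (a calibration guard
  against information leaking from training to test);
* a desk-scale pipeline configuration (shorter protein padding, a 32-wide
  embedding and a depth cap of 2) sized so a full repeated-CV experiment
  runs in minutes on one CPU while exercising every stage of the method.
"""

from __future__ import annotations

from lpidf.cascade_forest import CascadeConfig
from lpidf.evaluation import PipelineConfig
from lpidf.features_protein import EncoderSpec
from lpidf.synthetic_data import SyntheticSpec

#: overall interaction density of the strong fixture's class mixture:
#: 0.25 * 0.6 + 0.75 * 0.02
NULL_DENSITY = 0.165


def strong_fixture_spec(seed: int = 0) -> SyntheticSpec:
    """The learnable planted-signal dataset (the generator defaults)."""
    return SyntheticSpec(seed=seed)


def null_fixture_spec(seed: int = 0) -> SyntheticSpec:
    """Signal-free control: match = mismatch at the strong fixture's density."""
    return SyntheticSpec(
        seed=seed,
        interaction_prob_match=NULL_DENSITY,
        interaction_prob_mismatch=NULL_DENSITY,
    )


def desk_pipeline(seed: int = 0, n_folds: int = 5) -> PipelineConfig:
    """Desk-scale pipeline configuration for the fixture experiments."""
    return PipelineConfig(
        encoder=EncoderSpec(input_length=256, embedding_dim=32, epochs=50, seed=seed),
        cascade=CascadeConfig(max_layers=2, seed=seed),
        n_folds=n_folds,
        base_seed=seed,
    )


def reference_pipeline(seed: int = 0) -> PipelineConfig:
    """Full-size configuration: 256 k-mer + 544 embedding = 800-dim input."""
    return PipelineConfig(
        encoder=EncoderSpec(input_length=1024, embedding_dim=544, seed=seed),
        cascade=CascadeConfig(seed=seed),
        base_seed=seed,
    )
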