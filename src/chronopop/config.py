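"""YAML configuration for the model, the experiment design, and data loading.

A config file is a mapping with up to three optional sections::

    model:            # DurationChannelModel constructor parameters
      window_shape: raised_cosine
      adapt_strength: 0.8
      filter_params: {tau_exc_ms: 8.0}
    design:           # ExperimentDesign field overrides
      min_reps: 25
    column_map:       # file column -> canonical trial-table column
      subject: participant
      resp: response

Unknown keys are rejected so typos do not silently fall back to defaults.
"""

from __future__ import annotations

import yaml

from chronopop.channels import DurationChannelModel
from chronopop.stimuli import ExperimentDesign


def load_config(path) -> dict:
    """Read a YAML config file into a dict (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(cfg).__name__}")
    return cfg


def model_from_config(cfg: dict | None = None) -> DurationChannelModel:
    """Build a (unfitted) model from the ``model`` section of a config."""
    section = dict((cfg or {}).get("model", {}))
    model = DurationChannelModel()
    known = set(model.get_params())
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown model parameters in config: {sorted(unknown)}")
    model.set_params(**section)
    return model


def design_from_config(cfg: dict | None = None) -> ExperimentDesign:
    """Build an experiment design from the ``design`` section of a config."""
    section = dict((cfg or {}).get("design", {}))
    fields = set(ExperimentDesign.__dataclass_fields__)
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown design fields in config: {sorted(unknown)}")
    for key in ("standards_ms", "comparison_fractions", "adaptor_tf_hz"):
        if key in section:
            section[key] = tuple(section[key])
    return ExperimentDesign(**section)


def column_map_from_config(cfg: dict | None = None) -> dict | None:
    """The ``column_map`` section (``{file column: canonical column}``)."""
    section = (cfg or {}).get("column_map")
    if section is None:
        return None
    if not isinstance(section, dict):
        raise ValueError("column_map must be a mapping")
    return {str(k): str(v) for k, v in section.items()}
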