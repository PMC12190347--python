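"""Configuration defaults and YAML loading.

Every threshold and hyperparameter the pipeline uses is collected here so a
single YAML file can override them; unspecified keys fall back to the
defaults below.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "preprocess": {
        "twofold_log2": 1.0,      # |log2fc| threshold of the two-fold rule
        "prefold": 1.5,           # fold threshold at pre-resection samples
        "min_consecutive": 2,     # consecutive post-op points required
        "per_patient": False,     # rule on per-patient profiles vs the mean
    },
    "coexpress": {
        "K": 15,
        "min_module_size": 30,
        "cut_quantile": 0.99,
        "r2_target": 0.8,
        "som_epochs": 40,
    },
    "liverode": {
        "params": {},             # OdeParams field overrides
        "rtol": 1e-8,
        "atol": 1e-10,
    },
    "neuralmap": {
        "learning_rate": 1e-3,
        "epochs": 2000,
        "batch_size": None,       # full batch
        "dropout_p": 0.2,
        "include_fraction": True,
    },
    "synth": {
        "n_patients": 12,
        "K": 15,
        "genes_per_cluster": 40,
        "noise_sd": 0.1,
        "f_range": [0.5, 0.7],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    text = Path(path).read_text()
    override = yaml.safe_load(text) or {}
    if not isinstance(override, dict):
        raise ValueError("config file must contain a mapping")
    return _merge(DEFAULTS, override)
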