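"""Package-wide default configuration.

Defaults live in ``data/defaults.yaml`` and are exposed as a nested dict.
Call :func:`get_defaults` for a fresh deep copy that is safe to mutate.
"""

from __future__ import annotations

import copy
from importlib import resources

import yaml

_DEFAULTS: dict | None = None


def _load() -> dict:
    global _DEFAULTS
    if _DEFAULTS is None:
        text = resources.files("ferroscan.data").joinpath("defaults.yaml").read_text()
        _DEFAULTS = yaml.safe_load(text)
    return _DEFAULTS


def get_defaults() -> dict:
    """Return a deep copy of the default configuration tree."""
    return copy.deepcopy(_load())


def get_default(*keys):
    """Look up a single default, e.g. ``get_default("homology", "evalue_cutoff")``."""
    node = _load()
    for k in keys:
        node = node[k]
    return node
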