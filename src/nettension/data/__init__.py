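"""Bundled reference parameter sets and solution archives.

All fixtures here were produced by this package itself (tight-tolerance
integration plus the adaptive-walk search) and are stored as plain JSON
and CSV so they are diffable and language-portable.
"""

import json
from importlib import resources


def _read_text(filename: str) -> str:
    return resources.files(__name__).joinpath(filename).read_text()


def reference_params(name: str) -> dict:
    """Loads a bundled parameter set, e.g. ``reference_bistable``."""
    payload = json.loads(_read_text(f"{name}.json"))
    return {k: float(v) for k, v in payload["params"].items()}


def reference_meta(name: str) -> dict:
    """Full JSON payload (params plus stored reference values)."""
    return json.loads(_read_text(f"{name}.json"))


def archive_path(name: str):
    """Filesystem path of a bundled solution archive CSV."""
    return resources.files(__name__).joinpath(f"{name}.csv")
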