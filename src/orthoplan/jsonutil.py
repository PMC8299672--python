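"""Diff-stable JSON serialization: floats rounded to 9 significant
digits so identical runs produce byte-identical reports."""
from __future__ import annotations

import json
from pathlib import Path


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.9g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def dumps_json(obj) -> str:
    return json.dumps(_round_floats(obj), indent=2, sort_keys=True)


def dump_json(obj, path) -> None:
    Path(path).write_text(dumps_json(obj) + "\n")
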