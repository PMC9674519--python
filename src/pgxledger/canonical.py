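"""Canonical JSON serialization.

Every digest, signature and state comparison in the simulator is taken over
the canonical form produced here: key-sorted, minimal-separator, UTF-8 JSON.
Two structurally equal documents always serialize to identical bytes, which
is what makes content digests and replay equality well-defined.
"""

from __future__ import annotations

import json
from typing import Any

_JSON_SCALARS = (str, int, float, bool, type(None))


def _check(obj: Any, path: str = "$") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            if not isinstance(k, str):
                raise TypeError(f"non-string key at {path}: {k!r}")
            _check(v, f"{path}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check(v, f"{path}[{i}]")
    elif isinstance(obj, float):
        # floats round-trip ambiguously across platforms; the ledger only
        # carries ints and strings, so reject rather than risk divergence
        raise TypeError(f"float not allowed in canonical documents at {path}")
    elif not isinstance(obj, _JSON_SCALARS):
        raise TypeError(f"non-JSON value at {path}: {type(obj).__name__}")


def canonical_bytes(obj: Any) -> bytes:
    """Serialize *obj* to canonical JSON bytes (sorted keys, no whitespace)."""
    _check(obj)
    return json.dumps(
        obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False
    ).encode("utf-8")


def canonical_str(obj: Any) -> str:
    return canonical_bytes(obj).decode("utf-8")
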