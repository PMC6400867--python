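"""Stamped artifact I/O.

Every CSV the pipeline writes starts with a single comment line carrying
the config hash and seed; readers verify the stamp so artifacts produced
under different configurations refuse to be combined.  All tables are
UTF-8, comma-separated, decimal point.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ArtifactMismatchError

STAMP_PREFIX = "# stresscomp"


def _canonicalize(obj):
    """JSON-safe rendering: mapping keys become strings, sets/tuples lists."""
    if isinstance(obj, dict):
        return {str(k): _canonicalize(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple, set)):
        return [_canonicalize(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a canonical-JSON rendering of the config."""
    canonical = json.dumps(_canonicalize(config_dict), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, cfg_hash: str, seed: int) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{STAMP_PREFIX} config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_stamp(path) -> Optional[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first.startswith(STAMP_PREFIX):
        return None
    fields = dict(
        kv.split("=", 1) for kv in first[len(STAMP_PREFIX) :].split() if "=" in kv
    )
    return fields


def read_table(path, expect_hash: Optional[str] = None) -> pd.DataFrame:
    """Read a (possibly stamped) CSV, verifying the hash when asked."""
    stamp = read_stamp(path)
    if expect_hash is not None:
        if stamp is None:
            raise ArtifactMismatchError(f"{path}: missing artifact stamp")
        if stamp.get("config_hash") != expect_hash:
            raise ArtifactMismatchError(
                f"{path}: config_hash {stamp.get('config_hash')} != expected {expect_hash}"
            )
    return pd.read_csv(path, comment="#")
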