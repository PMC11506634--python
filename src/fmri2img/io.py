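"""Checkpoint and training-log helpers (npz weights + YAML metadata)."""

from __future__ import annotations

import csv
import os

import numpy as np
import yaml


def save_checkpoint(path: str, state: dict, meta: dict | None = None) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    arrays = {f"w::{k}": v for k, v in state.items()}
    arrays["__meta__"] = np.frombuffer(
        yaml.safe_dump(meta or {}).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> tuple[dict, dict]:
    with np.load(path if path.endswith(".npz") else path + ".npz") as f:
        meta = yaml.safe_load(bytes(f["__meta__"]).decode("utf-8"))
        state = {k[3:]: f[k] for k in f.files if k.startswith("w::")}
    return state, meta


def write_log_csv(path: str, rows: list[dict]) -> None:
    if not rows:
        return
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def state_checksum(state: dict) -> float:
    """Cheap content checksum for frozen-parameter assertions."""
    return float(sum(np.abs(v).sum() for v in state.values()))
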