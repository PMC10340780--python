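"""Deterministic single-file checkpoints.

Format: an ASCII magic line, an 8-byte big-endian header length, a JSON
header (sorted keys — no timestamps, so identical states produce identical
bytes), then the raw little-endian parameter buffers concatenated in header
order.  The header embeds the architecture id, the task, and arbitrary JSON
metadata such as a config hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..errors import ArchMismatchError, ConfigurationError
from .models import EncoderState, ModelBundle, build_classifier, build_segmenter

MAGIC = b"PSLCKPT1\n"


def _write(path, arch_id: str, task: str, state: dict[str, np.ndarray], meta: dict) -> None:
    entries = []
    buffers = []
    for name in sorted(state):
        arr = np.ascontiguousarray(state[name])
        le = arr.astype(arr.dtype.newbyteorder("<"), copy=False)
        entries.append({"name": name, "dtype": str(arr.dtype), "shape": list(arr.shape)})
        buffers.append(le.tobytes())
    header = json.dumps(
        {"arch_id": arch_id, "task": task, "meta": meta, "params": entries},
        sort_keys=True,
    ).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(len(header).to_bytes(8, "big"))
        fh.write(header)
        for b in buffers:
            fh.write(b)


def _read(path):
    with open(path, "rb") as fh:
        if fh.read(len(MAGIC)) != MAGIC:
            raise ConfigurationError(f"{path} is not a pslearn checkpoint")
        n = int.from_bytes(fh.read(8), "big")
        header = json.loads(fh.read(n).decode())
        state = {}
        for e in header["params"]:
            dt = np.dtype(e["dtype"]).newbyteorder("<")
            count = int(np.prod(e["shape"])) if e["shape"] else 1
            buf = fh.read(dt.itemsize * count)
            state[e["name"]] = (
                np.frombuffer(buf, dtype=dt).reshape(e["shape"]).astype(e["dtype"])
            )
    return header, state


def save_checkpoint(path, bundle: ModelBundle, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    if bundle.n_classes is not None:
        meta.setdefault("n_classes", bundle.n_classes)
    _write(path, bundle.arch_id, bundle.task, bundle.get_state(), meta)


def save_encoder_state(path, state: EncoderState, meta: dict | None = None) -> None:
    _write(path, state.arch_id, "encoder", state.params, dict(meta or {}))


def load_checkpoint(path) -> tuple[str, str, dict[str, np.ndarray], dict]:
    header, state = _read(path)
    return header["arch_id"], header["task"], state, header["meta"]


def load_encoder_state(path) -> EncoderState:
    header, state = _read(path)
    if header["task"] != "encoder":
        # a full bundle also carries an encoder; accept and strip the prefix
        state = {
            k.removeprefix("encoder."): v for k, v in state.items() if k.startswith("encoder.")
        }
        if not state:
            raise ArchMismatchError(f"{path} holds no encoder parameters")
    return EncoderState(header["arch_id"], state)


def load_model(path) -> ModelBundle:
    """Rebuild a full bundle from a checkpoint file."""
    arch_id, task, state, meta = load_checkpoint(Path(path))
    if task == "segmentation":
        bundle = build_segmenter(arch_id)
    elif task == "classification":
        bundle = build_classifier(arch_id, n_classes=int(meta.get("n_classes", 2)))
    else:
        raise ConfigurationError(f"checkpoint task {task!r} is not a full model")
    bundle.set_state(state)
    if meta.get("class_names"):
        bundle.class_names = tuple(meta["class_names"])
    return bundle
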