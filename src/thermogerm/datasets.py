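"""Packaged fixtures: transcribed germination tables, synthetic replicate
files consistent with them, and the transcribed fitted equations."""

from __future__ import annotations

from importlib.resources import files

from .germdata import GerminationMatrix, ReplicateRecord, read_matrix, read_replicates

__all__ = [
    "CULTIVARS",
    "load_matrix",
    "load_all_matrices",
    "load_replicates",
    "load_printed_equations",
]

CULTIVARS = ("c_dactylon", "savannah", "princess_vii")

_LABELS = {
    "c_dactylon": "C. dactylon",
    "savannah": "Savannah",
    "princess_vii": "Princess VII",
}


def _data(name: str):
    return str(files("thermogerm.data") / name)


def _key(cultivar: str) -> str:
    key = cultivar.lower().replace(" ", "_").replace(".", "").replace("__", "_")
    key = {"c_dactylon": "c_dactylon", "savannah": "savannah",
           "princess_vii": "princess_vii"}.get(key, key)
    if key not in CULTIVARS:
        raise ValueError(f"unknown cultivar {cultivar!r}; expected one of {CULTIVARS}")
    return key


def load_matrix(cultivar: str) -> GerminationMatrix:
    """Transcribed mean ± half-CI germination matrix for one cultivar."""
    return read_matrix(_data(f"matrix_{_key(cultivar)}.csv"))


def load_all_matrices() -> dict[str, GerminationMatrix]:
    return {_LABELS[k]: load_matrix(k) for k in CULTIVARS}


def load_replicates(cultivar: str) -> list[ReplicateRecord]:
    """Synthetic replicate-level counts consistent with the matrix means."""
    return read_replicates(_data(f"replicates_{_key(cultivar)}.csv"))


def load_printed_equations():
    """The nine transcribed fitted equations with calibrated metadata."""
    from .surface import load_printed_equations as _load

    return _load()
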