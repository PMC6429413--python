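"""NMD file export/import (VMD Normal Mode Wizard porcupine format).

An NMD file carries a title, per-atom metadata, reference coordinates and
one ``mode`` line per vector: ``mode <index> <scale> <3N components>``.
The Normal Mode Wizard draws each mode as per-atom arrows anchored at the
coordinates (porcupine plot).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParseError
from .structio import Structure

__all__ = ["write_nmd", "read_nmd"]


def write_nmd(
    path,
    title: str,
    coordinates: np.ndarray,
    modes: list[tuple[int, float, np.ndarray]],
    structure: Structure | None = None,
) -> None:
    """Write modes as an NMD file.

    ``modes`` is a list of ``(mode_number, scale, vector)`` with the vector
    of shape (N, 3) or (3N,).  ``scale`` is the amplitude prefactor the
    viewer applies (conventionally 1/sqrt(eigenvalue) for normal modes,
    sqrt(eigenvalue) for principal components, so arrow length tracks the
    motion's thermal or observed amplitude).
    """
    coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    n = coordinates.shape[0]
    lines = [f"name {title}"]
    if structure is not None:
        if structure.n_atoms != n:
            raise ValueError("structure and coordinates disagree on atom count")
        lines.append("atomnames " + " ".join(structure.annotation("name")))
        lines.append("resnames " + " ".join(structure.annotation("residue_name")))
        lines.append("resids " + " ".join(str(i) for i in structure.annotation("residue_index")))
        lines.append("chainids " + " ".join(structure.annotation("chain_id")))
    lines.append("coordinates " + " ".join(f"{x:.6f}" for x in coordinates.ravel()))
    for number, scale, vec in modes:
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != 3 * n:
            raise ValueError(f"mode {number}: vector length {vec.size} != 3N={3 * n}")
        comps = " ".join(f"{x:.10g}" for x in vec)
        lines.append(f"mode {int(number)} {scale:.10g} {comps}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_nmd(path) -> dict:
    """Parse an NMD file back into coordinates and (number, scale, vector) modes."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    out: dict = {"name": "", "coordinates": None, "modes": []}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        key, _, rest = line.partition(" ")
        if key == "name":
            out["name"] = rest
        elif key == "coordinates":
            out["coordinates"] = np.array(rest.split(), dtype=float).reshape(-1, 3)
        elif key == "mode":
            fields = rest.split()
            number = int(fields[0])
            scale = float(fields[1])
            vec = np.array(fields[2:], dtype=float).reshape(-1, 3)
            out["modes"].append((number, scale, vec))
        elif key in ("atomnames", "resnames", "resids", "chainids"):
            out[key] = rest.split()
    if out["coordinates"] is None:
        raise ParseError(f"{path}: no coordinates line")
    return out
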