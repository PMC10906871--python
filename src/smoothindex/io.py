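"""Reading and writing connectivity matrices and permutations.

Two plain-text formats are supported:

* **delimited** — one matrix row per line, comma / tab / whitespace
  separated (autodetected on read); ``#`` lines are comments.
* **matrix-market** — the standard coordinate or array ``.mtx`` format
  via :mod:`scipy.io`.

Matrix orientation is row = postsynaptic, column = presynaptic; every
file written by this module states that in a header comment, because a
silent transpose is the most dangerous failure mode when exchanging
connectome matrices.  Indices in permutation files are 0-based, one per
line.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.io
import scipy.sparse

from .costs import as_matrix
from .exceptions import MatrixFormatError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_permutation",
    "write_permutation",
    "is_binary",
]

_ORIENTATION = "rows = postsynaptic, columns = presynaptic"


def is_binary(M) -> bool:
    """True when every entry is 0 or 1 (an unweighted adjacency matrix)."""
    A = np.asarray(M)
    return bool(np.all((A == 0) | (A == 1)))


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("delimited", "matrix-market"):
            raise MatrixFormatError(f"unknown format {fmt!r}")
        return fmt
    return "matrix-market" if path.suffix.lower() in (".mtx", ".mm") else "delimited"


def _read_delimited(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "%")):
                continue
            for sep in (",", "\t", None):
                parts = line.split(sep)
                if len(parts) > 1 or sep is None:
                    break
            try:
                rows.append([float(p) for p in parts if p != ""])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise MatrixFormatError(f"{path}: no data rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MatrixFormatError(f"{path}: ragged rows, lengths {sorted(lengths)}")
    A = np.array(rows, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise MatrixFormatError(f"{path}: matrix is not square, shape {A.shape}")
    return A


def read_matrix(path, fmt: Optional[str] = None) -> np.ndarray:
    """Read a square connectivity matrix from a text file.

    ``fmt`` is ``"delimited"`` or ``"matrix-market"``; by default it is
    inferred from the extension (``.mtx`` / ``.mm`` -> Matrix Market).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-market":
        try:
            A = scipy.io.mmread(path)
        except Exception as exc:
            raise MatrixFormatError(f"{path}: not a readable Matrix Market file ({exc})") from None
        A = np.asarray(A.todense() if scipy.sparse.issparse(A) else A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise MatrixFormatError(f"{path}: matrix is not square, shape {A.shape}")
    else:
        A = _read_delimited(path)
    return as_matrix(A)


def write_matrix(M, path, fmt: Optional[str] = None, delimiter: str = ",") -> None:
    """Write a matrix; integer-valued matrices round-trip exactly."""
    A = as_matrix(M)
    path = Path(path)
    fmt = _infer_format(path, fmt)
    integral = np.all(A == np.round(A))
    if fmt == "matrix-market":
        comment = _ORIENTATION
        data = scipy.sparse.coo_matrix(A)
        scipy.io.mmwrite(path, data, comment=comment, field="integer" if integral else "real")
    else:
        buf = _io.StringIO()
        buf.write(f"# {_ORIENTATION}\n")
        np.savetxt(buf, A, fmt="%d" if integral else "%.17g", delimiter=delimiter)
        path.write_text(buf.getvalue())


def write_permutation(pi, path) -> None:
    """Write a permutation as one 0-based index per line."""
    pi = np.asarray(pi, dtype=int)
    lines = [f"# permutation, 0-based: row i of the reordered matrix is original vertex pi[i]"]
    lines += [str(int(v)) for v in pi]
    Path(path).write_text("\n".join(lines) + "\n")


def read_permutation(path) -> np.ndarray:
    """Read a permutation written by :func:`write_permutation`."""
    values = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        values.append(int(line))
    return np.asarray(values, dtype=np.intp)
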