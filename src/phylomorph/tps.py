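"""Thin-plate splines and the TPS landmark file format.

The 2D thin-plate spline with kernel U(r) = r^2 log r^2 interpolates a
deformation between two point configurations; it is used both to estimate
missing landmarks from a complete reference specimen and (through its
bending-energy matrix) as the objective for semilandmark sliding.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "tps_coefficients",
    "tps_warp",
    "bending_energy_matrix",
    "read_tps",
    "write_tps",
]


def _kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log(r^2), with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _design(src: np.ndarray):
    n = src.shape[0]
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=2)
    K = _kernel(d2)
    P = np.column_stack([np.ones(n), src])
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    return L


def tps_coefficients(src: np.ndarray, dst: np.ndarray):
    """Solve the interpolating spline mapping *src* points onto *dst*.

    Returns ``(W, A)``: kernel weights (n, 2) and affine part (3, 2).
    Raises on degenerate (collinear) source configurations.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to fit a thin-plate spline")
    # collinearity check on the affine design
    P = np.column_stack([np.ones(n), src])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise ValueError("source points are collinear; spline is degenerate")
    L = _design(src)
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    sol = np.linalg.solve(L, rhs)
    return sol[:n], sol[n:]


def tps_warp(src: np.ndarray, W: np.ndarray, A: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted spline at *points*."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = np.sum((points[:, None, :] - src[None, :, :]) ** 2, axis=2)
    U = _kernel(d2)
    return A[0] + points @ A[1:] + U @ W


def bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of the spline anchored at *ref* (n, 2).

    The quadratic form v' B v (per coordinate) measures the non-affine
    deformation energy of a displacement field v sampled at the reference
    points; B is the upper-left n-by-n block of the inverse spline design.
    """
    ref = np.asarray(ref, dtype=float)
    n = ref.shape[0]
    L = _design(ref)
    Linv = np.linalg.pinv(L)
    B = Linv[:n, :n]
    return (B + B.T) / 2.0


# ---------------------------------------------------------------------------
# TPS file dialect (LM=, IMAGE=, ID=, SCALE= records)
# ---------------------------------------------------------------------------


def read_tps(path) -> list:
    """Read specimens from a TPS landmark file.

    Returns a list of dicts with keys ``coords`` (n, 2 array; NaN rows for
    missing points coded as negative sentinel pairs are kept as NaN),
    ``image``, ``id`` and ``scale`` (applied to the coordinates when
    present).
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    specimens = []
    current = None
    n_expected = 0
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if current is not None:
                specimens.append(current)
            n_expected = int(line.split("=", 1)[1])
            current = {"coords": [], "image": None, "id": None, "scale": None}
        elif upper.startswith("IMAGE="):
            current["image"] = line.split("=", 1)[1]
        elif upper.startswith("ID="):
            current["id"] = line.split("=", 1)[1]
        elif upper.startswith("SCALE="):
            current["scale"] = float(line.split("=", 1)[1])
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"bad coordinate line in TPS file: {raw!r}")
            current["coords"].append([float(parts[0]), float(parts[1])])
    if current is not None:
        specimens.append(current)
    out = []
    for spec in specimens:
        coords = np.asarray(spec["coords"], dtype=float)
        if n_expected and coords.shape[0] != n_expected and len(specimens) == 1:
            raise ValueError("coordinate count does not match LM= record")
        # NegativeNegative sentinel (-1 -1 convention) marks missing points
        missing = np.all(coords == -1.0, axis=1)
        coords[missing] = np.nan
        if spec["scale"]:
            coords = coords * spec["scale"]
        out.append({"coords": coords, "image": spec["image"], "id": spec["id"],
                    "scale": spec["scale"]})
    return out


def write_tps(specimens, path) -> None:
    """Write specimens (dicts as from :func:`read_tps`) to a TPS file.

    Coordinates are written raw (no SCALE record), NaN points as the
    ``-1 -1`` missing sentinel.
    """
    def _fmt(x):
        return f"{x:.12g}"

    lines = []
    for spec in specimens:
        coords = np.asarray(spec["coords"], dtype=float)
        lines.append(f"LM={coords.shape[0]}")
        for pt in coords:
            if np.any(np.isnan(pt)):
                lines.append("-1 -1")
            else:
                lines.append(f"{_fmt(pt[0])} {_fmt(pt[1])}")
        if spec.get("image"):
            lines.append(f"IMAGE={spec['image']}")
        if spec.get("id") is not None:
            lines.append(f"ID={spec['id']}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
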