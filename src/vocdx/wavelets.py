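"""Periodized multilevel 2D discrete wavelet transform with the Daubechies
4-tap filter pair (2 vanishing moments).

The transform is strictly orthonormal: circular (periodized) convolution with
downsampling by two is applied along an axis only when that axis currently has
even length; an odd-length axis passes through a level untransformed. This
keeps the total coefficient count equal to the input size, makes the transform
energy-preserving to machine precision, and gives exact reconstruction at
every feasible level.

Band codes are two letters, first for the row axis, second for the column
axis: ``L`` = lowpass (or pass-through when the axis was not decomposed at
that level), ``H`` = highpass. A full 2D level produces LH, HL, HH detail
bands plus an LL approximation carried to the next level; a row-only level
produces a single HL detail band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_SQRT3 = np.sqrt(3.0)

#: Daubechies 4-tap analysis lowpass filter (orthonormal, 2 vanishing moments).
DEC_LO = np.array(
    [(1 + _SQRT3), (3 + _SQRT3), (3 - _SQRT3), (1 - _SQRT3)]
) / (4.0 * np.sqrt(2.0))

#: Conjugate quadrature highpass: g[m] = (-1)^m h[3-m].
DEC_HI = np.array([DEC_LO[3], -DEC_LO[2], DEC_LO[1], -DEC_LO[0]])

_BAND_ORDER = ("LH", "HL", "HH")


def _axis_transformable(length: int) -> bool:
    return length >= 2 and length % 2 == 0


def max_feasible_level(shape: tuple[int, int]) -> int:
    """Largest level count for which at least one axis decomposes each level."""
    rows, cols = shape
    level = 0
    while _axis_transformable(rows) or _axis_transformable(cols):
        if _axis_transformable(rows):
            rows //= 2
        if _axis_transformable(cols):
            cols //= 2
        level += 1
    return level


def _analysis_step(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis step along ``axis`` (length must be even)."""
    n = x.shape[axis]
    if not _axis_transformable(n):
        raise ValueError(f"axis length {n} not decomposable (must be even and >= 2)")
    lo = np.zeros_like(np.take(x, range(0, n, 2), axis=axis))
    hi = np.zeros_like(lo)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, None, 2)
    sl = tuple(sl)
    for m in range(4):
        shifted = np.roll(x, -m, axis=axis)[sl]  # x[(2k + m) mod n]
        lo = lo + DEC_LO[m] * shifted
        hi = hi + DEC_HI[m] * shifted
    return lo, hi


def _synthesis_step(lo: np.ndarray, hi: np.ndarray, axis: int) -> np.ndarray:
    """Inverse of :func:`_analysis_step`."""
    n = 2 * lo.shape[axis]
    up_shape = list(lo.shape)
    up_shape[axis] = n
    up_lo = np.zeros(up_shape, dtype=np.result_type(lo, hi))
    up_hi = np.zeros_like(up_lo)
    sl = [slice(None)] * lo.ndim
    sl[axis] = slice(0, None, 2)
    sl = tuple(sl)
    up_lo[sl] = lo
    up_hi[sl] = hi
    x = np.zeros_like(up_lo)
    for m in range(4):
        x = x + DEC_LO[m] * np.roll(up_lo, m, axis=axis)
        x = x + DEC_HI[m] * np.roll(up_hi, m, axis=axis)
    return x


@dataclass
class Wavedec2:
    """Multilevel 2D decomposition.

    ``details[l]`` holds the detail bands of level ``l+1`` keyed by band code;
    ``approx`` is the final LL band; ``axes[l]`` records which of (rows,
    columns) were decomposed at level ``l+1``.
    """

    shape: tuple[int, int]
    levels: int
    details: list[dict[str, np.ndarray]] = field(default_factory=list)
    approx: np.ndarray | None = None
    axes: list[tuple[bool, bool]] = field(default_factory=list)

    def coefficient_count(self) -> int:
        total = int(self.approx.size)
        for bands in self.details:
            total += sum(int(b.size) for b in bands.values())
        return total

    def energy(self) -> float:
        total = float(np.sum(self.approx.astype(float) ** 2))
        for bands in self.details:
            total += sum(float(np.sum(b.astype(float) ** 2)) for b in bands.values())
        return total


def wavedec2(x: np.ndarray, levels: int) -> Wavedec2:
    """Multilevel periodized 2D DWT of a 2D array.

    Raises ``ValueError`` when ``levels`` exceeds the maximum feasible depth
    for the input shape; the message states the maximum.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D array, got ndim={x.ndim}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    feasible = max_feasible_level(x.shape)
    if levels > feasible:
        raise ValueError(
            f"levels={levels} infeasible for shape {x.shape}; "
            f"max feasible level is {feasible}"
        )
    result = Wavedec2(shape=x.shape, levels=levels)
    approx = x
    for _ in range(levels):
        do_rows = _axis_transformable(approx.shape[0])
        do_cols = _axis_transformable(approx.shape[1])
        bands: dict[str, np.ndarray] = {}
        if do_rows:
            row_lo, row_hi = _analysis_step(approx, axis=0)
        else:
            row_lo, row_hi = approx, None
        if do_cols:
            ll, lh = _analysis_step(row_lo, axis=1)
            if row_hi is not None:
                hl, hh = _analysis_step(row_hi, axis=1)
                bands["HL"], bands["HH"] = hl, hh
            bands["LH"] = lh
        else:
            ll = row_lo
            if row_hi is not None:
                bands["HL"] = row_hi
        approx = ll
        result.details.append(bands)
        result.axes.append((do_rows, do_cols))
    result.approx = approx
    return result


def waverec2(dec: Wavedec2) -> np.ndarray:
    """Exact inverse of :func:`wavedec2`."""
    approx = dec.approx
    for bands, (did_rows, did_cols) in zip(dec.details[::-1], dec.axes[::-1]):
        if did_cols:
            row_lo = _synthesis_step(approx, bands["LH"], axis=1)
            if did_rows:
                row_hi = _synthesis_step(bands["HL"], bands["HH"], axis=1)
        else:
            row_lo = approx
            if did_rows:
                row_hi = bands["HL"]
        if did_rows:
            approx = _synthesis_step(row_lo, row_hi, axis=0)
        else:
            approx = row_lo
    return approx


def _band_names(level: int, code: str, shape: tuple[int, int]) -> list[str]:
    return [
        f"L{level}_{code}_{r}_{c}"
        for r in range(shape[0])
        for c in range(shape[1])
    ]


def flatten_coefficients(dec: Wavedec2, keep: str = "all_levels") -> tuple[list[str], np.ndarray]:
    """Flatten retained subbands into a deterministically ordered named vector.

    ``keep="all_levels"`` retains every detail band of every level plus the
    final approximation (a complete, non-redundant coefficient set whose
    length equals the input size). ``keep="coarsest_only"`` retains only the
    final level's approximation and detail bands. Ordering is a pure function
    of (shape, levels, keep): detail bands ascending by level in LH, HL, HH
    order, approximation last, each band row-major.
    """
    if keep not in ("all_levels", "coarsest_only"):
        raise ValueError(f"unknown keep mode: {keep!r}")
    names: list[str] = []
    chunks: list[np.ndarray] = []
    level_range = (
        range(1, dec.levels + 1) if keep == "all_levels" else [dec.levels]
    )
    for level in level_range:
        bands = dec.details[level - 1]
        for code in _BAND_ORDER:
            if code in bands:
                names.extend(_band_names(level, code, bands[code].shape))
                chunks.append(bands[code].ravel())
    names.extend(_band_names(dec.levels, "LL", dec.approx.shape))
    chunks.append(dec.approx.ravel())
    return names, np.concatenate(chunks)
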