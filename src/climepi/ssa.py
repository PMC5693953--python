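"""Singular Spectrum Analysis (SSA) of annual series.

SSA embeds a series in an M-dimensional lag space, eigendecomposes the
lag-covariance of the trajectory matrix, and recovers one "reconstructed
component" per eigenpair by diagonal averaging (Hankelization).  Because the
basis is data-adaptive, a multidecadal oscillation buried in noise typically
concentrates in the leading eigenpair(s), whose reconstruction is the
low-frequency component of the series.

Conventions (Broomhead–King): the lag-covariance is ``X^T X / K`` where X is
the K x M trajectory matrix of the mean-removed series and K = N - M + 1;
the sum of eigenvalues equals the trace of that matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import periodogram

from .exceptions import InvalidParameterError
from .series import AnnualSeries

DEFAULT_MAX_WINDOW = 80
DEFAULT_CUTOFF_PERIOD = 40.0


@dataclass
class SSADecomposition:
    """Full SSA eigen-decomposition of a series.

    ``eigenvectors[:, m]`` is the m-th orthonormal length-M basis vector,
    ``principal_components[:, m]`` the corresponding K scores, and
    ``reconstructed_components[m]`` the length-N series obtained from
    eigenpair m by diagonal averaging.  Eigenvalues are non-negative and
    descending.  Summing all M reconstructed components recovers the
    mean-removed input exactly.
    """

    years: np.ndarray
    mean: float
    window: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    principal_components: np.ndarray
    reconstructed_components: np.ndarray
    units: str = ""

    @property
    def n_points(self) -> int:
        return int(self.years.size)


def default_window(n: int) -> int:
    """M = min(floor(N/2), 80): large enough for a 60–80-yr period when the
    series allows, otherwise half the series."""
    return min(n // 2, DEFAULT_MAX_WINDOW)


def decompose(series: AnnualSeries, window: int | None = None) -> SSADecomposition:
    """SSA of the mean-removed series with embedding window ``window``."""
    x = series.values
    n = x.size
    m = default_window(n) if window is None else int(window)
    if not (2 <= m <= n // 2):
        raise InvalidParameterError(
            f"window must satisfy 2 <= M <= N/2 (N={n}), got {m}"
        )
    mean = float(x.mean())
    y = x - mean
    traj = sliding_window_view(y, m)  # (K, M), K = N - M + 1
    k = traj.shape[0]
    cov = traj.T @ traj / k
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for col in range(m):
        pivot = np.argmax(np.abs(eigvec[:, col]))
        if eigvec[pivot, col] < 0:
            eigvec[:, col] = -eigvec[:, col]
    pcs = traj @ eigvec  # (K, M)

    # diagonal averaging: RC_m is the full convolution of PC_m with EOF_m,
    # normalized by the number of antidiagonal terms at each position
    counts = np.convolve(np.ones(k), np.ones(m))  # length N
    rcs = np.empty((m, n), dtype=float)
    for comp in range(m):
        rcs[comp] = np.convolve(pcs[:, comp], eigvec[:, comp]) / counts

    return SSADecomposition(
        years=series.years.copy(),
        mean=mean,
        window=m,
        eigenvalues=eigval,
        eigenvectors=eigvec,
        principal_components=pcs,
        reconstructed_components=rcs,
        units=series.units,
    )


def reconstruct(
    decomp: SSADecomposition, component_indices: Sequence[int]
) -> AnnualSeries:
    """Sum of the selected reconstructed components plus the removed mean.

    Indices are 0-based; selecting all of ``range(M)`` returns the original
    series to numerical precision.
    """
    idx = np.asarray(list(component_indices), dtype=int)
    if idx.size == 0:
        raise InvalidParameterError("component selection must be non-empty")
    if idx.min() < 0 or idx.max() >= decomp.window:
        raise InvalidParameterError(
            f"component indices must lie in [0, {decomp.window - 1}]"
        )
    values = decomp.reconstructed_components[idx].sum(axis=0) + decomp.mean
    return AnnualSeries(decomp.years, values, units=decomp.units)


def lowfreq_indices(
    decomp: SSADecomposition, cutoff_period: float = DEFAULT_CUTOFF_PERIOD
) -> list[int]:
    """Indices of components whose periodogram peak is slower than ``cutoff_period``.

    The default 40-yr cutoff isolates the multidecadal (~60–80-yr) band from
    interannual variability.  Components with negligible variance are
    skipped; an empty selection is legitimate for a series with no
    low-frequency signal.
    """
    if cutoff_period <= 2.0:
        raise InvalidParameterError("cutoff_period must exceed 2 years (Nyquist)")
    f_cut = 1.0 / cutoff_period
    total = decomp.eigenvalues.sum()
    if total == 0.0:
        return []
    selected = []
    for m, rc in enumerate(decomp.reconstructed_components):
        if decomp.eigenvalues[m] <= 1e-12 * total:
            continue
        freqs, power = periodogram(rc, detrend=False)
        if freqs[np.argmax(power)] < f_cut:
            selected.append(m)
    return selected


def oscillatory_pairs(
    decomp: SSADecomposition, eigenvalue_tol: float = 0.1
) -> list[tuple[int, int]]:
    """Adjacent component pairs that look like one oscillation.

    A sinusoid splits across two eigenpairs with near-equal eigenvalues and
    principal components in near-quadrature; this standard heuristic pairs
    adjacent components whose eigenvalues differ by less than
    ``eigenvalue_tol`` (relatively) and whose dominant periodogram
    frequencies coincide to within one bin.
    """
    pairs: list[tuple[int, int]] = []
    used = -1
    for m in range(decomp.window - 1):
        if m <= used:
            continue
        lam1, lam2 = decomp.eigenvalues[m], decomp.eigenvalues[m + 1]
        if lam1 <= 0:
            break
        if (lam1 - lam2) / lam1 >= eigenvalue_tol:
            continue
        f1, p1 = periodogram(decomp.principal_components[:, m], detrend=False)
        f2, p2 = periodogram(decomp.principal_components[:, m + 1], detrend=False)
        i1, i2 = int(np.argmax(p1)), int(np.argmax(p2))
        if abs(i1 - i2) <= 1:
            pairs.append((m, m + 1))
            used = m + 1
    return pairs


def sign_change_years(series: AnnualSeries) -> list[int]:
    """Years where the series crosses zero (reported as the first year of
    the new sign)."""
    v = series.values
    years = series.years
    out = []
    for i in range(v.size - 1):
        if v[i] == 0.0:
            continue
        if v[i] * v[i + 1] < 0 or (v[i + 1] == 0.0 and v[i] != 0.0):
            out.append(int(years[i + 1]))
    return out
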