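"""Contact-matrix data model: masking, Knight–Ruiz balancing, O/E, correlation.

The central object is :class:`ContactMap`: one dense symmetric count matrix
per chromosome (intrachromosomal only), a per-bin exclusion mask, and —
after balancing — per-bin weights ``w`` such that ``diag(w) @ M @ diag(w)``
has unit row sums over unmasked bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import BinnedGenome


@dataclass
class BalanceReport:
    """Outcome of matrix balancing."""

    iterations: int
    max_rowsum_deviation: float
    converged: bool


@dataclass
class ContactMap:
    """Per-chromosome symmetric binned contact matrices.

    ``mask[chrom][i] == True`` means bin ``i`` is excluded from analysis.
    ``weights`` is ``None`` until :func:`kr_balance` has run; masked bins get
    NaN weights.
    """

    genome: BinnedGenome
    matrices: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    weights: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for chrom in self.genome.chrom_names:
            if chrom not in self.matrices:
                raise ValueError(f"missing matrix for {chrom}")
            m = np.asarray(self.matrices[chrom], dtype=float)
            n = self.genome.n_bins(chrom)
            if m.shape != (n, n):
                raise ValueError(f"{chrom}: matrix shape {m.shape} != ({n}, {n})")
            if not np.allclose(m, m.T):
                raise ValueError(f"{chrom}: matrix not symmetric")
            if (m < 0).any():
                raise ValueError(f"{chrom}: negative counts")
            self.matrices[chrom] = m
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(n, dtype=bool)

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def balanced(self, chrom: str) -> np.ndarray:
        """Balanced matrix for one chromosome; masked rows/cols are NaN."""
        if self.weights is None:
            raise ValueError("map is not balanced; run kr_balance first")
        w = self.weights[chrom]
        out = self.matrices[chrom] * np.outer(w, w)
        return out

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.genome,
            {c: m.copy() for c, m in self.matrices.items()},
            {c: m.copy() for c, m in self.mask.items()},
            None if self.weights is None else {c: w.copy() for c, w in self.weights.items()},
        )


def mask_low_coverage_bins(cmap: ContactMap, quantile: float = 0.02) -> ContactMap:
    """Mask zero-coverage bins and bins in the low tail of the marginal.

    Bins with an all-zero row are always masked.  Additionally, bins whose
    marginal (row sum) falls strictly below the given quantile of the
    nonzero marginals are masked.  Counts are untouched.
    """
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    out = cmap.copy()
    for chrom, m in out.matrices.items():
        marg = m.sum(axis=1)
        masked = marg == 0
        nonzero = marg[~masked]
        if quantile > 0 and nonzero.size:
            cutoff = np.quantile(nonzero, quantile)
            masked |= marg < cutoff
        out.mask[chrom] = out.mask[chrom] | masked
    out.weights = None
    return out


def _kr_core(A: np.ndarray, tol: float, max_outer: int) -> tuple[np.ndarray, int, bool]:
    """Knight–Ruiz inner–outer Newton iteration on a strictly balanceable matrix.

    Solves ``diag(x) A diag(x) 1 = 1``; returns (x, outer iterations, converged).
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt and outer < max_outer:
        outer += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 2 * n:  # inner stagnation guard
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x, outer, rout <= rt


def kr_balance(
    cmap: ContactMap,
    tol: float = 1e-6,
    max_iter: int = 300,
    on_fail: str = "raise",
) -> tuple[ContactMap, BalanceReport]:
    """Knight–Ruiz balancing of every chromosome's unmasked submatrix.

    Finds per-bin factors so the weighted matrix has unit row sums over
    unmasked bins, to within ``tol`` (max absolute row-sum deviation).
    Masked bins get NaN weights.

    ``on_fail`` controls non-convergence handling: ``"raise"`` or ``"warn"``.
    """
    if on_fail not in ("raise", "warn"):
        raise ValueError("on_fail must be 'raise' or 'warn'")
    out = cmap.copy()
    out.weights = {}
    worst_dev = 0.0
    worst_iter = 0
    all_converged = True
    for chrom, m in out.matrices.items():
        keep = ~out.mask[chrom]
        n = keep.sum()
        w_full = np.full(m.shape[0], np.nan)
        if n == 0:
            out.weights[chrom] = w_full
            continue
        sub = m[np.ix_(keep, keep)]
        marg = sub.sum(axis=1)
        if (marg <= 0).any():
            raise ValueError(
                f"{chrom}: unmasked bin with zero marginal; mask low-coverage bins first"
            )
        if n == 1:
            x = np.array([1.0 / np.sqrt(sub[0, 0])]) if sub[0, 0] > 0 else np.array([np.nan])
            iters, ok = 0, True
        else:
            # pre-scale improves conditioning; rescale of weights restores it
            scale = marg.mean()
            x, iters, ok = _kr_core(sub / scale, tol, max_iter)
            x = x / np.sqrt(scale)
        rowsum = x * (sub @ x)
        dev = float(np.abs(rowsum - 1.0).max()) if n else 0.0
        worst_dev = max(worst_dev, dev)
        worst_iter = max(worst_iter, iters)
        if not ok:
            all_converged = False
            msg = f"KR balancing did not converge on {chrom} (residual {dev:.3g})"
            if on_fail == "raise":
                raise RuntimeError(msg)
            warnings.warn(msg)
        w_full[keep] = x
        out.weights[chrom] = w_full
    return out, BalanceReport(worst_iter, worst_dev, all_converged)


def observed_over_expected(cmap: ContactMap) -> dict[str, np.ndarray]:
    """Divide each balanced entry by the mean unmasked entry at its distance.

    Returns one O/E matrix per chromosome.  Masked rows/columns and
    distances whose unmasked mean is zero are NaN.
    """
    if not cmap.is_balanced:
        raise ValueError("observed/expected requires a balanced map")
    out: dict[str, np.ndarray] = {}
    for chrom in cmap.genome.chrom_names:
        b = cmap.balanced(chrom)
        keep = ~cmap.mask[chrom]
        n = b.shape[0]
        oe = np.full_like(b, np.nan)
        valid = np.outer(keep, keep)
        for d in range(n):
            idx = (np.arange(n - d), np.arange(d, n))
            v = valid[idx]
            if not v.any():
                continue
            mean_d = b[idx][v].mean()
            if mean_d == 0:
                continue  # all-zero distance band stays NaN (flagged)
            band = np.where(v, b[idx] / mean_d, np.nan)
            oe[idx] = band
            if d > 0:
                oe[(idx[1], idx[0])] = band
        out[chrom] = oe
    return out


def correlation_matrix(oe: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between O/E rows over unmasked columns.

    NaN entries inside the unmasked block (all-zero distance bands) are
    treated as zero signal.  Constant rows yield NaN correlations.
    Output is full-size with NaN at masked rows/columns, symmetric, and has
    unit diagonal on defined entries.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    if mask is None:
        mask = np.all(np.isnan(oe), axis=0)
    keep = ~mask
    if keep.sum() < 2:
        raise ValueError("need at least 2 unmasked bins for a correlation matrix")
    sub = np.nan_to_num(oe[np.ix_(keep, keep)], nan=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant rows -> NaN
        c = np.corrcoef(sub)
    defined = sub.std(axis=1) > 0
    c[~defined, :] = np.nan
    c[:, ~defined] = np.nan
    c[defined, defined] = 1.0
    out = np.full((n, n), np.nan)
    out[np.ix_(keep, keep)] = c
    return out
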