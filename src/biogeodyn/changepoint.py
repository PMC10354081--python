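"""Piecewise-linear (segmented) regression with BIC model selection.

Change points in an MDE curve are estimated by Muggeo-style iterative
linearisation: given current breakpoints psi, the response is regressed on
{1, x, (x - psi_j)_+, I(x > psi_j)} and each breakpoint is moved by the
ratio of the gap coefficient (on the indicator) to the slope-difference
coefficient (on the hinge), until the update is below tolerance. Breakpoint
standard errors use the delta method on that ratio (a case-resampling
bootstrap is available as an alternative). The number of breakpoints is
chosen by fitting k = 1..4 from multiple starting configurations and
minimising BIC = n*ln(RSS/n) + p*ln(n) with p = 2 + 2k (intercept, base
slope, k slope changes, k breakpoint locations).

The surface follows the Model/Results idiom: ``SegmentedRegression(x, y,
n_breakpoints).fit()`` returns a :class:`SegmentedResults`;
:func:`select_changepoints` compares candidate k values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SegmentedRegression", "SegmentedResults", "fit_segmented",
           "select_changepoints"]

_MIN_GAP_FRAC = 1e-3  # minimum breakpoint separation, fraction of x range


class SegmentedRegression:
    """Piecewise-linear regression of y on x with k free breakpoints.

    x must be strictly monotone (ages are accepted in either direction and
    handled ascending internally); requires len(x) >= 2k + 4.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, n_breakpoints: int):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        dx = np.diff(x)
        if not ((dx > 0).all() or (dx < 0).all()):
            raise ValueError("x must be strictly monotone")
        if len(x) < 2 * n_breakpoints + 4:
            raise ValueError(
                f"need at least {2 * n_breakpoints + 4} points for "
                f"{n_breakpoints} breakpoints, got {len(x)}")
        order = np.argsort(x)
        self.x = x[order]
        self.y = y[order]
        self.k = int(n_breakpoints)

    # -- internals ---------------------------------------------------------

    def _design(self, psi: np.ndarray, with_gap: bool) -> np.ndarray:
        cols = [np.ones_like(self.x), self.x]
        for p in psi:
            cols.append(np.where(self.x > p, self.x - p, 0.0))
        if with_gap:
            for p in psi:
                cols.append((self.x > p).astype(float))
        return np.column_stack(cols)

    def _ols(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        beta, _, rank, _ = np.linalg.lstsq(X, self.y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError("collinear design matrix")
        resid = self.y - X @ beta
        return beta, float(resid @ resid)

    def _constrain(self, psi: np.ndarray) -> np.ndarray:
        lo, hi = self.x[1], self.x[-2]
        gap = max((self.x[-1] - self.x[0]) * _MIN_GAP_FRAC, 1e-12)
        psi = np.sort(np.clip(psi, lo, hi))
        for j in range(1, len(psi)):
            if psi[j] - psi[j - 1] < gap:
                psi[j] = min(psi[j - 1] + gap, hi)
        return psi

    def default_init(self) -> np.ndarray:
        qs = np.linspace(0, 1, self.k + 2)[1:-1]
        return np.quantile(self.x, qs)

    # -- fitting -----------------------------------------------------------

    def fit(self, init: np.ndarray | None = None, max_iter: int = 100,
            tol: float = 1e-6, ci_method: str = "delta",
            n_boot: int = 199, seed: int | None = None) -> "SegmentedResults":
        """Fit by iterative linearisation from ``init`` (default: k evenly
        spaced quantiles of x). Non-convergence is reported in the results,
        not raised."""
        if self.k == 0:
            X = self._design(np.empty(0), with_gap=False)
            beta, rss = self._ols(X)
            return self._results(np.empty(0), beta, rss, X, True, 0,
                                 ci_method, n_boot, seed)
        psi = self._constrain(np.asarray(init, dtype=float)
                              if init is not None else self.default_init())
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            X = self._design(psi, with_gap=True)
            try:
                beta, _ = self._ols(X)
            except np.linalg.LinAlgError:
                break
            slope_diff = beta[2:2 + self.k]
            gap = beta[2 + self.k:]
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(np.abs(slope_diff) > 1e-12,
                                gap / slope_diff, 0.0)
            # dampen late iterations to settle oscillating updates
            if it > 20:
                step = step * 0.5
            new_psi = self._constrain(psi - step)
            delta = np.max(np.abs(new_psi - psi))
            psi = new_psi
            if delta < tol:
                converged = True
                break
        X = self._design(psi, with_gap=False)
        beta, rss = self._ols(X)
        return self._results(psi, beta, rss, X, converged, it,
                             ci_method, n_boot, seed)

    def _results(self, psi, beta, rss, X, converged, it,
                 ci_method, n_boot, seed) -> "SegmentedResults":
        n, p = len(self.x), 2 + 2 * self.k
        if ci_method == "delta":
            ci = self._delta_ci(psi)
        elif ci_method == "bootstrap":
            ci = self._bootstrap_ci(psi, n_boot, seed)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        slopes = np.cumsum(np.concatenate([[beta[1]], beta[2:2 + self.k]]))
        dof = max(n - p, 1)
        bic = (n * np.log(rss / n) + p * np.log(n)) if rss > 0 else -np.inf
        return SegmentedResults(
            model=self, k=self.k, psi=psi.copy(), psi_ci=ci,
            intercept=float(beta[0]), slopes=slopes, params=beta.copy(),
            rss=rss, sigma2=rss / dof, nobs=n, bic=float(bic),
            converged=converged, iterations=it, ci_method=ci_method)

    def _delta_ci(self, psi: np.ndarray) -> list[tuple[float, float]]:
        """Delta-method 95% CIs for the breakpoints from the gap/slope-change
        coefficient covariance in the full linearised design at the solution."""
        if self.k == 0:
            return []
        X = self._design(psi, with_gap=True)
        beta, _, rank, _ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ beta
        n, p = X.shape
        dof = max(n - p, 1)
        s2 = float(resid @ resid) / dof
        try:
            cov = s2 * np.linalg.inv(X.T @ X)
        except np.linalg.LinAlgError:
            return [(np.nan, np.nan)] * self.k
        z = stats.t.ppf(0.975, dof)
        out = []
        for j in range(self.k):
            b = beta[2 + j]           # slope change
            g = beta[2 + self.k + j]  # gap (~0 at convergence)
            vb = cov[2 + j, 2 + j]
            vg = cov[2 + self.k + j, 2 + self.k + j]
            cbg = cov[2 + j, 2 + self.k + j]
            if abs(b) < 1e-12:
                out.append((np.nan, np.nan))
                continue
            ratio = g / b
            var = (vg + ratio ** 2 * vb - 2 * ratio * cbg) / b ** 2
            se = np.sqrt(max(var, 0.0))
            est = psi[j] - ratio
            out.append((est + z * se, est - z * se))  # (older, younger)
        return out

    def _bootstrap_ci(self, psi: np.ndarray, n_boot: int,
                      seed: int | None) -> list[tuple[float, float]]:
        rng = np.random.default_rng(seed)
        n = len(self.x)
        draws = np.full((n_boot, self.k), np.nan)
        for b in range(n_boot):
            idx = np.sort(rng.integers(0, n, n))
            xb, yb = self.x[idx], self.y[idx]
            keep = np.concatenate([[True], np.diff(xb) > 0])
            xb, yb = xb[keep], yb[keep]
            if len(xb) < 2 * self.k + 4:
                continue
            try:
                res = SegmentedRegression(xb, yb, self.k).fit(init=psi)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if res.converged:
                draws[b] = res.psi
        out = []
        for j in range(self.k):
            col = draws[:, j]
            col = col[~np.isnan(col)]
            if len(col) < 10:
                out.append((np.nan, np.nan))
            else:
                out.append((float(np.percentile(col, 97.5)),
                            float(np.percentile(col, 2.5))))
        return out


@dataclass
class SegmentedResults:
    """Fitted segmented regression: breakpoints with 95% CIs, per-segment
    slopes, RSS and BIC."""

    model: SegmentedRegression = field(repr=False)
    k: int
    psi: np.ndarray
    psi_ci: list[tuple[float, float]]
    intercept: float
    slopes: np.ndarray
    params: np.ndarray
    rss: float
    sigma2: float
    nobs: int
    bic: float
    converged: bool
    iterations: int
    ci_method: str

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = self.intercept + self.params[1] * x
        for j, p in enumerate(self.psi):
            out = out + self.params[2 + j] * np.where(x > p, x - p, 0.0)
        return out

    def breakpoints_by_age(self) -> list[tuple[float, tuple[float, float]]]:
        """(psi, (older CI bound, younger CI bound)) ordered old to young."""
        pairs = sorted(zip(self.psi, self.psi_ci), key=lambda t: -t[0])
        return [(float(p), ci) for p, ci in pairs]

    def summary(self) -> str:
        lines = [
            f"Segmented regression, k={self.k} breakpoint(s)",
            "=" * 44,
            f"n obs:       {self.nobs}",
            f"RSS:         {self.rss:.6g}",
            f"BIC:         {self.bic:.4f}" if np.isfinite(self.bic)
            else "BIC:         -inf (perfect fit)",
            f"converged:   {self.converged} ({self.iterations} iterations)",
            f"intercept:   {self.intercept:.6g}",
            "segment slopes (ascending x): "
            + ", ".join(f"{s:.6g}" for s in self.slopes),
        ]
        for p, (o, y) in self.breakpoints_by_age():
            if np.isnan(o):
                lines.append(f"breakpoint:  {p:.4f} (CI unavailable)")
            else:
                lines.append(f"breakpoint:  {p:.4f} ({o:.4f}-{y:.4f})")
        return "\n".join(lines)


def fit_segmented(x: np.ndarray, y: np.ndarray, k: int,
                  init: np.ndarray | None = None, **kwargs) -> SegmentedResults:
    """One-shot wrapper over SegmentedRegression(x, y, k).fit(init)."""
    return SegmentedRegression(x, y, k).fit(init=init, **kwargs)


def select_changepoints(x: np.ndarray, y: np.ndarray,
                        k_candidates: tuple[int, ...] = (1, 2, 3, 4),
                        n_random_starts: int = 5, seed: int = 0,
                        ) -> tuple[SegmentedResults, pd.DataFrame]:
    """Fit every candidate breakpoint count and pick the BIC minimiser.

    Each k is fitted from the quantile initialisation plus
    ``n_random_starts`` seeded random configurations; the best-RSS fit per k
    enters the BIC table. A zero-RSS (perfect) fit short-circuits selection
    to the smallest such k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    fits: dict[int, SegmentedResults] = {}
    for k in sorted(k_candidates):
        model = SegmentedRegression(x, y, k)
        inits = [model.default_init()]
        lo, hi = model.x[1], model.x[-2]
        for _ in range(n_random_starts):
            inits.append(np.sort(lo + (hi - lo) * rng.random(k)))
        best = None
        for init in inits:
            try:
                res = model.fit(init=init)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best is None or res.rss < best.rss:
                best = res
        if best is None:
            continue
        fits[k] = best
        rows.append({"k": k, "rss": best.rss, "bic": best.bic,
                     "converged": best.converged})
    if not fits:
        raise RuntimeError("no candidate model could be fitted")
    table = pd.DataFrame(rows)
    perfect = [k for k in fits if fits[k].rss <= 1e-12]
    if perfect:
        best_k = min(perfect)
    else:
        best_k = int(table.loc[table["bic"].idxmin(), "k"])
    return fits[best_k], table
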